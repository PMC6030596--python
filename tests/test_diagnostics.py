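import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import seabird_fmr as sf
from seabird_fmr.diagnostics import (
    autocorrelation,
    compute_dic,
    heritability,
    hpd_interval,
    jackknife,
    model_selection,
    p_mcmc,
    summarize_fit,
)
from seabird_fmr.pmm_sampler import ChainConfig, ModelSpec, PriorSpec, build_design, gibbs_fit


def brute_force_hpd(draws, prob):
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    w = math.ceil(prob * n)
    best = None
    for i in range(n - w + 1):
        width = x[i + w - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + w - 1])
    return best[1], best[2]


class TestHPD:
    def test_integers_1_to_100(self):
        assert hpd_interval(np.arange(1, 101), 0.95) == (1.0, 95.0)

    def test_degenerate_sample(self):
        assert hpd_interval(np.full(20, 3.7)) == (3.7, 3.7)

    def test_symmetric_tie_break(self):
        assert hpd_interval(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]), 0.6) == (-2.0, 0.0)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hpd_interval([1.0])

    def test_bad_prob(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(20), 1.0)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200),
        st.floats(0.05, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, draws, prob):
        assert hpd_interval(draws, prob) == brute_force_hpd(draws, prob)


class TestPMCMC:
    def test_sign_balance(self):
        x = np.concatenate([np.ones(500), -np.ones(500)])
        assert p_mcmc(x) == 1.0

    def test_floor(self):
        assert p_mcmc(np.ones(1000)) == pytest.approx(0.002)

    def test_direct_count(self):
        x = np.concatenate([np.ones(950), -np.ones(50)])
        assert p_mcmc(x) == pytest.approx(0.1)

    def test_too_few(self):
        with pytest.raises(ValueError):
            p_mcmc(np.ones(5))

    @given(st.floats(0.001, 1e6), st.integers(0, 2**31))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariant_and_sign_flip(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.3, 1.0, size=200)
        base = p_mcmc(x)
        assert p_mcmc(scale * x) == base
        assert p_mcmc(-x) == base


class TestHeritability:
    def test_equal_shares(self):
        s2 = {k: np.ones(10) for k in ("phylogeny", "species", "colony", "residual")}
        h2, m, _ = heritability(s2)
        assert np.allclose(h2, 0.25) and m == pytest.approx(0.25)

    def test_zero_limit(self):
        s2 = {"phylogeny": np.full(10, 1e-300), "residual": np.ones(10)}
        _, m, _ = heritability(s2)
        assert m == pytest.approx(0.0, abs=1e-290)

    def test_exact_fraction(self):
        s2 = {"phylogeny": np.full(10, 3.0), "species": np.ones(10),
              "colony": np.ones(10), "residual": np.ones(10)}
        _, m, _ = heritability(s2)
        assert m == pytest.approx(0.5)

    def test_absent_terms_contribute_zero(self):
        s2 = {"phylogeny": np.ones(10), "residual": np.ones(10)}
        _, m, _ = heritability(s2)
        assert m == pytest.approx(0.5)

    def test_missing_phylogeny(self):
        with pytest.raises(ValueError, match="phylogeny"):
            heritability({"residual": np.ones(10)})

    def test_in_unit_interval(self, sim_obs, sim_corr, quick_spec):
        obs, _ = sim_obs
        bundle = build_design(obs, quick_spec, sim_corr)
        s = gibbs_fit(bundle, quick_spec)
        h2, m, sd = heritability(s.sigma2)
        assert ((h2 >= 0) & (h2 <= 1)).all()
        assert 0 <= m <= 1

    def test_forced_small_phylo_variance(self):
        rng = np.random.default_rng(4)
        s2 = {
            "phylogeny": np.abs(rng.normal(0, 1e-4, 500)),
            "species": np.full(500, 0.02),
            "colony": np.full(500, 0.02),
            "residual": np.full(500, 0.02),
        }
        _, m, _ = heritability(s2)
        assert m < 0.05


class TestDIC:
    def test_zero_complexity_limit(self, sim_obs, quick_spec):
        # beta and residual variance pinned -> every retained draw identical,
        # so Dbar == D(mean) and pD == 0
        obs, _ = sim_obs
        spec = ModelSpec(fixed_terms=("intercept",), random_terms=(),
                         chain=quick_spec.chain)
        bundle = build_design(obs, spec, None)
        s = gibbs_fit(bundle, spec, fix_beta=np.array([2.0]), fix_residual=0.05)
        dic, pd_ = compute_dic(s, bundle)
        assert pd_ == pytest.approx(0.0, abs=1e-9)
        assert dic == pytest.approx(s.deviance[0], rel=1e-12)

    def test_dropping_strong_slope_increases_dic(self, sim_tree):
        gt = sf.GroundTruth(
            beta={"intercept": 1.0, "log_mass": 0.64},
            sigma2={"phylogeny": 0.001, "species": 0.002, "colony": 0.002,
                    "residual": 0.01},
        )
        obs, _ = sf.simulate_observations(sim_tree, gt, 60, seed=21)
        A = sf.tree_to_correlation(sim_tree)
        chain = ChainConfig(6000, 1000, 5, seed=3)
        dics = {}
        for label, terms in {
            "with": ("intercept", "log_mass", "phase", "abs_latitude"),
            "without": ("intercept", "phase", "abs_latitude"),
        }.items():
            spec = ModelSpec(fixed_terms=terms, chain=chain)
            bundle = build_design(obs, spec, A)
            s = gibbs_fit(bundle, spec)
            dics[label], _ = compute_dic(s, bundle)
        assert dics["without"] - dics["with"] > 10

    def test_pd_nonnegative_on_well_behaved_fit(self, sim_obs, sim_corr, quick_spec):
        obs, _ = sim_obs
        bundle = build_design(obs, quick_spec, sim_corr)
        s = gibbs_fit(bundle, quick_spec)
        dic, pd_ = compute_dic(s, bundle)
        assert math.isfinite(dic)
        assert pd_ > 0


class TestAutocorrelation:
    def test_white_noise(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        rho, ess = autocorrelation(x)
        assert abs(rho[1]) < 3 / math.sqrt(2000)
        assert ess > 1000

    def test_duplicated_pairs_halve_ess(self):
        rng = np.random.default_rng(2)
        x = np.repeat(rng.standard_normal(500), 2)
        _, ess = autocorrelation(x)
        assert 0.35 * 1000 < ess < 0.65 * 1000

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            _, ess = autocorrelation(np.ones(100))
        assert ess == 100

    def test_too_short(self):
        with pytest.raises(ValueError):
            autocorrelation(np.arange(10))


class TestJackknife:
    def test_closed_form_mean_oracle(self, obs3):
        # n=2 refits: a mildly informative residual prior keeps the
        # intercept posterior's tails light enough for a tight MC check
        spec = ModelSpec(
            fixed_terms=("intercept",),
            random_terms=(),
            priors=PriorSpec(fixed_effect_prior_var=float("inf"),
                             residual_df=3.0, residual_scale=0.5),
            chain=ChainConfig(12000, 2000, 1, seed=5),
        )
        res = jackknife(obs3, spec, None, chain=spec.chain)
        est = res["estimates"]["intercept"]
        # y = {1,2,3}: leave-one-out means 2.5, 2.0, 1.5
        np.testing.assert_allclose(
            est.loc[["r0", "r1", "r2"]], [2.5, 2.0, 1.5], atol=0.05
        )
        assert res["se"]["intercept"] == pytest.approx(math.sqrt(2 / 3 * 0.5), abs=0.05)

    def test_duplication_tightens(self, obs3):
        import dataclasses

        spec = ModelSpec(
            fixed_terms=("intercept",),
            random_terms=(),
            priors=PriorSpec(fixed_effect_prior_var=float("inf")),
            chain=ChainConfig(3000, 500, 2, seed=5),
        )
        res1 = jackknife(obs3, spec, None, chain=spec.chain)
        doubled = obs3 + [dataclasses.replace(o, record_id=o.record_id + "b") for o in obs3]
        res2 = jackknife(doubled, spec, None, chain=spec.chain)
        assert res2["se"]["intercept"] < res1["se"]["intercept"]

    def test_n2_precondition(self, obs3):
        spec = ModelSpec(fixed_terms=("intercept",), random_terms=())
        with pytest.raises(ValueError, match="at least 3"):
            jackknife(obs3[:2], spec)


class TestModelSelection:
    def test_duplicate_candidates_tie(self, sim_obs, sim_corr, short_chain):
        obs, _ = sim_obs
        spec = ModelSpec(chain=short_chain)
        comp = model_selection([spec, spec], obs, sim_corr)
        assert comp.table["delta_dic"].iloc[0] == 0.0
        assert comp.table["delta_dic"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_single_candidate_rejected(self, sim_obs, quick_spec):
        obs, _ = sim_obs
        with pytest.raises(ValueError, match="2 candidate"):
            model_selection([quick_spec], obs)

    def test_failing_candidate_excluded(self, sim_obs, sim_corr, short_chain):
        obs, _ = sim_obs
        good = ModelSpec(chain=short_chain)
        # log_rpp requested but every breeding_pairs value present -> fine;
        # break a candidate instead with a retained-0 chain
        bad = ModelSpec(chain=ChainConfig(n_iter=100, burn_in=99, thin=200))
        comp = model_selection([good, good, bad], obs, sim_corr)
        assert len(comp.table) == 2
        assert len(comp.failures) == 1


class TestSummarizeFit:
    def test_degenerate_posterior(self, make_degenerate_fit):
        fit = make_degenerate_fit({"intercept": 0.92, "log_mass": 0.64}, n_draws=1000)
        summary = summarize_fit(fit)
        row = summary.terms.set_index("effect").loc["log_mass"]
        assert row["estimate"] == 0.64
        assert (row["lower_95"], row["upper_95"]) == (0.64, 0.64)
        assert row["p_mcmc"] == pytest.approx(0.002)

    def test_h2_only_with_phylogeny(self, sim_obs, sim_corr, quick_spec, short_chain):
        obs, _ = sim_obs
        bundle = build_design(obs, quick_spec, sim_corr)
        s = gibbs_fit(bundle, quick_spec)
        summary = summarize_fit(s, bundle)
        assert 0 <= summary.h2_mean <= 1
        assert summary.dic is not None

        spec2 = ModelSpec(random_terms=("species", "colony"), chain=short_chain)
        bundle2 = build_design(obs, spec2, None)
        s2 = gibbs_fit(bundle2, spec2)
        assert summarize_fit(s2, bundle2).h2_mean is None

    def test_csv_layout(self, sim_obs, sim_corr, quick_spec, tmp_path):
        obs, _ = sim_obs
        bundle = build_design(obs, quick_spec, sim_corr)
        s = gibbs_fit(bundle, quick_spec)
        summary = summarize_fit(s, bundle)
        out = tmp_path / "summary.csv"
        summary.to_csv(out)
        text = out.read_text()
        assert "effect,estimate,lower_95,upper_95,p_mcmc" in text
        assert "H2_mean" in text and "DIC" in text

    def test_single_fit_recovery_smoke(self, sim_corr, sim_obs, truth):
        obs, _ = sim_obs
        spec = ModelSpec(chain=ChainConfig(8000, 2000, 5, seed=17))
        bundle = build_design(obs, spec, sim_corr)
        s = gibbs_fit(bundle, spec)
        summary = summarize_fit(s, bundle)
        row = summary.terms.set_index("effect").loc["log_mass"]
        assert row["lower_95"] <= truth.beta["log_mass"] <= row["upper_95"]
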