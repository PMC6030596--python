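import numpy as np
import pytest

import seabird_fmr as sf
from seabird_fmr.pmm_sampler import ChainConfig, ModelSpec, PriorSpec


def _parse(s):
    from seabird_fmr.phylogeny import parse_newick

    return parse_newick(s)


@pytest.fixture(scope="session")
def small_tree():
    return _parse("(((A:1,B:1):1,(C:1.5,D:0.5):1):1,(E:2,F:2):1);")


@pytest.fixture(scope="session")
def cherry_tree():
    return _parse("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def sim_tree():
    return sf.simulate_tree(12, seed=42)


@pytest.fixture(scope="session")
def sim_corr(sim_tree):
    return sf.tree_to_correlation(sim_tree)


@pytest.fixture(scope="session")
def truth():
    return sf.GroundTruth(
        beta=dict(sf.synthetic_data.DEFAULT_BETA),
        sigma2={"phylogeny": 0.004, "species": 0.008, "colony": 0.008, "residual": 0.02},
    )


@pytest.fixture(scope="session")
def sim_obs(sim_tree, truth):
    obs, latents = sf.simulate_observations(sim_tree, truth, n_records=60, seed=11)
    return obs, latents


@pytest.fixture
def short_chain():
    return ChainConfig(n_iter=2600, burn_in=600, thin=2, seed=7)


@pytest.fixture
def quick_spec(short_chain):
    return ModelSpec(chain=short_chain)


@pytest.fixture
def flat_priors():
    return PriorSpec(fixed_effect_prior_var=float("inf"))


@pytest.fixture
def make_degenerate_fit():
    """Posterior with every draw pinned at given values (constant draws)."""

    def factory(beta_means, sigma2=None, n_draws=1000, log_base=10.0):
        from seabird_fmr.pmm_sampler import PosteriorSamples

        names = list(beta_means)
        beta = np.tile(np.array([beta_means[k] for k in names]), (n_draws, 1))
        sigma2 = sigma2 or {"residual": 0.0}
        return PosteriorSamples(
            beta=beta,
            beta_names=names,
            sigma2={k: np.full(n_draws, v) for k, v in sigma2.items()},
            deviance=np.zeros(n_draws),
            effects={},
            species_levels=[],
            colony_levels=[],
            meta={"log_base": log_base},
        )

    return factory


@pytest.fixture
def obs3():
    """Three hand-built records with log10 FMR exactly 1, 2, 3."""
    return [
        sf.FMRObservation(
            record_id=f"r{i}",
            study_id=f"s{i}",
            species="Sterna paradisaea",
            colony="colony_x",
            latitude_deg=60.0,
            phase="brood",
            mass_g=100.0,
            fmr_kj_day=10.0 ** (i + 1),
        )
        for i in range(3)
    ]
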