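"""Posterior summaries, DIC model selection, heritability, chain and
jackknife diagnostics."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .phylogeny import PhyloCorrelation
from .pmm_sampler import (
    ChainConfig,
    DesignBundle,
    ModelSpec,
    PosteriorSamples,
    build_design,
    gibbs_fit,
)

__all__ = [
    "hpd_interval",
    "p_mcmc",
    "heritability",
    "compute_dic",
    "autocorrelation",
    "jackknife",
    "model_selection",
    "summarize_fit",
    "FitSummary",
    "ModelComparison",
]

#: Reduced chain used for leave-one-out refits, overridable by callers.
JACKKNIFE_CHAIN = ChainConfig(n_iter=26_000, burn_in=6_000, thin=20, seed=0)


def hpd_interval(draws, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of the sorted draws containing
    ``ceil(prob * n)`` of them; ties broken by the lowest start index."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws for an HPD interval")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    w = math.ceil(prob * n)
    if w > n:
        raise ValueError("window larger than sample")
    widths = x[w - 1:] - x[: n - w + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: lowest start
    return float(x[i]), float(x[i + w - 1])


def p_mcmc(draws) -> float:
    """Two-tailed posterior sign statistic: 2*min(P(>0), P(<0)),
    floored at 2/n and capped at 1."""
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws")
    frac_pos = np.mean(x > 0)
    frac_neg = np.mean(x < 0)
    return float(min(1.0, max(2.0 * min(frac_pos, frac_neg), 2.0 / n)))


def heritability(sigma2: dict[str, np.ndarray]) -> tuple[np.ndarray, float, float]:
    """Per-draw phylogenetic heritability H2 = sigma2_phylo / total
    random + residual variance; absent terms contribute 0.

    Returns (per-draw H2, mean, sd).
    """
    if "phylogeny" not in sigma2:
        raise ValueError("fit has no phylogeny variance component")
    num = np.asarray(sigma2["phylogeny"], dtype=float)
    denom = num.copy()
    for term in ("species", "colony", "residual"):
        if term in sigma2:
            denom = denom + np.asarray(sigma2[term], dtype=float)
    h2 = num / denom
    return h2, float(h2.mean()), float(h2.std(ddof=1)) if h2.size > 1 else 0.0


def _conditional_deviance(
    bundle: DesignBundle, beta: np.ndarray, effects: dict[str, np.ndarray], s2r: float
) -> float:
    fitted = bundle.X @ beta
    for term in bundle.random_terms:
        idx = bundle.species_idx if term in ("phylogeny", "species") else bundle.colony_idx
        fitted = fitted + effects[term][idx]
    e = bundle.y - fitted
    n = bundle.n
    return n * (math.log(2.0 * math.pi) + math.log(s2r)) + float(e @ e) / s2r


def compute_dic(samples: PosteriorSamples, bundle: DesignBundle) -> tuple[float, float]:
    """DIC = Dbar + pD with pD = Dbar - D(posterior means); deviance is
    conditional on the realized random effects, matching the sampler.

    Returns (DIC, pD).  A negative pD is kept and logged, never clipped.
    """
    dbar = float(samples.deviance.mean())
    beta_hat = samples.beta.mean(axis=0)
    eff_hat = {t: samples.effects[t].mean(axis=0) for t in bundle.random_terms}
    s2r_hat = float(samples.sigma2["residual"].mean())
    d_hat = _conditional_deviance(bundle, beta_hat, eff_hat, s2r_hat)
    if not math.isfinite(d_hat):
        raise FloatingPointError("deviance at posterior-mean parameters is not finite")
    pd_ = dbar - d_hat
    if pd_ < 0:
        warnings.warn(f"negative DIC complexity pD={pd_:.3g}", stacklevel=2)
    return dbar + pd_, pd_


def autocorrelation(draws, max_lag: int | None = None) -> tuple[np.ndarray, float]:
    """Normalized autocovariance up to ``max_lag`` plus an effective
    sample size via initial-positive-sequence truncation."""
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 50:
        raise ValueError("need at least 50 draws")
    if max_lag is None:
        max_lag = min(n - 1, 100)
    var = x.var()
    if var == 0:
        warnings.warn("constant series: ESS reported as draw count", stacklevel=2)
        return np.zeros(max_lag + 1), float(n)
    xc = x - x.mean()
    full = np.correlate(xc, xc, mode="full")[n - 1:]
    rho = full[: max_lag + 1] / full[0]
    tail = 0.0
    for k in range(1, max_lag + 1):
        if rho[k] <= 0:
            break
        tail += rho[k]
    ess = n / (1.0 + 2.0 * tail)
    return rho, float(ess)


@dataclass
class FitSummary:
    """Posterior-summary table: per-term mean, 95% HPD, p_MCMC;
    variance-component means; heritability; DIC."""

    terms: pd.DataFrame  # columns: effect, estimate, lower_95, upper_95, p_mcmc
    variance_means: dict[str, float]
    h2_mean: float | None
    h2_sd: float | None
    dic: float | None
    pd_: float | None
    n_draws: int
    log_base: object = 10.0

    def to_csv(self, path) -> None:
        self.terms.to_csv(path, index=False)
        extras = pd.DataFrame(
            {
                "key": ["H2_mean", "H2_sd", "DIC", "pD", "n_draws", "log_base"]
                + [f"sigma2_{k}" for k in self.variance_means],
                "value": [self.h2_mean, self.h2_sd, self.dic, self.pd_, self.n_draws,
                          self.log_base]
                + list(self.variance_means.values()),
            }
        )
        with open(path, "a", encoding="utf-8") as fh:
            fh.write("\n")
            extras.to_csv(fh, index=False)


def summarize_fit(
    samples: PosteriorSamples,
    bundle: DesignBundle | None = None,
    prob: float = 0.95,
) -> FitSummary:
    """Tabulate the posterior (mean, HPD, p_MCMC per fixed term, variance
    means, heritability when the phylogeny term is present, DIC when the
    design bundle is supplied)."""
    rows = []
    for j, name in enumerate(samples.beta_names):
        d = samples.beta[:, j]
        lo, hi = hpd_interval(d, prob)
        rows.append(
            {
                "effect": name,
                "estimate": float(d.mean()),
                "lower_95": lo,
                "upper_95": hi,
                "p_mcmc": p_mcmc(d),
            }
        )
    var_means = {k: float(v.mean()) for k, v in samples.sigma2.items()}
    h2_mean = h2_sd = None
    if "phylogeny" in samples.sigma2:
        _, h2_mean, h2_sd = heritability(samples.sigma2)
    dic = pd_ = None
    if bundle is not None:
        dic, pd_ = compute_dic(samples, bundle)
    return FitSummary(
        terms=pd.DataFrame(rows),
        variance_means=var_means,
        h2_mean=h2_mean,
        h2_sd=h2_sd,
        dic=dic,
        pd_=pd_,
        n_draws=samples.n_draws,
        log_base=samples.meta.get("log_base", 10.0),
    )


@dataclass
class ModelComparison:
    """Per-candidate DIC table; best model has delta_dic == 0."""

    table: pd.DataFrame  # columns: model, n_fixed_terms, dic, delta_dic
    best: ModelSpec
    failures: list[tuple[str, str]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def model_selection(
    candidates: Sequence[ModelSpec],
    observations,
    A: PhyloCorrelation | None = None,
) -> ModelComparison:
    """Fit each candidate, rank by DIC; ties broken by fewest fixed
    terms (the simplest competitive model wins).  Individual candidate
    failures are recorded and skipped as long as >= 2 candidates fit."""
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    rows = []
    fitted: list[ModelSpec] = []
    failures: list[tuple[str, str]] = []
    for spec in candidates:
        label = spec.label()
        try:
            bundle = build_design(observations, spec, A)
            samples = gibbs_fit(bundle, spec)
            dic, _ = compute_dic(samples, bundle)
        except Exception as exc:  # failed candidate: record, keep going
            failures.append((label, str(exc)))
            continue
        rows.append({"model": label, "n_fixed_terms": len(spec.fixed_terms), "dic": dic})
        fitted.append(spec)
    if len(rows) < 2:
        raise RuntimeError(
            f"fewer than 2 candidates fit successfully: {failures}"
        )
    tab = pd.DataFrame(rows)
    order = np.lexsort((tab["n_fixed_terms"].to_numpy(), tab["dic"].to_numpy()))
    best_i = int(order[0])
    tab["delta_dic"] = tab["dic"] - tab["dic"].iloc[best_i]
    tab = tab.iloc[order].reset_index(drop=True)
    return ModelComparison(table=tab, best=fitted[best_i], failures=failures)


def jackknife(
    observations,
    spec: ModelSpec,
    A: PhyloCorrelation | None = None,
    chain: ChainConfig | None = None,
) -> dict:
    """Leave-one-record-out refits.

    Returns a dict with per-held-out posterior-mean coefficient vectors
    (rows aligned to held-out record ids), the jackknife mean and the
    jackknife standard error sqrt((n-1)/n * sum((theta_i - theta_bar)^2)).
    Failed refits are recorded with a reason, not fatal.
    """
    observations = list(observations)
    n = len(observations)
    if n < 3:
        raise ValueError("jackknife needs at least 3 records")
    chain = chain or replace(JACKKNIFE_CHAIN, seed=spec.chain.seed)
    jk_spec = replace(spec, chain=chain)
    est_rows = {}
    failures = {}
    names: list[str] | None = None
    for i in range(n):
        subset = observations[:i] + observations[i + 1:]
        rid = observations[i].record_id
        try:
            bundle = build_design(subset, jk_spec, A)
            samples = gibbs_fit(bundle, jk_spec)
            est_rows[rid] = samples.beta.mean(axis=0)
            names = samples.beta_names
        except Exception as exc:
            failures[rid] = str(exc)
    if not est_rows:
        raise RuntimeError(f"all jackknife refits failed: {failures}")
    est = pd.DataFrame.from_dict(est_rows, orient="index", columns=names)
    m = len(est)
    theta_bar = est.mean(axis=0)
    se = np.sqrt((m - 1) / m * ((est - theta_bar) ** 2).sum(axis=0))
    return {
        "estimates": est,
        "mean": theta_bar,
        "se": se,
        "failures": failures,
    }
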