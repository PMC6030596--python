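"""Gibbs sampler for the Gaussian phylogenetic mixed model.

Model (on the log scale):

    y = X beta + Z_phylo u_p + Z_species u_s + Z_colony u_c + e

with u_p ~ N(0, sigma2_p * A) for the shared-ancestry term, the other
random effects iid Gaussian, and e ~ N(0, sigma2_r * I).  Random-effect
variances carry parameter-expanded priors: each effect vector is stored
as alpha * eta where eta has an inverse-Gamma-scaled variance and alpha
is a working scalar regression coefficient with its own Gaussian prior.
The induced prior on the effect standard deviation is heavy-tailed
(approximately half-t), which mixes well when a variance is near zero.

All conditionals are conjugate, so one sweep is: fixed effects (joint
Gaussian), each eta (Gaussian, A-structured precision for the phylogeny
term), each alpha (scalar Gaussian), each expanded variance and the
residual variance (inverse-Gamma).  A single seeded RNG stream drives
the whole chain.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .data_model import FMRObservation, predictor_frame
from .phylogeny import PhyloCorrelation, correlation_inverse

__all__ = [
    "FIXED_TERMS",
    "RANDOM_TERMS",
    "PriorSpec",
    "ChainConfig",
    "ModelSpec",
    "DesignBundle",
    "PosteriorSamples",
    "build_design",
    "gibbs_fit",
]

#: Canonical fixed-term order; "phase" expands to two dummies
#: (brood is the baseline level).
FIXED_TERMS = ("intercept", "log_mass", "phase", "abs_latitude", "brood_size", "log_rpp")
RANDOM_TERMS = ("phylogeny", "species", "colony")


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters; defaults are conventional weakly informative
    choices (inverse-Gamma scale/df and the working-parameter Gaussian),
    all configurable."""

    residual_scale: float = 1.0
    residual_df: float = 0.002
    re_scale: float = 1.0
    re_df: float = 1.0
    expansion_mean: float = 0.0
    expansion_var: float = 625.0
    fixed_effect_prior_var: float = 1e8

    def __post_init__(self) -> None:
        for name in ("residual_scale", "residual_df", "re_scale", "re_df", "expansion_var"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.fixed_effect_prior_var > 0:
            raise ValueError("fixed_effect_prior_var must be > 0")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC schedule.  Defaults follow the 260k/60k/200 convention."""

    n_iter: int = 260_000
    burn_in: int = 60_000
    thin: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass(frozen=True)
class ModelSpec:
    fixed_terms: tuple[str, ...] = ("intercept", "log_mass", "phase", "abs_latitude")
    random_terms: tuple[str, ...] = ("phylogeny", "species", "colony")
    priors: PriorSpec = field(default_factory=PriorSpec)
    chain: ChainConfig = field(default_factory=ChainConfig)
    log_base: float = 10.0

    def __post_init__(self) -> None:
        bad = set(self.fixed_terms) - set(FIXED_TERMS)
        if bad:
            raise ValueError(f"unknown fixed term(s): {sorted(bad)}")
        bad = set(self.random_terms) - set(RANDOM_TERMS)
        if bad:
            raise ValueError(f"unknown random term(s): {sorted(bad)}")
        if "intercept" not in self.fixed_terms:
            raise ValueError("intercept must always be included")
        if self.log_base not in (10.0, math.e):
            raise ValueError("log_base must be 10 or e")

    def label(self) -> str:
        return "+".join(t for t in FIXED_TERMS if t in self.fixed_terms)


@dataclass
class DesignBundle:
    """Numeric design assembled from observations + model spec."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    species_levels: list[str]
    species_idx: np.ndarray
    colony_levels: list[str]
    colony_idx: np.ndarray
    random_terms: tuple[str, ...]
    A: PhyloCorrelation | None  # subset to species_levels, same order

    @property
    def n(self) -> int:
        return len(self.y)

    def fingerprint(self) -> dict:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.y).tobytes())
        h.update(np.ascontiguousarray(self.X).tobytes())
        return {"n_records": int(self.n), "column_hash": h.hexdigest()[:16]}


def build_design(
    observations: Sequence[FMRObservation],
    spec: ModelSpec,
    A: PhyloCorrelation | None = None,
) -> DesignBundle:
    """Build response, fixed-effect matrix and random-effect groupings.

    The phylogeny and species terms share the species grouping; the
    phylogeny term is correlated through ``A`` (subset and reordered to
    the observed species), the species term is iid.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("no observations")
    use_phylo = "phylogeny" in spec.random_terms
    if use_phylo and A is None:
        raise ValueError("phylogeny random term requires a PhyloCorrelation")

    pf = predictor_frame(
        observations,
        spec.log_base,
        need_rpp="log_rpp" in spec.fixed_terms,
        need_brood="brood_size" in spec.fixed_terms,
    )
    y = pf["log_fmr"].to_numpy(dtype=float)

    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in FIXED_TERMS:
        if term not in spec.fixed_terms:
            continue
        if term == "intercept":
            cols.append(np.ones(len(pf)))
            names.append("intercept")
        elif term == "phase":
            cols.append(pf["phase_incubation"].to_numpy(dtype=float))
            names.append("phase_incubation")
            cols.append(pf["phase_creche"].to_numpy(dtype=float))
            names.append("phase_creche")
        else:
            cols.append(pf[term].to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    for j, name in enumerate(names):
        if name != "intercept" and np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor column {name!r} is constant (unidentifiable)")

    species_keys = [o.species_key for o in observations]
    if use_phylo:
        missing = sorted(set(species_keys) - set(A.tip_order))
        if missing:
            raise ValueError(f"species missing from correlation matrix: {', '.join(missing)}")
        # order species levels by tree tip order for a stable A subset
        present = set(species_keys)
        species_levels = [t for t in A.tip_order if t in present]
        A_sub = A.submatrix(species_levels)
    else:
        species_levels = sorted(set(species_keys))
        A_sub = None
    sp_pos = {s: i for i, s in enumerate(species_levels)}
    species_idx = np.array([sp_pos[s] for s in species_keys], dtype=np.intp)

    colony_levels = sorted({o.colony for o in observations})
    co_pos = {c: i for i, c in enumerate(colony_levels)}
    colony_idx = np.array([co_pos[o.colony] for o in observations], dtype=np.intp)

    return DesignBundle(
        y=y,
        X=X,
        x_names=names,
        species_levels=species_levels,
        species_idx=species_idx,
        colony_levels=colony_levels,
        colony_idx=colony_idx,
        random_terms=tuple(t for t in RANDOM_TERMS if t in spec.random_terms),
        A=A_sub,
    )


@dataclass
class PosteriorSamples:
    """Retained draws from one chain."""

    beta: np.ndarray  # (n_draws, p)
    beta_names: list[str]
    sigma2: dict[str, np.ndarray]  # per-term effective variance + "residual"
    deviance: np.ndarray
    effects: dict[str, np.ndarray]  # per-term (n_draws, q) effect draws
    species_levels: list[str]
    colony_levels: list[str]
    meta: dict

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def beta_draws(self, name: str) -> np.ndarray:
        try:
            j = self.beta_names.index(name)
        except ValueError:
            raise KeyError(f"fit has no fixed term {name!r}") from None
        return self.beta[:, j]

    def draws_frame(self) -> pd.DataFrame:
        """Flat table of retained draws, one column per parameter."""
        data = {f"beta.{n}": self.beta[:, j] for j, n in enumerate(self.beta_names)}
        for term, draws in self.sigma2.items():
            data[f"sigma2.{term}"] = draws
        data["deviance"] = self.deviance
        return pd.DataFrame(data)

    def save(self, csv_path, meta_path) -> None:
        self.draws_frame().to_csv(csv_path, index=False)
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump(self.meta, fh, indent=2, default=str)


def _invgamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def gibbs_fit(
    bundle: DesignBundle,
    spec: ModelSpec,
    *,
    fix_beta: np.ndarray | None = None,
    fix_residual: float | None = None,
) -> PosteriorSamples:
    """Run the Gibbs chain defined by ``spec`` on ``bundle``.

    ``fix_beta`` / ``fix_residual`` pin the fixed effects or residual
    variance (used by oracle tests and closed-form checks); both default
    to full sampling.
    """
    chain = spec.chain
    if chain.n_retained < 1:
        raise ValueError("chain config retains 0 draws")
    pr = spec.priors
    rng = np.random.default_rng(chain.seed)

    y, X = bundle.y, bundle.X
    n, p = X.shape
    XtX = X.T @ X
    prior_prec_beta = (
        0.0 if np.isinf(pr.fixed_effect_prior_var) else 1.0 / pr.fixed_effect_prior_var
    )

    terms = list(bundle.random_terms)
    n_terms = len(terms)
    idx_of = {"phylogeny": bundle.species_idx, "species": bundle.species_idx,
              "colony": bundle.colony_idx}
    q_of = {"phylogeny": len(bundle.species_levels), "species": len(bundle.species_levels),
            "colony": len(bundle.colony_levels)}
    counts = {t: np.bincount(idx_of[t], minlength=q_of[t]).astype(float) for t in terms}
    Ainv = correlation_inverse(bundle.A) if "phylogeny" in terms else None

    # state
    beta = np.zeros(p) if fix_beta is None else np.asarray(fix_beta, dtype=float).copy()
    if fix_beta is not None and beta.shape != (p,):
        raise ValueError(f"fix_beta must have shape ({p},)")
    eta = {t: np.zeros(q_of[t]) for t in terms}
    alpha = {t: 1.0 for t in terms}
    sig2eta = {t: pr.re_scale for t in terms}
    s2r = pr.residual_scale if fix_residual is None else float(fix_residual)

    n_draws = chain.n_retained
    out_beta = np.empty((n_draws, p))
    out_sigma2 = {t: np.empty(n_draws) for t in terms}
    out_sigma2["residual"] = np.empty(n_draws)
    out_dev = np.empty(n_draws)
    out_eff = {t: np.empty((n_draws, q_of[t])) for t in terms}

    log2pi = math.log(2.0 * math.pi)
    draw = 0
    for it in range(chain.n_iter):
        # total random-effect contribution per record
        contrib = np.zeros(n)
        for t in terms:
            contrib += alpha[t] * eta[t][idx_of[t]]

        # --- fixed effects ---
        if fix_beta is None:
            r = y - contrib
            P = XtX / s2r
            if prior_prec_beta > 0:
                P = P + prior_prec_beta * np.eye(p)
            b = X.T @ r / s2r
            L = np.linalg.cholesky(P)
            mean = np.linalg.solve(P, b)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(L.T, z)
        xb = X @ beta

        # --- random-effect vectors (eta then working scalar alpha) ---
        for t in terms:
            idx = idx_of[t]
            contrib -= alpha[t] * eta[t][idx]
            r = y - xb - contrib  # residual excluding this term
            gsum = np.bincount(idx, weights=r, minlength=q_of[t])
            a = alpha[t]
            if t == "phylogeny":
                q = q_of[t]
                P = Ainv / sig2eta[t]
                P.flat[:: q + 1] += (a * a / s2r) * counts[t]
                b = a * gsum / s2r
                L = np.linalg.cholesky(P)
                # mean via two triangular solves, then add L^{-T} z
                half = solve_triangular(L, b, lower=True, check_finite=False)
                z = rng.standard_normal(q)
                eta[t] = solve_triangular(
                    L, half + z, lower=True, trans="T", check_finite=False
                )
            else:
                d = (a * a / s2r) * counts[t] + 1.0 / sig2eta[t]
                mean = (a / s2r) * gsum / d
                eta[t] = mean + rng.standard_normal(q_of[t]) / np.sqrt(d)
            w = eta[t][idx]
            prec_a = w @ w / s2r + 1.0 / pr.expansion_var
            mean_a = (w @ r / s2r + pr.expansion_mean / pr.expansion_var) / prec_a
            alpha[t] = mean_a + rng.standard_normal() / math.sqrt(prec_a)
            contrib += alpha[t] * eta[t][idx]

        # --- variances ---
        for t in terms:
            quad = eta[t] @ Ainv @ eta[t] if t == "phylogeny" else eta[t] @ eta[t]
            sig2eta[t] = _invgamma(
                rng, 0.5 * (pr.re_df + q_of[t]), 0.5 * (pr.re_df * pr.re_scale + quad)
            )
        e = y - xb - contrib
        sse = e @ e
        if fix_residual is None:
            s2r = _invgamma(
                rng, 0.5 * (pr.residual_df + n), 0.5 * (pr.residual_df * pr.residual_scale + sse)
            )
        if not (math.isfinite(s2r) and s2r > 0):
            raise FloatingPointError(f"non-finite residual variance at iteration {it}")

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0 and draw < n_draws:
            out_beta[draw] = beta
            for t in terms:
                out_sigma2[t][draw] = alpha[t] * alpha[t] * sig2eta[t]
                out_eff[t][draw] = alpha[t] * eta[t]
            out_sigma2["residual"][draw] = s2r
            out_dev[draw] = n * (log2pi + math.log(s2r)) + sse / s2r
            draw += 1

    meta = {
        "fixed_terms": list(spec.fixed_terms),
        "random_terms": list(spec.random_terms),
        "beta_names": list(bundle.x_names),
        "log_base": "e" if spec.log_base == math.e else spec.log_base,
        "chain": asdict(chain),
        "priors": asdict(pr),
        "data": bundle.fingerprint(),
        "correlation_scaling": "correlation (unit diagonal)",
        "deviance": "conditional on realized random effects",
    }
    return PosteriorSamples(
        beta=out_beta[:draw],
        beta_names=list(bundle.x_names),
        sigma2={k: v[:draw] for k, v in out_sigma2.items()},
        deviance=out_dev[:draw],
        effects={k: v[:draw] for k, v in out_eff.items()},
        species_levels=list(bundle.species_levels),
        colony_levels=list(bundle.colony_levels),
        meta=meta,
    )
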