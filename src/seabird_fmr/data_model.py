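"""Observation records for field-metabolic-rate (FMR) meta-analysis.

Each record is one published FMR measurement: a species, a breeding
colony, the phase of the breeding season, the mean bird mass and the
daily FMR, plus optional brood size and colony breeding-pair count.
This module reads/writes the tabular CSV schema and derives the model
predictors (log mass, absolute latitude, phase dummies, colony-relative
predation pressure) from validated records.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "FMRObservation",
    "PredictorRow",
    "SchemaError",
    "ValidationError",
    "normalize_species",
    "read_fmr_table",
    "write_fmr_table",
    "derive_predictors",
    "predictor_frame",
]

#: Allowed breeding-phase levels.  "brood" is the model baseline.
PHASES = ("incubation", "brood", "creche")

#: Required CSV columns, in canonical order.
CSV_COLUMNS = (
    "record_id",
    "study_id",
    "species",
    "colony",
    "latitude_deg",
    "phase",
    "mass_g",
    "fmr_kj_day",
    "brood_size",
    "breeding_pairs",
)

_REQUIRED_COLUMNS = tuple(c for c in CSV_COLUMNS if c not in ("brood_size", "breeding_pairs"))


class SchemaError(ValueError):
    """The table is structurally wrong (missing column, empty file...)."""


class ValidationError(ValueError):
    """A record violates a field invariant."""


def normalize_species(name: str) -> str:
    """Canonical species key: trim, collapse whitespace to ``_``, lowercase.

    Used identically for observation tables and tree tip labels so the
    two sides join reliably.
    """
    return re.sub(r"\s+", "_", str(name).strip()).lower()


def _normalize_phase(raw: str) -> str:
    p = str(raw).strip().lower()
    # tolerate the accented spelling used in print
    if p in ("crèche", "creche"):
        return "creche"
    return p


@dataclass(frozen=True)
class FMRObservation:
    """One literature FMR record.

    Raises :class:`ValidationError` at construction if any field
    invariant fails.
    """

    record_id: str
    species: str
    colony: str
    latitude_deg: float
    phase: str
    mass_g: float
    fmr_kj_day: float
    study_id: str = ""
    brood_size: float | None = None
    breeding_pairs: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", _normalize_phase(self.phase))
        if self.phase not in PHASES:
            raise ValidationError(
                f"record {self.record_id!r}: phase {self.phase!r} not one of {list(PHASES)}"
            )
        if not -90.0 <= float(self.latitude_deg) <= 90.0:
            raise ValidationError(
                f"record {self.record_id!r}: latitude_deg {self.latitude_deg} outside [-90, 90]"
            )
        if not float(self.mass_g) > 0:
            raise ValidationError(f"record {self.record_id!r}: mass_g must be > 0")
        if not float(self.fmr_kj_day) > 0:
            raise ValidationError(f"record {self.record_id!r}: fmr_kj_day must be > 0")
        if self.brood_size is not None and float(self.brood_size) < 0:
            raise ValidationError(f"record {self.record_id!r}: brood_size must be >= 0")
        if self.breeding_pairs is not None and not float(self.breeding_pairs) > 0:
            raise ValidationError(f"record {self.record_id!r}: breeding_pairs must be > 0")

    @property
    def species_key(self) -> str:
        return normalize_species(self.species)


@dataclass(frozen=True)
class PredictorRow:
    """Model-ready transforms of one observation."""

    log_mass: float
    abs_latitude: float
    phase_incubation: int
    phase_creche: int
    log_fmr: float
    brood_size: float | None = None
    log_rpp: float | None = None


def _log(x: float, base: float) -> float:
    return math.log(x) if base == math.e else math.log(x) / math.log(base)


def derive_predictors(
    obs: FMRObservation,
    log_base: float = 10.0,
    *,
    need_rpp: bool = False,
    need_brood: bool = False,
) -> PredictorRow:
    """Derive the predictor transforms for one observation.

    ``log_rpp`` is the colony-relative predation pressure,
    log(breeding_pairs * mass_g**(2/3)).  If ``need_rpp`` (resp.
    ``need_brood``) is set and the underlying field is absent, a
    :class:`ValidationError` is raised rather than emitting NA.
    """
    if log_base not in (10.0, math.e):
        raise ValueError("log_base must be 10 or e")
    if need_rpp and obs.breeding_pairs is None:
        raise ValidationError(
            f"record {obs.record_id!r}: log_rpp term unavailable (breeding_pairs missing)"
        )
    if need_brood and obs.brood_size is None:
        raise ValidationError(
            f"record {obs.record_id!r}: brood_size term unavailable (brood_size missing)"
        )
    log_rpp = None
    if obs.breeding_pairs is not None:
        log_rpp = _log(float(obs.breeding_pairs) * float(obs.mass_g) ** (2.0 / 3.0), log_base)
    return PredictorRow(
        log_mass=_log(float(obs.mass_g), log_base),
        abs_latitude=abs(float(obs.latitude_deg)),
        phase_incubation=int(obs.phase == "incubation"),
        phase_creche=int(obs.phase == "creche"),
        log_fmr=_log(float(obs.fmr_kj_day), log_base),
        brood_size=None if obs.brood_size is None else float(obs.brood_size),
        log_rpp=log_rpp,
    )


def predictor_frame(
    observations: Sequence[FMRObservation],
    log_base: float = 10.0,
    *,
    need_rpp: bool = False,
    need_brood: bool = False,
) -> pd.DataFrame:
    """Vector form of :func:`derive_predictors` over a record collection."""
    rows = [
        derive_predictors(o, log_base, need_rpp=need_rpp, need_brood=need_brood)
        for o in observations
    ]
    return pd.DataFrame([vars(r) for r in rows])


def _parse_optional(value, record_id: str, column: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValidationError(f"record {record_id!r}: non-numeric {column}={value!r}") from exc


def read_fmr_table(path) -> list[FMRObservation]:
    """Read and validate an FMR observation CSV.

    Every row is checked against the :class:`FMRObservation` invariants;
    row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out: list[FMRObservation] = []
    for _, row in df.iterrows():
        rid = row["record_id"]
        try:
            out.append(
                FMRObservation(
                    record_id=rid,
                    study_id=row.get("study_id", ""),
                    species=row["species"],
                    colony=row["colony"],
                    latitude_deg=float(row["latitude_deg"]),
                    phase=row["phase"],
                    mass_g=float(row["mass_g"]),
                    fmr_kj_day=float(row["fmr_kj_day"]),
                    brood_size=_parse_optional(row.get("brood_size"), rid, "brood_size"),
                    breeding_pairs=_parse_optional(
                        row.get("breeding_pairs"), rid, "breeding_pairs"
                    ),
                )
            )
        except ValueError as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ValidationError(f"record {rid!r}: {exc}") from exc
    return out


def write_fmr_table(observations: Iterable[FMRObservation], path) -> None:
    """Write observations to the canonical CSV schema (empty cell = absent)."""
    observations = list(observations)
    if not observations:
        raise ValueError("cannot write an empty observation table")
    rows = []
    for o in observations:
        rows.append(
            {
                "record_id": o.record_id,
                "study_id": o.study_id,
                "species": o.species,
                "colony": o.colony,
                "latitude_deg": o.latitude_deg,
                "phase": o.phase,
                "mass_g": o.mass_g,
                "fmr_kj_day": o.fmr_kj_day,
                "brood_size": "" if o.brood_size is None else o.brood_size,
                "breeding_pairs": "" if o.breeding_pairs is None else o.breeding_pairs,
            }
        )
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)
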