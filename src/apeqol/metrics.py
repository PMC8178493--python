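"""Derived acoustic metrics: the 15 analyzed parameters per session.

From the six corner-vowel formants (F1 and F2 of /ɑ/, /i/, /u/) the module
derives:

* FCR, the formant centralization ratio of Sapir et al.:
  ``(F2_U + F2_A + F1_I + F1_U) / (F2_I + F1_A)`` — dimensionless,
  scale-invariant, and exactly 2 when the vowel triangle collapses to a
  point;
* VSA, the vowel space area (the triangle area in the F1-F2 plane, Hz²),
  and Joos-VSA, its base-10 logarithm;
* per-vowel compact-diffuse (CD) and grave-acute (GA) distinctive-feature
  correlates.  The defaults treat CD as formant proximity (F2 - F1) and GA
  as spectral balance ((F1 + F2) / 2); both are swappable via
  :class:`MetricFormulas` without touching callers.

Together with the six raw formants these make the 15-entry feature vector
consumed by the marker-screening SVMs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .formants import FormantProfile
from .synthetic import VOWELS

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "MetricFormulas",
    "compute_fcr",
    "compute_vsa",
    "compute_joos_vsa",
    "compute_cd",
    "compute_ga",
    "build_feature_vector",
    "feature_table",
]

#: Canonical order of the 15 analyzed acoustic parameters.
FEATURE_NAMES = (
    "F1_A", "F1_I", "F1_U",
    "F2_A", "F2_I", "F2_U",
    "FCR", "VSA", "JoosVSA",
    "CD_A", "CD_I", "CD_U",
    "GA_A", "GA_I", "GA_U",
)


@dataclass(frozen=True)
class MetricFormulas:
    """Config point for the distinctive-feature correlates."""

    cd: Callable[[float, float], float] = field(default=lambda f1, f2: f2 - f1)
    ga: Callable[[float, float], float] = field(default=lambda f1, f2: (f1 + f2) / 2.0)


DEFAULT_FORMULAS = MetricFormulas()


@dataclass(frozen=True)
class FeatureVector:
    """The 15 analyzed acoustic parameters of one session.

    ``JoosVSA`` is NaN when VSA = 0 (collinear vowels); any NaN marks the
    vector incomplete and excludes the session from model training.
    """

    values: dict

    def __post_init__(self) -> None:
        if set(self.values) != set(FEATURE_NAMES):
            raise ValueError("feature vector must carry exactly the 15 canonical metrics")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=float)

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))


def _six(profile: FormantProfile) -> dict[str, float]:
    vals = {}
    for v in VOWELS:
        vals[f"F1_{v}"] = float(profile.f1(v))
        vals[f"F2_{v}"] = float(profile.f2(v))
    if any(not math.isfinite(x) or x <= 0 for x in vals.values()):
        raise ValueError("profile contains missing or non-positive formants")
    return vals


def compute_fcr(profile: FormantProfile) -> float:
    """Formant centralization ratio (dimensionless, scale-invariant)."""
    f = _six(profile)
    denom = f["F2_I"] + f["F1_A"]
    if denom <= 0:
        raise ValueError("FCR denominator must be positive")
    return (f["F2_U"] + f["F2_A"] + f["F1_I"] + f["F1_U"]) / denom


def compute_vsa(profile: FormantProfile) -> float:
    """Vowel space area: triangle area of the three vowels in the F1-F2 plane (Hz²)."""
    f = _six(profile)
    return 0.5 * abs(
        f["F1_I"] * (f["F2_A"] - f["F2_U"])
        + f["F1_A"] * (f["F2_U"] - f["F2_I"])
        + f["F1_U"] * (f["F2_I"] - f["F2_A"])
    )


def compute_joos_vsa(profile: FormantProfile) -> float:
    """Base-10 logarithm of VSA; NaN for a degenerate (zero-area) triangle."""
    vsa = compute_vsa(profile)
    return math.log10(vsa) if vsa > 0 else float("nan")


def compute_cd(profile: FormantProfile, vowel: str, formulas: MetricFormulas = DEFAULT_FORMULAS) -> float:
    """Compact-diffuse correlate: formant proximity (compact = small F2 - F1)."""
    if vowel not in VOWELS:
        raise ValueError(f"vowel must be one of {VOWELS}")
    return float(formulas.cd(profile.f1(vowel), profile.f2(vowel)))


def compute_ga(profile: FormantProfile, vowel: str, formulas: MetricFormulas = DEFAULT_FORMULAS) -> float:
    """Grave-acute correlate: spectral balance (grave = low (F1 + F2) / 2)."""
    if vowel not in VOWELS:
        raise ValueError(f"vowel must be one of {VOWELS}")
    return float(formulas.ga(profile.f1(vowel), profile.f2(vowel)))


def build_feature_vector(
    profile: FormantProfile, formulas: MetricFormulas = DEFAULT_FORMULAS
) -> FeatureVector:
    """Assemble all 15 metrics; raw formants pass through unchanged."""
    vals = _six(profile)
    vals["FCR"] = compute_fcr(profile)
    vals["VSA"] = compute_vsa(profile)
    vals["JoosVSA"] = compute_joos_vsa(profile)
    for v in VOWELS:
        vals[f"CD_{v}"] = compute_cd(profile, v, formulas)
        vals[f"GA_{v}"] = compute_ga(profile, v, formulas)
    return FeatureVector(values=vals)


def feature_table(profiles, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row of the 15 metrics per profile, keyed by (speaker, timepoint).

    ``meta`` (optional) is merged on ``session_id`` to attach clinical
    covariates.  Sessions whose derived metrics are incomplete keep their
    row (bookkeeping) but are flagged ``complete = False``.
    """
    rows = []
    for p in profiles:
        fv = build_feature_vector(p)
        row = {
            "session_id": f"{p.speaker}_{p.timepoint}",
            "subject": p.speaker,
            "timepoint": p.timepoint,
            "gender": p.gender,
            **{k: fv[k] for k in FEATURE_NAMES},
            "complete": fv.complete,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    if meta is not None:
        extra = meta.drop(
            columns=[c for c in ("subject", "timepoint", "gender") if c in meta.columns]
        )
        table = table.merge(extra, on="session_id", how="left")
    return table
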