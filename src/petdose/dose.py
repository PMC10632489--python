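"""MIRD-schema absorbed doses and ICRP effective dose.

Absorbed dose to a target organ k is the residence-time-weighted sum of
S-values over source organs h:

    D_k = Σ_h τ_h · S(k ← h)        [per unit injected activity]

where S(k←h) = Σ_i φ_i(k←h)·Δ_i / m_k folds the absorbed fractions φ,
the equilibrium dose constants Δ and the target mass.  The effective
dose is the tissue-weighted sum E = Σ_T w_T · D_T · w_R with ICRP
weights w_T (Σ w_T = 1) and radiation weighting factor w_R (1 for the
photons/positrons of F-18, so μGy/MBq and μSv/MBq coincide numerically).

Units: S-values in mGy/(MBq·h); residence times in hours; doses are
reported ×1000 as μGy/MBq (≡ μSv/MBq at w_R = 1).

The remainder-of-body closure term is treated as an ordinary source
organ named ``"remainder"`` that must have its own column in the
supplied S-table, mirroring how phantom dose software folds it in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .residence import ResidenceTable

__all__ = [
    "SValueTable",
    "WeightingScheme",
    "DoseTable",
    "DoseLimits",
    "ComplianceReport",
    "s_from_components",
    "absorbed_doses",
    "effective_dose",
    "compliance_check",
    "ICRP103_WEIGHTS",
    "ICRP60_WEIGHTS",
    "get_weighting_scheme",
]

UGY_PER_MGY = 1000.0


def _norm(name: str) -> str:
    return str(name).strip().lower().replace(" ", "_").replace("-", "_")


#: Common aliases between image-analysis organ labels and ICRP tissue names.
_TISSUE_ALIASES = {
    "lungs": "lung",
    "urinary_bladder_wall": "urinary_bladder",
    "bladder": "urinary_bladder",
    "heart_wall": "heart",
    "kidney": "kidneys",
    "red_marrow": "red_bone_marrow",
    "esophagus": "oesophagus",
}


def _canonical(name: str) -> str:
    n = _norm(name)
    return _TISSUE_ALIASES.get(n, n)


def s_from_components(
    phi: Sequence[float], delta: Sequence[float], target_mass_g: float
) -> float:
    """S-value from absorbed fractions, equilibrium dose constants and
    target mass: S = Σ_i φ_i·Δ_i / m_t.

    ``delta`` carries units of g·mGy/(MBq·h) so the result is in
    mGy/(MBq·h).
    """
    phi = np.asarray(phi, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if phi.shape != delta.shape:
        raise ValueError("phi and delta must have the same length")
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("absorbed fractions must lie in [0, 1]")
    if np.any(delta < 0):
        raise ValueError("equilibrium dose constants must be non-negative")
    if not target_mass_g > 0:
        raise ValueError(f"target mass must be positive, got {target_mass_g}")
    return float(np.sum(phi * delta) / target_mass_g)


@dataclass
class SValueTable:
    """Source→target dose-rate matrix S(k←h) in mGy/(MBq·h).

    Stored as a target×source DataFrame; entries must be non-negative.
    Optional per-entry provenance (φ list, Δ list, target mass) can be
    attached and is validated against the stored S on construction.
    """

    matrix: pd.DataFrame  # index = targets, columns = sources
    phantom: str = ""
    provenance: Optional[pd.DataFrame] = None  # columns target, source, phi, delta, mass_g

    def __post_init__(self) -> None:
        self.matrix = self.matrix.astype(float)
        self.matrix.index = [_norm(i) for i in self.matrix.index]
        self.matrix.columns = [_norm(c) for c in self.matrix.columns]
        if (self.matrix.values < 0).any():
            raise ValueError("S-values must be non-negative")
        if self.provenance is not None:
            self._check_provenance()

    def _check_provenance(self) -> None:
        for row in self.provenance.itertuples(index=False):
            rebuilt = s_from_components(row.phi, row.delta, row.mass_g)
            stored = self.value(row.target, row.source)
            if stored == rebuilt == 0.0:
                continue
            if abs(rebuilt - stored) > 1e-9 * max(abs(stored), abs(rebuilt)):
                raise ValueError(
                    f"S({row.target}←{row.source}) = {stored} inconsistent with "
                    f"Σφ·Δ/m = {rebuilt}"
                )

    @property
    def targets(self) -> list:
        return list(self.matrix.index)

    @property
    def sources(self) -> list:
        return list(self.matrix.columns)

    def value(self, target: str, source: str) -> float:
        tgt, src = _norm(target), _norm(source)
        try:
            return float(self.matrix.at[tgt, src])
        except KeyError:
            raise KeyError(f"no S-value for target {target!r} ← source {source!r}") from None


@dataclass(frozen=True)
class WeightingScheme:
    """ICRP tissue-weighting factors w_T plus the radiation weight w_R.

    Σ w_T must equal 1 (to 1e-6): the effective dose of a uniform
    whole-body dose d is then d itself.
    """

    name: str
    w_t: Mapping[str, float]
    w_r: float = 1.0

    def __post_init__(self) -> None:
        wt = {_canonical(k): float(v) for k, v in self.w_t.items()}
        object.__setattr__(self, "w_t", wt)
        if any(v < 0 for v in wt.values()):
            raise ValueError("tissue weights must be non-negative")
        total = sum(wt.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"tissue weights of {self.name!r} sum to {total}, expected 1")
        if not self.w_r > 0:
            raise ValueError("radiation weighting factor must be positive")

    def weight(self, tissue: str) -> float:
        return self.w_t.get(_canonical(tissue), 0.0)


#: ICRP Publication 103 tissue weighting factors (2007 recommendations).
ICRP103_WEIGHTS = {
    "red_bone_marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "breast": 0.12,
    "remainder_tissues": 0.12,
    "gonads": 0.08,
    "urinary_bladder": 0.04,
    "oesophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone_surface": 0.01,
    "brain": 0.01,
    "salivary_glands": 0.01,
    "skin": 0.01,
}

#: ICRP Publication 60 tissue weighting factors (1990 recommendations).
ICRP60_WEIGHTS = {
    "gonads": 0.20,
    "red_bone_marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "urinary_bladder": 0.05,
    "breast": 0.05,
    "liver": 0.05,
    "oesophagus": 0.05,
    "thyroid": 0.05,
    "skin": 0.01,
    "bone_surface": 0.01,
    "remainder_tissues": 0.05,
}

_SCHEMES = {
    "icrp103": lambda: WeightingScheme("icrp103", ICRP103_WEIGHTS, 1.0),
    "icrp60": lambda: WeightingScheme("icrp60", ICRP60_WEIGHTS, 1.0),
}


def get_weighting_scheme(name: str = "icrp103") -> WeightingScheme:
    """Built-in weighting schemes by name (``icrp103`` default, ``icrp60``)."""
    try:
        return _SCHEMES[_norm(name)]()
    except KeyError:
        raise ValueError(
            f"unknown weighting scheme {name!r}; available: {sorted(_SCHEMES)}"
        ) from None


@dataclass
class DoseTable:
    """Per-target absorbed dose per injected activity, μGy/MBq."""

    doses_ugy_per_mbq: Dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        for organ, d in self.doses_ugy_per_mbq.items():
            if d < 0:
                raise ValueError(f"{organ}: negative dose")

    def __getitem__(self, organ: str) -> float:
        return self.doses_ugy_per_mbq[_norm(organ)]

    @property
    def organs(self) -> list:
        return list(self.doses_ugy_per_mbq)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"organ": o, "dose_uSv_per_MBq": d} for o, d in self.doses_ugy_per_mbq.items()]
        )


def absorbed_doses(residence: ResidenceTable, s: SValueTable) -> DoseTable:
    """D_k = Σ_h τ_h·S(k←h) for every target in the S-table, in μGy/MBq.

    Every source in the residence table — including the remainder term —
    must appear as a column of the S-table.
    """
    taus = residence.with_remainder()
    missing = [h for h in taus if _norm(h) not in set(s.sources)]
    if missing:
        raise KeyError(f"S-table lacks source column(s) for: {missing}")
    doses = {}
    for target in s.targets:
        d_mgy = sum(tau * s.value(target, h) for h, tau in taus.items())
        doses[target] = d_mgy * UGY_PER_MGY
    return DoseTable(doses, label=residence.subject_id or residence.sex)


def effective_dose(doses: DoseTable, weights: WeightingScheme) -> float:
    """E = Σ_T w_T·D_T·w_R in μSv/MBq.

    Weighted tissues with no matching dose entry contribute zero, with a
    warning naming them (an S-table restricted to source organs cannot
    dose every ICRP tissue).
    """
    dose_map = {_canonical(o): d for o, d in doses.doses_ugy_per_mbq.items()}
    e = 0.0
    unmatched = []
    for tissue, w in weights.w_t.items():
        d = dose_map.get(tissue)
        if d is None:
            if w > 0:
                unmatched.append(tissue)
            continue
        e += w * d * weights.w_r
    if unmatched:
        warnings.warn(
            f"tissues with no dose entry contribute 0 to effective dose: "
            f"{sorted(unmatched)}",
            stacklevel=2,
        )
    return e


@dataclass(frozen=True)
class DoseLimits:
    """Regulatory effective-dose limits, mSv (research-subject protection
    limits: 30 mSv per administration, 50 mSv per year)."""

    per_administration_msv: float = 30.0
    per_year_msv: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.per_administration_msv <= self.per_year_msv:
            raise ValueError(
                "require 0 < per-administration limit <= per-year limit, got "
                f"{self.per_administration_msv} / {self.per_year_msv}"
            )


@dataclass(frozen=True)
class ComplianceReport:
    total_msv: float
    limits: DoseLimits

    @property
    def pass_per_administration(self) -> bool:
        # strict-exceed rule: a total exactly at the limit passes
        return not self.total_msv > self.limits.per_administration_msv

    @property
    def pass_per_year(self) -> bool:
        return not self.total_msv > self.limits.per_year_msv

    @property
    def pass_all(self) -> bool:
        return self.pass_per_administration and self.pass_per_year

    def __str__(self) -> str:
        def mark(ok):
            return "PASS" if ok else "FAIL"

        return (
            f"effective dose {self.total_msv:.3f} mSv | "
            f"{self.limits.per_administration_msv:g} mSv/administration: "
            f"{mark(self.pass_per_administration)} | "
            f"{self.limits.per_year_msv:g} mSv/year: {mark(self.pass_per_year)}"
        )


def compliance_check(
    e_usv_per_mbq: float,
    injected_mbq: float,
    limits: DoseLimits = DoseLimits(),
) -> ComplianceReport:
    """Total effective dose for one administration against the limits.

    total [mSv] = E [μSv/MBq] × injected [MBq] / 1000.
    """
    if e_usv_per_mbq < 0 or injected_mbq < 0:
        raise ValueError("dose coefficient and injected activity must be non-negative")
    total = e_usv_per_mbq * injected_mbq / 1000.0
    return ComplianceReport(total_msv=total, limits=limits)
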