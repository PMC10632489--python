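"""Comparison of two dosimetry pipelines.

When the same subjects are analysed by two implementations (e.g. an
in-house trapezoid pipeline and a vendor tool), per-organ residence
times and doses differ by implementation details.  This module
quantifies those differences: per-subject percent differences are
computed first and then averaged within sex strata (never on
already-averaged tables), alongside mean ± SD of the raw values per
method per stratum.

Percent-difference conventions:

* ``rel_first``: signed, (a−b)/a·100 — difference relative to the first
  (reference) method;
* ``rel_mean``: symmetric, |a−b|/((a+b)/2)·100.

A zero denominator yields NaN rather than raising, so tables containing
genuine 0.000 entries (an organ with no uptake) still render.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["percent_difference", "compare_tables", "ComparisonReport", "SubjectValues"]

CONVENTIONS = ("rel_first", "rel_mean")


def percent_difference(a: float, b: float, convention: str = "rel_first") -> float:
    """Percent difference between two scalars under the chosen convention.

    Returns NaN (not an exception) when the denominator is zero.
    """
    if convention == "rel_first":
        if a == 0:
            return math.nan if b != 0 else 0.0
        return (a - b) / a * 100.0
    if convention == "rel_mean":
        m = (a + b) / 2.0
        if m == 0:
            return math.nan if a != b else 0.0
        return abs(a - b) / m * 100.0
    raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")


@dataclass(frozen=True)
class SubjectValues:
    """One subject's per-organ values (τ in hours or dose in μSv/MBq)
    under one analysis method."""

    subject_id: str
    sex: str
    values: Mapping[str, float]


@dataclass
class ComparisonReport:
    """Per-organ comparison of two methods with sex-stratified summaries.

    Attributes
    ----------
    by_organ : pd.DataFrame
        One row per (organ, stratum) with mean ± SD per method, the mean
        (and mean absolute) per-subject percent difference and n.
    convention : str
        Percent-difference convention used.
    """

    by_organ: pd.DataFrame
    convention: str
    method_names: tuple = ("method_a", "method_b")

    def overall(self) -> pd.DataFrame:
        return self.by_organ[self.by_organ["stratum"] == "all"].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.by_organ.to_csv(path, index=False)

    def __str__(self) -> str:
        cols = ["organ", "stratum", "n", "mean_a", "sd_a", "mean_b", "sd_b", "pct_diff_mean"]
        return self.overall()[[c for c in cols if c in self.by_organ.columns]].to_string(
            index=False, float_format=lambda x: f"{x:.4g}"
        )


def _check_aligned(method_a: Sequence[SubjectValues], method_b: Sequence[SubjectValues]):
    ids_a = {s.subject_id for s in method_a}
    ids_b = {s.subject_id for s in method_b}
    if ids_a != ids_b:
        raise ValueError(f"subject mismatch between methods: {sorted(ids_a ^ ids_b)}")
    a_by_id = {s.subject_id: s for s in method_a}
    b_by_id = {s.subject_id: s for s in method_b}
    for sid in ids_a:
        if a_by_id[sid].sex != b_by_id[sid].sex:
            raise ValueError(f"subject {sid}: sex differs between methods")
        oa, ob = set(a_by_id[sid].values), set(b_by_id[sid].values)
        if oa != ob:
            raise ValueError(f"subject {sid}: organ mismatch: {sorted(oa ^ ob)}")
    return a_by_id, b_by_id


def compare_tables(
    method_a: Sequence[SubjectValues],
    method_b: Sequence[SubjectValues],
    convention: str = "rel_first",
    method_names: Sequence[str] = ("method_a", "method_b"),
) -> ComparisonReport:
    """Compare two methods' per-subject tables organ by organ.

    Percent differences are computed per subject and then averaged
    within each sex stratum and overall; mean ± SD (sample SD, ddof=1;
    0 for n=1) of the raw values is reported per method.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")
    a_by_id, b_by_id = _check_aligned(method_a, method_b)

    records: List[dict] = []
    for sid in sorted(a_by_id):
        sa, sb = a_by_id[sid], b_by_id[sid]
        for organ in sa.values:
            va, vb = float(sa.values[organ]), float(sb.values[organ])
            records.append(
                {
                    "subject_id": sid,
                    "sex": sa.sex,
                    "organ": organ,
                    "a": va,
                    "b": vb,
                    "pct_diff": percent_difference(va, vb, convention),
                }
            )
    long = pd.DataFrame(records)

    def summarize(group: pd.DataFrame) -> pd.Series:
        diffs = group["pct_diff"].to_numpy(dtype=float)
        finite = diffs[np.isfinite(diffs)]
        return pd.Series(
            {
                "n": len(group),
                "mean_a": group["a"].mean(),
                "sd_a": group["a"].std(ddof=1) if len(group) > 1 else 0.0,
                "mean_b": group["b"].mean(),
                "sd_b": group["b"].std(ddof=1) if len(group) > 1 else 0.0,
                "pct_diff_mean": finite.mean() if finite.size else math.nan,
                "pct_diff_mean_abs": np.abs(finite).mean() if finite.size else math.nan,
            }
        )

    frames = []
    for stratum, sub in [("all", long)] + [
        (sex, long[long["sex"] == sex]) for sex in sorted(long["sex"].unique())
    ]:
        if sub.empty:
            continue
        agg = sub.groupby("organ", sort=False).apply(summarize, include_groups=False)
        agg = agg.reset_index()
        agg.insert(1, "stratum", stratum)
        frames.append(agg)
    by_organ = pd.concat(frames, ignore_index=True)
    by_organ["n"] = by_organ["n"].astype(int)
    return ComparisonReport(
        by_organ=by_organ, convention=convention, method_names=tuple(method_names)
    )
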