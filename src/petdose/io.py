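"""File formats and run configuration.

All tables are UTF-8, comma-delimited text with a mandatory header row.

TAC file — one subject per file.  Subject metadata lives in ``# key = value``
comment lines above the header::

    # id = sub-01
    # sex = male
    # injected_MBq = 250.0
    # isotope = F-18
    # half_life_min = 109.77
    organ,frame_start_min,frame_end_min,activity_MBq,decay_corrected
    liver,0,8,31.2,0
    ...

S-value file — long format: ``target,source,S_mGy_per_MBq_h`` plus
optional provenance columns ``phi``, ``delta`` (semicolon-separated
lists) and ``mass_g``.

Weighting scheme / run configuration — YAML.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from .dose import DoseLimits, SValueTable, WeightingScheme, get_weighting_scheme
from .residence import ResidenceTable, TailMethod
from .tac import F18, FrameSchedule, Isotope, Subject, TimeActivityCurve

__all__ = [
    "read_tac_file",
    "write_tac_file",
    "read_s_table",
    "write_s_table",
    "read_weighting_scheme",
    "write_weighting_scheme",
    "write_residence_table",
    "write_olinda_residence",
    "RunConfig",
]

_REQUIRED_META = ("id", "sex", "injected_mbq")
_TAC_COLUMNS = ["organ", "frame_start_min", "frame_end_min", "activity_MBq", "decay_corrected"]


def _parse_meta(path: Path) -> Dict[str, str]:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip().lower()] = val.strip()
    return meta


def read_tac_file(path) -> Subject:
    """Read a one-subject TAC file into a validated :class:`Subject`.

    Raises ``ValueError`` with the offending row/field on negative
    activities, overlapping frames or missing metadata.
    """
    path = Path(path)
    meta = _parse_meta(path)
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"{path}: missing required metadata line '# {key} = ...'")
    isotope_name = meta.get("isotope", F18.name)
    if "half_life_min" in meta:
        isotope = Isotope(isotope_name, float(meta["half_life_min"]))
    elif isotope_name.upper().replace("", "") in ("F-18", "F18", "18F"):
        isotope = F18
    else:
        raise ValueError(
            f"{path}: unknown isotope {isotope_name!r} without a half_life_min line"
        )

    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing_cols = [c for c in _TAC_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {missing_cols}")

    tacs: Dict[str, TimeActivityCurve] = {}
    for organ, grp in table.groupby("organ", sort=False):
        grp = grp.sort_values("frame_start_min")
        neg = grp[grp["activity_MBq"] < 0]
        if not neg.empty:
            row = neg.index[0] + 2  # header + 1-based
            raise ValueError(f"{path}: negative activity for {organ!r} near line {row}")
        flags = set(grp["decay_corrected"].astype(int))
        if len(flags) > 1:
            raise ValueError(f"{path}: inconsistent decay_corrected flag for {organ!r}")
        schedule = FrameSchedule(list(zip(grp["frame_start_min"], grp["frame_end_min"])))
        tacs[str(organ)] = TimeActivityCurve(
            str(organ), schedule, grp["activity_MBq"].tolist(), bool(flags.pop())
        )
    return Subject(
        id=meta["id"],
        sex=meta["sex"],
        injected_mbq=float(meta["injected_mbq"]),
        isotope=isotope,
        tacs=tacs,
    )


def write_tac_file(subject: Subject, path) -> None:
    """Write a subject in the format :func:`read_tac_file` reads."""
    path = Path(path)
    rows = []
    for organ, tac in subject.tacs.items():
        for (start, end), act in zip(tac.schedule.intervals, tac.activity_mbq):
            rows.append(
                {
                    "organ": organ,
                    "frame_start_min": start,
                    "frame_end_min": end,
                    "activity_MBq": repr(act),
                    "decay_corrected": int(tac.decay_corrected),
                }
            )
    buf = _io.StringIO()
    pd.DataFrame(rows, columns=_TAC_COLUMNS).to_csv(buf, index=False)
    header = (
        f"# id = {subject.id}\n"
        f"# sex = {subject.sex}\n"
        f"# injected_MBq = {subject.injected_mbq!r}\n"
        f"# isotope = {subject.isotope.name}\n"
        f"# half_life_min = {subject.isotope.half_life_min!r}\n"
    )
    path.write_text(header + buf.getvalue(), encoding="utf-8")


def _parse_float_list(cell: str):
    return [float(x) for x in str(cell).split(";")]


def read_s_table(path, phantom: str = "") -> SValueTable:
    """Read a long-format S-value file into a target×source matrix."""
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"target", "source", "S_mGy_per_MBq_h"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: S-table needs columns {sorted(required)}")
    matrix = table.pivot(index="target", columns="source", values="S_mGy_per_MBq_h")
    if matrix.isna().any().any():
        missing = [
            f"{t}<-{s}"
            for t in matrix.index
            for s in matrix.columns
            if pd.isna(matrix.at[t, s])
        ]
        raise ValueError(f"{path}: incomplete S matrix; missing pairs: {missing[:5]} ...")
    provenance = None
    if {"phi", "delta", "mass_g"}.issubset(table.columns):
        prov = table.dropna(subset=["phi", "delta", "mass_g"])
        if not prov.empty:
            provenance = pd.DataFrame(
                {
                    "target": prov["target"],
                    "source": prov["source"],
                    "phi": prov["phi"].map(_parse_float_list),
                    "delta": prov["delta"].map(_parse_float_list),
                    "mass_g": prov["mass_g"].astype(float),
                }
            )
    return SValueTable(matrix, phantom=phantom, provenance=provenance)


def write_s_table(s: SValueTable, path) -> None:
    rows = [
        {"target": t, "source": h, "S_mGy_per_MBq_h": repr(s.value(t, h))}
        for t in s.targets
        for h in s.sources
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_weighting_scheme(path) -> WeightingScheme:
    """Load a tissue-weighting scheme from YAML
    (``name``, ``w_R``, ``w_T: {tissue: weight}``)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return WeightingScheme(
        name=str(raw.get("name", Path(path).stem)),
        w_t=raw["w_T"],
        w_r=float(raw.get("w_R", 1.0)),
    )


def write_weighting_scheme(scheme: WeightingScheme, path) -> None:
    payload = {"name": scheme.name, "w_R": scheme.w_r, "w_T": dict(scheme.w_t)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def write_residence_table(table: ResidenceTable, path) -> None:
    """CSV export: organ, tau_h, with the remainder as the last row."""
    frame = table.to_frame()
    frame["tau_h"] = frame["tau_h"].map(repr)
    frame.to_csv(path, index=False)


def write_olinda_residence(table: ResidenceTable, path) -> None:
    """Flat text export (one 'organ  tau_hours' line per source) for
    phantom dose software."""
    lines = [f"{organ}  {tau:.6f}" for organ, tau in table.with_remainder().items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    tac_path: str = ""
    s_table_path: Optional[str] = None
    out_dir: str = "."
    tail: str = "physical"  # physical | expfit
    tail_k_points: int = 3
    leading: str = "ramp"  # ramp | flat | none
    weights: str = "icrp103"
    convention: str = "rel_first"
    isotope: str = "F-18"
    half_life_min: float = 109.77
    limit_per_administration_msv: float = 30.0
    limit_per_year_msv: float = 50.0
    seed: int = 0

    def tail_method(self) -> TailMethod:
        if self.tail == "physical":
            return TailMethod.physical()
        if self.tail == "expfit":
            return TailMethod.expfit(self.tail_k_points)
        raise ValueError(f"tail must be 'physical' or 'expfit', got {self.tail!r}")

    def isotope_obj(self) -> Isotope:
        return Isotope(self.isotope, self.half_life_min)

    def weighting_scheme(self) -> WeightingScheme:
        p = Path(self.weights)
        if p.suffix in (".yml", ".yaml") and p.exists():
            return read_weighting_scheme(p)
        return get_weighting_scheme(self.weights)

    def limits(self) -> DoseLimits:
        return DoseLimits(self.limit_per_administration_msv, self.limit_per_year_msv)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
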