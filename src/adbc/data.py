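"""Longitudinal biomarker tables: reading, writing, normalization, severity orientation.

Raw regional biomarkers come in four modalities: amyloid PET SUVR (``Abeta``),
tau PET SUVR (``tau``), cortical thickness (``Nct``) and the whole-brain MMSE
cognitive score (``MMSE``, 0-30).  Modeling requires all biomarkers on a common
[0, ~1] scale that *increases* with disease severity, so:

* ``Abeta``, ``tau``  ->  value / y_ref                    (already severity-increasing)
* ``Nct``             ->  N = 1 - value / y_ref            (thickness decreases with severity)
* ``MMSE``            ->  C = 1 - value / 30               (score decreases with severity)

where y_ref is a per-(biomarker, region) reference value.  The default
reference rule is the cohort maximum, so normalized trajectories saturate near
1 at end stage.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

RAW_BIOMARKERS = ("Abeta", "tau", "Nct", "MMSE")
MODEL_BIOMARKERS = ("Abeta", "tau", "N", "C")
REGIONAL_BIOMARKERS = ("Abeta", "tau", "N")  # C is whole-brain
MMSE_MAX = 30.0

COLUMNS = ["subject_id", "age", "biomarker", "region", "value"]

__all__ = [
    "RawObservation",
    "LongitudinalRecord",
    "ReferenceTable",
    "read_longitudinal_table",
    "write_longitudinal_table",
    "build_reference_table",
    "normalize",
    "read_fc_csv",
    "write_fc_csv",
    "records_to_frame",
]


class TableFormatError(ValueError):
    """Malformed input table (missing column or unparseable row)."""


@dataclass(frozen=True)
class RawObservation:
    """One raw measurement at (subject, age): regional SUVR/thickness or whole-brain MMSE."""

    subject_id: str
    age: float
    biomarker: str
    region: int | None  # 1-based region index; None for MMSE
    value: float

    def __post_init__(self):
        if self.biomarker not in RAW_BIOMARKERS:
            raise ValueError(f"unknown biomarker {self.biomarker!r}")
        if self.biomarker == "MMSE":
            if not (0.0 <= self.value <= MMSE_MAX):
                raise ValueError(f"MMSE value {self.value} outside [0, {MMSE_MAX:g}]")
        elif self.region is None:
            raise ValueError(f"regional biomarker {self.biomarker} requires a region")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass(frozen=True)
class LongitudinalRecord:
    """One normalized, severity-oriented value at (subject, age, region)."""

    subject_id: str
    age: float
    biomarker: str  # one of Abeta, tau, N, C
    region: int | None  # None for C (whole-brain)
    value: float

    def __post_init__(self):
        if self.biomarker not in MODEL_BIOMARKERS:
            raise ValueError(f"unknown model biomarker {self.biomarker!r}")
        if not np.isfinite(self.value):
            raise ValueError("non-finite normalized value")


@dataclass(frozen=True)
class ReferenceTable:
    """Per-(biomarker, region) reference values used as normalization denominators."""

    values: dict[tuple[str, int | None], float]

    def __post_init__(self):
        for key, v in self.values.items():
            if v <= 0:
                raise ValueError(f"non-positive reference value {v} for {key}: division unsafe")

    def get(self, biomarker: str, region: int | None) -> float:
        try:
            return self.values[(biomarker, region)]
        except KeyError:
            raise KeyError(f"no reference value for biomarker={biomarker!r}, region={region!r}")


def _parse_region(raw, biomarker: str):
    if biomarker == "MMSE" or biomarker == "C":
        return None
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    return int(raw)


def read_longitudinal_table(
    path: str | Path | io.TextIOBase, sep: str | None = None
) -> list[RawObservation]:
    """Read a delimited biomarker table with header subject_id,age,biomarker,region,value.

    Delimiter is sniffed from the header (comma or tab) unless given.  A
    malformed numeric field raises :class:`TableFormatError` naming the line.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    lines = text.splitlines()
    if not lines:
        raise TableFormatError("empty file: no header")
    if sep is None:
        sep = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(sep)]
    missing = [c for c in COLUMNS if c not in header]
    if missing:
        raise TableFormatError(f"missing column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in COLUMNS}
    out: list[RawObservation] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(sep)
        try:
            age = float(parts[idx["age"]])
            value = float(parts[idx["value"]])
        except (ValueError, IndexError) as exc:
            raise TableFormatError(f"line {lineno}: cannot parse row: {exc}") from exc
        biomarker = parts[idx["biomarker"]].strip()
        region = _parse_region(parts[idx["region"]].strip(), biomarker)
        out.append(
            RawObservation(
                subject_id=parts[idx["subject_id"]].strip(),
                age=age,
                biomarker=biomarker,
                region=region,
                value=value,
            )
        )
    return out


def records_to_frame(records: Iterable[LongitudinalRecord | RawObservation]) -> pd.DataFrame:
    rows = [
        (r.subject_id, r.age, r.biomarker, "" if r.region is None else r.region, r.value)
        for r in records
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def write_longitudinal_table(
    records: Iterable[LongitudinalRecord | RawObservation], path: str | Path, sep: str = ","
) -> None:
    """Write records as delimited text, full float precision (round-trip safe)."""
    df = records_to_frame(records)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def build_reference_table(
    observations: Iterable[RawObservation],
    rule: Literal["cohort_max", "cohort_quantile", "fixed_table"] = "cohort_max",
    quantile: float = 0.95,
    fixed: ReferenceTable | None = None,
) -> ReferenceTable:
    """Choose the normalization denominator per (biomarker, region).

    ``cohort_max`` (default) makes normalized trajectories approach 1 at end
    stage; ``cohort_quantile`` is robust to outliers; ``fixed_table`` passes a
    user table through unchanged.  MMSE is excluded (its scale is fixed at 30).
    """
    if rule == "fixed_table":
        if fixed is None:
            raise ValueError("fixed_table rule requires a ReferenceTable")
        return fixed
    pools: dict[tuple[str, int | None], list[float]] = {}
    for obs in observations:
        if obs.biomarker == "MMSE":
            continue
        pools.setdefault((obs.biomarker, obs.region), []).append(obs.value)
    values: dict[tuple[str, int | None], float] = {}
    for key, vals in pools.items():
        if rule == "cohort_max":
            ref = max(vals)
        elif rule == "cohort_quantile":
            ref = float(np.quantile(vals, quantile))
        else:
            raise ValueError(f"unknown reference rule {rule!r}")
        values[key] = ref
    return ReferenceTable(values)


def normalize(
    observations: Iterable[RawObservation], references: ReferenceTable
) -> list[LongitudinalRecord]:
    """Normalize raw observations and orient all biomarkers to increase with severity.

    Abeta, tau -> value/y_ref; Nct -> N = 1 - value/y_ref; MMSE -> C = 1 - value/30.
    Missing references raise a keyed error.
    """
    out: list[LongitudinalRecord] = []
    for obs in observations:
        if obs.biomarker == "MMSE":
            biomarker, value = "C", 1.0 - obs.value / MMSE_MAX
        else:
            ref = references.get(obs.biomarker, obs.region)
            scaled = obs.value / ref
            if obs.biomarker == "Nct":
                biomarker, value = "N", 1.0 - scaled
            else:
                biomarker, value = obs.biomarker, scaled
        out.append(
            LongitudinalRecord(
                subject_id=obs.subject_id,
                age=obs.age,
                biomarker=biomarker,
                region=obs.region,
                value=value,
            )
        )
    return out


def read_normalized_table(path: str | Path, sep: str | None = None) -> list[LongitudinalRecord]:
    """Read an already-normalized table (biomarkers Abeta/tau/N/C)."""
    if sep is None:
        head = Path(path).read_text(encoding="utf-8").split("\n", 1)[0]
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing column(s): {', '.join(missing)}")
    out = []
    for row in df.itertuples(index=False):
        region = _parse_region(row.region, row.biomarker)
        out.append(
            LongitudinalRecord(
                subject_id=str(row.subject_id),
                age=float(row.age),
                biomarker=str(row.biomarker),
                region=region,
                value=float(row.value),
            )
        )
    return out


def read_fc_csv(r_path: str | Path, p_path: str | Path | None = None):
    """Read a square FC matrix (and optional parallel p-value matrix) from headerless CSV."""
    from .graph import FcMatrix

    r = np.loadtxt(r_path, delimiter=",")
    p = np.loadtxt(p_path, delimiter=",") if p_path is not None else None
    return FcMatrix(r=r, p=p)


def write_fc_csv(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter=",", fmt="%.17g")
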