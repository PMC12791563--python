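"""Run configuration and CSV readers/writers for all tabular artifacts.

All tables travel as comma-separated UTF-8 text with a mandatory header row.
Sample ID is the join key everywhere and joins are strict: with cohorts of a
handful of subjects a silently dropped sample would distort every downstream
statistic, so any mismatch raises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .registry import CELL_TYPES, ClockRegistry

logger = logging.getLogger("spaceclock")

#: Mission sampling schedule: 45 days pre-launch, flight days 4 and 7,
#: return days 1 and 7.
DEFAULT_TIMEPOINTS = ("L-45", "FD+4", "FD+7", "R+1", "R+7")
DEFAULT_REFERENCE = "L-45"

METRICS = ("EAD", "EAA", "IEAA")

_SEX_CODES = {
    "f": 1, "female": 1, "1": 1,
    "m": 0, "male": 0, "0": 0,
}


class TableFormatError(ValueError):
    """A CSV did not match the expected schema."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, mirroring the YAML config file.

    Either ``cell_table`` or the pair ``beta_matrix`` + ``reference_matrix``
    must be given when IEAA is requested; with beta input the cell fractions
    are deconvolved first.
    """

    metadata: Path
    output_dir: Path
    clock_table: Path | None = None
    cell_table: Path | None = None
    beta_matrix: Path | None = None
    reference_matrix: Path | None = None
    clock_registry: Path | None = None
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    reference_timepoint: str = DEFAULT_REFERENCE
    n_permutations: int = 10_000
    rng_seed: int = 0
    metrics: tuple[str, ...] = METRICS
    sensitivity: bool = False

    def __post_init__(self) -> None:
        self.metadata = Path(self.metadata)
        self.output_dir = Path(self.output_dir)
        for attr in ("clock_table", "cell_table", "beta_matrix",
                     "reference_matrix", "clock_registry"):
            val = getattr(self, attr)
            if val is not None:
                setattr(self, attr, Path(val))
        self.timepoints = tuple(str(t) for t in self.timepoints)
        self.metrics = tuple(str(m) for m in self.metrics)
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if len(set(self.timepoints)) < 2:
            raise ValueError("timepoint ordering needs >= 2 distinct labels")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoint ordering contains duplicates")
        if self.reference_timepoint not in self.timepoints:
            raise ValueError(
                f"reference timepoint {self.reference_timepoint!r} not in "
                f"ordering {self.timepoints}"
            )
        bad = set(self.metrics) - set(METRICS)
        if bad:
            raise ValueError(f"unknown metrics {sorted(bad)}; allowed {METRICS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise TableFormatError(f"config {path} is not a mapping")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for key, val in self.__dict__.items():
            if isinstance(val, Path):
                val = str(val)
            elif isinstance(val, tuple):
                val = list(val)
            out[key] = val
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_indexed_csv(path: str | Path, what: str) -> pd.DataFrame:
    """Read a CSV whose first column is the row identifier; IDs must be unique."""
    frame = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if frame.shape[1] < 2:
        raise TableFormatError(f"{what} {path}: need an ID column plus data")
    id_col = frame.columns[0]
    ids = frame[id_col].astype(str)
    if ids.duplicated().any():
        dup = sorted(ids[ids.duplicated()].unique())
        raise TableFormatError(f"{what} {path}: duplicate IDs {dup}")
    frame = frame.set_index(id_col)
    frame.index.name = "sample_id"
    return frame


def _coerce_numeric(frame: pd.DataFrame, path: str | Path, what: str) -> pd.DataFrame:
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise TableFormatError(
            f"{what} {path}: non-numeric value {frame.loc[row, col]!r} "
            f"at row {row!r}, column {col!r}"
        )
    return numeric.astype(float)


def read_clock_table(path: str | Path, registry: ClockRegistry) -> pd.DataFrame:
    """Read a samples × clocks table of epigenetic age estimates.

    Unknown clock columns are reported and dropped; a registered clock missing
    from the file is an error.
    """
    frame = _read_indexed_csv(path, "clock table")
    extra = [c for c in frame.columns if c not in registry]
    if extra:
        logger.warning("clock table %s: dropping unregistered columns %s", path, extra)
        frame = frame.drop(columns=extra)
    missing = [n for n in registry.names if n not in frame.columns]
    if missing:
        raise TableFormatError(f"clock table {path}: missing registered clocks {missing}")
    frame = frame[registry.names]
    return _coerce_numeric(frame, path, "clock table")


def parse_sex(value: object) -> int:
    """Normalise a sex label to the Female=1 / Male=0 coding."""
    key = str(value).strip().lower()
    if key not in _SEX_CODES:
        raise TableFormatError(f"unparseable sex value {value!r}")
    return _SEX_CODES[key]


def read_metadata(
    path: str | Path,
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
) -> pd.DataFrame:
    """Read sample metadata: subject, sex, chronological age, timepoint.

    Returns a DataFrame indexed by sample ID with columns ``subject`` (str),
    ``sex`` (int, Female=1/Male=0), ``age`` (float years) and ``timepoint``
    (ordered categorical following ``timepoints``).
    """
    frame = _read_indexed_csv(path, "metadata")
    required = {"subject", "sex", "age", "timepoint"}
    missing = required - set(frame.columns)
    if missing:
        raise TableFormatError(f"metadata {path}: missing columns {sorted(missing)}")
    out = pd.DataFrame(index=frame.index)
    out["subject"] = frame["subject"].astype(str)
    out["sex"] = [parse_sex(v) for v in frame["sex"]]
    out["age"] = pd.to_numeric(frame["age"], errors="raise").astype(float)
    if (out["age"] <= 0).any():
        bad = out.index[out["age"] <= 0].tolist()
        raise TableFormatError(f"metadata {path}: non-positive age for {bad}")
    labels = frame["timepoint"].astype(str)
    unknown = sorted(set(labels) - set(timepoints))
    if unknown:
        raise TableFormatError(
            f"metadata {path}: unknown timepoint labels {unknown}; "
            f"ordering is {tuple(timepoints)}"
        )
    out["timepoint"] = pd.Categorical(labels, categories=list(timepoints), ordered=True)
    dup = out.duplicated(subset=["subject", "timepoint"])
    if dup.any():
        raise TableFormatError(
            f"metadata {path}: more than one record per (subject, timepoint): "
            f"{out.index[dup].tolist()}"
        )
    return out


def read_cell_table(
    path: str | Path,
    cell_types: Sequence[str] = CELL_TYPES,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Read a samples × cell-types fraction table and validate the simplex."""
    frame = _read_indexed_csv(path, "cell table")
    missing = [c for c in cell_types if c not in frame.columns]
    if missing:
        raise TableFormatError(f"cell table {path}: missing cell types {missing}")
    frame = _coerce_numeric(frame[list(cell_types)], path, "cell table")
    validate_cell_table(frame, tol=tol)
    return frame


def validate_cell_table(frame: pd.DataFrame, tol: float = 1e-6) -> None:
    vals = frame.to_numpy(float)
    if (vals < -tol).any() or (vals > 1 + tol).any():
        raise TableFormatError("cell fractions outside [0, 1]")
    sums = vals.sum(axis=1)
    off = np.abs(sums - 1.0) > tol
    if off.any():
        bad = frame.index[off].tolist()
        raise TableFormatError(f"cell fraction rows do not sum to 1: {bad}")


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a CpG × sample beta matrix (values in [0, 1])."""
    frame = _read_indexed_csv(path, "beta matrix")
    frame.index.name = "cpg"
    frame = _coerce_numeric(frame, path, "beta matrix")
    vals = frame.to_numpy(float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise TableFormatError(f"beta matrix {path}: values outside [0, 1]")
    return frame


def read_reference_matrix(path: str | Path) -> pd.DataFrame:
    """Read a CpG × cell-type reference matrix of pure-cell beta profiles."""
    frame = _read_indexed_csv(path, "reference matrix")
    frame.index.name = "cpg"
    frame = _coerce_numeric(frame, path, "reference matrix")
    if frame.shape[1] < 2:
        raise TableFormatError(f"reference matrix {path}: need >= 2 cell types")
    vals = frame.to_numpy(float)
    if vals.min() < 0 or vals.max() > 1:
        raise TableFormatError(f"reference matrix {path}: values outside [0, 1]")
    return frame


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a table as CSV (full ``repr`` float precision, so values round-trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=index)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out["timepoint"] = out["timepoint"].astype(str)
    write_table(out, path)
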