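"""Mission-like synthetic cohorts with known ground truth.

The generator emulates the study design this package analyses: a handful of
crew members sampled at five timepoints around a short orbital mission, with
per-clock linear age models, a subject-level random intercept, per-timepoint
true acceleration pulses, and immune cell-composition shifts that propagate
into clock estimates with clock-specific sensitivities.  Every stochastic
component is recorded in a :class:`SyntheticTruth` so recovery tests can
compare estimates against what was actually simulated.

The generative model for a year-scale clock c, subject i, timepoint t is

    value(c,i,t) = a_c + b_c * age_{i,t} + s_c * sex_i + u_i
                   + gamma_c * delta_t
                   + sum_k w_{c,k} (pi_{i,t,k} - mean_k pi)
                   + eps,   eps ~ Normal(0, sigma_c^2)

with u_i ~ Normal(0, sigma_u^2) drawn once per subject, delta_t a fixed
per-timepoint acceleration (years, 0 at the reference timepoint), and
pi_{i,t,.} the sample's simplex of 12 cell fractions.  DunedinPACE is
generated by the same expression with pace-scale parameters (values near 1).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import CELL_TYPES, ClockRegistry, default_registry

# -- study-condition defaults ----------------------------------------------

#: (label, days from launch).  Return occurs on day 9 of the mission, so
#: R+1 and R+7 fall on days 10 and 16.
DEFAULT_TIMEPOINT_OFFSETS: tuple[tuple[str, float], ...] = (
    ("L-45", -45.0),
    ("FD+4", 4.0),
    ("FD+7", 7.0),
    ("R+1", 10.0),
    ("R+7", 16.0),
)

DEFAULT_REFERENCE = "L-45"

#: Crew roster: (subject, sex code Female=1/Male=0, age in years at L-45).
DEFAULT_SUBJECTS: tuple[tuple[str, int, float], ...] = (
    ("A1", 0, 67.7),
    ("A2", 1, 63.2),
    ("A3", 0, 31.1),
    ("A4", 1, 34.6),
)

#: Mean acceleration trajectory in years relative to the pre-flight baseline:
#: a rise in early flight peaking at flight day 7, an overshoot below baseline
#: right after return, and near-recovery a week later.
DEFAULT_DELTA: dict[str, float] = {
    "L-45": 0.0,
    "FD+4": 0.76,
    "FD+7": 1.91,
    "R+1": -1.57,
    "R+7": -0.30,
}

#: Baseline mean blood fractions for the 12-cell immune panel.
DEFAULT_BASELINE_FRACTIONS: dict[str, float] = {
    "Bas": 0.010,
    "Bnv": 0.025,
    "Bmem": 0.015,
    "CD4nv": 0.040,
    "CD4mem": 0.100,
    "CD8nv": 0.030,
    "CD8mem": 0.060,
    "Treg": 0.015,
    "NK": 0.060,
    "Mono": 0.080,
    "Neu": 0.540,
    "Eos": 0.025,
}

#: Per-timepoint mean shifts on the logit scale for designated cell types:
#: regulatory and naive CD4 T cells dip in early flight, rebound at flight
#: day 7 and dip again after return; neutrophils move the opposite way.
DEFAULT_LOGIT_SHIFTS: dict[str, dict[str, float]] = {
    "FD+4": {"Treg": -0.4, "CD4nv": -0.4, "Neu": 0.15},
    "FD+7": {"Treg": 0.4, "CD4nv": 0.4, "Neu": -0.3},
    "R+1": {"Treg": -0.3, "CD4nv": -0.3},
}


def _stream(seed: int, stage: str) -> np.random.Generator:
    """One RNG stream per stage, derived from the master seed by stage name.

    Adding a stage never perturbs the draws of existing stages.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


# -- parameter containers ---------------------------------------------------

@dataclass(frozen=True)
class SubjectSpec:
    subject: str
    sex: int          # Female=1, Male=0
    age: float        # years at the reference timepoint


@dataclass
class CohortParams:
    """Cohort design: who is sampled, when, and the true acceleration."""

    subjects: tuple[SubjectSpec, ...] = tuple(
        SubjectSpec(*s) for s in DEFAULT_SUBJECTS
    )
    timepoints: tuple[tuple[str, float], ...] = DEFAULT_TIMEPOINT_OFFSETS
    reference: str = DEFAULT_REFERENCE
    delta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DELTA))
    sigma_subject: float = 1.0

    def __post_init__(self) -> None:
        labels = [t for t, _ in self.timepoints]
        if self.reference not in labels:
            raise ValueError(f"reference {self.reference!r} not in {labels}")
        if self.sigma_subject < 0:
            raise ValueError("sigma_subject must be >= 0")
        missing = set(labels) - set(self.delta)
        if missing:
            raise ValueError(f"delta missing timepoints {sorted(missing)}")
        if abs(self.delta[self.reference]) > 1e-12:
            raise ValueError("delta at the reference timepoint must be 0")

    @property
    def labels(self) -> list[str]:
        return [t for t, _ in self.timepoints]

    def sample_frame(self) -> pd.DataFrame:
        """Metadata table with chronological age advanced by calendar offsets."""
        offsets = dict(self.timepoints)
        ref_off = offsets[self.reference]
        rows = []
        for s in self.subjects:
            for label, off in self.timepoints:
                rows.append(
                    {
                        "sample_id": f"{s.subject}_{label}",
                        "subject": s.subject,
                        "sex": s.sex,
                        "age": s.age + (off - ref_off) / 365.25,
                        "timepoint": label,
                    }
                )
        frame = pd.DataFrame(rows).set_index("sample_id")
        frame["timepoint"] = pd.Categorical(
            frame["timepoint"], categories=self.labels, ordered=True
        )
        return frame


@dataclass
class ClockSimParams:
    """Per-clock generative parameters."""

    name: str
    intercept: float
    slope: float
    sex_effect: float
    noise_sd: float
    gamma: float = 1.0
    cell_weights: np.ndarray | None = None   # length-12, years per unit fraction
    units: str = "years"
    subject_scale: float = 1.0   # multiplier on u_i (pace clocks use ~0.01)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")
        if self.units == "years" and self.slope <= 0:
            raise ValueError(f"{self.name}: year-scale clocks need slope > 0")


@dataclass
class CellShiftParams:
    """Dirichlet baseline plus per-timepoint mean logit shifts."""

    cell_types: tuple[str, ...] = CELL_TYPES
    baseline: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_FRACTIONS)
    )
    concentration: float = 300.0
    logit_shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LOGIT_SHIFTS.items()}
    )

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        vec = self.baseline_vector()
        if (vec <= 0).any():
            raise ValueError("baseline fractions must be > 0")

    def baseline_vector(self) -> np.ndarray:
        vec = np.array([float(self.baseline[c]) for c in self.cell_types])
        return vec / vec.sum()


@dataclass
class SyntheticTruth:
    """Everything needed to recompute each generated value minus its noise."""

    seed: int
    subject_effects: dict[str, float]
    delta: dict[str, float]
    gamma: dict[str, float]
    cell_weights: pd.DataFrame          # clocks × cell types
    cell_fractions: pd.DataFrame        # samples × cell types
    expected: pd.DataFrame | None = None  # samples × clocks, noise-free values


# -- default clock parameters ----------------------------------------------

def default_clock_params(
    registry: ClockRegistry | None = None,
    noise_sd: float = 1.0,
    w_scale: float = 10.0,
    gamma: float = 1.0,
    cell_types: Sequence[str] = CELL_TYPES,
    param_seed: int = 20230521,
) -> list[ClockSimParams]:
    """Deterministic, realistic per-clock parameters for the default registry.

    Slopes are drawn once (fixed internal seed) in [0.85, 1.1] so every
    year-scale clock tracks chronological age strongly; sex effects are small
    (|s_c| ~ 0.5 yr); cell-sensitivity weights load mainly on Treg, naive CD4
    T cells and neutrophils with clock-specific magnitude ``w_scale`` (years
    per unit fraction change).  Pass ``w_scale=0`` for cell-insensitive clocks
    or ``gamma=0`` to silence the acceleration term.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(param_seed)
    cell_types = tuple(cell_types)
    idx = {c: i for i, c in enumerate(cell_types)}
    params: list[ClockSimParams] = []
    for clock in registry:
        if clock.units == "rate":
            w = rng.normal(0.0, 0.002, len(cell_types))
            params.append(
                ClockSimParams(
                    name=clock.name,
                    intercept=0.65,
                    slope=0.006,
                    sex_effect=rng.normal(0.0, 0.01),
                    noise_sd=0.02,
                    gamma=0.01 * gamma,
                    cell_weights=w,
                    units="rate",
                    subject_scale=0.01,
                )
            )
            continue
        pattern = rng.normal(0.0, 0.15, len(cell_types))
        for cell, load in (("Treg", 1.0), ("CD4nv", 0.8), ("Neu", 0.6)):
            pattern[idx[cell]] += load * rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
        w = w_scale * pattern
        params.append(
            ClockSimParams(
                name=clock.name,
                intercept=rng.normal(0.0, 3.0),
                slope=rng.uniform(0.85, 1.10),
                sex_effect=rng.normal(0.0, 0.5),
                noise_sd=noise_sd,
                gamma=gamma,
                cell_weights=w,
            )
        )
    return params


# -- generators -------------------------------------------------------------

def generate_cell_fractions(
    params: CellShiftParams,
    cohort: CohortParams,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Draw one simplex of cell fractions per sample.

    Each sample's fractions are Dirichlet draws around the baseline mean;
    designated cell types then receive their timepoint's mean shift on the
    logit scale before renormalisation, so shifted compositions remain on the
    simplex exactly.
    """
    rng = _stream(seed, "cells")
    meta = cohort.sample_frame()
    base = params.baseline_vector()
    alpha = params.concentration * base
    rows = np.empty((len(meta), len(params.cell_types)))
    idx = {c: i for i, c in enumerate(params.cell_types)}
    for r, (sample, rec) in enumerate(meta.iterrows()):
        pi = rng.dirichlet(alpha)
        shifts = params.logit_shifts.get(str(rec["timepoint"]), {})
        for cell, shift in shifts.items():
            j = idx[cell]
            logit = np.log(pi[j] / (1.0 - pi[j]))
            pi[j] = 1.0 / (1.0 + np.exp(-(logit + shift)))
        rows[r] = pi / pi.sum()
    frame = pd.DataFrame(rows, index=meta.index, columns=list(params.cell_types))
    truth_part = {"cell_fractions": frame, "seed": int(seed)}
    return frame, truth_part


def generate_clock_estimates(
    cohort: CohortParams,
    clocks: Sequence[ClockSimParams],
    cells: pd.DataFrame,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate the samples × clocks estimate table plus full ground truth.

    Cell effects enter through fractions centred at the cohort mean, keeping
    the acceleration pulse ``delta_t`` and the weights ``w`` separately
    identifiable in recovery tests.
    """
    meta = cohort.sample_frame()
    if not meta.index.equals(cells.index):
        if set(meta.index) != set(cells.index):
            raise ValueError("cell table rows do not match cohort samples")
        cells = cells.loc[meta.index]
    n_cells = cells.shape[1]
    for cp in clocks:
        if cp.cell_weights is not None and len(cp.cell_weights) != n_cells:
            raise ValueError(
                f"clock {cp.name}: {len(cp.cell_weights)} cell weights for "
                f"{n_cells} cell types"
            )

    subj_rng = _stream(seed, "subjects")
    noise_rng = _stream(seed, "noise")
    u = {
        s.subject: float(subj_rng.normal(0.0, cohort.sigma_subject))
        for s in cohort.subjects
    }
    centered = cells.to_numpy(float) - cells.to_numpy(float).mean(axis=0)

    age = meta["age"].to_numpy(float)
    sex = meta["sex"].to_numpy(float)
    u_vec = meta["subject"].map(u).to_numpy(float)
    delta_vec = meta["timepoint"].astype(str).map(cohort.delta).to_numpy(float)

    expected = np.empty((len(meta), len(clocks)))
    values = np.empty_like(expected)
    for j, cp in enumerate(clocks):
        w = np.zeros(n_cells) if cp.cell_weights is None else np.asarray(cp.cell_weights, float)
        mean = (
            cp.intercept
            + cp.slope * age
            + cp.sex_effect * sex
            + cp.subject_scale * u_vec
            + cp.gamma * delta_vec
            + centered @ w
        )
        expected[:, j] = mean
        values[:, j] = mean + noise_rng.normal(0.0, cp.noise_sd, len(meta))

    names = [cp.name for cp in clocks]
    clock_df = pd.DataFrame(values, index=meta.index, columns=names)
    truth = SyntheticTruth(
        seed=int(seed),
        subject_effects=u,
        delta=dict(cohort.delta),
        gamma={cp.name: cp.gamma for cp in clocks},
        cell_weights=pd.DataFrame(
            [np.zeros(n_cells) if cp.cell_weights is None else cp.cell_weights
             for cp in clocks],
            index=names,
            columns=list(cells.columns),
        ),
        cell_fractions=cells,
        expected=pd.DataFrame(expected, index=meta.index, columns=names),
    )
    return clock_df, meta, truth


def make_reference_matrix(
    n_cpgs: int = 500,
    cell_types: Sequence[str] = CELL_TYPES,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic CpG × cell-type reference of pure-cell beta profiles.

    Profiles are Beta(0.6, 0.6) draws, giving the bimodal methylation pattern
    that makes cell types distinguishable; this stands in for an experimental
    sorted-cell reference and is labelled synthetic throughout.
    """
    rng = _stream(seed, "reference")
    vals = rng.beta(0.6, 0.6, size=(n_cpgs, len(cell_types)))
    return pd.DataFrame(
        vals,
        index=[f"cg{i:06d}" for i in range(n_cpgs)],
        columns=list(cell_types),
    )


def generate_methylation(
    reference: pd.DataFrame,
    cells: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mix pure-cell reference profiles by each sample's fractions.

    beta(j, sample) = sum_k R[j, k] * pi[sample, k] + noise, truncated to
    [0, 1].  Enables testing clock application and deconvolution without
    array data.
    """
    vals = reference.to_numpy(float)
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("reference values outside [0, 1]")
    missing = [c for c in reference.columns if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing reference cell types {missing}")
    pi = cells[list(reference.columns)].to_numpy(float)
    beta = vals @ pi.T
    if noise_sd > 0:
        rng = _stream(seed, "methylation-noise")
        beta = beta + rng.normal(0.0, noise_sd, beta.shape)
    beta = np.clip(beta, 0.0, 1.0)
    return pd.DataFrame(beta, index=reference.index, columns=cells.index)


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    clock_table: pd.DataFrame
    metadata: pd.DataFrame
    cell_fractions: pd.DataFrame
    truth: SyntheticTruth


def simulate_cohort(
    seed: int,
    cohort: CohortParams | None = None,
    clocks: Sequence[ClockSimParams] | None = None,
    cells: CellShiftParams | None = None,
) -> SimulatedCohort:
    """Generate a full mission-like cohort at the default study conditions."""
    cohort = cohort or CohortParams()
    cells = cells or CellShiftParams()
    clocks = clocks if clocks is not None else default_clock_params()
    frac, _ = generate_cell_fractions(cells, cohort, seed)
    clock_df, meta, truth = generate_clock_estimates(cohort, clocks, frac, seed)
    return SimulatedCohort(clock_df, meta, frac, truth)
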