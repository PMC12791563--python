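"""Per-clock biological-age metrics and their summaries.

Three metrics are computed per clock and sample, all in years:

* **EAD** (epigenetic age difference): clock estimate minus chronological age.
* **EAA** (epigenetic age acceleration): residual of the clock estimate from
  an OLS fit on chronological age and sex (Female=1, Male=0), pooled over all
  samples.
* **IEAA** (intrinsic EAA): residual after additionally adjusting for the 12
  predicted immune-cell fractions (one fraction is dropped from the design —
  the fractions sum to one, so the span, and hence the residual, is invariant
  to which).

Pace-of-aging clocks (DunedinPACE) are excluded from all three metrics and
summarised separately as raw per-subject deltas.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import ClockRegistry

logger = logging.getLogger("spaceclock")


@dataclass
class AgeMetricTable:
    """samples × clocks values for one metric, plus the fitted-model audit.

    ``audit`` carries, per clock, the OLS coefficients actually fitted and
    the design rank (None for EAD, which involves no fit).
    """

    metric: str
    values: pd.DataFrame
    audit: pd.DataFrame | None = None

    def long(self) -> pd.DataFrame:
        out = self.values.stack().rename("value").reset_index()
        out.columns = ["sample_id", "clock", "value"]
        out.insert(2, "metric", self.metric)
        return out


def _check_join(clocks: pd.DataFrame, meta: pd.DataFrame) -> None:
    missing = clocks.index.difference(meta.index)
    if len(missing):
        raise ValueError(
            f"samples in clock table absent from metadata: {list(missing)}"
        )


def _year_clock_values(
    clocks: pd.DataFrame, registry: ClockRegistry | None
) -> pd.DataFrame:
    if registry is None:
        return clocks
    keep = [c for c in clocks.columns if c in registry and registry.units_of(c) == "years"]
    unregistered = [c for c in clocks.columns if c not in registry]
    if unregistered:
        raise KeyError(f"unregistered clocks in table: {unregistered}")
    return clocks[keep]


def compute_ead(
    clocks: pd.DataFrame,
    meta: pd.DataFrame,
    registry: ClockRegistry | None = None,
) -> AgeMetricTable:
    """EAD(c, sample) = clock estimate − chronological age."""
    _check_join(clocks, meta)
    vals = _year_clock_values(clocks, registry)
    age = meta.loc[vals.index, "age"].to_numpy(float)
    return AgeMetricTable("EAD", vals.sub(age, axis=0))


def _ols_residuals(
    y: np.ndarray, design: pd.DataFrame, what: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Residuals of each column of y on the design; errors on rank deficiency."""
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify the dependent columns by greedy rank growth
        bad = []
        cols: list[int] = []
        for j in range(x.shape[1]):
            trial = cols + [j]
            if np.linalg.matrix_rank(x[:, trial]) == len(cols):
                bad.append(design.columns[j])
            else:
                cols = trial
        raise ValueError(
            f"{what}: rank-deficient design (rank {rank} of {x.shape[1]}); "
            f"collinear columns: {bad}"
        )
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef, coef, rank


def _drop_constant(design: pd.DataFrame, protect: Sequence[str]) -> pd.DataFrame:
    out = design
    for col in design.columns:
        if col in protect:
            continue
        if np.ptp(design[col].to_numpy(float)) == 0:
            warnings.warn(
                f"design column {col!r} is constant across samples; dropped",
                stacklevel=3,
            )
            out = out.drop(columns=[col])
    return out


def _fit_metric(
    metric: str,
    vals: pd.DataFrame,
    design: pd.DataFrame,
) -> AgeMetricTable:
    resid, coef, rank = _ols_residuals(vals.to_numpy(float), design, metric)
    audit = pd.DataFrame(coef.T, index=vals.columns, columns=design.columns)
    audit["design_rank"] = rank
    return AgeMetricTable(metric, pd.DataFrame(resid, index=vals.index, columns=vals.columns), audit)


def compute_eaa(
    clocks: pd.DataFrame,
    meta: pd.DataFrame,
    registry: ClockRegistry | None = None,
) -> AgeMetricTable:
    """Residual of each clock from pooled OLS on chronological age and sex."""
    _check_join(clocks, meta)
    vals = _year_clock_values(clocks, registry)
    if len(vals) < 4:
        raise ValueError("EAA needs at least 4 samples")
    m = meta.loc[vals.index]
    design = pd.DataFrame(
        {"intercept": 1.0, "age": m["age"].astype(float), "sex": m["sex"].astype(float)},
        index=vals.index,
    )
    design = _drop_constant(design, protect=["intercept", "age"])
    return _fit_metric("EAA", vals, design)


def compute_ieaa(
    clocks: pd.DataFrame,
    meta: pd.DataFrame,
    cells: pd.DataFrame,
    registry: ClockRegistry | None = None,
    drop_cell: str | None = None,
) -> AgeMetricTable:
    """Residual after adjusting for age, sex and predicted cell composition.

    One cell fraction (by default the last listed) is excluded from the
    design because the twelve fractions sum to one; the residuals do not
    depend on which is excluded.  Cell columns that are constant across
    samples are dropped with a warning (if all are, IEAA reduces to EAA).
    """
    _check_join(clocks, meta)
    vals = _year_clock_values(clocks, registry)
    missing = vals.index.difference(cells.index)
    if len(missing):
        raise ValueError(f"samples missing from cell table: {list(missing)}")
    cells = cells.loc[vals.index]
    if drop_cell is None:
        drop_cell = cells.columns[-1]
    elif drop_cell not in cells.columns:
        raise KeyError(f"drop_cell {drop_cell!r} not a cell-table column")
    m = meta.loc[vals.index]
    design = pd.DataFrame(
        {"intercept": 1.0, "age": m["age"].astype(float), "sex": m["sex"].astype(float)},
        index=vals.index,
    )
    for col in cells.columns:
        if col == drop_cell:
            continue
        design[col] = cells[col].astype(float)
    design = _drop_constant(design, protect=["intercept", "age"])
    n, p = design.shape
    if n <= p:
        raise ValueError(
            f"IEAA model saturated: {n} samples for {p} design columns"
        )
    if n - p < 10:
        warnings.warn(
            f"IEAA fit has only {n - p} residual degrees of freedom",
            stacklevel=2,
        )
    return _fit_metric("IEAA", vals, design)


# ---------------------------------------------------------------------------
# pace of aging
# ---------------------------------------------------------------------------

def compute_pace_changes(
    pace: pd.Series,
    meta: pd.DataFrame,
    reference: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject pace deltas versus a comparison timepoint, plus cohort means.

    Returns a tidy frame (subject, timepoint, pace, delta) and the cohort
    mean delta per timepoint.  ``reference`` may be any timepoint label, so
    both pre-flight- and in-flight-referenced changes can be produced.
    """
    joined = meta.loc[pace.index].copy()
    joined["pace"] = pace.astype(float)
    ref_vals = (
        joined[joined["timepoint"] == reference]
        .set_index("subject")["pace"]
    )
    missing = set(joined["subject"]) - set(ref_vals.index)
    if missing:
        raise ValueError(f"subjects without a {reference!r} pace value: {sorted(missing)}")
    out = joined.reset_index()[["sample_id", "subject", "timepoint", "pace"]]
    out["delta"] = out["pace"].to_numpy() - out["subject"].map(ref_vals).to_numpy()
    means = out.groupby("timepoint", observed=True)["delta"].mean()
    return out, means


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def clock_mean_changes(
    metric: AgeMetricTable,
    meta: pd.DataFrame,
    t1: str,
    t2: str,
) -> pd.Series:
    """Per-clock change t2 − t1, averaged over subjects."""
    m = meta.loc[metric.values.index]
    v1 = metric.values[m["timepoint"] == t1]
    v2 = metric.values[m["timepoint"] == t2]
    s1 = m.loc[v1.index, "subject"]
    s2 = m.loc[v2.index, "subject"]
    common = sorted(set(s1) & set(s2))
    if not common:
        raise ValueError(f"no subjects sampled at both {t1!r} and {t2!r}")
    a = v1.set_axis(s1.to_numpy(), axis=0).loc[common]
    b = v2.set_axis(s2.to_numpy(), axis=0).loc[common]
    return (b - a).mean(axis=0)


def category_means(
    metric: AgeMetricTable,
    registry: ClockRegistry,
    meta: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Mean metric change per clock category for each timepoint pair.

    The category mean is the unweighted mean of its member clocks' mean
    changes; a ``grand_mean`` row averages the category means.
    """
    rows = []
    for t1, t2 in pairs:
        per_clock = clock_mean_changes(metric, meta, t1, t2)
        cats = pd.Series(
            {c: registry.category_of(c) for c in per_clock.index}, name="category"
        )
        by_cat = per_clock.groupby(cats).mean()
        for cat, val in by_cat.items():
            rows.append(
                {
                    "metric": metric.metric,
                    "category": cat,
                    "t1": t1,
                    "t2": t2,
                    "mean_change": float(val),
                    "n_clocks": int((cats == cat).sum()),
                }
            )
        rows.append(
            {
                "metric": metric.metric,
                "category": "grand_mean",
                "t1": t1,
                "t2": t2,
                "mean_change": float(by_cat.mean()),
                "n_clocks": int(len(per_clock)),
            }
        )
    return pd.DataFrame(rows)


def correlation_structure(
    metric: AgeMetricTable,
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation between samples' across-clock vectors.

    Each sample pair is labelled ``same_individual``, ``same_timepoint`` or
    ``neither`` (one record per subject and timepoint, so the first two are
    exclusive).  Returns the m × m correlation matrix, the tidy pair table
    and per-stratum summaries (mean, median, n).  Zero-variance vectors give
    undefined correlations, recorded as missing.
    """
    vals = metric.values
    if vals.shape[1] < 3:
        raise ValueError("correlation structure needs >= 3 clocks")
    x = vals.to_numpy(float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=vals.index, columns=vals.index)

    m = meta.loc[vals.index]
    rows = []
    for i, j in itertools.combinations(range(len(vals)), 2):
        si, sj = vals.index[i], vals.index[j]
        if m.loc[si, "subject"] == m.loc[sj, "subject"]:
            stratum = "same_individual"
        elif m.loc[si, "timepoint"] == m.loc[sj, "timepoint"]:
            stratum = "same_timepoint"
        else:
            stratum = "neither"
        rows.append({"sample_1": si, "sample_2": sj, "r": corr[i, j], "stratum": stratum})
    pairs = pd.DataFrame(rows)
    summary = (
        pairs.groupby("stratum")["r"]
        .agg(["mean", "median", "count"])
        .rename(columns={"count": "n_pairs"})
        .reset_index()
    )
    return corr_df, pairs, summary
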