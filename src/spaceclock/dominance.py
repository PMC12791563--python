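"""Dominance analysis: how much each cell type explains of EAA − IEAA.

Dominance analysis decomposes a regression's R² among predictors by averaging
each predictor's incremental R² over every subset of the others.  Here the
outcome is the per-(sample, clock) difference between epigenetic age
acceleration and its cell-adjusted (intrinsic) counterpart, and the
predictors are the sample's 12 immune-cell fractions — the decomposition
attributes the EAA-vs-IEAA divergence to individual cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .age_metrics import AgeMetricTable


@dataclass
class DominanceResult:
    """General dominance weights (R² units) plus supporting decompositions.

    ``general`` sums to ``full_r2`` (telescoping identity); ``conditional``
    holds the mean incremental R² at each subset size (rows: size of the
    conditioning subset, 0..p−1); ``marginal`` is each predictor's
    single-regressor R²; ``complete[i, j]`` is the fraction of shared
    conditioning subsets on which predictor i's incremental R² is at least
    predictor j's (1.0 everywhere off-diagonal in a row means i completely
    dominates every other predictor).
    """

    general: pd.Series
    conditional: pd.DataFrame
    marginal: pd.Series
    full_r2: float
    n_models: int
    complete: pd.DataFrame | None = None


def build_dominance_dataset(
    eaa: AgeMetricTable,
    ieaa: AgeMetricTable,
    cells: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Stack EAA − IEAA over (sample, clock) with the sample's cell fractions.

    Predictor columns are centred; each sample's fraction row is repeated
    across its clock observations so a single R² per cell type is obtained
    across all clocks.
    """
    if list(eaa.values.columns) != list(ieaa.values.columns):
        raise ValueError("EAA and IEAA tables have different clocks")
    if not eaa.values.index.equals(ieaa.values.index):
        raise ValueError("EAA and IEAA tables have different samples")
    missing = eaa.values.index.difference(cells.index)
    if len(missing):
        raise ValueError(f"samples missing from cell table: {list(missing)}")

    gap = eaa.values - ieaa.values
    long = gap.stack().rename("gap")
    long.index.names = ["sample_id", "clock"]
    x = cells.loc[long.index.get_level_values("sample_id")]
    x = x.set_index(long.index)
    x = x - x.mean(axis=0)
    return long, x


def _subset_r2(sxx: np.ndarray, sxy: np.ndarray, syy: float, p: int) -> np.ndarray:
    """R² for every non-empty predictor subset, indexed by bitmask.

    Singular subsets (e.g. the full simplex of fractions) are solved by
    minimum-norm least squares; R² is the projection onto the subset's column
    space, which is well defined regardless of rank.
    """
    r2 = np.zeros(2**p)
    warned = False
    for mask in range(1, 2**p):
        idx = [j for j in range(p) if mask >> j & 1]
        a = sxx[np.ix_(idx, idx)]
        b = sxy[idx]
        sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
        if rank < len(idx) and not warned:
            warnings.warn(
                "rank-deficient predictor subset encountered; using "
                "minimum-norm fits",
                stacklevel=3,
            )
            warned = True
        r2[mask] = float(sol @ b) / syy
    return r2


def dominance_analysis(
    outcome: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
) -> DominanceResult:
    """General dominance weights over all 2^p − 1 predictor subsets.

    The weight of predictor j is the average over conditioning-subset sizes
    k = 0..p−1 of the mean incremental R² from adding j to size-k subsets
    that lack it.  Weights sum to the full-model R² exactly.
    """
    y = np.asarray(outcome, float)
    x = predictors.to_numpy(float)
    n, p = x.shape
    if p > 16:
        raise ValueError(f"{p} predictors: subset enumeration capped at 16")
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} observations, got {n}")

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    rank = np.linalg.matrix_rank(xc)
    if rank < p - 1:
        from scipy.linalg import qr

        _, _, piv = qr(xc, pivoting=True)
        offending = sorted(predictors.columns[j] for j in piv[rank:])
        raise ValueError(
            f"predictor matrix rank {rank} < {p - 1}: collinear columns "
            f"beyond the simplex redundancy: {offending}"
        )
    syy = float(yc @ yc)
    names = list(predictors.columns)
    if syy == 0.0:
        warnings.warn("outcome has zero variance; all weights set to 0", stacklevel=2)
        zero = pd.Series(np.zeros(p), index=names)
        return DominanceResult(
            general=zero,
            conditional=pd.DataFrame(np.zeros((p, p)), index=range(p), columns=names),
            marginal=zero.copy(),
            full_r2=0.0,
            n_models=2**p - 1,
            complete=pd.DataFrame(np.ones((p, p)), index=names, columns=names),
        )

    sxx = xc.T @ xc
    sxy = xc.T @ yc
    r2 = _subset_r2(sxx, sxy, syy, p)

    masks = np.arange(2**p)
    sizes = np.array([int(m).bit_count() for m in masks])
    conditional = np.empty((p, p))      # [size k, predictor j]
    for j in range(p):
        bit = 1 << j
        without = masks[(masks & bit) == 0]
        incr = r2[without | bit] - r2[without]
        k = sizes[without]
        sums = np.bincount(k, weights=incr, minlength=p)
        counts = np.bincount(k, minlength=p)
        conditional[:, j] = sums / counts
    general = conditional.mean(axis=0)

    complete = np.ones((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            both = (1 << i) | (1 << j)
            shared = masks[(masks & both) == 0]
            inc_i = r2[shared | (1 << i)] - r2[shared]
            inc_j = r2[shared | (1 << j)] - r2[shared]
            complete[i, j] = float(np.mean(inc_i >= inc_j - 1e-12))

    return DominanceResult(
        general=pd.Series(general, index=names),
        conditional=pd.DataFrame(conditional, index=range(p), columns=names),
        marginal=pd.Series([r2[1 << j] for j in range(p)], index=names),
        full_r2=float(r2[-1]),
        n_models=2**p - 1,
        complete=pd.DataFrame(complete, index=names, columns=names),
    )


def dominance_table(result: DominanceResult) -> pd.DataFrame:
    """CSV-ready view keyed by cell type."""
    out = pd.DataFrame(
        {
            "general_dominance": result.general,
            "marginal_R2": result.marginal,
        }
    )
    out["full_model_R2"] = result.full_r2
    out.index.name = "cell_type"
    return out.reset_index()
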