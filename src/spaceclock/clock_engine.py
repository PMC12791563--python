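"""Apply linear epigenetic clocks to beta matrices and deconvolve cell fractions.

The engine is generic: a clock is any sparse linear model over CpG beta
values (published coefficient sets are user-supplied resources).  Cell
composition is estimated by reference-based deconvolution: non-negative least
squares of each sample's profile on pure-cell reference profiles, followed by
sum-to-one renormalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.optimize import nnls

logger = logging.getLogger("spaceclock")


@dataclass
class ClockModel:
    """A sparse linear clock: intercept plus CpG coefficients (years/beta unit)."""

    name: str
    intercept: float
    coefficients: Mapping[str, float]
    post_transform: str = "identity"   # hook for e.g. anti-log clocks

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError(f"clock model {self.name!r} has no coefficients")
        if len(set(self.coefficients)) != len(self.coefficients):
            raise ValueError(f"clock model {self.name!r} has duplicate CpGs")
        if self.post_transform not in ("identity",):
            raise ValueError(
                f"unsupported post-transform {self.post_transform!r}"
            )


def write_clock_model(model: ClockModel, path: str | Path) -> None:
    """CSV with a one-line header record (# name, intercept) then CpG rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# name={model.name},intercept={model.intercept!r}\n")
        fh.write("CpG,coefficient\n")
        for cpg, coef in model.coefficients.items():
            fh.write(f"{cpg},{coef!r}\n")


def read_clock_model(path: str | Path) -> ClockModel:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# name="):
            raise ValueError(f"clock model {path}: missing header record")
        meta = dict(kv.split("=", 1) for kv in header[2:].split(","))
        body = pd.read_csv(fh)
    coeffs = dict(zip(body["CpG"].astype(str), body["coefficient"].astype(float)))
    return ClockModel(meta["name"], float(meta["intercept"]), coeffs)


@dataclass
class ClockApplication:
    """Per-sample ages plus a coverage report for missing model CpGs."""

    ages: pd.Series
    n_model_cpgs: int
    n_measured: int
    n_imputed: int
    n_dropped: int
    dropped: list[str] = field(default_factory=list)


def apply_linear_clock(
    beta: pd.DataFrame,
    model: ClockModel,
    impute: Mapping[str, float] | None = None,
    max_missing_fraction: float = 0.1,
) -> ClockApplication:
    """age(sample) = intercept + sum_j coef_j * beta[j, sample].

    Model CpGs absent from ``beta`` are imputed from the user-supplied
    per-CpG default table (e.g. blood-specific medians) when available,
    otherwise dropped; CpGs that are neither measured nor imputable count
    toward ``max_missing_fraction``.
    """
    impute = impute or {}
    cpgs = list(model.coefficients)
    present = [c for c in cpgs if c in beta.index]
    absent = [c for c in cpgs if c not in beta.index]
    imputable = [c for c in absent if c in impute]
    dropped = [c for c in absent if c not in impute]
    frac_lost = len(dropped) / len(cpgs)
    if frac_lost > max_missing_fraction:
        raise ValueError(
            f"clock {model.name!r}: {frac_lost:.1%} of model CpGs are absent "
            f"and not imputable (limit {max_missing_fraction:.1%})"
        )
    if dropped:
        logger.warning(
            "clock %s: dropping %d unmeasured CpGs with no imputation default",
            model.name, len(dropped),
        )

    coefs = np.array([model.coefficients[c] for c in present])
    ages = model.intercept + coefs @ beta.loc[present].to_numpy(float)
    for cpg in imputable:
        ages = ages + model.coefficients[cpg] * float(impute[cpg])
    return ClockApplication(
        ages=pd.Series(ages, index=beta.columns, name=model.name),
        n_model_cpgs=len(cpgs),
        n_measured=len(present),
        n_imputed=len(imputable),
        n_dropped=len(dropped),
        dropped=dropped,
    )


@dataclass
class DeconvolutionResult:
    """Simplex-constrained fractions plus per-sample residual norms."""

    fractions: pd.DataFrame       # samples × cell types, rows sum to 1
    residual_norm: pd.Series      # ||R pi_raw - beta|| per sample
    n_cpgs_used: int


def _rank_check(ref: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(ref)
    if rank < ref.shape[1]:
        # column-pivoted QR flags the profiles that add no independent signal
        _, _, piv = qr(ref, pivoting=True)
        offending = sorted(columns[j] for j in piv[rank:])
        raise ValueError(
            f"reference matrix is rank deficient (rank {rank} < "
            f"{ref.shape[1]} cell types); collinear profiles: {offending}"
        )


def deconvolve_cell_fractions(
    beta: pd.DataFrame,
    reference: pd.DataFrame,
) -> DeconvolutionResult:
    """Estimate cell fractions per sample by NNLS against pure-cell profiles.

    For each sample, solve min ||R pi - beta||^2 subject to pi >= 0 over the
    CpGs shared between beta and reference, then renormalise to sum 1.
    """
    shared = reference.index.intersection(beta.index)
    k = reference.shape[1]
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} shared CpGs for {k} cell types; "
            "need at least as many CpGs as cell types"
        )
    r = reference.loc[shared].to_numpy(float)
    cols = list(reference.columns)
    _rank_check(r, cols)

    b = beta.loc[shared].to_numpy(float)
    frac = np.empty((beta.shape[1], k))
    resid = np.empty(beta.shape[1])
    for s in range(beta.shape[1]):
        pi, rnorm = nnls(r, b[:, s])
        total = pi.sum()
        if total <= 0:
            raise ValueError(
                f"sample {beta.columns[s]!r}: all-zero NNLS solution; "
                "profile is orthogonal to every reference column"
            )
        frac[s] = pi / total
        resid[s] = rnorm
    return DeconvolutionResult(
        fractions=pd.DataFrame(frac, index=beta.columns, columns=cols),
        residual_norm=pd.Series(resid, index=beta.columns, name="residual_norm"),
        n_cpgs_used=len(shared),
    )
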