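"""Significance machinery for clock-wise repeated measures.

For each crew member and timepoint pair the vector of per-clock metric
differences is tested two ways: a paired Wilcoxon signed-rank test, and a
sign-flip permutation test on the mean difference that respects the strong
dependence between clocks (the signs of all clocks' differences are
randomised jointly to build the null of the mean).  Cross-subject effects
are estimated with a linear mixed model with crossed random intercepts for
crew member and clock.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .age_metrics import AgeMetricTable

logger = logging.getLogger("spaceclock")


# ---------------------------------------------------------------------------
# paired differences
# ---------------------------------------------------------------------------

@dataclass
class PairedDiffVector:
    """Per-clock metric differences value(t2) − value(t1) for one subject."""

    subject: str
    metric: str
    t1: str
    t2: str
    clocks: list[str]
    diffs: np.ndarray

    def __len__(self) -> int:
        return len(self.diffs)


def paired_differences(
    metric: AgeMetricTable,
    meta: pd.DataFrame,
    subject: str,
    t1: str,
    t2: str,
) -> PairedDiffVector:
    """Difference vector across clocks for one subject and timepoint pair.

    Clocks missing (NaN) at either timepoint are excluded and logged.
    """
    m = meta.loc[metric.values.index]
    sel1 = (m["subject"] == subject) & (m["timepoint"] == t1)
    sel2 = (m["subject"] == subject) & (m["timepoint"] == t2)
    if sel1.sum() != 1 or sel2.sum() != 1:
        raise ValueError(
            f"subject {subject!r} needs exactly one sample at {t1!r} and {t2!r}"
        )
    v1 = metric.values[sel1].iloc[0]
    v2 = metric.values[sel2].iloc[0]
    diff = v2 - v1
    keep = diff.notna()
    if (~keep).any():
        logger.warning(
            "subject %s %s->%s: excluding clocks with missing values: %s",
            subject, t1, t2, list(diff.index[~keep]),
        )
    return PairedDiffVector(
        subject=subject,
        metric=metric.metric,
        t1=t1,
        t2=t2,
        clocks=list(diff.index[keep]),
        diffs=diff[keep].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    p: float
    w_plus: float
    n_nonzero: int
    n_zeros: int
    method: str


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all sign assignments, midranks allowed.

    Midranks are multiples of 1/2, so doubling them gives integers and the
    null distribution of 2·W⁺ is built by subset-sum counting.  Two-sided p
    is twice the smaller tail, capped at 1 (the distribution is symmetric).
    """
    scaled = np.rint(2 * ranks).astype(np.int64)
    total = int(scaled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()          # 2^n
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    diffs: Sequence[float] | np.ndarray,
    exact_limit: int = 25,
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on a difference vector.

    Zeros are dropped (their count reported), tied magnitudes get midranks.
    The exact null distribution is used for n ≤ ``exact_limit``; beyond that
    a normal approximation with continuity correction, with the variance
    computed from the realised (mid)ranks so ties are accounted for.
    """
    d = np.asarray(diffs, float)
    n_zeros = int((d == 0).sum())
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(1.0, 0.0, 0, n_zeros, "degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        return WilcoxonResult(
            _exact_signed_rank_p(ranks, w_plus), w_plus, n, n_zeros, "exact"
        )
    mean = ranks.sum() / 2.0
    sd = np.sqrt((ranks**2).sum() / 4.0)
    z = w_plus - mean
    z = (z - 0.5 * np.sign(z)) / sd       # continuity correction toward the mean
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(p, w_plus, n, n_zeros, "normal-approx")


# ---------------------------------------------------------------------------
# sign-flip permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_mean: float
    p: float
    exceedance: int
    n_permutations: int

    @property
    def label(self) -> str:
        """Reported p; zero exceedances are reported as '< 1/n_permutations'."""
        if self.exceedance == 0:
            return f"< {1.0 / self.n_permutations:.2e}"
        return f"{self.p:.4g}"


def signflip_permutation_test(
    diffs: Sequence[float] | np.ndarray,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Sign-flip permutation test on the mean of a paired-difference vector.

    Each permutation assigns a random ± sign to every difference; the p-value
    is the plain proportion of permuted means whose absolute value meets or
    exceeds the observed absolute mean (no +1 smoothing, so a zero exceedance
    count is representable and labelled '< 1/n_permutations').
    """
    d = np.asarray(diffs, float)
    if d.size == 0:
        raise ValueError("empty difference vector")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    obs = float(d.mean())
    signs = rng.integers(0, 2, size=(n_permutations, d.size)) * 2 - 1
    means = (signs @ d) / d.size
    tol = 1e-12 * max(1.0, abs(obs))
    exceed = int((np.abs(means) >= abs(obs) - tol).sum())
    return PermutationResult(obs, exceed / n_permutations, exceed, n_permutations)


def signflip_exact_p(diffs: Sequence[float] | np.ndarray) -> float:
    """Exhaustive sign-flip p over all 2^n assignments (n ≤ 20)."""
    d = np.asarray(diffs, float)
    n = d.size
    if n == 0:
        raise ValueError("empty difference vector")
    if n > 20:
        raise ValueError("exhaustive enumeration limited to n <= 20")
    masks = np.arange(2**n, dtype=np.int64)
    signs = 1 - 2 * ((masks[:, None] >> np.arange(n)) & 1)
    means = (signs @ d) / n
    obs = float(d.mean())
    tol = 1e-12 * max(1.0, abs(obs))
    return float((np.abs(means) >= abs(obs) - tol).mean())


# ---------------------------------------------------------------------------
# per-comparison results
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """One (subject, metric, timepoint pair) row: effect size and both tests."""

    subject: str
    metric: str
    t1: str
    t2: str
    n_clocks: int
    mean_diff: float
    se: float
    ci_low: float
    ci_high: float
    p_wilcoxon: float
    p_perm: float
    exceedance: int
    n_permutations: int
    p_perm_label: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compare_timepoints(
    metric: AgeMetricTable,
    meta: pd.DataFrame,
    subject: str,
    t1: str,
    t2: str,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> ComparisonResult:
    """Mean paired difference across clocks with t-based 95% CI and both tests."""
    vec = paired_differences(metric, meta, subject, t1, t2)
    d = vec.diffs
    n = d.size
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    if n > 1:
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (mean - tcrit * se, mean + tcrit * se)
    else:
        ci = (float("nan"), float("nan"))
    wil = wilcoxon_signed_rank(d)
    perm = signflip_permutation_test(d, n_permutations=n_permutations, seed=seed)
    return ComparisonResult(
        subject=subject,
        metric=metric.metric,
        t1=t1,
        t2=t2,
        n_clocks=n,
        mean_diff=mean,
        se=se,
        ci_low=ci[0],
        ci_high=ci[1],
        p_wilcoxon=wil.p,
        p_perm=perm.p,
        exceedance=perm.exceedance,
        n_permutations=perm.n_permutations,
        p_perm_label=perm.label,
    )


# ---------------------------------------------------------------------------
# linear mixed model with crossed random intercepts
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """REML fit of value ~ timepoint with crossed subject and clock intercepts."""

    t1: str
    t2: str
    beta0: float
    beta1: float
    p_value: float
    var_subject: float
    var_clock: float
    var_resid: float
    method: str
    converged: bool
    n_obs: int
    effects: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)


class LMMConvergenceError(RuntimeError):
    pass


def _fit_mixedlm(data: pd.DataFrame, formula: str):
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = smf.mixedlm(
        formula,
        data=data,
        groups=pd.Series(np.zeros(len(data)), index=data.index),
        vc_formula={"subject": "0 + C(subject)", "clock": "0 + C(clock)"},
        re_formula="0",
    )
    last_err: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                res = model.fit(reml=True, method=method, maxiter=500)
            if res.converged:
                return model, res
            last_err = RuntimeError(f"optimizer {method!r} did not converge")
        except Exception as err:          # singular Hessian etc.
            last_err = err
    raise LMMConvergenceError(f"mixed-model fit failed: {last_err}")


def _vcomp_map(model, res) -> dict[str, float]:
    names = list(model.exog_vc.names)
    return {name: float(v) for name, v in zip(names, res.vcomp)}


def fit_lmm(long: pd.DataFrame, t1: str, t2: str) -> LMMFit:
    """Pairwise contrast: REML fit on the two timepoints' rows only.

    ``long`` needs columns subject, clock, timepoint, value.  The fixed
    effect β₁ is the t2 − t1 difference; subject and clock contribute crossed
    random intercepts.  P-values are Wald-z (recorded in ``method``); a
    variance component estimated at 0 triggers a warning, not an error.
    """
    data = long[long["timepoint"].astype(str).isin([t1, t2])].copy()
    if data["subject"].nunique() < 2 or data["clock"].nunique() < 2:
        raise ValueError("need >= 2 subjects and >= 2 clocks")
    for t in (t1, t2):
        if not (data["timepoint"].astype(str) == t).any():
            raise ValueError(f"no rows at timepoint {t!r}")
    data["tp01"] = (data["timepoint"].astype(str) == t2).astype(float)
    model, res = _fit_mixedlm(data, "value ~ tp01")
    vc = _vcomp_map(model, res)
    if min(vc.values()) <= 1e-10:
        warnings.warn("a random-intercept variance was estimated at 0", stacklevel=2)
    return LMMFit(
        t1=t1,
        t2=t2,
        beta0=float(res.params["Intercept"]),
        beta1=float(res.params["tp01"]),
        p_value=float(res.pvalues["tp01"]),
        var_subject=vc.get("subject", float("nan")),
        var_clock=vc.get("clock", float("nan")),
        var_resid=float(res.scale),
        method="reml/wald-z",
        converged=bool(res.converged),
        n_obs=len(data),
        effects={f"{t2}-{t1}": float(res.params["tp01"])},
        pvalues={f"{t2}-{t1}": float(res.pvalues["tp01"])},
    )


def fit_lmm_trajectory(long: pd.DataFrame, reference: str) -> LMMFit:
    """Whole-trajectory variant: all timepoints in one model vs the reference."""
    data = long.copy()
    data["timepoint"] = data["timepoint"].astype(str)
    if reference not in set(data["timepoint"]):
        raise ValueError(f"reference {reference!r} absent from data")
    formula = f"value ~ C(timepoint, Treatment(reference={reference!r}))"
    model, res = _fit_mixedlm(data, formula)
    vc = _vcomp_map(model, res)
    effects, pvals = {}, {}
    for name, val in res.params.items():
        if name.startswith("C(timepoint"):
            label = name.split("[T.")[-1].rstrip("]")
            effects[f"{label}-{reference}"] = float(val)
            pvals[f"{label}-{reference}"] = float(res.pvalues[name])
    first = next(iter(effects), None)
    return LMMFit(
        t1=reference,
        t2="(all)",
        beta0=float(res.params["Intercept"]),
        beta1=effects.get(first, float("nan")),
        p_value=pvals.get(first, float("nan")),
        var_subject=vc.get("subject", float("nan")),
        var_clock=vc.get("clock", float("nan")),
        var_resid=float(res.scale),
        method="reml/wald-z",
        converged=bool(res.converged),
        n_obs=len(data),
        effects=effects,
        pvalues=pvals,
    )


def metric_long_table(metric: AgeMetricTable, meta: pd.DataFrame) -> pd.DataFrame:
    """(subject, clock, timepoint, value) rows for mixed-model fitting."""
    long = metric.long().merge(
        meta[["subject", "timepoint"]].reset_index(), on="sample_id"
    )
    return long[["subject", "clock", "timepoint", "value"]]


# ---------------------------------------------------------------------------
# leave-one-out sensitivity
# ---------------------------------------------------------------------------

def leave_one_out_sensitivity(
    metric: AgeMetricTable,
    meta: pd.DataFrame,
    subject: str,
    pair: tuple[str, str],
    n_permutations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    exact: bool = False,
) -> pd.DataFrame:
    """Re-run mean/Wilcoxon/permutation with each clock excluded in turn.

    Flags exclusions whose p-value crosses ``alpha`` relative to the
    all-clock analysis, exposing single clocks that drive significance.
    With ``exact=True`` (feasible for ≤ 20 clocks) the sign-flip p is the
    exhaustive-enumeration value instead of a sampled estimate.
    """
    t1, t2 = pair
    vec = paired_differences(metric, meta, subject, t1, t2)
    if len(vec) < 3:
        raise ValueError("sensitivity analysis needs >= 3 clocks")
    rng = np.random.default_rng(seed)

    def _perm_p(d: np.ndarray) -> tuple[float, str]:
        if exact:
            p = signflip_exact_p(d)
            return p, f"{p:.4g}"
        res = signflip_permutation_test(d, n_permutations=n_permutations, seed=rng)
        return res.p, res.label

    full_w = wilcoxon_signed_rank(vec.diffs).p
    full_p, _ = _perm_p(vec.diffs)
    rows = []
    for k, clock in enumerate(vec.clocks):
        d = np.delete(vec.diffs, k)
        wil = wilcoxon_signed_rank(d)
        p_perm, label = _perm_p(d)
        rows.append(
            {
                "excluded_clock": clock,
                "mean_diff": float(d.mean()),
                "p_wilcoxon": wil.p,
                "p_perm": p_perm,
                "p_perm_label": label,
                "crosses_alpha_wilcoxon": (wil.p < alpha) != (full_w < alpha),
                "crosses_alpha_perm": (p_perm < alpha) != (full_p < alpha),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["full_p_wilcoxon"] = full_w
    out.attrs["full_p_perm"] = full_p
    return out
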