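"""Inferential toolbox for panel response analysis.

Covers the procedures used to read a receptor-panel experiment: one-way
ANOVA for differential activation across odorants, Tukey's HSD for pairwise
odorant contrasts, Dunnett's many-to-one test for response-onset timing,
Benjamini-Hochberg FDR for enzyme co-expression comparisons, and ordinary
least-squares regression with R-squared defined as the squared Pearson
correlation.

All two-sample t-tests default to the Welch (unequal-variance) form; a
pooled-variance option is available for cross-checking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .errors import DataError, InsufficientDataError, ParameterError
from .traceproc import ResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult", "RegressionResult", "OnsetResult",
    "one_way_anova", "f_critical", "tukey_hsd",
    "differential_activation_counts", "dunnett_onset", "bh_fdr",
    "ces1d_compare", "regression_r2", "reproducibility_contrast",
    "welch_t_test", "fit_hill",
]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float


@dataclass(frozen=True)
class OnsetResult:
    onset_cycle: int | None       # earliest cycle with adjusted p < alpha and rise
    anova: AnovaResult
    adjusted_p: dict[int, float]  # per non-baseline cycle


def _check_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise InsufficientDataError(f"group {i} has n < 2 replicates")
    return arrays


def one_way_anova(groups) -> AnovaResult:
    """Classical between/within sum-of-squares decomposition.

    Seven odorant groups of three replicates give df = (6, 14), the design
    under which the panel's differential-activation F statistics are read.
    """
    arrays = _check_groups(groups)
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = all_values.size - len(arrays)
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = 1.0 if f == 0 else float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(f=float(f), df_between=df_b, df_within=df_w, p=p)


def f_critical(df1: int, df2: int, alpha: float = 0.05) -> float:
    """Upper-tail critical value of the F distribution."""
    if df1 < 1 or df2 < 1:
        raise ParameterError("degrees of freedom must be >= 1")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    return float(sps.f.isf(alpha, df1, df2))


def tukey_hsd(groups, labels=None) -> pd.DataFrame:
    """All-pairs studentized-range comparisons after a one-way layout.

    Returns a tidy frame with columns group_i, group_j, mean_diff, p_adj
    (one row per unordered pair, i < j in label order).
    """
    arrays = _check_groups(groups)
    if labels is None:
        labels = list(range(len(arrays)))
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append({
                "group_i": labels[i],
                "group_j": labels[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)


def differential_activation_counts(
    matrix: ResponseMatrix,
    alpha: float = 0.05,
    exclude_control: bool = True,
) -> pd.DataFrame:
    """Count, per odorant pair, the receptors that distinguish the pair.

    For each receptor, responses across odorant conditions (replicate level)
    enter a one-way ANOVA followed by Tukey's HSD; a receptor counts toward
    a pair when the adjusted p is below ``alpha``.  Returns a symmetric
    odorant x odorant integer table.
    """
    odorants = list(dict.fromkeys(matrix.tidy["odorant_id"]))
    if len(odorants) < 2:
        raise InsufficientDataError("need >= 2 odorant conditions")
    keys = matrix.condition_keys
    by_odorant = {}
    for k in keys:
        od = matrix.tidy.loc[matrix.tidy["condition"] == k, "odorant_id"].iloc[0]
        if od in by_odorant:
            raise ParameterError(
                "matrix mixes several conditions per odorant; restrict to one concentration first")
        by_odorant[od] = k
    or_ids = [o for o in matrix.or_ids if not (exclude_control and o == matrix.control_id)]
    counts = pd.DataFrame(0, index=odorants, columns=odorants, dtype=int)
    for or_id in or_ids:
        groups = [matrix.replicate_values(or_id, by_odorant[od]) for od in odorants]
        if one_way_anova(groups).p >= alpha:
            continue
        pairs = tukey_hsd(groups, labels=odorants)
        for _, row in pairs.iterrows():
            if row["p_adj"] < alpha:
                counts.loc[row["group_i"], row["group_j"]] += 1
                counts.loc[row["group_j"], row["group_i"]] += 1
    return counts


def dunnett_onset(
    cycle_values: dict[int, np.ndarray],
    baseline_cycle: int = 1,
    alpha: float = 0.05,
    seed: int = 0,
) -> OnsetResult:
    """Earliest reading cycle whose response exceeds the baseline cycle.

    One-way ANOVA across cycles gates the analysis; if significant, each
    non-baseline cycle is compared with the baseline cycle using Dunnett's
    many-to-one procedure (equi-correlated multivariate-t adjustment, exact
    for balanced designs).  The onset is the earliest cycle with adjusted
    p < alpha and a positive mean difference; ``None`` if no onset.
    """
    if baseline_cycle not in cycle_values:
        raise ParameterError(f"baseline cycle {baseline_cycle} missing from data")
    cycles = sorted(cycle_values)
    arrays = {c: np.asarray(cycle_values[c], dtype=float) for c in cycles}
    anova = one_way_anova([arrays[c] for c in cycles])
    others = [c for c in cycles if c != baseline_cycle]
    if anova.p >= alpha:
        return OnsetResult(onset_cycle=None, anova=anova,
                           adjusted_p={c: 1.0 for c in others})
    res = sps.dunnett(*[arrays[c] for c in others], control=arrays[baseline_cycle],
                      random_state=seed)
    adjusted = {c: float(p) for c, p in zip(others, res.pvalue)}
    control_mean = arrays[baseline_cycle].mean()
    onset = None
    for c in others:
        if adjusted[c] < alpha and arrays[c].mean() > control_mean:
            onset = c
            break
    return OnsetResult(onset_cycle=onset, anova=anova, adjusted_p=adjusted)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def welch_t_test(a, b, equal_var: bool = False):
    """Two-sided two-sample t-test (Welch by default). Returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need >= 2 replicates per group")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def ces1d_compare(
    matrix_without: ResponseMatrix,
    matrix_with: ResponseMatrix,
    alpha: float = 0.05,
    exclude_control: bool = True,
) -> pd.DataFrame:
    """Per (receptor, odorant) fold change with vs without enzyme co-expression.

    Fold = mean response with enzyme / mean response without; a two-sided
    Welch t-test per cell is FDR-adjusted (Benjamini-Hochberg) across the
    receptor panel within each odorant.  Cells with a non-positive
    denominator mean get fold = NaN and are flagged undefined.
    """
    odorants = list(dict.fromkeys(matrix_without.tidy["odorant_id"]))
    or_ids = [o for o in matrix_without.or_ids
              if not (exclude_control and o == matrix_without.control_id)]
    key_wo = {(r.or_id, r.odorant_id) for r in matrix_without.tidy.itertuples()}
    rows = []
    for odorant in odorants:
        cond_wo = [k for k in matrix_without.condition_keys
                   if matrix_without.tidy.loc[matrix_without.tidy["condition"] == k,
                                              "odorant_id"].iloc[0] == odorant]
        cond_wi = [k for k in matrix_with.condition_keys
                   if matrix_with.tidy.loc[matrix_with.tidy["condition"] == k,
                                           "odorant_id"].iloc[0] == odorant]
        if len(cond_wo) != 1 or len(cond_wi) != 1:
            raise ParameterError(f"expected exactly one condition per odorant ({odorant})")
        block = []
        for or_id in or_ids:
            if (or_id, odorant) not in key_wo:
                continue
            without = matrix_without.replicate_values(or_id, cond_wo[0])
            with_enz = matrix_with.replicate_values(or_id, cond_wi[0])
            t, p = welch_t_test(with_enz, without)
            mean_wo = without.mean()
            mean_wi = with_enz.mean()
            fold = mean_wi / mean_wo if mean_wo > 0 else np.nan
            if mean_wo <= 0:
                logger.warning("fold undefined for %s/%s: non-positive denominator", or_id, odorant)
            block.append({
                "or_id": or_id, "odorant_id": odorant,
                "mean_without": mean_wo, "mean_with": mean_wi,
                "fold": fold, "p": p,
                "direction": "up" if mean_wi > mean_wo else "down",
            })
        adj = bh_fdr([r["p"] for r in block])
        for r, q in zip(block, adj):
            r["p_adj"] = float(q)
            r["significant"] = bool(q < alpha)
        rows.extend(block)
    return pd.DataFrame(rows)


def regression_r2(x, y) -> RegressionResult:
    """OLS line y ~ x with R-squared defined as the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise DataError("zero variance in x: regression undefined")
    if np.ptp(y) == 0:
        warnings.warn("zero variance in y: R-squared defined as 0", stacklevel=2)
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, p=1.0)
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2), p=float(res.pvalue))


def reproducibility_contrast(same_r2, different_r2, equal_var: bool = False):
    """Compare same-odorant cross-run R^2 values with different-odorant R^2 values.

    Returns (t, p, mean_same, mean_different) from a two-sided two-sample
    t-test; a positive t with small p supports that replicate runs of the
    same odorant reproduce better than runs of different analogs correlate.
    """
    same = np.asarray(same_r2, dtype=float)
    diff = np.asarray(different_r2, dtype=float)
    if same.size < 2 or diff.size < 2:
        raise InsufficientDataError("need >= 2 values per list")
    t, p = welch_t_test(same, diff, equal_var=equal_var)
    return t, p, float(same.mean()), float(diff.mean())


def fit_hill(concentrations, responses, *, max_efficacy: float | None = None):
    """Fit a Hill dose-response r = E * c^h / (c^h + K^h) to scalar responses.

    Fitting is done on log10(EC50) with positivity bounds; returns
    (ec50, efficacy, hill).  Used to check that generative dose-response
    parameters are recoverable from simulated dose series.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size != r.size or c.size < 4:
        raise InsufficientDataError("need >= 4 dose points")
    if np.any(c <= 0):
        raise ParameterError("concentrations must be positive")

    def model(logc, log_ec50, efficacy, hill):
        return efficacy / (1.0 + 10 ** (hill * (log_ec50 - logc)))

    logc = np.log10(c)
    e0 = max_efficacy or max(r.max(), 1e-6)
    p0 = [np.median(logc), e0, 1.0]
    bounds = ([logc.min() - 4, 0.0, 0.1], [logc.max() + 4, 10 * e0, 6.0])
    popt, _ = optimize.curve_fit(model, logc, r, p0=p0, bounds=bounds, maxfev=20000)
    return 10.0 ** popt[0], float(popt[1]), float(popt[2])
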