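"""Statistical layer: group comparisons, regression diagnostics, multiple
comparisons, and GEE modeling of longitudinal percent change.

The centerpiece is :func:`gee_fit`, a generalized-estimating-equations fit
with identity link, normal variance, and an exchangeable working
correlation: iterate (1) a GLS-type update of the coefficients given the
working correlation and (2) moment estimates of the dispersion φ and the
within-subject correlation α from Pearson residuals, until the
coefficients stabilize.  The returned covariance is the robust (sandwich)
estimator, so inference is valid even when the exchangeable assumption is
wrong.  :func:`estimate_group_day_change` turns a fit into the estimated
percent change from baseline for one group at one follow-up interval with
a normal-quantile 95 % CI.

The surrounding tests are the field's standard toolkit: exact and
asymptotic Mann–Whitney U, one-way ANOVA and Kruskal–Wallis, Holm
step-down adjustment, and Pearson correlation with simple-regression
influence diagnostics (DFFITS).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dosi_recovery import INTERVAL_LABELS, assign_interval, percent_change
from .synthetic_cohort import POST, PRE

__all__ = [
    "MannWhitneyResult", "GroupTestResult", "HolmResult",
    "RegressionDiagnostics", "GEEFit", "ContrastEstimate", "ConvergenceError",
    "mann_whitney", "anova_oneway", "kruskal_wallis", "holm_adjust",
    "pearson_with_diagnostics", "prepare_change_table", "gee_fit",
    "estimate_group_day_change",
]


class ConvergenceError(RuntimeError):
    """Iterative estimation failed to converge."""


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x over y with mid-rank tie handling."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def mann_whitney(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    ``mode="exact"`` enumerates every assignment of the pooled sample to
    the two groups (mid-rank ties included) and counts assignments whose U
    is at least as far from its null mean as the observed one; it is the
    default for combined sample sizes up to 16.  Larger samples use the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if n_x + n_y <= 16 else "asymptotic"

    u_obs = _u_statistic(x, y)
    if mode == "exact":
        # mid-ranks of the pooled sample are assignment-invariant, so each
        # candidate U is just a rank-subset sum
        ranks = sps.rankdata(np.concatenate([x, y]))
        offset = n_x * (n_x + 1) / 2.0
        mu = n_x * n_y / 2.0
        dev_obs = abs(u_obs - mu)
        count = total = 0
        for chosen in itertools.combinations(ranks, n_x):
            u = sum(chosen) - offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return MannWhitneyResult(u=u_obs, p_value=count / total, method="exact")

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue),
                             method="asymptotic")


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    df: tuple


def _check_groups(groups):
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    return groups


def anova_oneway(*groups) -> GroupTestResult:
    """Classical one-way ANOVA F test across the groups."""
    groups = _check_groups(groups)
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("F undefined: zero within-group variance everywhere")
    stat, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    return GroupTestResult(statistic=float(stat), p_value=float(p),
                           df=(k - 1, n - k))


def kruskal_wallis(*groups) -> GroupTestResult:
    """Kruskal–Wallis H test with tie correction, chi-square p-value."""
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    if np.unique(pooled).size < 2:
        raise ValueError("H undefined: all observations identical")
    stat, p = sps.kruskal(*groups)
    return GroupTestResult(statistic=float(stat), p_value=float(p),
                           df=(len(groups) - 1,))


# ---------------------------------------------------------------------------
# multiple comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HolmResult:
    adjusted: np.ndarray
    reject: np.ndarray
    alpha: float


def holm_adjust(p_values, alpha: float = 0.05) -> HolmResult:
    """Bonferroni–Holm step-down adjustment at family-wise level alpha.

    Adjusted p-values are monotone non-decreasing when read in raw-p
    order, and decisions are invariant to the input ordering.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=alpha, method="holm")
    return HolmResult(adjusted=adjusted, reject=reject, alpha=alpha)


# ---------------------------------------------------------------------------
# correlation and regression diagnostics
# ---------------------------------------------------------------------------

@dataclass
class RegressionDiagnostics:
    """Pearson correlation plus simple-regression influence diagnostics."""

    r: float
    p_value: float
    slope: float
    intercept: float
    residuals: np.ndarray
    leverage: np.ndarray
    dffits: np.ndarray
    influential: np.ndarray
    dffits_threshold: float


def pearson_with_diagnostics(x, y) -> RegressionDiagnostics:
    """Pearson r with t-based two-sided p, OLS line, and DFFITS per point.

    DFFITS is computed from the leave-one-out closed form
    ``DFFITS_i = e_i √h_i / (s_(i) (1 − h_i))`` with the externally
    studentized scale ``s_(i)``; points with |DFFITS| > 2√(2/n) are
    flagged.  A perfect linear fit has zero residuals and, by convention,
    zero DFFITS.  Requires n ≥ 3 and nonconstant x and y (DFFITS needs
    n ≥ 4 and is NaN at n = 3).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")

    r, p = sps.pearsonr(x, y)
    design = np.stack([np.ones(n), x], axis=1)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    # hat diagonal of simple regression
    h = 1.0 / n + (x - x.mean()) ** 2 / np.sum((x - x.mean()) ** 2)
    sse = float(resid @ resid)
    p_params = 2
    dffits = np.full(n, np.nan)
    if n - p_params - 1 > 0:
        sse_i = sse - resid**2 / (1.0 - h)
        sse_i = np.maximum(sse_i, 0.0)
        s_i = np.sqrt(sse_i / (n - p_params - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            dffits = resid * np.sqrt(h) / (s_i * (1.0 - h))
        dffits[np.isclose(resid, 0.0) & (s_i == 0)] = 0.0
        if sse == 0:
            dffits = np.zeros(n)
    threshold = 2.0 * math.sqrt(2.0 / n)
    with np.errstate(invalid="ignore"):
        influential = np.abs(dffits) > threshold
    return RegressionDiagnostics(
        r=float(r), p_value=float(p),
        slope=float(beta[1]), intercept=float(beta[0]),
        residuals=resid, leverage=h, dffits=dffits,
        influential=influential, dffits_threshold=threshold,
    )


# ---------------------------------------------------------------------------
# GEE on percent change from baseline
# ---------------------------------------------------------------------------

@dataclass
class GEEFit:
    """Converged GEE fit with robust (sandwich) covariance."""

    params: np.ndarray
    param_names: list
    cov_robust: np.ndarray
    cov_model: np.ndarray
    alpha: float
    dispersion: float
    n_iter: int
    converged: bool
    n_subjects: int
    n_obs: int
    outcome: str


@dataclass(frozen=True)
class ContrastEstimate:
    """Estimated percent change from baseline with a 95 % CI."""

    estimate: float
    ci_lower: float
    ci_upper: float
    group: str
    day: object


def prepare_change_table(cohort: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Per-subject percent change from baseline, binned into intervals.

    Expects the wide cohort layout (columns ``subject, group, day`` plus
    parameter columns).  The baseline row of each subject is ``day`` in
    the baseline bin; follow-up rows become one observation each with
    columns ``subject, group, interval, change``.  Subjects without a
    baseline or without follow-ups are dropped.
    """
    rows = []
    for subject, grp in cohort.groupby("subject"):
        labels = grp["day"].map(assign_interval)
        base = grp.loc[labels == "baseline", parameter]
        if base.empty:
            continue
        baseline = float(base.mean())
        if baseline == 0:
            continue
        for _, row in grp.loc[labels != "baseline"].iterrows():
            rows.append({
                "subject": subject,
                "group": row["group"],
                "interval": assign_interval(row["day"]),
                "change": percent_change(float(row[parameter]), baseline),
            })
    return pd.DataFrame(rows)


def _build_design(table: pd.DataFrame):
    """Saturated group × interval design on the follow-up rows.

    One indicator column per nonempty (group, interval) cell — the
    cell-means parameterization of the full interaction model.  It is
    equivalent to intercept + group + interval dummies + interactions when
    every cell is filled, and stays identifiable on unbalanced panels
    where whole cells are missing.  The baseline itself is the implicit
    zero of the percent-change outcome.
    """
    intervals = [lab for lab in INTERVAL_LABELS if lab in set(table["interval"])]
    if not intervals:
        raise ValueError("no follow-up observations")
    group = table["group"].to_numpy()
    interval = table["interval"].to_numpy()
    cols, names = [], []
    for g, tag in ((PRE, "pre"), (POST, "post")):
        for lab in intervals:
            ind = ((group == g) & (interval == lab)).astype(float)
            if ind.any():
                cols.append(ind)
                names.append(f"{tag}:day{lab}")
    return np.stack(cols, axis=1), names, intervals


def gee_fit(
    table: pd.DataFrame,
    outcome: str = "change",
    *,
    force_alpha: float | None = None,
    bias_corrected: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> GEEFit:
    """GEE with identity link, normal variance, exchangeable correlation.

    ``table`` must carry columns ``subject, group, interval`` and the
    outcome (one row per follow-up observation; baseline is the implicit
    zero of the percent-change outcome).  Iterates GLS coefficient
    updates with moment re-estimation of dispersion φ and exchangeable α
    from Pearson residuals until ``max |Δβ| < tol``.  ``force_alpha=0``
    reproduces pooled OLS exactly.  The robust sandwich covariance is
    always returned alongside the model-based one; with
    ``bias_corrected=True`` (default) the cluster residuals entering the
    sandwich are inflated by the Mancl–DeRouen leverage factor
    ``(I − H_ii)⁻¹``, which counteracts the well-known downward bias of
    the plain sandwich when the number of subjects is small (tens of
    clusters, as in typical NAC cohorts).
    """
    design, names, _ = _build_design(table)
    y = table[outcome].to_numpy(float)
    subjects = table["subject"].to_numpy()
    n, p = design.shape
    if n <= p:
        raise ValueError("fewer observations than parameters")
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("singular design matrix")

    order = np.argsort(subjects, kind="stable")
    design, y, subjects = design[order], y[order], subjects[order]
    _, starts = np.unique(subjects, return_index=True)
    bounds = sorted(starts.tolist()) + [n]
    clusters = [(design[a:b], y[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]
    max_size = max(b - a for a, b in zip(bounds[:-1], bounds[1:]))

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    alpha = 0.0 if force_alpha is None else float(force_alpha)
    phi = 1.0
    converged = False
    for it in range(1, max_iter + 1):
        resid = y - design @ beta
        phi = float(resid @ resid) / (n - p)
        if force_alpha is None:
            num, n_pairs = 0.0, 0
            pos = 0
            for X_i, y_i in clusters:
                m = y_i.size
                r_i = resid[pos:pos + m]
                pos += m
                if m > 1:
                    s = r_i.sum()
                    num += (s * s - r_i @ r_i) / 2.0
                    n_pairs += m * (m - 1) // 2
            if n_pairs > p:
                alpha = num / ((n_pairs - p) * phi)
            else:
                alpha = 0.0
            lo = -1.0 / (max_size - 1) + 1e-6 if max_size > 1 else -0.99
            alpha = float(np.clip(alpha, lo, 0.999))

        a_mat = np.zeros((p, p))
        b_vec = np.zeros(p)
        for X_i, y_i in clusters:
            XtVi = _exchangeable_solve(X_i, alpha, phi)
            a_mat += XtVi @ X_i
            b_vec += XtVi @ y_i
        beta_new = np.linalg.solve(a_mat, b_vec)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"GEE did not converge in {max_iter} iterations")

    resid = y - design @ beta
    phi = float(resid @ resid) / (n - p)
    a_mat = np.zeros((p, p))
    pos = 0
    cluster_terms = []
    for X_i, y_i in clusters:
        m = y_i.size
        e_i = resid[pos:pos + m]
        pos += m
        XtVi = _exchangeable_solve(X_i, alpha, phi)
        a_mat += XtVi @ X_i
        cluster_terms.append((X_i, XtVi, e_i))
    bread = np.linalg.inv(a_mat)
    meat = np.zeros((p, p))
    for X_i, XtVi, e_i in cluster_terms:
        if bias_corrected:
            h_ii = X_i @ bread @ XtVi
            e_i = np.linalg.solve(np.eye(e_i.size) - h_ii, e_i)
        g_i = XtVi @ e_i
        meat += np.outer(g_i, g_i)
    cov_robust = bread @ meat @ bread
    cov_robust = (cov_robust + cov_robust.T) / 2.0
    return GEEFit(
        params=beta, param_names=names,
        cov_robust=cov_robust, cov_model=bread,
        alpha=float(alpha), dispersion=phi,
        n_iter=it, converged=converged,
        n_subjects=len(clusters), n_obs=n, outcome=outcome,
    )


def _exchangeable_solve(X_i: np.ndarray, alpha: float, phi: float) -> np.ndarray:
    """Return X_iᵀ V_i⁻¹ for V_i = φ [(1−α) I + α J] (closed form)."""
    m = X_i.shape[0]
    if m == 1:
        return X_i.T / phi
    one_minus = 1.0 - alpha
    denom = one_minus + m * alpha
    col_sums = X_i.sum(axis=0)
    # V^-1 = 1/(phi (1-a)) [I - a/(1-a+m a) J]
    XtVinv = (X_i.T - np.outer(col_sums, np.ones(m)) * (alpha / denom)) / (
        phi * one_minus
    )
    return XtVinv


def estimate_group_day_change(fit: GEEFit, group: str, day) -> ContrastEstimate:
    """Linear contrast for one group at one interval, 95 % normal CI.

    ``day="baseline"`` returns the structural zero of the percent-change
    parameterization (zero-width CI).
    """
    if day == "baseline":
        return ContrastEstimate(0.0, 0.0, 0.0, group, "baseline")
    if group not in (PRE, POST):
        raise ValueError(f"unknown group {group!r}")
    names = fit.param_names
    cell = f"{'pre' if group == PRE else 'post'}:day{day}"
    if cell not in names:
        raise ValueError(f"no observations for {group} in interval {day!r}")
    contrast = np.zeros(len(names))
    contrast[names.index(cell)] = 1.0
    est = float(contrast @ fit.params)
    se = float(np.sqrt(contrast @ fit.cov_robust @ contrast))
    z = sps.norm.ppf(0.975)
    return ContrastEstimate(
        estimate=est, ci_lower=est - z * se, ci_upper=est + z * se,
        group=group, day=day,
    )
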