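"""Group-level inference on network fALFF and behavior.

Implements the statistical layer applied to the per-subject network fALFF
table: the conflict-effect score of the attention network test, pooled
two-sample t-tests (from raw values or printed mean/sd/n summaries),
covariate-adjusted single-response F-tests per network (the ANCOVA the
multivariate analysis reduces to for one response), partial correlations by
the residual method, a Shapiro-Wilk-gated log transform, and Tukey far-out
outlier flagging.

Sex enters covariate matrices coded 0/1; correlations and F statistics are
invariant to any affine recoding by construction.  No multiple-testing
correction is applied across networks by default; Bonferroni and
Benjamini-Hochberg adjustments are available as opt-in flags.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DegenerateInputError

__all__ = [
    "conflict_effect",
    "conflict_effect_from_trials",
    "two_sample_t",
    "ancova_group_f",
    "partial_correlation",
    "normality_gate_log_transform",
    "flag_outliers",
    "GroupTestResult",
    "PartialCorrelationResult",
    "TransformReport",
    "OutlierReport",
    "network_group_table",
    "encode_covariates",
    "manova_group",
]


def conflict_effect(rt_incongruent: float, rt_congruent: float) -> float:
    """Conflict effect of the attention network test: incongruent minus
    congruent reaction time (ms); may be negative."""
    if rt_incongruent <= 0 or rt_congruent <= 0:
        raise DataError("reaction times must be positive")
    return float(rt_incongruent) - float(rt_congruent)


def conflict_effect_from_trials(
    trials: pd.DataFrame,
    rt_col: str = "rt",
    condition_col: str = "condition",
    incongruent: str = "incongruent",
    congruent: str = "congruent",
) -> float:
    """Conflict effect from a per-trial table: per-condition mean RTs are
    computed first, then differenced."""
    means = trials.groupby(condition_col)[rt_col].mean()
    for cond in (incongruent, congruent):
        if cond not in means.index:
            raise DataError(f"no trials in condition {cond!r}")
    return conflict_effect(float(means[incongruent]), float(means[congruent]))


def _summary(group) -> tuple[float, float, int]:
    if isinstance(group, tuple) and len(group) == 3:
        mean, sd, n = group
        return float(mean), float(sd), int(n)
    x = np.asarray(group, dtype=np.float64)
    if x.size < 2:
        raise DataError("each group needs at least 2 values")
    return float(x.mean()), float(x.std(ddof=1)), int(x.size)


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sided two-sample t-test.

    Each group is either an array of raw values or a (mean, sd, n) summary
    triple; both routes give identical results on matching data.
    Returns (t, p) with df = n_a + n_b - 2.
    """
    ma, sa, na = _summary(group_a)
    mb, sb, nb = _summary(group_b)
    if na < 2 or nb < 2:
        raise DataError("need n >= 2 per group")
    df = na + nb - 2
    pooled_var = ((na - 1) * sa**2 + (nb - 1) * sb**2) / df
    if pooled_var <= 0:
        raise DegenerateInputError("zero pooled variance; t undefined")
    t = (ma - mb) / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


@dataclass(frozen=True)
class GroupTestResult:
    network: str
    group_means: dict[str, float]
    t_or_f: float
    p: float
    covariates: tuple[str, ...]
    statistic: str = "F"


def encode_covariates(
    table: pd.DataFrame, covariates: tuple[str, ...]
) -> np.ndarray:
    """Covariate matrix with sex coded 0/1 (M = 1)."""
    cols = []
    for c in covariates:
        col = table[c].to_numpy()
        if col.dtype.kind in "OU":
            col = (col == "M").astype(float)
        cols.append(np.asarray(col, dtype=np.float64))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ beta
    return float(r @ r)


def ancova_group_f(
    falff: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    covariate_names: tuple[str, ...] = (),
    network: str = "",
) -> GroupTestResult:
    """Covariate-adjusted F-test for the group term in a linear model
    falff ~ group + covariates.

    F = ((RSS_reduced - RSS_full) / 1) / (RSS_full / (n - p)) with a
    two-sided p from the F(1, n - p) reference distribution.
    """
    y = np.asarray(falff, dtype=np.float64)
    g = np.asarray(group)
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise DataError(f"need exactly two groups, got {levels}")
    z = covariates if covariates is not None else np.empty((y.size, 0))
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 1:
        z = z[:, None]
    n, k = y.size, z.shape[1]
    if n <= 5 + k:
        raise DataError(f"too few subjects (n={n}) for {k} covariates")
    g01 = (g == levels[1]).astype(float)
    full = np.column_stack([np.ones(n), g01, z])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        bad = []
        for j in range(full.shape[1]):
            others = np.delete(full, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(full):
                bad.append(["intercept", "group", *covariate_names][j] if j < 2 + len(covariate_names) else f"col{j}")
        raise DataError(f"singular design; collinear columns: {bad}")
    reduced = np.column_stack([np.ones(n), z])
    rss_full = _rss(full, y)
    rss_red = _rss(reduced, y)
    dof = n - full.shape[1]
    if rss_full <= 0:
        raise DegenerateInputError("perfect fit; F undefined")
    f = (rss_red - rss_full) / (rss_full / dof)
    p = float(sps.f.sf(f, 1, dof))
    means = {lev: float(y[g == lev].mean()) for lev in levels}
    return GroupTestResult(
        network=network,
        group_means=means,
        t_or_f=float(f),
        p=p,
        covariates=tuple(covariate_names),
        statistic="F",
    )


@dataclass(frozen=True)
class PartialCorrelationResult:
    x: str
    y: str
    covariates: tuple[str, ...]
    r: float
    p: float
    n: int
    excluded: tuple[str, ...] = ()


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    names: tuple[str, str] = ("x", "y"),
    covariate_names: tuple[str, ...] = (),
    excluded: tuple[str, ...] = (),
) -> PartialCorrelationResult:
    """Partial correlation by the residual method.

    x and y are each regressed on [intercept | covariates]; r is the Pearson
    correlation of the residuals, with a two-sided p from
    t = r * sqrt(df / (1 - r^2)), df = n - 2 - #covariates.
    With no covariates this reduces to the plain Pearson correlation.
    """
    xv = np.asarray(x, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise DataError("x and y must be equal-length vectors")
    z = covariates if covariates is not None else np.empty((xv.size, 0))
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 1:
        z = z[:, None]
    n, k = xv.size, z.shape[1]
    if n < k + 3:
        raise DataError(f"need n >= #covariates + 3 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), z])
    bx, *_ = np.linalg.lstsq(design, xv, rcond=None)
    by, *_ = np.linalg.lstsq(design, yv, rcond=None)
    rx = xv - design @ bx
    ry = yv - design @ by
    if rx.std() == 0 or ry.std() == 0:
        raise DegenerateInputError("degenerate residual variance")
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * rx.std() * ry.std()))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if df < 1:
        raise DataError("non-positive degrees of freedom")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(
        x=names[0], y=names[1], covariates=tuple(covariate_names), r=r, p=p, n=n,
        excluded=tuple(excluded),
    )


@dataclass(frozen=True)
class TransformReport:
    values: np.ndarray
    transformed: bool
    shapiro_p_before: float
    shapiro_p_after: float | None


def normality_gate_log_transform(
    values: np.ndarray, alpha_gate: float = 0.1
) -> TransformReport:
    """Shapiro-Wilk-gated natural-log transform.

    If the Shapiro-Wilk p falls below ``alpha_gate`` the (strictly positive)
    values are log-transformed and both pre/post p-values are reported.
    Downstream Pearson correlations are invariant to the log base.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 3:
        raise DataError("Shapiro-Wilk needs at least 3 values")
    p_before = float(sps.shapiro(v).pvalue)
    if p_before >= alpha_gate:
        return TransformReport(v.copy(), False, p_before, None)
    if np.any(v <= 0):
        raise DataError(
            "log transform triggered but values are not all positive; "
            "add an offset before transforming"
        )
    logged = np.log(v)
    p_after = float(sps.shapiro(logged).pvalue)
    return TransformReport(logged, True, p_before, p_after)


@dataclass(frozen=True)
class OutlierReport:
    flags: np.ndarray
    q1: float
    q3: float
    iqr: float
    lo_fence: float
    hi_fence: float


def flag_outliers(values: np.ndarray, k: float = 3.0) -> OutlierReport:
    """Tukey far-out rule: flag values beyond Q3 + k*IQR or Q1 - k*IQR
    (default k = 3, the far-out fence).

    Flagged subjects are meant to be excluded from correlation analyses only
    and retained in group tests.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 4:
        raise DataError("need at least 4 values for the quartile rule")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return OutlierReport(
        flags=(v < lo) | (v > hi), q1=float(q1), q3=float(q3), iqr=float(iqr),
        lo_fence=float(lo), hi_fence=float(hi),
    )


def network_group_table(
    falff_wide: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    correction: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-network group comparison table.

    ``falff_wide`` is subjects x networks (indexed by subject_id); the cohort
    table supplies group labels and covariates.  Both a plain pooled
    two-sample t and a covariate-adjusted F are reported side by side.
    ``correction`` in {None, "bonferroni", "fdr_bh"} adjusts the F p-values.
    """
    merged = cohort.set_index("subject_id").join(falff_wide, how="inner")
    nets = [c for c in falff_wide.columns]
    z = encode_covariates(merged.reset_index(), covariates)
    rows = []
    for net in nets:
        y = merged[net].to_numpy(dtype=np.float64)
        g = merged["group"].to_numpy()
        tcc, ctr = y[g == "TCC"], y[g == "CTR"]
        t, p_t = two_sample_t(tcc, ctr)
        res = ancova_group_f(
            y, g, z, covariate_names=covariates, network=net
        )
        rows.append(
            {
                "network": net,
                "mean_tcc": tcc.mean(),
                "sd_tcc": tcc.std(ddof=1),
                "mean_ctr": ctr.mean(),
                "sd_ctr": ctr.std(ddof=1),
                "t": t,
                "p_t": p_t,
                "F": res.t_or_f,
                "p_F": res.p,
                "covariates": ",".join(covariates),
            }
        )
    out = pd.DataFrame(rows)
    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        out["p_F_adj"] = multipletests(out["p_F"], alpha=alpha, method=correction)[1]
    return out


def manova_group(
    falff_wide: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
) -> pd.DataFrame:
    """Optional true multivariate mode: one MANOVA across all networks with
    the group term adjusted for covariates (Pillai's trace and friends)."""
    from statsmodels.multivariate.manova import MANOVA

    merged = cohort.set_index("subject_id").join(falff_wide, how="inner").reset_index()
    nets = list(falff_wide.columns)
    merged["_group01"] = (merged["group"] == "TCC").astype(float)
    z = encode_covariates(merged, covariates)
    for i, name in enumerate(covariates):
        merged[f"_cov_{name}"] = z[:, i]
    lhs = " + ".join(nets)
    rhs = " + ".join(["_group01"] + [f"_cov_{c}" for c in covariates])
    mv = MANOVA.from_formula(f"{lhs} ~ {rhs}", data=merged)
    return mv.mv_test().results["_group01"]["stat"]
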