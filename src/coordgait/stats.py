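"""Group-level inference: 2x2 mixed ANOVA and effect sizes.

The study design crosses one between-subjects factor (group: recent ankle
sprain history vs control) with one within-subjects factor (time: pre vs
post training). For each outcome (coordination angle or variability, per
joint pair and subphase) a 2x2 mixed ANOVA is run; effect sizes are partial
eta-squared, eta_p^2 = SS_effect / (SS_effect + SS_error_for_that_effect),
with 95% confidence intervals obtained by inverting the noncentral F
distribution. With only two levels of the within factor sphericity holds
trivially, so no correction is applied.

The sums-of-squares decomposition is written out explicitly (subjects nested
in groups; the between-effect error term is subjects-within-groups, the
within-effect error term is time x subjects-within-groups). Subjects with a
missing pre or post value are excluded listwise for that outcome, which is
what shifts the error df (e.g. 22 -> 21 for n=24 with one exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "AnovaResult",
    "MixedAnovaOutput",
    "mixed_anova_2x2",
    "mixed_anova_arrays",
    "eta_p2_ci",
    "label_effect_size",
    "independent_t_test",
    "interaction_null_rejection_rate",
]

EFFECTS = ("group", "time", "interaction")


@dataclass
class AnovaResult:
    """One effect from a 2x2 mixed ANOVA."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float
    ci95: tuple[float, float]
    size_label: str


@dataclass
class MixedAnovaOutput:
    """All three effects plus bookkeeping of listwise exclusions."""

    effects: dict[str, AnovaResult]
    n_per_group: dict[str, int]
    excluded_subjects: list


def label_effect_size(eta_p2: float) -> str:
    """Conventional partial-eta-squared magnitude label.

    Thresholds 0.01 / 0.06 / 0.14 for small / medium / large; below 0.01 is
    negligible.
    """
    if not 0.0 <= eta_p2 <= 1.0:
        raise ValueError("eta_p2 must lie in [0, 1]")
    if eta_p2 < 0.01:
        return "negligible"
    if eta_p2 < 0.06:
        return "small"
    if eta_p2 < 0.14:
        return "medium"
    return "large"


def eta_p2_ci(
    F: float, df1: int, df2: int, level: float = 0.95, conversion: str = "error_df"
) -> tuple[float, float]:
    """Noncentral-F confidence interval for partial eta-squared.

    Finds noncentrality bounds lambda_lo, lambda_hi with
    CDF(F; df1, df2, lambda) equal to (1+level)/2 and (1-level)/2
    respectively (clamped at zero), then maps each noncentrality to a
    partial eta-squared.

    Two mappings are in circulation and differ in the third decimal for
    typical dfs: ``conversion="error_df"`` uses
    eta_p2 = lambda / (lambda + df2), the convention behind the
    SPSS-style noncentral intervals this package reproduces;
    ``conversion="total_n"`` uses lambda / (lambda + df1 + df2 + 1)
    (Smithson's convention).
    """
    if not np.isfinite(F) or F < 0:
        raise ValueError("F must be finite and non-negative")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if conversion not in ("error_df", "total_n"):
        raise ValueError(f"unknown conversion '{conversion}'")
    alpha = 1.0 - level

    def _solve(target_cdf: float) -> float:
        # CDF(F; lam) decreases in lam; lam solves CDF = target.
        if sps.ncf.cdf(F, df1, df2, 0.0) <= target_cdf:
            return 0.0
        hi = 4.0 * (F * df1 + df1 + df2) + 10.0
        while sps.ncf.cdf(F, df1, df2, hi) > target_cdf:
            hi *= 2.0
            if hi > 1e8:  # pragma: no cover - numerically unreachable
                break
        return float(
            optimize.brentq(
                lambda lam: sps.ncf.cdf(F, df1, df2, lam) - target_cdf, 0.0, hi, xtol=1e-10
            )
        )

    lam_lo = _solve(1.0 - alpha / 2.0)
    lam_hi = _solve(alpha / 2.0)
    denom = df2 if conversion == "error_df" else df1 + df2 + 1
    lo = lam_lo / (lam_lo + denom)
    hi = lam_hi / (lam_hi + denom)
    return (min(lo, hi), max(lo, hi))


def mixed_anova_arrays(
    pre: np.ndarray, post: np.ndarray, group: np.ndarray, ci: bool = True
) -> dict[str, AnovaResult]:
    """2x2 mixed ANOVA from parallel arrays (one row per subject).

    ``group`` is any array with exactly two levels. Unbalanced groups use
    group-size-weighted cell means (identical to the textbook balanced
    decomposition when n1 == n2).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    masks = [group == g for g in levels]
    ns = np.array([m.sum() for m in masks])
    if (ns < 2).any():
        raise ValueError("each group needs at least 2 complete subjects")
    N = int(ns.sum())

    y = np.stack([pre, post], axis=1)  # (N, 2)
    gm = y.mean()
    subj_mean = y.mean(axis=1)
    group_mean = np.array([subj_mean[m].mean() for m in masks])
    time_mean = y.mean(axis=0)
    cell_mean = np.array([[y[m, t].mean() for t in (0, 1)] for m in masks])

    ss_total = ((y - gm) ** 2).sum()
    ss_subjects = 2.0 * ((subj_mean - gm) ** 2).sum()
    ss_group = 2.0 * (ns * (group_mean - gm) ** 2).sum()
    ss_err_between = ss_subjects - ss_group
    ss_time = N * ((time_mean - gm) ** 2).sum()
    ss_cells = (ns[:, None] * (cell_mean - gm) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_time
    ss_err_within = ss_total - ss_subjects - ss_time - ss_inter

    df_err = N - 2
    out: dict[str, AnovaResult] = {}
    for effect, ss_eff, ss_err in (
        ("group", ss_group, ss_err_between),
        ("time", ss_time, ss_err_within),
        ("interaction", ss_inter, ss_err_within),
    ):
        ss_eff = max(ss_eff, 0.0)
        ss_err = max(ss_err, 0.0)
        if ss_err <= 0.0:
            f = 0.0 if ss_eff <= 0.0 else float("inf")
        else:
            f = (ss_eff / 1.0) / (ss_err / df_err)
        p = float(sps.f.sf(f, 1, df_err)) if np.isfinite(f) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        ci95 = eta_p2_ci(f, 1, df_err) if (ci and np.isfinite(f)) else (0.0, 1.0)
        out[effect] = AnovaResult(
            effect=effect,
            F=float(f),
            df1=1,
            df2=df_err,
            p=p,
            eta_p2=float(eta),
            ci95=ci95,
            size_label=label_effect_size(float(np.clip(eta, 0.0, 1.0))),
        )
    return out


def mixed_anova_2x2(table: pd.DataFrame, ci: bool = True) -> MixedAnovaOutput:
    """2x2 mixed ANOVA for a design table.

    ``table`` has one row per subject with columns ``subject``, ``group``,
    ``pre``, ``post``. Subjects with a missing pre or post value are excluded
    listwise and reported in the output.
    """
    required = {"subject", "group", "pre", "post"}
    if not required.issubset(table.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    if table["subject"].duplicated().any():
        raise ValueError("each subject may appear only once")

    complete = table[["pre", "post"]].notna().all(axis=1)
    excluded = table.loc[~complete, "subject"].tolist()
    t = table.loc[complete]

    effects = mixed_anova_arrays(
        t["pre"].to_numpy(), t["post"].to_numpy(), t["group"].to_numpy(), ci=ci
    )
    n_per_group = t.groupby("group", sort=False).size().to_dict()
    return MixedAnovaOutput(effects=effects, n_per_group=n_per_group, excluded_subjects=excluded)


def independent_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance independent t-test.

    Degenerate zero-variance input with equal means returns (0.0, 1.0)
    rather than raising, matching how identical groups should read.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def interaction_null_rejection_rate(
    n_per_group: int, n_sims: int, alpha: float = 0.05, seed: int = 0
) -> float:
    """Monte-Carlo type-I error of the interaction test under the null.

    Simulates ``n_sims`` datasets of iid standard-normal pre/post values for
    two groups of ``n_per_group`` subjects and runs the full mixed ANOVA on
    each, returning the fraction of interaction p-values below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    group = np.repeat([0, 1], n_per_group)
    rejections = 0
    for _ in range(n_sims):
        y = rng.standard_normal((2 * n_per_group, 2))
        res = mixed_anova_arrays(y[:, 0], y[:, 1], group, ci=False)
        if res["interaction"].p < alpha:
            rejections += 1
    return rejections / n_sims
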