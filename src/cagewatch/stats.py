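"""Study-level statistics: design power, group contrasts, endpoint correlation.

Implements the operations the study design defines: the two-sample t-test
power computation (noncentral-t closed form, with a Monte-Carlo cross-check
mode), Welch t contrasts with Satterthwaite degrees of freedom, Pearson
correlation + least-squares regression for endpoint pathology, a Fisher-z
confidence interval, the >=20% body-weight-loss humane-endpoint rule, and an
optional Holm multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import InputError, PowerSpec


def power_two_sample_t(
    spec: PowerSpec,
    sided: str = "two",
    mode: str = "analytic",
    n_rep: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Power of the two-sample (pooled) t-test for the designed effect.

    The true mean difference is ``effect_fraction * baseline_mean`` with
    common SD ``pooled_sd`` and ``n_per_group`` per arm.  ``mode="analytic"``
    uses the noncentral-t distribution; ``mode="mc"`` simulates ``n_rep``
    replicate experiments and must agree with the closed form to ~0.005 at
    the default replicate count.
    """
    if spec.n_per_group < 2:
        raise InputError("n_per_group must be at least 2")
    n = spec.n_per_group
    df = 2 * n - 2
    diff = spec.effect_fraction * spec.baseline_mean
    ncp = diff / (spec.pooled_sd * np.sqrt(2.0 / n))

    if mode == "analytic":
        if sided == "two":
            tc = sps.t.ppf(1 - spec.alpha / 2, df)
            return float(sps.nct.sf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp))
        tc = sps.t.ppf(1 - spec.alpha, df)
        return float(sps.nct.sf(tc, df, ncp))

    if mode != "mc":
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    a = rng.standard_normal((n_rep, n)) * spec.pooled_sd
    b = rng.standard_normal((n_rep, n)) * spec.pooled_sd + diff
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp2 = (va + vb) / 2.0
    t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(sp2 * 2.0 / n)
    if sided == "two":
        tc = sps.t.ppf(1 - spec.alpha / 2, df)
        return float(np.mean(np.abs(t) > tc))
    tc = sps.t.ppf(1 - spec.alpha, df)
    return float(np.mean(t > tc))


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch t statistic, Satterthwaite df, and two-sided p-value.

    Computed from the standard formulas (cross-checked against
    ``scipy.stats.ttest_ind(equal_var=False)`` in the test suite).  Two
    zero-variance groups with equal means return (0, df, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise InputError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    md = a.mean() - b.mean()
    if se2 == 0.0:
        df = float(na + nb - 2)
        if md == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(md) * np.inf), df, 0.0
    t = md / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its least-squares regression line."""

    r: float
    p: float
    slope: float
    intercept: float
    n: int
    ok: bool = True


def pearson_regression(x, y) -> CorrelationResult:
    """Pearson r (two-sided p via the t transform) and least-squares fit.

    Incomplete pairs are dropped listwise; fewer than 3 complete pairs is an
    error, and zero variance in either variable yields a flagged, undefined
    result rather than a number.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InputError("pearson_regression needs at least 3 complete pairs")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, n, ok=False)
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / ((n - 1) * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    slope = float(np.dot(xc, yc) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    return CorrelationResult(r, p, slope, intercept, n)


def fisher_z_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise InputError("Fisher-z interval needs n >= 4")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = sps.norm.ppf(0.5 + conf / 2)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


def flag_humane_endpoint(
    weights: pd.DataFrame,
    reference_day: int = 0,
    loss_fraction: float = 0.20,
) -> pd.DataFrame:
    """Flag study days at or beyond the humane weight-loss endpoint.

    ``weights`` needs columns ``study_day`` and ``weight_g`` (one animal).
    The flag turns on at the first day the weight drops to at or below
    ``(1 - loss_fraction)`` of the Day ``reference_day`` weight (loss of
    exactly 20% counts) and stays on for all later days.
    """
    w = weights.sort_values("study_day").reset_index(drop=True)
    ref_rows = w[w["study_day"] == reference_day]
    if not len(ref_rows) or not np.isfinite(ref_rows["weight_g"].iloc[0]):
        raise InputError(f"missing reference weight on study day {reference_day}")
    ref = float(ref_rows["weight_g"].iloc[0])
    if ref <= 0:
        raise InputError("reference weight must be positive")
    loss = 1.0 - w["weight_g"] / ref
    # compare weights directly so a loss of exactly 20% flags (no fp slack)
    crossed = (w["weight_g"] <= (1.0 - loss_fraction) * ref).cummax()
    return pd.DataFrame(
        {
            "study_day": w["study_day"],
            "weight_g": w["weight_g"],
            "loss_fraction": loss,
            "flag": crossed.astype(bool),
        }
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def groupwise_welch(
    changes: pd.DataFrame,
    groups: pd.DataFrame,
    value_col: str = "delta_br",
    group_a: str = "injured",
    group_b: str = "control",
) -> pd.DataFrame:
    """Per-study-day Welch contrasts of a change metric between two groups."""
    df = changes.merge(groups[["animal_id", "group"]].drop_duplicates(), on="animal_id")
    rows = []
    for d, sub in df.groupby("study_day"):
        a = sub.loc[sub["group"] == group_a, value_col].dropna()
        b = sub.loc[sub["group"] == group_b, value_col].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        t, dof, p = welch_t(a, b)
        rows.append(
            {"study_day": int(d), "metric": value_col, "t": t, "df": dof, "p": p,
             "n_a": len(a), "n_b": len(b)}
        )
    return pd.DataFrame(rows)
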