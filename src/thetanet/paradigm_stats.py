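"""Paradigm-level inferential statistics for habituation/dishabituation designs.

Works on long-format measure tables — one value per (subject, region, period,
measure) — and provides the within-subject tests used for encounter-level
theta measures: Bonferroni-corrected paired t contrasts (one-sided when a
direction was declared before the experiment), one-way repeated-measures
ANOVA across encounters, and the two-way within-subject experiment x
theta-band interaction.

Normality and sphericity screening is delegated to established routines
(scipy / statsmodels) and reported, never used to gate tests automatically.
No sphericity correction is applied by default; Greenhouse-Geisser is exposed
as an option on the one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.anova import AnovaRM

from .signal_io import ValidationError

#: required columns of a long-format measure table
MEASURE_COLUMNS = ("subject", "region", "period", "measure", "value")


@dataclass
class ContrastResult:
    t: float
    df: int
    p_raw: float
    p_corrected: float
    n_comparisons: int
    direction: str             # "two-sided" | "greater" | "less"
    degenerate: bool = False   # zero-variance difference with nonzero mean


@dataclass
class AnovaResult:
    F: float
    df_num: float
    df_den: float
    p: float
    design: str                # "one-way-RM" | "two-way-RM-interaction"


def validate_measure_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"measure table missing columns {missing}")
    dup = table.duplicated(subset=["subject", "region", "period", "measure"])
    if dup.any():
        raise ValidationError("measure table has duplicate (subject, region, period, measure) cells")
    return table


def paired_t(values_a: np.ndarray, values_b: np.ndarray,
             direction: str = "two-sided", n_comparisons: int = 1) -> ContrastResult:
    """Paired t-test on per-subject values with Bonferroni correction.

    ``direction="greater"`` tests mean(a - b) > 0.  The corrected p is
    ``min(1, p_raw * n_comparisons)``.  A zero-variance difference with a
    nonzero mean is reported as a degenerate boundary (p = 0) and flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("paired_t needs equal-length 1-D samples with n >= 2")
    if direction not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown direction {direction!r}")
    d = a - b
    n = len(d)
    if np.std(d, ddof=1) == 0:
        if d.mean() == 0:
            return ContrastResult(0.0, n - 1, 1.0, 1.0, n_comparisons, direction)
        t = float(np.inf * np.sign(d.mean()))
        if direction == "two-sided":
            p = 0.0
        elif direction == "greater":
            p = 0.0 if t > 0 else 1.0
        else:
            p = 0.0 if t < 0 else 1.0
        p_corr = min(1.0, p * n_comparisons)
        return ContrastResult(t, n - 1, p, p_corr, n_comparisons, direction,
                              degenerate=True)
    res = sstats.ttest_rel(a, b, alternative=direction)
    p_corr = min(1.0, float(res.pvalue) * n_comparisons)
    return ContrastResult(float(res.statistic), n - 1, float(res.pvalue), p_corr,
                          n_comparisons, direction)


def _check_complete(table: pd.DataFrame, subject: str, within: list[str]) -> None:
    counts = table.groupby([subject] + within, observed=True).size()
    levels = [table[c].nunique() for c in [subject] + within]
    if (counts != 1).any() or len(counts) != int(np.prod(levels)):
        raise ValidationError(
            "incomplete or unbalanced within-subject design: every subject needs "
            "exactly one value per cell (no imputation is performed)"
        )


def rm_anova_oneway(table: pd.DataFrame, value: str = "value",
                    subject: str = "subject", factor: str = "period",
                    greenhouse_geisser: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA: F = MS_factor / MS_(factor x subject).

    Requires a complete balanced design.  ``greenhouse_geisser=True`` scales
    both degrees of freedom by the epsilon estimated from the per-subject
    covariance of the factor levels.
    """
    _check_complete(table, subject, [factor])
    wide = table.pivot_table(index=subject, columns=factor, values=value)
    n, k = wide.shape
    level_means = wide.mean(axis=0).to_numpy()
    ss_factor = n * np.sum((level_means - level_means.mean()) ** 2)
    total_scale = max(float(np.var(wide.to_numpy())) * wide.size, 1.0)
    if ss_factor <= 1e-12 * total_scale:  # no between-level variance at all
        return AnovaResult(0.0, float(k - 1), float((k - 1) * (n - 1)), 1.0,
                           "one-way-RM")
    res = AnovaRM(table, depvar=value, subject=subject, within=[factor]).fit()
    row = res.anova_table.iloc[0]
    F = float(row["F Value"])
    df1, df2 = float(row["Num DF"]), float(row["Den DF"])
    if greenhouse_geisser:
        wide = table.pivot_table(index=subject, columns=factor, values=value)
        eps = _gg_epsilon(wide.to_numpy())
        df1, df2 = df1 * eps, df2 * eps
        p = float(sstats.f.sf(F, df1, df2))
    else:
        p = float(row["Pr > F"])
    return AnovaResult(F, df1, df2, p, "one-way-RM")


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of factor levels."""
    k = data.shape[1]
    s = np.cov(data, rowvar=False)
    mean_diag = np.trace(s) / k
    grand = s.mean()
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(s ** 2) - 2 * k * np.sum(s.mean(axis=1) ** 2)
                     + k ** 2 * grand ** 2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova_interaction(table: pd.DataFrame, value: str = "value",
                         subject: str = "subject", factor_a: str = "experiment",
                         factor_b: str = "band") -> AnovaResult:
    """Two-way within-subject interaction F (experiment x theta-band)."""
    for f in (factor_a, factor_b):
        if table[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} needs >= 2 levels for an interaction")
    _check_complete(table, subject, [factor_a, factor_b])
    res = AnovaRM(table, depvar=value, subject=subject,
                  within=[factor_a, factor_b]).fit()
    row = res.anova_table.loc[f"{factor_a}:{factor_b}"]
    return AnovaResult(float(row["F Value"]), float(row["Num DF"]),
                       float(row["Den DF"]), float(row["Pr > F"]),
                       "two-way-RM-interaction")


def enc_vs_post_contrast(table: pd.DataFrame, measure: str = "dtp_db",
                         enc_periods: tuple[str, ...] = ("Enc1", "Enc2", "Enc3", "Enc4", "Enc5"),
                         post_periods: tuple[str, ...] = ("Post1", "Post2", "Post3", "Post4", "Post5"),
                         direction: str = "two-sided",
                         n_comparisons: int = 1) -> dict[str, ContrastResult]:
    """Per region: paired t between per-subject mean Enc and mean Post values."""
    validate_measure_table(table)
    sub = table[table["measure"] == measure]
    out: dict[str, ContrastResult] = {}
    for region, grp in sub.groupby("region", observed=True):
        wide = grp.pivot_table(index="subject", columns="period", values="value")
        missing = [p for p in enc_periods + post_periods if p not in wide.columns]
        if missing or wide[list(enc_periods + post_periods)].isna().any().any():
            raise ValidationError(
                f"region {region!r}: missing Enc/Post values (need {missing or 'complete cells'})"
            )
        enc_mean = wide[list(enc_periods)].mean(axis=1).to_numpy()
        post_mean = wide[list(post_periods)].mean(axis=1).to_numpy()
        out[str(region)] = paired_t(enc_mean, post_mean, direction, n_comparisons)
    return out


def normality_report(values: np.ndarray) -> dict[str, float]:
    """Shapiro-Wilk screening (reported, never gate-keeping)."""
    stat, p = sstats.shapiro(np.asarray(values, dtype=float))
    return {"shapiro_w": float(stat), "shapiro_p": float(p)}
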