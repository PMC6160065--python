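"""Group-comparison and diagnostic-performance statistics.

Two-group comparisons of imaging variables use the Mann-Whitney U test with
Benjamini-Hochberg false-discovery-rate adjustment across variables;
dehiscence rates between cohorts are compared with a Pearson chi-squared
test. Classifier performance is summarized by sensitivity, specificity,
accuracy, and the diagnostic odds ratio (DOR) with a Woolf (log-scale) 95%
confidence interval. The positive class is always ``dehisced``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "mann_whitney_u",
    "bh_fdr_adjust",
    "chi_squared_2x2",
    "confusion_metrics",
    "diagnostic_odds_ratio",
    "dor_from_rates",
    "enumerate_consistent_confusions",
    "round_half_away",
    "group_comparison_table",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with ``dehisced`` as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fn, self.fp, self.tn)
        if any(c < 0 for c in cells):
            raise ValueError("confusion-matrix cells must be non-negative")
        if sum(cells) < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive="dehisced") -> "ConfusionMatrix":
        yt = np.asarray(y_true) == positive
        yp = np.asarray(y_pred) == positive
        return cls(
            tp=int((yt & yp).sum()),
            fn=int((yt & ~yp).sum()),
            fp=int((~yt & yp).sum()),
            tn=int((~yt & ~yp).sum()),
        )


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    dor: float = math.nan
    dor_ci_low: float = math.nan
    dor_ci_high: float = math.nan


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midranks for ties.

    The exact null distribution is used for small samples (n_x*n_y <= 400)
    without ties; otherwise the normal approximation with tie and continuity
    corrections. Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must contain at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def chi_squared_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a 2x2 array of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-squared is undefined for a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def confusion_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity, specificity and accuracy of a confusion matrix."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("both classes must be represented to compute metrics")
    return DiagnosticMetrics(
        sensitivity=cm.tp / (cm.tp + cm.fn),
        specificity=cm.tn / (cm.tn + cm.fp),
        accuracy=(cm.tp + cm.tn) / cm.total,
    )


def diagnostic_odds_ratio(
    cm: ConfusionMatrix, zero_correction: bool = True
) -> tuple[float, float, float]:
    """DOR = (TP*TN)/(FP*FN) with a Woolf 95% CI.

    The Woolf interval is exp(ln DOR +/- z*sqrt(1/TP + 1/FN + 1/FP + 1/TN)).
    With a zero cell and ``zero_correction`` on, 0.5 is added to every cell
    (Haldane-Anscombe) before both formulas; with it off, a zero cell raises.
    """
    cells = np.array([cm.tp, cm.fn, cm.fp, cm.tn], dtype=float)
    if np.any(cells == 0):
        if not zero_correction:
            raise ZeroDivisionError(
                "diagnostic odds ratio undefined with a zero cell (correction off)"
            )
        cells = cells + 0.5
    tp, fn, fp, tn = cells
    dor = (tp * tn) / (fp * fn)
    se = math.sqrt(1 / tp + 1 / fn + 1 / fp + 1 / tn)
    lo = math.exp(math.log(dor) - Z_95 * se)
    hi = math.exp(math.log(dor) + Z_95 * se)
    return dor, lo, hi


def dor_from_rates(sensitivity: float, specificity: float) -> float:
    """DOR as the product of the positive and negative-class odds,
    (sens/(1-sens)) * (spec/(1-spec)), for rates given directly."""
    if not (0 < sensitivity < 1 and 0 < specificity < 1):
        raise ValueError("rates must lie strictly inside (0, 1)")
    return (sensitivity / (1 - sensitivity)) * (specificity / (1 - specificity))


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for printed percents)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def enumerate_consistent_confusions(
    n_total: int,
    prevalence: float,
    printed_sensitivity_pct: float,
    printed_specificity_pct: float,
    printed_accuracy_pct: float,
) -> list[ConfusionMatrix]:
    """All integer 2x2 matrices consistent with printed performance figures.

    Candidates have ``n_total`` observations, a positive count within +/-1 of
    ``prevalence * n_total``, and sensitivity/specificity/accuracy that round
    (half away from zero, one decimal, in percent) to the printed values.
    """
    target = prevalence * n_total
    out = []
    for pos in range(n_total + 1):
        if abs(pos - target) > 1:
            continue
        neg = n_total - pos
        if pos == 0 or neg == 0:
            continue
        for tp in range(pos + 1):
            fn = pos - tp
            if round_half_away(100.0 * tp / pos) != printed_sensitivity_pct:
                continue
            for tn in range(neg + 1):
                fp = neg - tn
                if round_half_away(100.0 * tn / neg) != printed_specificity_pct:
                    continue
                if round_half_away(100.0 * (tp + tn) / n_total) != printed_accuracy_pct:
                    continue
                out.append(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
    return out


def group_comparison_table(
    df: pd.DataFrame,
    variables,
    group_col: str = "outcome",
    groups: tuple[str, str] = ("healed", "dehisced"),
) -> pd.DataFrame:
    """Per-variable two-group comparison with BH-adjusted p-values.

    Returns one row per variable: group means and SEMs, the U statistic, the
    raw two-sided p and the BH-adjusted p (adjusted across the listed
    variables). Missing values are dropped per variable.
    """
    a_label, b_label = groups
    rows = []
    for var in variables:
        a = df.loc[df[group_col] == a_label, var].dropna().to_numpy()
        b = df.loc[df[group_col] == b_label, var].dropna().to_numpy()
        u, p = mann_whitney_u(a, b)
        rows.append(
            {
                "variable": var,
                f"mean_{a_label}": a.mean(),
                f"sem_{a_label}": a.std(ddof=1) / math.sqrt(len(a)) if len(a) > 1 else math.nan,
                f"mean_{b_label}": b.mean(),
                f"sem_{b_label}": b.std(ddof=1) / math.sqrt(len(b)) if len(b) > 1 else math.nan,
                "U": u,
                "p_raw": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_fdr_adjust(table["p_raw"].to_numpy())
    return table
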