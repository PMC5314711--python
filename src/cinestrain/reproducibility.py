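"""Variability statistics for repeated strain readings.

Implements the agreement toolbox used for intra-observer,
inter-observer and inter-study (test-retest) comparison of
end-systolic strain: Bland-Altman bias and 95% limits of agreement,
coefficient of variation, coefficient of repeatability
(CR = 2.77 * SD of the paired differences, SD with the n-1
denominator), two-way absolute-agreement single-measurement ICC with
95% CI, paired t-test of the bias against zero, two-tailed F-tests
between variabilities, and the D'Agostino-Pearson normality test.
Readings are harmonized first: only items present in every compared
reading are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

CR_FACTOR = 2.77  # approx 1.96 * sqrt(2): 95% bound on a repeat difference
LOA_FACTOR = 1.96


@dataclass
class ReadingSet:
    """Paired repeated readings of the same items.

    ``data`` is items x readings; NaN marks a missing item in a
    reading.  ``pairing='first'`` compares every reading against the
    first (the multi-acquisition convention); ``'consecutive'``
    compares each against the previous one.
    """

    data: pd.DataFrame
    pairing: str = "first"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValidationError("a ReadingSet needs at least 2 readings")
        if self.pairing not in ("first", "consecutive"):
            raise ValidationError("pairing must be 'first' or 'consecutive'")

    @property
    def labels(self) -> list:
        return list(self.data.columns)

    def differences(self) -> np.ndarray:
        """Stacked paired differences per the pairing convention."""
        cols = [self.data[c].to_numpy() for c in self.data.columns]
        diffs = []
        for k in range(1, len(cols)):
            ref = cols[0] if self.pairing == "first" else cols[k - 1]
            diffs.append(cols[k] - ref)
        return np.concatenate(diffs)

    def pooled(self) -> np.ndarray:
        return self.data.to_numpy().ravel()


def harmonize(readings: ReadingSet) -> ReadingSet:
    """Drop every item missing in any compared reading."""
    kept = readings.data.dropna(axis=0, how="any")
    dropped = len(readings.data) - len(kept)
    if len(kept) == 0:
        raise ValidationError("no items remain after harmonization")
    return ReadingSet(kept, readings.pairing, n_dropped=dropped)


# ----------------------------------------------------------------------
# pairwise agreement statistics


def _paired(a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 paired samples")
    return a - b


def bland_altman(a, b) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (bias +/- 1.96 SD)."""
    d = _paired(a, b)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - LOA_FACTOR * sd, bias + LOA_FACTOR * sd


def coefficient_of_repeatability(a, b) -> float:
    """CR = 2.77 * SD of the paired differences."""
    d = _paired(a, b)
    return CR_FACTOR * float(np.std(d, ddof=1))


def cr_from_loa(bias: float, loa_lower: float, loa_upper: float) -> float:
    """Recover CR from printed Bland-Altman summaries.

    SD = (upper - lower) / (2 * 1.96), CR = 2.77 * SD — lets published
    bias/LOA/CR triples be audited for internal consistency.
    """
    if loa_upper < loa_lower:
        raise ValidationError("limits of agreement are inverted")
    sd = (loa_upper - loa_lower) / (2.0 * LOA_FACTOR)
    return CR_FACTOR * sd


def coefficient_of_variation(a, b) -> float:
    """SD of the paired differences over |mean of all samples|, in %."""
    d = _paired(a, b)
    pooled_mean = float(np.mean(np.concatenate([np.asarray(a, float), np.asarray(b, float)])))
    if pooled_mean == 0:
        return float("nan")
    return float(np.std(d, ddof=1)) / abs(pooled_mean) * 100.0


def paired_t_zero(a, b) -> float:
    """Two-tailed paired t-test of the mean difference against zero."""
    d = _paired(a, b)
    sd = np.std(d, ddof=1)
    if sd == 0:
        return 1.0 if np.mean(d) == 0 else 0.0
    return float(stats.ttest_1samp(d, 0.0).pvalue)


def variance_f_test(d1, d2) -> float:
    """Two-tailed F-test comparing the variances of two difference sets."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.size < 2 or d2.size < 2:
        raise ValidationError("each sample needs at least 2 values")
    v1 = np.var(d1, ddof=1)
    v2 = np.var(d2, ddof=1)
    if v2 == 0:
        raise ValidationError("second sample has zero variance")
    f = v1 / v2
    dist = stats.f(d1.size - 1, d2.size - 1)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def normality_dagostino(x) -> float:
    """D'Agostino-Pearson omnibus K^2 normality test p-value."""
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        raise ValidationError("normality test undefined for a constant sample")
    if x.size < 20:
        warnings.warn("D'Agostino-Pearson approximation is poor below n = 20")
    return float(stats.normaltest(x).pvalue)


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("Pearson r undefined for a zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


# ----------------------------------------------------------------------
# ICC


def icc_agreement(matrix) -> tuple[float, float, float]:
    """ICC(2,1): two-way random, absolute agreement, single measurement.

    Returns ``(icc, ci_low, ci_high)`` with the 95% CI from the
    F-distribution method.  ``matrix`` is items x readings.
    """
    import pingouin as pg

    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValidationError("ICC needs an items x readings matrix with >= 2 readings")
    if np.any(~np.isfinite(m)):
        raise ValidationError("ICC input must be complete (harmonize first)")
    if np.ptp(m) == 0:
        raise ValidationError("ICC undefined for zero total variance")
    if m.shape[0] < 5:
        warnings.warn("fewer than 5 items: ICC estimate will be unstable")
    n_items, n_read = m.shape
    long = pd.DataFrame(
        {
            "item": np.repeat(np.arange(n_items), n_read),
            "reading": np.tile(np.arange(n_read), n_items),
            "value": m.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            long, targets="item", raters="reading", ratings="value"
        ).set_index("Type")
    # row/column labels vary across pingouin releases
    key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[key]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    icc = float(min(1.0, row["ICC"]))
    lo, hi = row[ci_col]
    return icc, float(lo), float(min(1.0, hi))


# ----------------------------------------------------------------------
# full report


@dataclass
class VariabilityReport:
    """One agreement-table row: bias/LOA/CV/CR/ICC and the bias t-test."""

    group: str
    component: str
    n: int
    bias: float
    loa_lower: float
    loa_upper: float
    cv: float
    cr: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    p_bias: float
    normality_p: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.loa_lower - 1e-12 <= self.bias <= self.loa_upper + 1e-12):
            raise ValidationError("bias must lie within the limits of agreement")
        if self.cr < 0:
            raise ValidationError("CR must be non-negative")

    def as_dict(self) -> dict:
        return {
            "group": self.group, "component": self.component, "n": self.n,
            "bias": self.bias, "loa_lower": self.loa_lower, "loa_upper": self.loa_upper,
            "cv": self.cv, "cr": self.cr, "icc": self.icc,
            "icc_ci_low": self.icc_ci_low, "icc_ci_high": self.icc_ci_high,
            "p_bias": self.p_bias, "normality_p": self.normality_p,
        }


def _report_from_readings(rs: ReadingSet, group: str, component: str) -> VariabilityReport:
    rs = harmonize(rs)
    d = rs.differences()
    cols = [rs.data[c].to_numpy() for c in rs.data.columns]
    stacked_a = np.concatenate(
        [cols[k] for k in range(1, len(cols))]
    )
    stacked_ref = np.concatenate(
        [cols[0] if rs.pairing == "first" else cols[k - 1] for k in range(1, len(cols))]
    )
    bias, lo, hi = bland_altman(stacked_a, stacked_ref)
    cr = coefficient_of_repeatability(stacked_a, stacked_ref)
    cv = coefficient_of_variation(stacked_a, stacked_ref)
    icc, ci_lo, ci_hi = icc_agreement(rs.data.to_numpy())
    p_bias = paired_t_zero(stacked_a, stacked_ref)
    try:
        norm_p = normality_dagostino(d) if d.size >= 8 else float("nan")
    except ValidationError:
        norm_p = float("nan")
    return VariabilityReport(
        group=group, component=component, n=int(d.size),
        bias=bias, loa_lower=lo, loa_upper=hi, cv=cv, cr=cr,
        icc=icc, icc_ci_low=ci_lo, icc_ci_high=ci_hi,
        p_bias=p_bias, normality_p=norm_p,
    )


def variability_report(
    tidy: pd.DataFrame,
    reading_col: str = "reading",
    value_col: str = "value",
    component_col: str = "component",
    item_cols: list | None = None,
    group_col: str = "group",
    pairing: str = "first",
) -> pd.DataFrame:
    """Agreement table with one row per (component, group).

    ``tidy`` holds one row per measured value with its item identifiers
    (e.g. subject/slice/segment), the reading label, the strain
    component and the grouping (``global`` vs ``segmental``, possibly
    by level).  Internally consistent: ``cr_from_loa`` applied to a
    row's bias/LOA reproduces its CR.
    """
    if item_cols is None:
        item_cols = [
            c for c in tidy.columns
            if c not in (reading_col, value_col, component_col, group_col)
        ]
    rows = []
    for (comp, grp), sub in tidy.groupby([component_col, group_col], sort=True):
        wide = sub.pivot_table(
            index=item_cols, columns=reading_col, values=value_col, aggfunc="mean"
        )
        rs = ReadingSet(wide, pairing=pairing)
        rows.append(_report_from_readings(rs, str(grp), str(comp)).as_dict())
    return pd.DataFrame(rows)
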