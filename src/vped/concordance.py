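"""Agreement between cycle-dating methods: correlation, bias, cohort reports.

The headline comparison is a Pearson correlation between the day estimates
of two methods over a cohort, with an adjusted coefficient derived from the
small-sample-corrected R^2 (adj R^2 = 1 - (1-R^2)(n-1)/(n-2)); both plain
and adjusted values are reported so the choice is transparent.  Per-point
errors are carried through for plotting, not used as regression weights by
default; an errors-in-variables (Deming) fit is available as an opt-in.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MethodComparison", "correlate", "systematic_bias", "cohort_report"]


@dataclass
class MethodComparison:
    method_a: str
    method_b: str
    n: int
    pearson_r: float
    adjusted_r: float
    slope: float
    intercept: float
    pvalue: float
    errors_a: np.ndarray | None = None
    errors_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12):
            raise ValueError(f"correlation out of range: {self.pearson_r}")


def correlate(days_a, days_b, errors_a=None, errors_b=None,
              method_a: str = "a", method_b: str = "b",
              deming: bool = False) -> MethodComparison:
    """Pearson correlation and regression between two methods' day estimates.

    Requires n >= 3 paired finite values; constant inputs raise (the
    correlation is undefined).  The two-sided p-value tests the null of no
    correlation via the t transform.  ``deming=True`` replaces the OLS line
    with a Deming fit (equal error variances) — R is unaffected.
    """
    a = np.asarray(days_a, float)
    b = np.asarray(days_b, float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant method")
    r, p = stats.pearsonr(a, b)
    adj_r2 = 1.0 - (1.0 - r * r) * (n - 1) / (n - 2)
    adj_r = float(np.sign(r) * np.sqrt(max(adj_r2, 0.0)))
    if deming:
        # equal-variance Deming: symmetric errors-in-variables line
        sxx = np.var(a, ddof=1)
        syy = np.var(b, ddof=1)
        sxy = np.cov(a, b, ddof=1)[0, 1]
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy ** 2)) / (2 * sxy)
        intercept = float(np.mean(b) - slope * np.mean(a))
    else:
        res = stats.linregress(a, b)
        slope, intercept = float(res.slope), float(res.intercept)
    return MethodComparison(
        method_a=method_a, method_b=method_b, n=int(n),
        pearson_r=float(r), adjusted_r=adj_r,
        slope=float(slope), intercept=intercept, pvalue=float(p),
        errors_a=None if errors_a is None else np.asarray(errors_a, float)[ok],
        errors_b=None if errors_b is None else np.asarray(errors_b, float)[ok],
    )


def systematic_bias(days_a, days_b):
    """Mean offset a - b with an exact binomial sign test on its sign.

    Returns ``(mean_offset, sign_test_p)``; ties (zero differences) are
    excluded from the sign test, as is standard.
    """
    a = np.asarray(days_a, float)
    b = np.asarray(days_b, float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return 0.0, 1.0
    k = int(np.sum(nonzero > 0))
    p = stats.binomtest(k, nonzero.size, 0.5).pvalue
    return float(diff.mean()), float(p)


def cohort_report(datings: pd.DataFrame, config=None) -> dict:
    """Cohort-level agreement report.

    ``datings`` has one row per patient and one column per dating method
    (plus optional ``<method>_err`` columns); columns with fewer than 3
    finite values are skipped.  Returns the per-patient table, the pairwise
    :class:`MethodComparison` list, a symmetric R matrix and a text summary.
    """
    if len(datings) == 0:
        raise ValueError("empty cohort")
    methods = [c for c in datings.columns
               if not c.endswith("_err") and c != "patient_id"
               and np.isfinite(pd.to_numeric(datings[c], errors="coerce")).sum() >= 3]
    comparisons = []
    r_matrix = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for m1, m2 in itertools.combinations(methods, 2):
        a = pd.to_numeric(datings[m1], errors="coerce")
        b = pd.to_numeric(datings[m2], errors="coerce")
        try:
            comp = correlate(a, b,
                             errors_a=datings.get(f"{m1}_err"),
                             errors_b=datings.get(f"{m2}_err"),
                             method_a=m1, method_b=m2)
        except ValueError:
            continue
        comparisons.append(comp)
        r_matrix.loc[m1, m2] = r_matrix.loc[m2, m1] = comp.pearson_r
    lines = [f"Cohort of {len(datings)} patients; methods: {', '.join(methods)}"]
    for c in comparisons:
        lines.append(f"  {c.method_a} vs {c.method_b}: R={c.pearson_r:.3f} "
                     f"(adjusted {c.adjusted_r:.3f}), slope={c.slope:.3f}, "
                     f"p={c.pvalue:.2e}, n={c.n}")
    return {"table": datings, "comparisons": comparisons,
            "r_matrix": r_matrix, "summary": "\n".join(lines)}
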