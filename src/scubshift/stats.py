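"""Statistical layer: cross-table chi-square, t-test, CV, Cronbach's alpha."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05  # significance threshold used for summary flags throughout


class DegenerateTableError(ValueError):
    """Raised when a contingency table has an all-zero row or column."""


@dataclass(frozen=True)
class CrossTableResult:
    statistic: float
    df: int
    p_value: float
    table_dims: tuple
    min_expected: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def chi_square_cross_table(table, correction: bool = False) -> CrossTableResult:
    """Pearson chi-square on an r x c table of nonnegative counts.

    No continuity correction by default (codon tallies are large); pass
    ``correction=True`` for the Yates-corrected 2x2 variant.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(f"need an r>=2 x c>=2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")
    stat, p, df, expected = sps.chi2_contingency(t, correction=correction)
    min_expected = float(expected.min())
    if min_expected < 5:
        logger.warning(
            "chi-square table has min expected count %.3g < 5", min_expected
        )
    return CrossTableResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        table_dims=t.shape,
        min_expected=min_expected,
    )


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def two_sample_t_test(
    xs: Sequence[float], ys: Sequence[float], equal_var: bool = False
) -> TTestResult:
    """Two-sided two-sample t-test; Welch (unequal variance) by default."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        # degenerate: both groups constant
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, x.mean() - y.mean()), df, 0.0)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = float(x.size + y.size - 2)
    else:
        a = vx / x.size
        b = vy / y.size
        df = (a + b) ** 2 / (a**2 / (x.size - 1) + b**2 / (y.size - 1))
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def coefficient_of_variation(values: Sequence[float]) -> Optional[float]:
    """Sample standard deviation (n-1) over mean; ``None`` when mean is 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0:
        return None
    return float(v.std(ddof=1) / mean)


def cronbach_alpha(matrix) -> Optional[float]:
    """Internal-consistency alpha for an items x cases matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(case totals)),
    with sample (n-1) variances.  ``None`` when the total-score variance
    is zero.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >=2 items and >=2 cases")
    k = m.shape[0]
    item_vars = m.var(axis=1, ddof=1)
    total_var = m.sum(axis=0).var(ddof=1)
    if total_var == 0:
        return None
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
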