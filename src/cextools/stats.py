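"""Shared statistical primitives with fixed, documented conventions.

All tests are two-sided and use no continuity correction, so results are
reproducible across implementations. Conventions:

* ``ks_two_sample`` — D is the exact supremum of the ECDF difference over the
  pooled sample (ties handled by evaluating at pooled unique points); p-value
  is the asymptotic two-sided Kolmogorov distribution by default, exact on
  request.
* ``mann_whitney`` — U counts pairs (x_i, y_j) with x_i < y_j plus half the
  ties; the reported statistic is min(U, n1*n2 - U). The p-value is the
  two-sided normal approximation with tie correction and no continuity
  correction.
* ``chi_square`` — Pearson statistic on an r x k contingency table with
  margin-derived expected counts, df = (r-1)(k-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or contingency test."""

    statistic: float
    p: float
    df: int | None
    n: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"sample {name!r} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return arr


def ks_two_sample(x, y, exact: bool = False) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    Parameters
    ----------
    x, y : array-like
        The two samples; both must be nonempty.
    exact : bool
        Use the exact small-sample null distribution for the p-value instead
        of the asymptotic one.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    res = sps.ks_2samp(xa, ya, method="exact" if exact else "asymp")
    return TestResult(
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        df=None,
        n=(xa.size, ya.size),
        method="ks_two_sample",
    )


def mann_whitney(x, y) -> TestResult:
    """Two-sample Mann-Whitney (Wilcoxon rank-sum) test.

    U counts pairs with x below y (ties counted half); the reported statistic
    is the smaller of U and its complement. The p-value is the two-sided
    normal approximation with tie correction; when every pooled value is tied
    the statistic is exactly n1*n2/2 and p is reported as 1.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    # rank-sum identity: U(x>y) = R1 - n1(n1+1)/2; we want U(x<y).
    u_greater = r1 - n1 * (n1 + 1) / 2.0
    u = n1 * n2 - u_greater
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if sigma2 <= 0:
        p = 1.0
    else:
        z = (u - mu) / np.sqrt(sigma2)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(
        statistic=float(min(u, n1 * n2 - u)),
        p=p,
        df=None,
        n=(n1, n2),
        method="mann_whitney",
    )


def chi_square(table) -> TestResult:
    """Pearson chi-square test of independence on an r x k count table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    expected = sps.contingency.expected_freq(tab)
    if np.any(expected <= 0):
        raise ValueError(
            "zero expected count in contingency table; merge sparse categories "
            "before testing"
        )
    res = sps.chi2_contingency(tab, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=int(res.dof),
        n=tuple(int(s) for s in tab.sum(axis=1)),
        method="chi_square",
    )
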