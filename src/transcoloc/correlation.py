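"""Per-cell transcript-count correlation between two species.

Pearson's R (with the regression F test for significance) and Spearman's
rho on mid-ranks (with the two-tailed t approximation).  The denominator is
the product of the two standard deviations, sigma_x * sigma_y, which is
what constrains R to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (zero variance / all-tied input)."""


@dataclass
class CorrelationResult:
    n_cells: int
    r: float
    r2: float
    p_pearson: float
    rho: float
    p_spearman: float

    def summary(self) -> str:
        return "\n".join(
            [
                f"Per-cell count correlation, n = {self.n_cells} cells",
                f"  Pearson  R = {self.r:.4f}  (R^2 = {self.r2:.4f}), "
                f"p = {self.p_pearson:.3g} (F test)",
                f"  Spearman rho = {self.rho:.4f}, p = {self.p_spearman:.3g} "
                f"(two-tailed)",
            ]
        )


def _validate(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("at least 3 paired observations are required")
    return x, y


def pearson(x, y):
    """Pearson R, R^2, and the F-test p value.

    R = Cov(x, y) / (sigma_x * sigma_y); significance from
    F = R^2 (n-2) / (1 - R^2) on (1, n-2) degrees of freedom (upper tail,
    equivalent to the two-sided t test on the regression slope).
    """
    x, y = _validate(x, y)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    cov = np.cov(x, y, ddof=1)[0, 1]
    r = cov / (sx * sy)
    r = float(np.clip(r, -1.0, 1.0))
    if 1.0 - abs(r) < 1e-12:  # exact monotone data up to rounding
        r = float(np.sign(r))
    n = x.size
    if abs(r) == 1.0:
        p = 0.0
    else:
        f = r**2 * (n - 2) / (1.0 - r**2)
        p = float(stats.f.sf(f, 1, n - 2))
    return r, r**2, p


def spearman(x, y):
    """Spearman rho on mid-ranks and the two-tailed t-approximation p value."""
    x, y = _validate(x, y)
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    if rx.std(ddof=1) == 0 or ry.std(ddof=1) == 0:
        raise UndefinedCorrelationError("all-tied input has no rank ordering")
    rho, _, _ = pearson(rx, ry)
    n = x.size
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def correlate(x, y) -> CorrelationResult:
    """Both statistics bundled into a :class:`CorrelationResult`."""
    r, r2, p_p = pearson(x, y)
    rho, p_s = spearman(x, y)
    return CorrelationResult(
        n_cells=int(np.asarray(x).size), r=r, r2=r2, p_pearson=p_p,
        rho=rho, p_spearman=p_s,
    )
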