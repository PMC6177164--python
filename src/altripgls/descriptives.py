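"""Descriptive statistics and the Lilliefors normality statistic.

The Lilliefors test is the one-sample Kolmogorov-Smirnov test against a
normal distribution whose mean and SD are estimated from the sample; its
statistic D evaluates both one-sided empirical-CDF gaps at every order
statistic.  The p-value uses the Dallal-Wilkinson approximation and is
reported as a textual bound, since small-sample Lilliefors p-values are
conventionally read off critical-value tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DescriptiveSummary", "summarize", "lilliefors_D", "lilliefors_p",
           "p_bound", "count_where"]


@dataclass
class DescriptiveSummary:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    ks_D: float
    ks_p_bound: str

    def row(self, label: str, digits: int = 3) -> str:
        r = lambda x: f"{x:.{digits}f}"
        return "\t".join([label, str(self.n), r(self.mean), r(self.sd),
                          r(self.min), r(self.max), r(self.ks_D),
                          self.ks_p_bound])


def summarize(values) -> DescriptiveSummary:
    """Mean, sample SD (n-1), range and the Lilliefors statistic of a vector."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    D = lilliefors_D(v) if v.size >= 4 and v.std(ddof=1) > 0 else float("nan")
    bound = p_bound(lilliefors_p(D, v.size)) if np.isfinite(D) else "n/a"
    return DescriptiveSummary(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        min=float(v.min()),
        max=float(v.max()),
        ks_D=float(D),
        ks_p_bound=bound,
    )


def lilliefors_D(values) -> float:
    """Sup-norm distance between the empirical CDF and N(mean, sd_{n-1})."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 4:
        raise ValueError("Lilliefors statistic needs n >= 4")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    F = stats.norm.cdf((v - v.mean()) / sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - F)
    d_minus = np.max(F - (i - 1) / n)
    return float(max(d_plus, d_minus))


def lilliefors_p(D: float, n: int) -> float:
    """Dallal-Wilkinson approximation to the Lilliefors p-value.

    The analytic formula holds for p <= 0.1; above that the statistic is
    mapped through the Stephens modification and interpolated, following the
    standard implementation of the test.  Values are clipped to (0, 1).
    """
    if n < 5:
        raise ValueError("approximation requires n >= 5")
    kd = D
    nd = n
    if nd > 100:
        kd = D * (nd / 100.0) ** 0.49
        nd = 100
    p = math.exp(
        -7.01256 * kd * kd * (nd + 2.78019)
        + 2.99587 * kd * math.sqrt(nd + 2.78019)
        - 0.122119
        + 0.974598 / math.sqrt(nd)
        + 1.67997 / nd
    )
    if p <= 0.1:
        return min(max(p, 1e-300), 1.0)
    # large-p branch: Stephens-modified statistic, piecewise polynomials
    kk = (math.sqrt(n) - 0.01 + 0.85 / math.sqrt(n)) * D
    if kk <= 0.302:
        return 1.0
    if kk <= 0.5045:
        return (2.76773 - 19.828315 * kk + 80.709644 * kk**2
                - 138.55152 * kk**3 + 81.218052 * kk**4)
    if kk <= 0.9:
        return (-4.901232 + 40.662806 * kk - 97.490286 * kk**2
                + 94.029866 * kk**3 - 32.355711 * kk**4)
    if kk <= 1.31:
        return (6.198765 - 19.558097 * kk + 23.186922 * kk**2
                - 12.234627 * kk**3 + 2.423045 * kk**4)
    return 0.0


def p_bound(p: float) -> str:
    """Textual significance bound in the style used for tabled tests."""
    for cut in (0.001, 0.01, 0.05, 0.1, 0.2):
        if p < cut:
            return f"P < {cut:.3f}"
    return "P > 0.200"


def count_where(values, predicate) -> int:
    """Exact count of entries satisfying *predicate* (vectorized or scalar)."""
    v = np.asarray(values, dtype=float)
    try:
        mask = np.asarray(predicate(v), dtype=bool)
        if mask.shape != v.shape:
            raise TypeError
    except TypeError:
        mask = np.array([bool(predicate(x)) for x in v])
    return int(mask.sum())
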