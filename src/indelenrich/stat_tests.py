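"""Auxiliary hypothesis tests: 2x2 chi-square (with and without Yates
continuity correction) and the Mann-Whitney U test.

Both chi-square conventions are always computed, because published 2x2
statistics mix the two; reports show both. p-values that underflow double
precision are reported as "< 1E-300" together with log10 p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import mannwhitneyu, norm


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    log10_p: float
    corrected: bool

    @property
    def p_display(self) -> str:
        if self.p_value > 0:
            return f"{self.p_value:.3g}"
        return f"< 1E-300 (log10 p = {self.log10_p:.1f})"


def chi_square_2x2(table, correction: bool = True) -> Chi2Result:
    """Pearson chi-square for a 2x2 table of counts.

    statistic = N * (|ad - bc| - c)^2 / (r1 r2 c1 c2), with c = N/2 under
    the Yates continuity correction (floored so |ad - bc| - N/2 never goes
    negative) and c = 0 otherwise. A zero row or column margin leaves the
    statistic undefined and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("zero row/column margin: chi-square undefined")
    det = abs(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0])
    adj = min(n / 2.0, det) if correction else 0.0
    stat = n * (det - adj) ** 2 / (r[0] * r[1] * c[0] * c[1])
    p = float(chi2_dist.sf(stat, df=1))
    # chi2(1 df) tail = 2 * normal upper tail at sqrt(stat); norm.logsf has
    # an asymptotic expansion that stays finite where chi2.logsf underflows
    log10_p = float((np.log(2.0) + norm.logsf(np.sqrt(stat))) / np.log(10))
    return Chi2Result(float(stat), p, log10_p, correction)


def mann_whitney_u(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when both groups have <= 8 observations and no
    ties span the groups; otherwise the normal approximation with tie
    correction and continuity correction. Returns (U for group a, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
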