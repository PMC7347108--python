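"""Small self-contained statistical utilities used by the analyses.

An exact two-sided Fisher test (sum of hypergeometric probabilities no
larger than the observed table's), the Wilson score interval for a binomial
proportion, and a Kaplan-Meier median for right-censored waiting times
(bridge lifetimes censored at mitotic entry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must contain at least one observation")


def fisher_exact_2x2(table: ContingencyTable2x2 | tuple) -> float:
    """Two-sided Fisher exact p for a 2x2 table with fixed margins.

    p = sum over tables (with the observed margins) whose hypergeometric
    probability is <= that of the observed table, with a small relative
    tolerance for ties.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table if len(table) == 2 else ((table[0], table[1]), (table[2], table[3]))
        table = ContingencyTable2x2(a, b, c, d)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = sps.hypergeom.pmf(a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(1.0, p)


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    z = sps.norm.ppf(0.5 + level / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


@dataclass
class LifetimeSample:
    """Durations (hours) with right-censoring flags (True = censored)."""

    durations: list[float]
    censored: list[bool]

    def __post_init__(self) -> None:
        if not self.durations:
            raise ValueError("empty lifetime sample")
        if len(self.durations) != len(self.censored):
            raise ValueError("durations and censoring flags must align")
        if any(d <= 0 for d in self.durations):
            raise ValueError("durations must be positive")


def km_median_lifetime(sample: LifetimeSample) -> float | None:
    """Kaplan-Meier median: first time at which survival drops to <= 0.5.

    Returns None (undefined) when the survival curve never reaches 0.5,
    e.g. when too many observations are censored.
    """
    order = np.argsort(sample.durations, kind="stable")
    t = np.asarray(sample.durations, dtype=float)[order]
    cens = np.asarray(sample.censored, dtype=bool)[order]
    n = len(t)
    at_risk = n
    surv = 1.0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        deaths = int(np.sum(~cens[i : j + 1]))
        if deaths > 0:
            surv *= 1.0 - deaths / at_risk
            if surv <= 0.5:
                return float(t[i])
        at_risk -= (j - i + 1)
        i = j + 1
    return None
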