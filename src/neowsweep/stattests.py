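"""Self-contained statistical tests used by the crossing and screening
analyses: Yates-corrected chi-squared for 2x2 tables, exact two-sided
binomial, Wilcoxon signed-rank, a normal-approximation binomial sample-size
formula, and the coverage-ratio infection classifier."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    p: float
    n: int
    method: str
    note: str = ""

    def __post_init__(self) -> None:
        # p-values are reported in (0, 1]; exactly-zero p is never returned
        if self.p is not None:
            self.p = float(min(1.0, max(self.p, 5e-324)))


def chisq_2x2(table, correction: bool = True) -> TestResult:
    """Chi-squared test of independence on a 2x2 table.

    With ``correction`` (default) the Yates continuity correction is applied:
    sum((|O-E| - 0.5)^2 / E), with the correction capped so that the
    corrected deviation never goes negative.  p from chi2 with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    dev = np.abs(t - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev ** 2 / expected))
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(stat, p, int(n),
                      "chi-squared" + (", Yates-corrected" if correction
                                       else ""))


def binom_two_sided(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test (minimum-likelihood method)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    res = stats.binomtest(k, n, p0, alternative="two-sided")
    return TestResult(float(k), res.pvalue, n, "exact binomial, two-sided")


def binom_sample_size(p0: float, p1: float, alpha: float = 0.05,
                      power: float = 0.8) -> int:
    """Required n to distinguish binomial proportions p0 vs p1.

    Normal approximation with two-sided alpha:
    n = ((z_{1-a/2} sqrt(p0 q0) + z_{1-b} sqrt(p1 q1)) / |p1-p0|)^2,
    rounded up.
    """
    if not (0 < p0 < 1 and 0 < p1 < 1) or p0 == p1:
        raise ValueError("need 0 < p0, p1 < 1 and p0 != p1")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    num = za * math.sqrt(p0 * (1 - p0)) + zb * math.sqrt(p1 * (1 - p1))
    return int(math.ceil((num / abs(p1 - p0)) ** 2))


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values (or differences).

    Zero differences are dropped (signed-rank convention); ties are
    mid-ranked.  The exact null distribution is used below n = 25 when there
    are no ties, the normal approximation otherwise.  All-zero differences
    give p = 1 with a flag rather than an error.
    """
    d = np.asarray(x, dtype=float) if y is None else (
        np.asarray(x, dtype=float) - np.asarray(y, dtype=float))
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(0.0, 1.0, 0, "wilcoxon signed-rank",
                          note="all differences zero")
    method = "exact" if (nz.size < 25 and
                         np.unique(np.abs(nz)).size == nz.size) else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", correction=False,
                         alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), int(nz.size),
                      f"wilcoxon signed-rank ({method})")


def infection_call(scaffold_depths, symbiont_scaffolds, genome_mean_depth,
                   threshold: float = 0.1) -> str:
    """Classify a sample as symbiont-infected from relative coverage.

    ``scaffold_depths`` maps scaffold id -> mean read depth.  The sample is
    "infected" iff the mean depth over the symbiont scaffolds is at least
    ``threshold`` times the genome-wide mean.
    """
    if not symbiont_scaffolds:
        raise ValueError("empty symbiont scaffold set")
    if genome_mean_depth <= 0:
        raise ValueError("genome-wide mean depth must be positive")
    depths = [scaffold_depths[s] for s in symbiont_scaffolds]
    if any(d < 0 for d in depths):
        raise ValueError("negative depth")
    sym = float(np.mean(depths))
    return "infected" if sym >= threshold * genome_mean_depth else "uninfected"
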