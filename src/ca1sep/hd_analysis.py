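"""Analytic theory of Hamming-distance distributions between activity patterns.

If every cell spikes independently with probability p, a single component of
two independent patterns differs with probability pr_HD = 2p(1-p), so the HD
between the patterns is Binomial(N, 2p(1-p)).  The mean HD N·2p(1-p), its SD,
and the expected overlap N·p − mean/2 are the chance-level references against
which the network's output distances are judged.

Because the samplers here use exact active-cell counts (k of N), the exact
pairwise-HD law is hypergeometric rather than binomial; ``exact_hd_distribution``
provides it, and at the population sizes of interest the two agree to a small
fraction of a percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .patterns import BinaryPattern, hamming

__all__ = [
    "HDStats",
    "binomial_hd_stats",
    "exact_hd_distribution",
    "relative_sd_active",
    "HDSummary",
    "empirical_hd_summary",
    "normal_approx_pdf",
    "ks_normal_vs_exact",
]


def _round_even(x: float) -> int:
    return 2 * math.floor(x / 2 + 0.5)


@dataclass(frozen=True)
class HDStats:
    """Closed-form binomial summary of pairwise Hamming distances.

    Attributes
    ----------
    n : int
        Pattern length (population size).
    p : float
        Per-cell spiking probability.
    pr_hd : float
        Per-component difference probability 2p(1-p).
    mean_hd, sd_hd : float
        Mean and SD of the binomial HD distribution.
    expected_overlap : float
        Expected number of cells active in both patterns of a random pair,
        n·p − mean_hd/2.
    rounding : str
        "exact" or "printed" — whether pr_hd was rounded before the
        downstream arithmetic (see ``binomial_hd_stats``).
    """

    n: int
    p: float
    pr_hd: float
    mean_hd: float
    sd_hd: float
    expected_overlap: float
    rounding: str = "exact"

    @property
    def n_active(self) -> int:
        """Active cells at this probability, round(n·p)."""
        return int(math.floor(self.n * self.p + 0.5))

    @property
    def mean_hd_int(self) -> int:
        """Mean HD as the nearest even integer (equal-count HDs are even)."""
        return _round_even(self.mean_hd)

    @property
    def sd_hd_int(self) -> int:
        return int(math.floor(self.sd_hd + 0.5))


def binomial_hd_stats(
    n: int, p: float, rounding: str = "exact", digits: int = 2
) -> HDStats:
    """Binomial HD statistics for patterns of length n at activity p.

    ``rounding="printed"`` rounds pr_hd to ``digits`` decimals *before*
    computing the mean/SD/overlap.  The two modes exist because published
    summaries sometimes carry a rounded pr_hd (0.24 for p=0.14) through the
    arithmetic; "exact" is the default and the mathematically consistent mode.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p={p} outside [0, 1]")
    if rounding not in ("exact", "printed"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    pr = 2 * p * (1 - p)
    if rounding == "printed":
        pr = round(pr, digits)
    mean = n * pr
    sd = math.sqrt(n * pr * (1 - pr))
    overlap = n * p - mean / 2
    return HDStats(
        n=n, p=p, pr_hd=pr, mean_hd=mean, sd_hd=sd,
        expected_overlap=overlap, rounding=rounding,
    )


def exact_hd_distribution(n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact HD law between two independent uniform k-active patterns.

    The overlap m (cells active in both) is hypergeometric — drawing the
    second pattern's k actives from n cells of which k are "marked" — and
    HD = 2(k - m).  Returns ``(hd_values, pmf)`` with hd_values = 0, 2, 4, ...
    ascending; the pmf sums to 1.

    P(HD = 2j) = C(k, j) C(n-k, j) / C(n, k) for j = 0..min(k, n-k).
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    j = np.arange(0, min(k, n - k) + 1)
    # overlap m = k - j; hypergeom(M=n, n_marked=k, N_draws=k)
    pmf = sps.hypergeom.pmf(k - j, n, k, k)
    return 2 * j, pmf


def relative_sd_active(p: float, s: int) -> float:
    """Relative SD (percent) of a cell's active-synapse count.

    With s synapse slots each independently active with probability p, the
    active count is Binomial(s, p) and its SD relative to s is
    sqrt(p(1-p)/s); returned in percent.  This is the cell-to-cell input
    variability that makes pathways with fewer synapses (EC, s=1918) noisier
    than those with more (CA3, s=4407).
    """
    if not 0 < p < 1:
        raise ValueError(f"p={p} outside (0, 1)")
    if s <= 0:
        raise ValueError(f"s={s} must be positive")
    return math.sqrt(p * (1 - p) / s) * 100.0


@dataclass(frozen=True)
class HDSummary:
    """Empirical summary of pairwise HDs for a set of output pattern pairs."""

    n_pairs: int
    hds: np.ndarray
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def se(self) -> float:
        """Standard error of the mean HD."""
        return self.sd / math.sqrt(self.n_pairs)


def empirical_hd_summary(
    pairs: Sequence[tuple[BinaryPattern, BinaryPattern]],
    bins: int = 10,
) -> HDSummary:
    """Sample mean/SD and histogram of HDs over pattern pairs.

    Invariant to pair order and to the order within each pair (the metric is
    symmetric).  Requires at least two pairs so the SD is defined.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for an empirical summary")
    hds = np.array([hamming(a, b) for a, b in pairs], dtype=float)
    counts, edges = np.histogram(hds, bins=bins)
    return HDSummary(
        n_pairs=len(pairs),
        hds=hds,
        mean=float(hds.mean()),
        sd=float(hds.std(ddof=1)),
        bin_edges=edges,
        counts=counts,
    )


def normal_approx_pdf(stats: HDStats):
    """Gaussian density with (mean_hd, sd_hd), the usual binomial approximation.

    Returns a frozen ``scipy.stats.norm`` distribution; raises on sd_hd = 0
    (degenerate — all pairwise distances identical).
    """
    if stats.sd_hd <= 0:
        raise ValueError("degenerate HD distribution (sd_hd = 0)")
    return sps.norm(loc=stats.mean_hd, scale=stats.sd_hd)


def exact_hd_moments(n: int, k: int) -> tuple[float, float]:
    """Mean and SD of the exact (hypergeometric) pairwise-HD law.

    The mean agrees with the binomial theory to O(1/n); the SD does *not* —
    fixing the active count removes most of the between-pattern count
    variance, so the exact SD is far below the binomial one (17 vs 51 at the
    CA3 scale).  See the methods note.
    """
    hd, pmf = exact_hd_distribution(n, k)
    mean = float(np.sum(hd * pmf))
    var = float(np.sum((hd - mean) ** 2 * pmf))
    return mean, math.sqrt(var)


def ks_normal_vs_exact(n: int, k: int) -> float:
    """Kolmogorov–Smirnov distance between the exact (hypergeometric) HD law
    and its moment-matched normal approximation.

    The normal CDF is evaluated with a half-lattice continuity correction
    (HD lives on even integers, spacing 2).
    """
    hd, pmf = exact_hd_distribution(n, k)
    exact_cdf = np.cumsum(pmf)
    mean, sd = exact_hd_moments(n, k)
    if sd <= 0:
        raise ValueError("degenerate exact distribution")
    approx_cdf = sps.norm.cdf(hd + 1, loc=mean, scale=sd)
    return float(np.max(np.abs(exact_cdf - approx_cdf)))
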