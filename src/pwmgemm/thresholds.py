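"""p-value calibrated score thresholds via dynamic programming.

Under the background model, the score of a random length-m window is a sum
of m independent draws, one per motif column.  Discretizing the weights to
an integer grid of width ``epsilon`` (bits) turns the score distribution
into a finite probability mass function that a per-position convolution
computes exactly:

    D_0 = point mass at 0
    D_{j+1}(s) = sum_i  b_i * D_j(s - e'_{i,j})

where ``e'_{i,j} = round(weight_{i,j} / epsilon)``.  The threshold for a
p-value ``p`` is the smallest grid score whose upper tail mass is <= p,
reported back in bits.  The true-score error introduced by discretization
is bounded by ``m * epsilon / 2``; with the default epsilon of 1e-3 bits
this is far below any practically meaningful score difference.

The grid threshold is applied unchanged to the undiscretized floating-point
scores produced during scanning; the naive reference scanner applies the
identical rule, so equivalence between the two is unaffected by the
discretization choice.  Matches are windows with ``score >= threshold``
(non-strict, so p = 1 admits every window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np

from .motifs import PWM, BackgroundModel

#: default score grid width, in bits
DEFAULT_EPSILON = 1e-3
#: refuse distributions wider than this many bins (guards epsilon misuse)
DEFAULT_MAX_BINS = 8_000_000


def discretize(pwm_or_weights, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Round weights to the integer grid: ``e' = round(e / epsilon)``.

    Nearest-integer rounding (ties to even), so the reconstruction error
    ``|epsilon * e' - e|`` is at most ``epsilon / 2`` per entry.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    weights = pwm_or_weights.weights if isinstance(pwm_or_weights, PWM) else pwm_or_weights
    return np.rint(np.asarray(weights, dtype=float) / epsilon).astype(np.int64)


@dataclass(frozen=True)
class ScoreDistribution:
    """PMF of a PWM's discretized score under the background model.

    ``mass[k]`` is the probability of integer grid score ``k - offset``;
    the score in bits is ``(k - offset) * bin_width``.
    """

    bin_width: float
    offset: int
    mass: np.ndarray
    m: int

    @property
    def min_int(self) -> int:
        return -self.offset

    @property
    def max_int(self) -> int:
        return len(self.mass) - 1 - self.offset

    def support(self) -> np.ndarray:
        """Integer grid scores carrying the mass vector, ascending."""
        return np.arange(len(self.mass)) - self.offset

    def as_dict(self) -> Dict[int, float]:
        """{integer grid score: probability}, zero bins dropped."""
        return {
            int(s): float(p)
            for s, p in zip(self.support(), self.mass)
            if p != 0.0
        }

    def tail(self, t_int: int) -> float:
        """P(score >= t_int) on the integer grid."""
        if t_int > self.max_int:
            return 0.0
        if t_int <= self.min_int:
            return 1.0
        return float(self.mass[t_int + self.offset:].sum())

    def threshold(self, p: float) -> float:
        """Smallest grid score (in bits) whose tail mass is <= p."""
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value must lie in (0, 1], got {p}")
        tails = np.cumsum(self.mass[::-1])[::-1]
        admissible = np.nonzero(tails <= p)[0]
        if len(admissible) == 0:
            t_int = self.max_int + 1  # p below the point mass at the maximum
        else:
            t_int = int(admissible[0]) - self.offset
        return t_int * self.bin_width

    def pvalue(self, threshold_bits: float) -> float:
        """Tail mass at or above ``round(threshold / bin_width)``."""
        return self.tail(int(np.rint(threshold_bits / self.bin_width)))


def score_distribution(
    pwm: PWM,
    background: Optional[BackgroundModel] = None,
    epsilon: float = DEFAULT_EPSILON,
    max_bins: int = DEFAULT_MAX_BINS,
) -> ScoreDistribution:
    """Exact PMF of the discretized PWM score under the background model.

    Equals, bin for bin, the enumeration over all 4^m words of the product
    of background probabilities grouped by integer score (the dynamic
    program just factorizes that sum position by position).
    """
    bg = background if background is not None else BackgroundModel.uniform()
    grid = discretize(pwm, epsilon)
    col_min = grid.min(axis=0)
    col_max = grid.max(axis=0)
    width = int((col_max - col_min).sum()) + 1
    if width > max_bins:
        raise ValueError(
            f"score support of {width} bins exceeds the budget of {max_bins}; "
            "use a larger epsilon"
        )
    mass = np.array([1.0])
    cur_min = 0
    for j in range(pwm.length):
        new = np.zeros(len(mass) + int(col_max[j] - col_min[j]))
        for i in range(4):
            shift = int(grid[i, j] - col_min[j])
            new[shift:shift + len(mass)] += bg.probs[i] * mass
        mass = new
        cur_min += int(col_min[j])
    return ScoreDistribution(bin_width=epsilon, offset=-cur_min, mass=mass, m=pwm.length)


def pvalue_to_threshold(
    pwm: PWM,
    background: Optional[BackgroundModel] = None,
    p: float = 1e-4,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Score threshold (bits) whose null tail probability is <= p.

    Monotone: a smaller p never yields a smaller threshold.  The returned
    value never exceeds max_score + epsilon.
    """
    return score_distribution(pwm, background, epsilon).threshold(p)


def threshold_to_pvalue(
    pwm: PWM,
    background: Optional[BackgroundModel] = None,
    threshold_bits: float = 0.0,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Realized p-value of a threshold: null tail mass at or above it."""
    return score_distribution(pwm, background, epsilon).pvalue(threshold_bits)


def thresholds_for_motifs(
    pwms: Iterable[PWM],
    background: Optional[BackgroundModel] = None,
    p: float = 1e-4,
    epsilon: float = DEFAULT_EPSILON,
) -> Dict[str, float]:
    """Per-motif thresholds {name: bits} at a common p-value.

    Thresholds are derived from each forward PWM's distribution and are
    applied to both strands during scanning (under a uniform background
    the reverse complement has the identical distribution anyway).
    """
    return {pwm.name: pvalue_to_threshold(pwm, background, p, epsilon) for pwm in pwms}
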