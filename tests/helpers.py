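"""Independent oracles and small utilities shared across tests.

The oracles here deliberately avoid the code paths they check: the score
distribution is obtained by exhaustive enumeration of all 4^m words, and
window scoring for cross-checks goes through the scalar primitive only.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from pwmgemm import PWM, BackgroundModel, pfm_to_pwm
from pwmgemm.fixtures import random_pfm


def enumerate_distribution(grid_weights: np.ndarray, bg: BackgroundModel) -> Dict[int, float]:
    """{integer score: probability} by brute force over all 4^m words."""
    m = grid_weights.shape[1]
    scores = np.zeros(1, dtype=np.int64)
    probs = np.ones(1)
    for j in range(m):
        scores = (scores[:, None] + grid_weights[:, j][None, :]).ravel()
        probs = (probs[:, None] * bg.probs[None, :]).ravel()
    out: Dict[int, float] = {}
    for s, p in zip(scores, probs):
        out[int(s)] = out.get(int(s), 0.0) + float(p)
    return out


def enumerate_threshold(grid_weights: np.ndarray, bg: BackgroundModel, p: float) -> int:
    """Minimal integer grid score whose enumerated tail mass is <= p."""
    dist = enumerate_distribution(grid_weights, bg)
    support = sorted(dist)
    tail = 0.0
    # walk from the top down: once the tail first exceeds p at support score
    # s, the minimal admissible integer is s + 1 (possibly an empty bin)
    for s in reversed(support):
        tail += dist[s]
        if tail > p:
            return s + 1
    return support[0]


def random_pwms(n: int, m_range: Tuple[int, int], seed: int,
                alpha: float = 1.0, bg: BackgroundModel = None,
                concentration: float = 4.0) -> List[PWM]:
    """n random PWMs with lengths uniform in m_range, deterministic in seed."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        m_j = int(rng.integers(m_range[0], m_range[1] + 1))
        pfm = random_pfm(m_j, depth=100, concentration=concentration, rng=rng)
        pwm = pfm_to_pwm(pfm, alpha=alpha, background=bg)
        out.append(PWM(name=f"M{k:03d}", weights=pwm.weights))
    return out


def random_records(n_records: int, lengths, seed: int) -> List[Tuple[str, str]]:
    rng = np.random.default_rng(seed)
    return [
        (f"r{i}", "".join(rng.choice(list("ACGT"), size=lengths[i % len(lengths)])))
        for i in range(n_records)
    ]


def occ_keys(occurrences):
    """Positional identity of occurrences (scores compared separately)."""
    return [(o.record, o.start, o.motif, o.strand) for o in occurrences]
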