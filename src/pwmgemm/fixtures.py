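"""Deterministic synthetic motifs and sequences.

Every generator is a pure function of its seed/spec, so tests and the
acceptance script never need external downloads.  Defaults mirror a
JASPAR-like motif collection: motif lengths uniform in [5, 30], count
depth 100 per column, i.i.d. background sequence.  Planted sites overwrite
the sequence with a motif's consensus (or its reverse complement for
minus-strand plants), whose score is exactly the motif's maximum score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .motifs import (
    ALPHABET,
    PFM,
    PWM,
    consensus,
    reverse_complement,
    reverse_complement_dna,
    score_extrema,
)


class PlantedSite(NamedTuple):
    """Ground truth for one planted occurrence."""

    record: str
    start: int
    motif: str
    strand: str
    score: float
    length: int


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible recipe for a synthetic motif/sequence data set."""

    seed: int = 0
    record_lengths: Tuple[int, ...] = (4000, 3500, 2500)
    background: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_motifs: int = 20
    m_range: Tuple[int, int] = (5, 30)
    depth: int = 100
    concentration: float = 4.0


def random_pfm(
    m_j: int,
    depth: int = 100,
    concentration: float = 4.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PFM:
    """Random PFM with per-column counts summing to ``depth``.

    Column probabilities are a flat Dirichlet draw sharpened by raising it
    to the ``concentration`` power and renormalizing: concentration 1
    leaves the flat Dirichlet, large values drive each column toward a
    single letter (consensus-like), so motifs become more informative as
    concentration grows.
    """
    if m_j < 1 or depth < 1:
        raise ValueError("motif length and depth must both be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    counts = np.zeros((4, m_j))
    for j in range(m_j):
        # sharpen in log space so extreme concentrations stay finite
        logp = concentration * np.log(rng.dirichlet(np.ones(4)))
        logp -= logp.max()
        probs = np.exp(logp)
        probs /= probs.sum()
        counts[:, j] = rng.multinomial(depth, probs)
    return PFM(name=f"SYN{rng.integers(10**8):08d}", counts=counts)


def random_motif_set(spec: FixtureSpec) -> List[PFM]:
    """``spec.n_motifs`` random PFMs with lengths uniform in ``m_range``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.m_range
    pfms = []
    for k in range(spec.n_motifs):
        m_j = int(rng.integers(lo, hi + 1))
        pfm = random_pfm(m_j, depth=spec.depth, concentration=spec.concentration, rng=rng)
        pfms.append(PFM(name=f"SYN{k:04d}", counts=pfm.counts))
    return pfms


def random_sequences(spec: FixtureSpec) -> List[Tuple[str, str]]:
    """(id, sequence) records of i.i.d. letters from the spec background."""
    rng = np.random.default_rng(spec.seed + 1)  # independent of the motif stream
    probs = np.asarray(spec.background, dtype=float)
    probs = probs / probs.sum()
    records = []
    for r, length in enumerate(spec.record_lengths):
        letters = rng.choice(list(ALPHABET), size=length, p=probs)
        records.append((f"rec{r}", "".join(letters)))
    return records


def plant_sites(
    records: Sequence[Tuple[str, str]],
    pwms: Sequence[PWM],
    sites: Sequence[Tuple[int, int, int, str]],
) -> Tuple[List[Tuple[str, str]], List[PlantedSite]]:
    """Overwrite consensus windows at stated positions.

    ``sites`` holds (motif index, record index, position, strand) tuples;
    minus-strand sites plant the reverse complement of the consensus, and
    the truth table reports the leftmost forward-strand coordinate either
    way.  The truth score is the motif's maximum score (the consensus
    score by construction).  Out-of-bounds sites raise.
    """
    seqs = {r: list(seq) for r, (_rid, seq) in enumerate(records)}
    ids = [rid for rid, _ in records]
    truth: List[PlantedSite] = []
    for motif_idx, rec_idx, pos, strand in sites:
        pwm = pwms[motif_idx]
        word = consensus(pwm)
        if strand == "-":
            word = reverse_complement_dna(word)
        elif strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if rec_idx not in seqs:
            raise IndexError(f"record index {rec_idx} out of range")
        if pos < 0 or pos + len(word) > len(seqs[rec_idx]):
            raise IndexError(
                f"site at record {rec_idx} position {pos} (length {len(word)}) "
                "falls outside the record"
            )
        seqs[rec_idx][pos:pos + len(word)] = word
        # realize the consensus score in the exact summation order the
        # scanner uses for this strand (minus-strand columns are reversed)
        scored = pwm if strand == "+" else reverse_complement(pwm)
        truth.append(
            PlantedSite(
                record=ids[rec_idx], start=pos, motif=pwm.name, strand=strand,
                score=score_extrema(scored)[1], length=pwm.length,
            )
        )
    planted = [(ids[r], "".join(seqs[r])) for r in range(len(ids))]
    return planted, truth


def random_nonoverlapping_sites(
    pwms: Sequence[PWM],
    record_lengths: Sequence[int],
    n_sites: int,
    seed: int,
    max_tries: int = 10_000,
) -> List[Tuple[int, int, int, str]]:
    """Sample ``n_sites`` mutually non-overlapping (motif, record, pos, strand)
    plant sites so no later plant can clobber an earlier one."""
    rng = np.random.default_rng(seed)
    taken = {r: [] for r in range(len(record_lengths))}
    sites: List[Tuple[int, int, int, str]] = []
    tries = 0
    while len(sites) < n_sites:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_sites} non-overlapping sites in "
                f"{sum(record_lengths)} nt"
            )
        k = int(rng.integers(len(pwms)))
        r = int(rng.integers(len(record_lengths)))
        m_j = pwms[k].length
        if record_lengths[r] < m_j:
            continue
        pos = int(rng.integers(0, record_lengths[r] - m_j + 1))
        if any(pos < q_end and q_start < pos + m_j for q_start, q_end in taken[r]):
            continue
        taken[r].append((pos, pos + m_j))
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append((k, r, pos, strand))
    return sites


def fasta_text(records: Sequence[Tuple[str, str]], width: int = 60) -> str:
    """Render records as FASTA text (fixed wrap width, byte-reproducible)."""
    lines = []
    for rid, seq in records:
        lines.append(f">{rid}")
        lines.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(lines) + "\n" if lines else ""
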