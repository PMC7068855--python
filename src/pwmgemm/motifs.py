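"""Position-specific motif models: PFM -> PPM -> PWM.

A motif over the DNA alphabet is represented at three levels:

* **PFM** (position frequency matrix): a 4 x m table of non-negative
  nucleotide counts per alignment column, row order A, C, G, T.
* **PPM** (position probability matrix): the column-normalized PFM with
  additive pseudocount smoothing,
  ``PPM(i,j) = (PFM(i,j) + alpha) / sum_i (PFM(i,j) + alpha)``.
* **PWM** (position weight matrix): base-2 log-odds against a background
  model, ``PWM(i,j) = log2(PPM(i,j) / b_i)``, in bits.

The score of a length-m window is the sum of the per-position weights
selected by the window's nucleotides.  Non-ACGT symbols (IUPAC ambiguity
codes, the internal record separator) contribute exactly 0 under the default
policy -- the same convention the one-hot encoding of the matrix engine
enforces -- or render the window unscoreable under the stricter ``exclude``
policy.

This module also hosts the JASPAR-style PFM text parser/writer and the
scalar :func:`score_window` primitive that serves as the ground truth for
all matrix-product scoring paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Union

import numpy as np

ALPHABET = "ACGT"
#: complement of row index i is row 3 - i (A<->T, C<->G)

#: sentinel returned by :func:`score_window` under the ``exclude`` policy;
#: never satisfies ``score >= threshold`` for any finite threshold.
UNSCOREABLE = float("-inf")


class MotifParseError(ValueError):
    """Raised when a motif record cannot be parsed."""


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: 4 x m non-negative counts (rows A,C,G,T)."""

    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.array(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"PFM {self.name!r}: counts must be 4 x m, got shape {counts.shape}")
        if counts.shape[1] < 1:
            raise ValueError(f"PFM {self.name!r}: motif length must be >= 1")
        if np.any(counts < 0):
            raise ValueError(f"PFM {self.name!r}: counts must be non-negative")
        counts.flags.writeable = False
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class BackgroundModel:
    """Nucleotide probabilities b_i of the null sequence model (A,C,G,T)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.array(self.probs, dtype=float)
        if probs.shape != (4,):
            raise ValueError("background must have exactly 4 probabilities (A,C,G,T)")
        if np.any(probs <= 0):
            raise ValueError("background probabilities must all be > 0")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("background probabilities must sum to 1")
        probs.flags.writeable = False
        object.__setattr__(self, "probs", probs)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_counts(cls, counts: Iterable[float]) -> "BackgroundModel":
        """Normalize raw A,C,G,T counts (or weights) into a background."""
        arr = np.asarray(list(counts), dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("background counts must have a positive sum")
        return cls(arr / total)

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "BackgroundModel":
        """Estimate mononucleotide frequencies from input sequences.

        A pseudocount of 1 per letter keeps all probabilities positive even
        for degenerate inputs.  Non-ACGT symbols are ignored.
        """
        counts = np.ones(4)
        for seq in sequences:
            for i, letter in enumerate(ALPHABET):
                counts[i] += seq.upper().count(letter)
        return cls(counts / counts.sum())


@dataclass(frozen=True)
class PPM:
    """Position probability matrix: column-stochastic 4 x m matrix."""

    name: str
    probs: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        probs = np.array(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError(f"PPM {self.name!r}: probs must be 4 x m")
        if np.any(probs < 0):
            raise ValueError(f"PPM {self.name!r}: probabilities must be >= 0")
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-12):
            raise ValueError(f"PPM {self.name!r}: columns must sum to 1")
        probs.flags.writeable = False
        object.__setattr__(self, "probs", probs)

    @property
    def length(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: 4 x m base-2 log-odds weights (bits)."""

    name: str
    weights: np.ndarray
    strand: str = "+"

    def __post_init__(self) -> None:
        weights = np.array(self.weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != 4:
            raise ValueError(f"PWM {self.name!r}: weights must be 4 x m")
        if self.strand not in ("+", "-"):
            raise ValueError(f"PWM {self.name!r}: strand must be '+' or '-'")
        weights.flags.writeable = False
        object.__setattr__(self, "weights", weights)

    @property
    def length(self) -> int:
        return self.weights.shape[1]


# ---------------------------------------------------------------------------
# JASPAR-style PFM text
# ---------------------------------------------------------------------------

def _parse_count_line(line: str, record: str) -> tuple:
    """Return (letter or None, list-of-floats) for one count row."""
    cleaned = line.replace("[", " ").replace("]", " ")
    tokens = cleaned.split()
    letter = None
    if tokens and len(tokens[0]) == 1 and tokens[0].upper() in ALPHABET:
        letter = tokens[0].upper()
        tokens = tokens[1:]
    values = []
    for tok in tokens:
        try:
            val = float(tok)
        except ValueError:
            raise MotifParseError(
                f"record {record!r}: non-numeric count {tok!r}"
            ) from None
        if val < 0:
            raise MotifParseError(f"record {record!r}: negative count {tok!r}")
        values.append(val)
    if not values:
        raise MotifParseError(f"record {record!r}: count row {line!r} holds no numbers")
    return letter, values


def _build_pfm(name: str, rows: list) -> PFM:
    if len(rows) != 4:
        raise MotifParseError(
            f"record {name!r}: expected 4 count rows (A,C,G,T), got {len(rows)}"
        )
    lengths = {len(values) for _, values in rows}
    if len(lengths) != 1:
        raise MotifParseError(
            f"record {name!r}: ragged count rows with lengths "
            f"{sorted(len(v) for _, v in rows)}"
        )
    letters = [letter for letter, _ in rows]
    if all(letter is None for letter in letters):
        ordered = [values for _, values in rows]
    elif all(letter is not None for letter in letters):
        if sorted(letters) != list(ALPHABET):
            raise MotifParseError(
                f"record {name!r}: row letters {letters} are not a permutation of A,C,G,T"
            )
        by_letter = {letter: values for letter, values in rows}
        ordered = [by_letter[letter] for letter in ALPHABET]
    else:
        raise MotifParseError(
            f"record {name!r}: mixes labelled and unlabelled count rows"
        )
    return PFM(name=name, counts=np.array(ordered, dtype=float))


def parse_jaspar(source: Union[str, IO[str]]) -> list:
    """Parse JASPAR-style PFM text into a list of :class:`PFM`.

    Accepts both the raw dialect (header then 4 bare count rows) and the
    bracketed dialect (``A  [ 4 19 0 ]`` ...).  When letter prefixes are
    present the rows may appear in any order; they are re-ordered to the
    canonical A,C,G,T.  The motif name is the first whitespace-delimited
    token of the header.
    """
    text = source.read() if hasattr(source, "read") else source
    records = []
    name = None
    rows: list = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append(_build_pfm(name, rows))
            header = line[1:].strip()
            if not header:
                raise MotifParseError("motif header has no identifier")
            name = header.split()[0]
            rows = []
        else:
            if name is None:
                raise MotifParseError(f"count row {line!r} appears before any '>' header")
            rows.append(_parse_count_line(line, name))
    if name is not None:
        records.append(_build_pfm(name, rows))
    return records


def write_jaspar(pfms: Iterable[PFM]) -> str:
    """Serialize PFMs in the bracketed JASPAR dialect (round-trip exact)."""
    chunks = []
    for pfm in pfms:
        lines = [f">{pfm.name}"]
        for i, letter in enumerate(ALPHABET):
            cells = " ".join(_format_count(v) for v in pfm.counts[i])
            lines.append(f"{letter} [ {cells} ]")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + ("\n" if chunks else "")


def _format_count(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(value)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def pfm_to_ppm(pfm: PFM, alpha: float = 1.0) -> PPM:
    """Column-normalize a PFM with pseudocount ``alpha``.

    ``PPM(i,j) = (PFM(i,j) + alpha) / sum_i (PFM(i,j) + alpha)``.
    """
    if alpha < 0:
        raise ValueError(f"pseudocount alpha must be >= 0, got {alpha}")
    denom = pfm.counts.sum(axis=0) + 4.0 * alpha
    if np.any(denom == 0):
        raise ZeroDivisionError(
            f"PFM {pfm.name!r} has an all-zero column; use a pseudocount alpha > 0"
        )
    return PPM(name=pfm.name, probs=(pfm.counts + alpha) / denom, alpha=alpha)


def ppm_to_pwm(ppm: PPM, background: BackgroundModel = None) -> PWM:
    """Base-2 log-odds of the PPM against the background model."""
    bg = background if background is not None else BackgroundModel.uniform()
    if np.any(ppm.probs <= 0):
        raise ValueError(
            f"PPM {ppm.name!r} contains zero probabilities; "
            "rebuild it with a pseudocount alpha > 0 before taking log-odds"
        )
    return PWM(name=ppm.name, weights=np.log2(ppm.probs / bg.probs[:, None]))


def pfm_to_pwm(pfm: PFM, alpha: float = 1.0, background: BackgroundModel = None) -> PWM:
    """Convenience composition of :func:`pfm_to_ppm` and :func:`ppm_to_pwm`."""
    return ppm_to_pwm(pfm_to_ppm(pfm, alpha), background)


def reverse_complement(pwm: PWM) -> PWM:
    """Reverse-complement a PWM: reverse the columns, swap A<->T and C<->G.

    Scoring the result on a window equals scoring the original on the
    window's reverse complement; the strand label is flipped.
    """
    return PWM(
        name=pwm.name,
        weights=pwm.weights[::-1, ::-1],
        strand="-" if pwm.strand == "+" else "+",
    )


# ---------------------------------------------------------------------------
# Scalar scoring
# ---------------------------------------------------------------------------

def score_window(pwm: PWM, window: str, non_acgt: str = "zero") -> float:
    """Score one window of length ``pwm.length`` (sum of selected weights).

    Under the default ``zero`` policy a non-ACGT symbol contributes exactly
    0 (the one-hot "otherwise -> 0000" encoding); under ``exclude`` any
    non-ACGT symbol makes the window unscoreable and :data:`UNSCOREABLE`
    is returned.  Lowercase letters are uppercased first, so soft-masked
    sequence is scanned like unmasked sequence.
    """
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != motif length {pwm.length}"
        )
    if non_acgt not in ("zero", "exclude"):
        raise ValueError(f"unknown non-ACGT policy {non_acgt!r}")
    total = 0.0
    for j, char in enumerate(window.upper()):
        i = ALPHABET.find(char)
        if i < 0:
            if non_acgt == "exclude":
                return UNSCOREABLE
            continue
        total += pwm.weights[i, j]
    return total


def score_extrema(pwm: PWM) -> tuple:
    """(min_score, max_score): column-wise minima/maxima summed.

    Accumulated position by position in the same order as
    :func:`score_window`, so the maximum equals the consensus window's
    score bit for bit.
    """
    lo = hi = 0.0
    for j in range(pwm.length):
        lo += pwm.weights[:, j].min()
        hi += pwm.weights[:, j].max()
    return float(lo), float(hi)


def consensus(pwm: PWM) -> str:
    """Per-column argmax letters; ties resolved toward A < C < G < T.

    The consensus scores exactly ``score_extrema(pwm)[1]``.
    """
    return "".join(ALPHABET[i] for i in np.argmax(pwm.weights, axis=0))


def reverse_complement_dna(seq: str) -> str:
    """Reverse-complement a DNA string; non-ACGT symbols map to N."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp.get(ch, "N") for ch in reversed(seq.upper()))
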