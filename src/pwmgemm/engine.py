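"""Dense matrix-product motif scanning.

The brute-force scan -- score every motif at every position -- is recast as
a sequence of dense matrix-matrix products:

* A **pattern matrix** ``P`` of shape ``4m x c`` holds every PWM unrolled
  into one column (position-major, letter-minor), zero-padded to the
  maximum motif length ``m``; with reverse complements included, ``c``
  doubles and the extra columns carry strand ``'-'``.
* Each **sequence chunk** of ``h*w + m - 1`` symbols is one-hot encoded
  (A=1000, C=0100, G=0010, T=0001, anything else 0000) and laid out as an
  ``h x 4(w+m-1)`` **sequence matrix** ``S`` whose rows encode substrings
  overlapping by ``m - 1`` symbols.
* For each offset ``o`` in ``[0, w)`` the product
  ``R^o = S[:, 4o:4(o+m)] @ P`` yields an ``h x c`` score block whose
  entry ``(i, j)`` is the score of pattern column ``j`` at chunk-local
  position ``i*w + o``.

Because the one-hot rows merely select weights, the products compute the
very same sums as the scalar scorer; the zero encoding of non-ACGT symbols
makes them contribute exactly 0.  Multiple input records are concatenated
with a single sentinel symbol in between; a validity mask derived from the
record bookkeeping suppresses any window that would span a record boundary
or sentinel padding, so no occurrence can bridge two records.

:func:`naive_scan` is the three-nested-loop reference scanner; the central
contract of this module is that :func:`scan_stream` reproduces its output
identically for any chunk geometry, worker count, and tiling setting.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

from .motifs import PWM, BackgroundModel, reverse_complement

#: byte -> code lookup: A/a=0, C/c=1, G/g=2, T/t=3, everything else 4
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _CODE_LUT[ord(_ch)] = _i
    _CODE_LUT[ord(_ch.lower())] = _i

#: code -> one-hot row; the 5th row (non-ACGT / sentinel) is all zeros
_ONEHOT = np.zeros((5, 4), dtype=np.float64)
_ONEHOT[:4] = np.eye(4)

SENTINEL_CODE = 4


def dna_to_codes(dna: str) -> np.ndarray:
    """Map a DNA string to uint8 codes 0..3 (A,C,G,T) with 4 for non-ACGT."""
    if not dna:
        return np.zeros(0, dtype=np.uint8)
    raw = np.frombuffer(dna.encode("latin-1"), dtype=np.uint8)
    return _CODE_LUT[raw]


def encode_sequence(dna: str) -> np.ndarray:
    """One-hot encode a DNA string into a 0/1 vector of length 4*|dna|."""
    return _ONEHOT[dna_to_codes(dna)].ravel()


# ---------------------------------------------------------------------------
# Pattern matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternColumn:
    """Metadata of one pattern-matrix column."""

    motif: str
    strand: str
    length: int
    index: int  # column index in the original (unsorted) pattern matrix


@dataclass
class PatternMatrix:
    """4m x c matrix of unrolled PWMs plus per-column metadata."""

    values: np.ndarray
    columns: Tuple[PatternColumn, ...]
    m: int
    tiles: Optional[list] = None

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def build_pattern_matrix(pwms: Sequence[PWM], include_rc: bool = True) -> PatternMatrix:
    """Unroll PWMs into columns of a 4m x c matrix, zero-padded to length m.

    ``P(i, j) = PWM_j(i mod 4, i // 4)`` for ``i < 4*m_j`` and 0 above --
    the trailing zeros never contribute to any dot product.  With
    ``include_rc`` the reverse complement of every motif is appended as an
    extra column with strand ``'-'`` (same motif name).
    """
    if not pwms:
        raise ValueError("at least one motif is required to build a pattern matrix")
    stranded = [(pwm, pwm.strand) for pwm in pwms]
    if include_rc:
        stranded += [(reverse_complement(pwm), "-") for pwm in pwms]
    m = max(pwm.length for pwm, _ in stranded)
    values = np.zeros((4 * m, len(stranded)))
    columns = []
    for k, (pwm, strand) in enumerate(stranded):
        # position-major, letter-minor unrolling: rows 4j..4j+3 hold column j
        values[: 4 * pwm.length, k] = pwm.weights.T.ravel()
        columns.append(PatternColumn(motif=pwm.name, strand=strand, length=pwm.length, index=k))
    return PatternMatrix(values=values, columns=tuple(columns), m=m)


# ---------------------------------------------------------------------------
# Sequence matrix and score blocks
# ---------------------------------------------------------------------------

def build_sequence_matrix(s_enc: np.ndarray, h: int, w: int, m: int) -> np.ndarray:
    """Lay a one-hot vector of 4(hw+m-1) entries out as an h x 4(w+m-1) matrix.

    ``S(i, j) = s_enc(4*i*w + j)``; consecutive rows share ``4(m-1)``
    entries, i.e. encode substrings overlapping by m-1 symbols.  Returns a
    strided view (no copy).
    """
    s_enc = np.ascontiguousarray(s_enc, dtype=np.float64)
    expected = 4 * (h * w + m - 1)
    if s_enc.shape != (expected,):
        raise ValueError(
            f"encoded length {s_enc.shape} does not match 4*(h*w+m-1) = {expected} "
            f"for h={h}, w={w}, m={m}"
        )
    width = 4 * (w + m - 1)
    return np.lib.stride_tricks.sliding_window_view(s_enc, width)[:: 4 * w][:h]


@dataclass(frozen=True)
class ScoreBlock:
    """h x c block of scores at chunk-local positions ``i*w + offset``."""

    values: np.ndarray
    offset: int


def score_block(S: np.ndarray, pattern: PatternMatrix, o: int) -> ScoreBlock:
    """``R^o = S[:, 4o:4(o+m)] @ P`` on a contiguous column slice of S."""
    w = S.shape[1] // 4 - (pattern.m - 1)
    if not 0 <= o < w:
        raise ValueError(f"offset {o} out of range [0, {w})")
    sub = S[:, 4 * o: 4 * (o + pattern.m)]
    if pattern.tiles:
        from .tiling import tiled_product
        return ScoreBlock(values=tiled_product(S, pattern, pattern.tiles, o), offset=o)
    return ScoreBlock(values=sub @ pattern.values, offset=o)


# ---------------------------------------------------------------------------
# Chunks and occurrences
# ---------------------------------------------------------------------------

class Occurrence(NamedTuple):
    """One motif match: leftmost forward-strand coordinate, 0-based."""

    record: str
    start: int
    motif: str
    strand: str
    score: float
    length: int

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length


@dataclass
class SequenceChunk:
    """A window of hw+m-1 concatenated symbols with its origin bookkeeping.

    ``codes``/``rec_index``/``rec_pos`` all have length ``h*w + m - 1``;
    sentinel separators and right-padding carry code 4 and record index -1.
    """

    chunk_index: int
    codes: np.ndarray
    rec_index: np.ndarray
    rec_pos: np.ndarray
    h: int
    w: int
    m: int
    record_ids: Sequence[str]
    non_acgt: str = "zero"
    _valid_cache: dict = field(default_factory=dict, repr=False)

    @property
    def dna(self) -> str:
        """Chunk symbols; sentinels and non-ACGT render as N."""
        return "".join("ACGTN"[c] for c in self.codes)

    def valid_for_length(self, m_j: int) -> np.ndarray:
        """Boolean mask over the hw scoring positions: True where a window
        of length m_j lies entirely inside one record (no sentinel, no
        padding; under the ``exclude`` policy, no non-ACGT symbol either)."""
        cached = self._valid_cache.get(m_j)
        if cached is not None:
            return cached
        hw = self.h * self.w
        first = self.rec_index[:hw]
        last = self.rec_index[m_j - 1: hw + m_j - 1]
        valid = (first == last) & (first >= 0)
        if self.non_acgt == "exclude":
            bad = np.concatenate(([0], np.cumsum(self.codes > 3)))
            valid &= (bad[m_j:hw + m_j] - bad[:hw]) == 0
        self._valid_cache[m_j] = valid
        return valid


def _column_thresholds(pattern: PatternMatrix, thresholds: Dict[str, float]) -> np.ndarray:
    out = np.empty(pattern.n_columns)
    for k, col in enumerate(pattern.columns):
        if col.motif not in thresholds:
            raise KeyError(f"no threshold defined for motif {col.motif!r}")
        out[k] = thresholds[col.motif]
    return out


def extract_occurrences(
    block: ScoreBlock,
    pattern: PatternMatrix,
    thresholds: Union[Dict[str, float], np.ndarray],
    chunk: SequenceChunk,
) -> List[Occurrence]:
    """Emit occurrences for every block entry at or above its threshold.

    Only windows that map entirely inside a single record (no sentinel,
    no padding) are reported; minus-strand hits use the leftmost
    forward-strand coordinate, i.e. the same ``start`` convention as
    plus-strand hits.
    """
    thr = (
        np.asarray(thresholds, dtype=float)
        if isinstance(thresholds, np.ndarray)
        else _column_thresholds(pattern, thresholds)
    )
    h = block.values.shape[0]
    positions = np.arange(h) * chunk.w + block.offset
    hits = block.values >= thr[None, :]
    # group columns by motif length so each validity mask is built once
    by_length: Dict[int, list] = {}
    for k, col in enumerate(pattern.columns):
        by_length.setdefault(col.length, []).append(k)
    for m_j, cols in by_length.items():
        hits[:, cols] &= chunk.valid_for_length(m_j)[positions, None]
    out = []
    for i, j in zip(*np.nonzero(hits)):
        pos = positions[i]
        col = pattern.columns[j]
        out.append(
            Occurrence(
                record=chunk.record_ids[chunk.rec_index[pos]],
                start=int(chunk.rec_pos[pos]),
                motif=col.motif,
                strand=col.strand,
                score=float(block.values[i, j]),
                length=col.length,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Streaming scan
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    """Resolved parameters of one scan run.

    ``h`` and ``w`` govern the chunk geometry (defaults 1000 x 250); they
    change performance only, never output.  Exactly one of ``pvalue`` /
    ``thresholds`` must be provided.
    """

    h: int = 1000
    w: int = 250
    pvalue: Optional[float] = None
    thresholds: Optional[Dict[str, float]] = None
    background: Optional[BackgroundModel] = None
    include_rc: bool = True
    non_acgt: str = "zero"
    workers: int = 1
    n_occ_buf: int = 1_000_000
    tiling: bool = True
    tile_min_area: int = 4096
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if self.h < 1 or self.w < 1:
            raise ValueError("chunk dimensions h and w must both be >= 1")
        if self.workers < 1:
            raise ValueError("worker count must be >= 1")
        if self.n_occ_buf < 1:
            raise ValueError("occurrence buffer capacity must be >= 1")
        if (self.pvalue is None) == (self.thresholds is None):
            raise ValueError("provide exactly one of pvalue or thresholds")
        if self.pvalue is not None and not 0 < self.pvalue <= 1:
            raise ValueError(f"p-value must lie in (0, 1], got {self.pvalue}")


@dataclass
class ScanResult:
    """Canonically ordered occurrences plus run summary."""

    occurrences: List[Occurrence]
    n: int  # total nucleotides scanned
    n_occ: int
    record_ids: List[str]
    record_lengths: List[int]
    thresholds: Dict[str, float]
    n_tiles: int = 1


def _concatenate_records(records: Sequence[Tuple[str, str]]):
    """Concatenate records with one sentinel symbol between neighbours.

    Returns (codes, rec_index, rec_pos) arrays over the concatenation; the
    sentinel carries code 4 and record index -1, so no window can silently
    bridge two records even before the validity mask is consulted.
    """
    codes_parts, idx_parts, pos_parts = [], [], []
    for r, (_rid, seq) in enumerate(records):
        if r > 0:
            codes_parts.append(np.array([SENTINEL_CODE], dtype=np.uint8))
            idx_parts.append(np.array([-1], dtype=np.int64))
            pos_parts.append(np.array([-1], dtype=np.int64))
        codes = dna_to_codes(seq)
        codes_parts.append(codes)
        idx_parts.append(np.full(len(codes), r, dtype=np.int64))
        pos_parts.append(np.arange(len(codes), dtype=np.int64))
    if not codes_parts:
        empty_i = np.zeros(0, dtype=np.int64)
        return np.zeros(0, dtype=np.uint8), empty_i, empty_i
    return (
        np.concatenate(codes_parts),
        np.concatenate(idx_parts),
        np.concatenate(pos_parts),
    )


def _canonical_sort(occurrences: List[Occurrence], record_order: Dict[str, int],
                    column_order: Dict[Tuple[str, str], int]) -> List[Occurrence]:
    return sorted(
        occurrences,
        key=lambda occ: (
            record_order[occ.record],
            occ.start,
            column_order[(occ.motif, occ.strand)],
        ),
    )


def scan_stream(
    records: Iterable[Tuple[str, str]],
    pwms: Sequence[PWM],
    config: Optional[ScanConfig] = None,
    **kwargs,
) -> ScanResult:
    """Scan all records for all motifs; the package's main entry point.

    Records are concatenated with sentinel separators and processed in
    chunks of ``h*w + m - 1`` symbols overlapping by ``m - 1``; for every
    offset the score block is one dense matrix product.  Chunks may be
    processed by several worker threads, but results are serialized in
    chunk order and finally sorted by (record order, start, pattern
    column), so the output is identical for any worker count and any
    chunk geometry.
    """
    config = config if config is not None else ScanConfig(**kwargs)
    pwms = list(pwms)
    if not pwms:
        raise ValueError("at least one motif is required")
    record_list = [(rid, seq) for rid, seq in records]
    record_ids = [rid for rid, _ in record_list]
    record_lengths = [len(seq) for _, seq in record_list]

    if config.thresholds is not None:
        thresholds = dict(config.thresholds)
    else:
        from .thresholds import thresholds_for_motifs
        thresholds = thresholds_for_motifs(
            pwms, config.background, config.pvalue, config.epsilon
        )

    pattern = build_pattern_matrix(pwms, include_rc=config.include_rc)
    n_tiles = 1
    if config.tiling:
        from .tiling import partition, sort_columns
        pattern, _perm = sort_columns(pattern)
        pattern.tiles = partition(pattern, config.tile_min_area)
        n_tiles = len(pattern.tiles)
    thr_arr = _column_thresholds(pattern, thresholds)

    max_record = max(record_lengths, default=0)
    for pwm in pwms:
        if pwm.length > max_record:
            warnings.warn(
                f"motif {pwm.name!r} (length {pwm.length}) is longer than every "
                "record and cannot match",
                stacklevel=2,
            )

    codes, rec_index, rec_pos = _concatenate_records(record_list)
    n = int(sum(record_lengths))
    m = pattern.m
    h, w = config.h, config.w
    hw = h * w
    chunk_len = hw + m - 1

    def process(chunk_index: int) -> List[Occurrence]:
        start = chunk_index * hw
        stop = min(start + chunk_len, len(codes))
        pad = chunk_len - (stop - start)
        c_codes = np.concatenate([codes[start:stop], np.full(pad, SENTINEL_CODE, np.uint8)])
        c_idx = np.concatenate([rec_index[start:stop], np.full(pad, -1, np.int64)])
        c_pos = np.concatenate([rec_pos[start:stop], np.full(pad, -1, np.int64)])
        chunk = SequenceChunk(
            chunk_index=chunk_index, codes=c_codes, rec_index=c_idx, rec_pos=c_pos,
            h=h, w=w, m=m, record_ids=record_ids, non_acgt=config.non_acgt,
        )
        S = build_sequence_matrix(_ONEHOT[c_codes].ravel(), h, w, m)
        found: List[Occurrence] = []
        for o in range(w):
            block = score_block(S, pattern, o)
            found.extend(extract_occurrences(block, pattern, thr_arr, chunk))
        return found

    n_chunks = max(0, -(-len(codes) // hw))
    if config.workers > 1 and n_chunks > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            batches = list(pool.map(process, range(n_chunks)))
    else:
        batches = [process(ci) for ci in range(n_chunks)]

    occurrences = [occ for batch in batches for occ in batch]
    record_order = {rid: r for r, rid in enumerate(record_ids)}
    column_order = {(c.motif, c.strand): c.index for c in pattern.columns}
    occurrences = _canonical_sort(occurrences, record_order, column_order)
    return ScanResult(
        occurrences=occurrences,
        n=n,
        n_occ=len(occurrences),
        record_ids=record_ids,
        record_lengths=record_lengths,
        thresholds=thresholds,
        n_tiles=n_tiles,
    )


# ---------------------------------------------------------------------------
# Naive reference scanner
# ---------------------------------------------------------------------------

def naive_scan(
    records: Iterable[Tuple[str, str]],
    pwms: Sequence[PWM],
    thresholds: Dict[str, float],
    include_rc: bool = True,
    non_acgt: str = "zero",
) -> List[Occurrence]:
    """Brute-force reference scan: every record x motif x position.

    Scores are accumulated position by position (left to right), exactly
    like :func:`pwmgemm.motifs.score_window`; this is the reference
    semantics every matrix-product path is tested against.  Output uses
    the same canonical ordering as :func:`scan_stream`.
    """
    record_list = [(rid, seq) for rid, seq in records]
    stranded = [(pwm, pwm.strand) for pwm in pwms]
    if include_rc:
        stranded += [(reverse_complement(pwm), "-") for pwm in pwms]
    out: List[Occurrence] = []
    for rid, seq in record_list:
        codes = dna_to_codes(seq)
        for pwm, strand in stranded:
            m_j = pwm.length
            n_pos = len(codes) - m_j + 1
            if n_pos <= 0:
                continue
            if pwm.name not in thresholds:
                raise KeyError(f"no threshold defined for motif {pwm.name!r}")
            thr = thresholds[pwm.name]
            weights5 = np.vstack([pwm.weights, np.zeros((1, m_j))])
            scores = np.zeros(n_pos)
            for j in range(m_j):
                scores += weights5[codes[j:j + n_pos], j]
            if non_acgt == "exclude":
                bad = np.concatenate(([0], np.cumsum(codes > 3)))
                scores[(bad[m_j:] - bad[:n_pos]) > 0] = -np.inf
            for pos in np.nonzero(scores >= thr)[0]:
                out.append(
                    Occurrence(
                        record=rid, start=int(pos), motif=pwm.name, strand=strand,
                        score=float(scores[pos]), length=m_j,
                    )
                )
    record_order = {rid: r for r, rid in enumerate(rid for rid, _ in record_list)}
    column_order = {
        (pwm.name, strand): k for k, (pwm, strand) in enumerate(stranded)
    }
    return _canonical_sort(out, record_order, column_order)
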