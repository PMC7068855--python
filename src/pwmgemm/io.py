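"""Readers and writers: FASTA, thresholds, manifests, occurrence files.

Coordinates are 0-based half-open internally; the writers convert per
format (GFF3 is 1-based inclusive, BED6 keeps 0-based half-open).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple, Union

from Bio import SeqIO

from .engine import Occurrence

PathLike = Union[str, Path]

OUTPUT_FORMATS = ("gff3", "bed", "tsv")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> Iterator[Tuple[str, str]]:
    """Lazily yield (id, sequence) from a FASTA file (gzip transparent).

    The record id is the first whitespace-delimited header token; wrapped
    sequence lines are concatenated and CRLF endings are normalized.
    """
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.lstrip().startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected a '>' header, got {line.strip()!r}"
                    )
                break
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            yield record.id, str(record.seq)


def write_fasta(records: Iterable[Tuple[str, str]], path: PathLike, width: int = 60) -> None:
    """Write records as FASTA at a fixed wrap width (round-trip stable)."""
    from .fixtures import fasta_text
    with _open_text(path, "wt") as handle:
        handle.write(fasta_text(list(records), width=width))


# ---------------------------------------------------------------------------
# Manifests and thresholds
# ---------------------------------------------------------------------------

def write_manifest(records: Iterable[Tuple[str, int]], out) -> None:
    """Two-column TSV of (record id, length) plus a total line."""
    close, handle = _as_handle(out, "wt")
    try:
        handle.write("record\tlength\n")
        total = 0
        for rid, length in records:
            handle.write(f"{rid}\t{length}\n")
            total += length
        handle.write(f"#total\t{total}\n")
    finally:
        if close:
            handle.close()


def write_thresholds(thresholds: Dict[str, float], out) -> None:
    """Two-column TSV of (motif id, threshold in bits)."""
    close, handle = _as_handle(out, "wt")
    try:
        handle.write("motif\tthreshold\n")
        for name, value in thresholds.items():
            handle.write(f"{name}\t{value:.6f}\n")
    finally:
        if close:
            handle.close()


def read_thresholds(path: PathLike) -> Dict[str, float]:
    """Parse a thresholds TSV written by :func:`write_thresholds`."""
    thresholds: Dict[str, float] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line == "motif\tthreshold":
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            thresholds[parts[0]] = float(parts[1])
    return thresholds


# ---------------------------------------------------------------------------
# Occurrence writers
# ---------------------------------------------------------------------------

def _as_handle(out, mode: str):
    if hasattr(out, "write"):
        return False, out
    return True, _open_text(out, mode)


def write_occurrences(occurrences: Sequence[Occurrence], out, fmt: str = "gff3") -> None:
    """Write occurrences in GFF3 (1-based inclusive), BED6+score or TSV.

    The stream is expected in the scanner's canonical order (record order,
    start, pattern column); it is written unchanged, so identical scans
    produce byte-identical files.  BED clamps the integer score column to
    [0, 1000] and carries the true score in a 7th column.
    """
    if fmt not in OUTPUT_FORMATS:
        raise ValueError(f"unknown output format {fmt!r}; choose from {OUTPUT_FORMATS}")
    close, handle = _as_handle(out, "wt")
    try:
        if fmt == "gff3":
            handle.write("##gff-version 3\n")
            for occ in occurrences:
                handle.write(
                    f"{occ.record}\tpwmgemm\tTF_binding_site\t{occ.start + 1}\t{occ.end}\t"
                    f"{occ.score:.4f}\t{occ.strand}\t.\tName={occ.motif}\n"
                )
        elif fmt == "bed":
            for occ in occurrences:
                bed_score = int(min(1000, max(0, round(occ.score))))
                handle.write(
                    f"{occ.record}\t{occ.start}\t{occ.end}\t{occ.motif}\t"
                    f"{bed_score}\t{occ.strand}\t{occ.score:.4f}\n"
                )
        else:
            handle.write("record\tstart\tend\tmotif\tstrand\tscore\n")
            for occ in occurrences:
                handle.write(
                    f"{occ.record}\t{occ.start}\t{occ.end}\t{occ.motif}\t"
                    f"{occ.strand}\t{occ.score!r}\n"
                )
    finally:
        if close:
            handle.close()


def read_occurrences_tsv(path: PathLike) -> List[Occurrence]:
    """Parse the TSV dialect back into occurrences (round-trip helper)."""
    out: List[Occurrence] = []
    with _open_text(path) as handle:
        header = handle.readline()
        if header.strip() != "record\tstart\tend\tmotif\tstrand\tscore":
            raise ValueError(f"{path}: not a pwmgemm occurrence TSV")
        for line in handle:
            rec, start, end, motif, strand, score = line.rstrip("\n").split("\t")
            out.append(
                Occurrence(
                    record=rec, start=int(start), motif=motif, strand=strand,
                    score=float(score), length=int(end) - int(start),
                )
            )
    return out
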