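"""Quality control of short sequencing reads.

The pipeline applies three filters, in order, to each read:

1. *Quality trimming* — bases with a Phred quality below a threshold
   (default 20) are removed by keeping the longest contiguous run of
   bases at or above the threshold (leftmost run on ties).
2. *Length filter* — trimmed reads shorter than a minimum length
   (default 5 bp) are discarded.
3. *Ambiguity filter* — reads containing any ambiguous base call
   (``N``, ``n`` or ``.``) are discarded.

In paired-end mode a fragment is retained only if both mates pass all
three filters (orphan retention is available via ``require_both=False``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from .utils import percent

DEFAULT_QUALITY_THRESHOLD = 20
DEFAULT_MIN_LENGTH = 5
AMBIGUOUS_BASES = frozenset("Nn.")

_MAX_PHRED = 93


@dataclass(frozen=True)
class SequencedRead:
    """A single read: identifier, base calls and per-base Phred scores."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 or q > _MAX_PHRED for q in self.quals):
            raise ValueError(f"read {self.id!r}: Phred scores must be in [0, {_MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QCSummary:
    """Per-library retention summary (read counts, not pair counts)."""

    library_name: str
    raw_reads: int
    retained_reads: int

    def __post_init__(self) -> None:
        if not 0 <= self.retained_reads <= self.raw_reads:
            raise ValueError("retained_reads must be in [0, raw_reads]")

    @property
    def retention_pct(self) -> float:
        return percent(self.retained_reads, self.raw_reads, ndigits=1)


def trim_low_quality(
    read: SequencedRead, threshold: int = DEFAULT_QUALITY_THRESHOLD
) -> SequencedRead:
    """Trim a read to its longest run of bases with quality >= threshold.

    Ties are broken in favour of the leftmost run; a read with no base at
    or above the threshold becomes empty.
    """
    best_start = best_len = 0
    run_start = run_len = 0
    for i, q in enumerate(read.quals):
        if q >= threshold:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    stop = best_start + best_len
    return SequencedRead(read.id, read.bases[best_start:stop], read.quals[best_start:stop])


def filter_read(
    read: SequencedRead,
    min_len: int = DEFAULT_MIN_LENGTH,
    ambiguous: frozenset[str] = AMBIGUOUS_BASES,
) -> bool:
    """Keep/drop decision for an (already trimmed) read.

    Dropped iff shorter than `min_len` or containing any ambiguous base.
    Returns True when the read is kept.
    """
    if len(read) < min_len:
        return False
    return not any(b in ambiguous for b in read.bases)


def qc_read(
    read: SequencedRead,
    threshold: int = DEFAULT_QUALITY_THRESHOLD,
    min_len: int = DEFAULT_MIN_LENGTH,
    ambiguous: frozenset[str] = AMBIGUOUS_BASES,
) -> SequencedRead | None:
    """Trim then filter a single read; None if the read is discarded."""
    trimmed = trim_low_quality(read, threshold)
    return trimmed if filter_read(trimmed, min_len, ambiguous) else None


# ---------------------------------------------------------------------------
# FASTQ I/O


def detect_phred_offset(path: str | Path, max_records: int = 1000) -> int:
    """Guess the Phred encoding offset (33 or 64) from quality characters.

    Any quality character below chr(59) proves Phred+33; a file whose
    minimum quality character is at or above chr(64) is taken as Phred+64.
    Ambiguous files default to 33 (the modern encoding).
    """
    lo = 0x7F
    with open(path) as fh:
        for i, (_, _, qual) in enumerate(_iter_fastq_lines(fh)):
            if qual:
                lo = min(lo, min(map(ord, qual)))
            if lo < 59 or i + 1 >= max_records:
                break
    if lo < 59:
        return 33
    if lo >= 64:
        return 64
    return 33


def _iter_fastq_lines(handle: TextIO) -> Iterator[tuple[str, str, str]]:
    """Yield (id, bases, qual-string) triplets from 4-line FASTQ records."""
    for index in itertools.count():
        header = handle.readline()
        if not header:
            return
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        if not header.startswith("@") or not plus.startswith("+") or not qual:
            raise ValueError(f"malformed FASTQ record at index {index}")
        seq, qual = seq.strip(), qual.strip()
        if len(seq) != len(qual):
            raise ValueError(
                f"malformed FASTQ record at index {index}: "
                f"sequence and quality lengths differ"
            )
        yield header[1:].strip().split()[0], seq, qual


def read_fastq(path: str | Path, offset: int | str = "auto") -> Iterator[SequencedRead]:
    """Iterate over a FASTQ file as :class:`SequencedRead` objects."""
    if offset == "auto":
        offset = detect_phred_offset(path)
    if offset not in (33, 64):
        raise ValueError("offset must be 33, 64 or 'auto'")
    with open(path) as fh:
        for rid, bases, qual in _iter_fastq_lines(fh):
            yield SequencedRead(rid, bases, tuple(ord(c) - offset for c in qual))


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.bases}\n+\n")
            fh.write("".join(chr(q + 33) for q in read.quals) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Orchestration


def qc_reads(
    reads: Iterable[SequencedRead],
    threshold: int = DEFAULT_QUALITY_THRESHOLD,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[SequencedRead], int]:
    """Apply trim+filter to every read; (retained reads, raw count)."""
    raw = 0
    kept: list[SequencedRead] = []
    for read in reads:
        raw += 1
        out = qc_read(read, threshold, min_len)
        if out is not None:
            kept.append(out)
    return kept, raw


def qc_read_pairs(
    pairs: Iterable[tuple[SequencedRead, SequencedRead]],
    threshold: int = DEFAULT_QUALITY_THRESHOLD,
    min_len: int = DEFAULT_MIN_LENGTH,
    require_both: bool = True,
) -> tuple[list[tuple[SequencedRead | None, SequencedRead | None]], int]:
    """QC mate pairs; (list of surviving (mate1, mate2) pairs, raw read count).

    With ``require_both`` (default) a fragment survives only if both mates
    pass, mirroring downstream paired-end assembly requirements. With
    ``require_both=False`` passing mates are retained as orphans (the
    failing mate is None).
    """
    raw = 0
    kept: list[tuple[SequencedRead | None, SequencedRead | None]] = []
    for r1, r2 in pairs:
        raw += 2
        o1 = qc_read(r1, threshold, min_len)
        o2 = qc_read(r2, threshold, min_len)
        if require_both:
            if o1 is not None and o2 is not None:
                kept.append((o1, o2))
        elif o1 is not None or o2 is not None:
            kept.append((o1, o2))
    return kept, raw


@dataclass
class QCResult:
    summary: QCSummary
    retained: list[SequencedRead] = field(repr=False)


def run_qc(
    fastq_in: str | Path,
    fastq_in2: str | Path | None = None,
    out: str | Path | None = None,
    out2: str | Path | None = None,
    threshold: int = DEFAULT_QUALITY_THRESHOLD,
    min_len: int = DEFAULT_MIN_LENGTH,
    offset: int | str = "auto",
    require_both: bool = True,
    library_name: str | None = None,
) -> QCResult:
    """Run the full QC pipeline on one FASTQ file or a mate pair of files.

    Counts in the returned summary are per-read even in paired mode.
    Retained reads are written (Phred+33) to `out`/`out2` when given;
    in paired mode mate order is preserved between the two outputs.
    """
    name = library_name or Path(fastq_in).name
    if fastq_in2 is None:
        kept, raw = qc_reads(read_fastq(fastq_in, offset), threshold, min_len)
        if out is not None:
            write_fastq(kept, out)
        return QCResult(QCSummary(name, raw, len(kept)), kept)

    _SENTINEL = object()
    pair_iter = itertools.zip_longest(
        read_fastq(fastq_in, offset), read_fastq(fastq_in2, offset), fillvalue=_SENTINEL
    )

    def checked_pairs() -> Iterator[tuple[SequencedRead, SequencedRead]]:
        for r1, r2 in pair_iter:
            if r1 is _SENTINEL or r2 is _SENTINEL:
                raise ValueError("mate FASTQ files have unequal record counts")
            yield r1, r2  # type: ignore[misc]

    kept_pairs, raw = qc_read_pairs(checked_pairs(), threshold, min_len, require_both)
    retained = [r for pair in kept_pairs for r in pair if r is not None]
    if out is not None:
        write_fastq((p[0] for p in kept_pairs if p[0] is not None), out)
    if out2 is not None:
        write_fastq((p[1] for p in kept_pairs if p[1] is not None), out2)
    return QCResult(QCSummary(name, raw, len(retained)), retained)


def summary_tsv(summaries: Sequence[QCSummary]) -> str:
    """Render QC summaries as a TSV table (library, raw, retained, pct)."""
    lines = ["library\traw_reads\tretained_reads\tretention_pct"]
    for s in summaries:
        lines.append(f"{s.library_name}\t{s.raw_reads}\t{s.retained_reads}\t{s.retention_pct}")
    return "\n".join(lines) + "\n"
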