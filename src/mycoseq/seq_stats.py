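"""Assembly and sequence-set summary statistics (N50, totals, coverage)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .utils import round_half_away


@dataclass(frozen=True)
class AssemblyStats:
    """Summary of a set of assembled sequences (scaffolds or contigs)."""

    n_seqs: int
    total_bp: int
    n50: int
    mean_len: int
    max_len: int
    min_len: int

    def to_tsv(self) -> str:
        lines = [
            f"n_seqs\t{self.n_seqs}",
            f"total_bp\t{self.total_bp}",
            f"n50\t{self.n50}",
            f"mean_len\t{self.mean_len}",
            f"max_len\t{self.max_len}",
            f"min_len\t{self.min_len}",
        ]
        return "\n".join(lines) + "\n"


def n50(lengths: Sequence[int]) -> int:
    """N50 of a set of sequence lengths.

    The smallest length L such that sequences of length >= L together
    cover at least half the total assembly. Uses the inclusive (">= half")
    convention, the dominant one among assembly tools.
    """
    if not lengths:
        raise ValueError("n50 requires at least one sequence length")
    if any(x <= 0 for x in lengths):
        raise ValueError("sequence lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def mean_length(total_bp: int, n_seqs: int) -> int:
    """Mean sequence length, rounded to the nearest integer."""
    if n_seqs <= 0:
        raise ValueError("n_seqs must be positive")
    return round_half_away(total_bp / n_seqs)


def stats_from_lengths(lengths: Sequence[int]) -> AssemblyStats:
    if not lengths:
        raise ValueError("no sequences")
    total = sum(lengths)
    return AssemblyStats(
        n_seqs=len(lengths),
        total_bp=total,
        n50=n50(lengths),
        mean_len=mean_length(total, len(lengths)),
        max_len=max(lengths),
        min_len=min(lengths),
    )


def assembly_stats(fasta: str | Path) -> AssemblyStats:
    """Compute assembly summary statistics over all records of a FASTA file."""
    lengths = [len(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")]
    if not lengths:
        raise ValueError(f"empty FASTA: {fasta}")
    return stats_from_lengths(lengths)


def depth_estimate(total_bases: float, genome_size: float) -> int:
    """Mean fold coverage: total sequenced bases over genome size, rounded."""
    if total_bases <= 0 or genome_size <= 0:
        raise ValueError("total_bases and genome_size must be positive")
    return round_half_away(total_bases / genome_size)
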