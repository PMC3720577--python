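"""Synthetic fixtures with known ground truth.

Three generators stand in for real sequencing data so every pipeline
stage can be verified against a planted truth:

* ``simulate_genomes`` — order-1 Markov-chain genomes whose transition
  matrices carry group-specific compositional bias, giving each group a
  distinct tetranucleotide signature.
* ``simulate_transcriptomes`` — two unigene sets (two tissues) sharing a
  controllable fraction of near-identical genes, plus noiseless 100 bp
  reads drawn per gene at planted expression levels, written as
  perfect-match SAM alignments; optional exact-copy homolog families
  generate multi-mapped reads.
* ``simulate_fastq`` — reads with controllable quality profiles, planted
  low-quality runs and ambiguous sites, with a sidecar truth table
  replaying the QC filter rules.

All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import Unigene
from .read_qc import SequencedRead, qc_read, write_fastq

BASES = "ACGT"
_UNIFORM = np.full((4, 4), 0.25)


# ---------------------------------------------------------------------------
# Markov genomes


@dataclass(frozen=True)
class MarkovGenomeSpec:
    """Recipe for one order-1 Markov genome."""

    group_label: str
    transition_matrix: np.ndarray  # 4x4, rows sum to 1 (A,C,G,T order)
    length: int
    seed: int
    initial_probs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    genome_id: str | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        p0 = np.asarray(self.initial_probs, dtype=float)
        if T.shape != (4, 4) or (T < 0).any() or np.abs(T.sum(axis=1) - 1).max() > 1e-12:
            raise ValueError("transition_matrix must be 4x4 row-stochastic")
        if p0.shape != (4,) or (p0 < 0).any() or abs(p0.sum() - 1) > 1e-12:
            raise ValueError("initial_probs must be a length-4 probability vector")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        object.__setattr__(self, "transition_matrix", T)
        object.__setattr__(self, "initial_probs", p0)


def _markov_sequence(spec: MarkovGenomeSpec) -> str:
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.length)
    cum = np.cumsum(spec.transition_matrix, axis=1)
    cum0 = np.cumsum(spec.initial_probs)
    out = np.empty(spec.length, dtype=np.int64)
    state = int(np.searchsorted(cum0, u[0], side="right"))
    state = min(state, 3)
    out[0] = state
    for i in range(1, spec.length):
        row = cum[state]
        x = u[i]
        state = int(x > row[0]) + int(x > row[1]) + int(x > row[2])
        out[i] = state
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[out].tobytes().decode("ascii")


def simulate_genomes(specs: Sequence[MarkovGenomeSpec]) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Generate (genome_id, sequence) records plus an id -> group map."""
    records: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    for i, spec in enumerate(specs):
        gid = spec.genome_id or f"{spec.group_label}_g{i}"
        if gid in labels:
            raise ValueError(f"duplicate genome id {gid!r}")
        records.append((gid, _markov_sequence(spec)))
        labels[gid] = spec.group_label
    return records, labels


def grouped_genome_specs(
    n_groups: int = 3,
    genomes_per_group: int = 4,
    length: int = 100_000,
    seed: int = 0,
    concentration: float = 2.0,
) -> list[MarkovGenomeSpec]:
    """Specs for a planted-group study: one transition matrix per group.

    Each group draws a 4x4 row-stochastic matrix with Dirichlet(
    `concentration`) rows; genomes within a group share the matrix and
    differ only in their sampling seed, so their tetranucleotide
    signatures converge to the same group-specific profile.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for g in range(n_groups):
        T = rng.dirichlet(np.full(4, concentration), size=4)
        for j in range(genomes_per_group):
            specs.append(
                MarkovGenomeSpec(
                    group_label=f"group{g}",
                    transition_matrix=T,
                    length=length,
                    seed=int(rng.integers(2**31)),
                    genome_id=f"group{g}_g{j}",
                )
            )
    return specs


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transcriptomes


@dataclass
class TranscriptomeSimulation:
    """Everything a cross-assembly expression analysis consumes, plus truth.

    ``truth`` has one row per ancestral gene with its per-tissue unigene
    ids, lengths, planted read counts, expected mapped counts (equal to
    planted counts except within homolog families, whose members collect
    each other's reads), expected RPKM, fold-change ratio and class.
    """

    unigenes_fruiting: list[Unigene]
    unigenes_mycelia: list[Unigene]
    reads_fruiting: list[SequencedRead]
    reads_mycelia: list[SequencedRead]
    sam_fruiting: str
    sam_mycelia: str
    truth: pd.DataFrame
    library_size_fruiting: int
    library_size_mycelia: int

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write FASTA/FASTQ/SAM/TSV files; returns the path of each."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "unigenes_fruiting": d / "unigenes_fruiting.fasta",
            "unigenes_mycelia": d / "unigenes_mycelia.fasta",
            "reads_fruiting": d / "reads_fruiting.fastq",
            "reads_mycelia": d / "reads_mycelia.fastq",
            "sam_fruiting": d / "fruiting.sam",
            "sam_mycelia": d / "mycelia.sam",
            "truth": d / "truth.tsv",
        }
        write_fasta([(u.id, u.sequence) for u in self.unigenes_fruiting], paths["unigenes_fruiting"])
        write_fasta([(u.id, u.sequence) for u in self.unigenes_mycelia], paths["unigenes_mycelia"])
        write_fastq(self.reads_fruiting, paths["reads_fruiting"])
        write_fastq(self.reads_mycelia, paths["reads_mycelia"])
        paths["sam_fruiting"].write_text(self.sam_fruiting)
        paths["sam_mycelia"].write_text(self.sam_mycelia)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_dna(rng: np.random.Generator, length: int) -> str:
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    codes = {ord(b): i for i, b in enumerate(BASES)}
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    for i in hit:
        # substitute with one of the three other bases
        arr[i] = lut[(codes[arr[i]] + rng.integers(1, 4)) % 4]
    return arr.tobytes().decode("ascii")


def _sam_header(unigenes: Sequence[Unigene]) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{u.id}\tLN:{len(u)}" for u in unigenes]
    return lines


def _classify_ratio(ratio: float, fold: float = 2.0) -> str:
    if np.isnan(ratio):
        return "unclassified"
    if ratio > fold:
        return "up"
    if ratio < 1.0 / fold:
        return "down"
    return "equal"


def simulate_transcriptomes(
    n_genes: int = 200,
    shared_fraction: float = 0.8,
    mutation_rate: float = 0.02,
    expression_mu: float = 3.0,
    expression_sigma: float = 1.0,
    read_len: int = 100,
    gene_len_range: tuple[int, int] = (300, 1500),
    homolog_families: Sequence[int] = (),
    seed: int = 0,
) -> TranscriptomeSimulation:
    """Simulate two tissue transcriptomes with planted ground truth.

    `n_genes` ancestral genes are drawn with lengths uniform in
    `gene_len_range`; a `shared_fraction` of them appear in both unigene
    sets (the mycelium copy carrying point substitutions at
    `mutation_rate`), the rest alternate between tissue-specific sets.
    Expression levels are log-normal(mu, sigma) per tissue; the planted
    read count of a gene is max(1, round(level)). Reads are noiseless
    `read_len` bp substrings at uniform random positions and appear in
    the SAM output as perfect-match alignments at their true positions.

    ``homolog_families`` plants exact-copy gene families in the fruiting
    set (one extra gene of the given size per entry); every read from a
    family member additionally aligns to all other members, producing
    multi-mapped reads.
    """
    if not 0 <= shared_fraction <= 1 or not 0 <= mutation_rate <= 1:
        raise ValueError("shared_fraction and mutation_rate must be in [0, 1]")
    if read_len > gene_len_range[0]:
        raise ValueError("read_len must not exceed the shortest gene length")
    rng = np.random.default_rng(seed)

    n_shared = int(round(shared_fraction * n_genes))
    rows: list[dict] = []
    fruiting: list[Unigene] = []
    mycelia: list[Unigene] = []
    family_of: dict[str, str] = {}  # fruiting unigene id -> family id
    members_of: dict[str, list[str]] = {}

    for g in range(n_genes):
        L = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        seq = _random_dna(rng, L)
        shared = g < n_shared
        in_f = shared or (g - n_shared) % 2 == 0
        in_m = shared or not in_f
        fid = f"FB_{g:05d}" if in_f else ""
        mid = f"MY_{g:05d}" if in_m else ""
        if in_f:
            fruiting.append(Unigene(fid, seq))
        if in_m:
            mseq = _mutate(rng, seq, mutation_rate) if shared else seq
            mycelia.append(Unigene(mid, mseq))
        rows.append(
            {"gene": f"gene_{g:05d}", "fruiting_id": fid, "mycelia_id": mid,
             "shared": shared, "family": ""}
        )

    for fam_idx, size in enumerate(homolog_families):
        if size < 2:
            raise ValueError("homolog family size must be >= 2")
        L = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        seq = _random_dna(rng, L)
        fam = f"fam{fam_idx}"
        ids = []
        for m in range(size):
            fid = f"FB_{fam}_{m}"
            fruiting.append(Unigene(fid, seq))
            family_of[fid] = fam
            ids.append(fid)
            rows.append(
                {"gene": f"{fam}_m{m}", "fruiting_id": fid, "mycelia_id": "",
                 "shared": False, "family": fam}
            )
        members_of[fam] = ids

    truth = pd.DataFrame(rows)
    f_len = {u.id: len(u) for u in fruiting}
    m_len = {u.id: len(u) for u in mycelia}
    truth["length_fruiting"] = truth.fruiting_id.map(f_len).astype("Int64")
    truth["length_mycelia"] = truth.mycelia_id.map(m_len).astype("Int64")

    def planted_counts(ids: list[str]) -> dict[str, int]:
        levels = rng.lognormal(expression_mu, expression_sigma, size=len(ids))
        return {uid: max(1, int(round(lv))) for uid, lv in zip(ids, levels)}

    counts_f = planted_counts([u.id for u in fruiting])
    counts_m = planted_counts([u.id for u in mycelia])

    def make_reads_and_sam(
        unigenes: list[Unigene], counts: dict[str, int], tag: str, multimap: bool
    ) -> tuple[list[SequencedRead], str]:
        seqs = {u.id: u.sequence for u in unigenes}
        reads: list[SequencedRead] = []
        lines = _sam_header(unigenes)
        for u in unigenes:
            c = counts[u.id]
            starts = rng.integers(0, len(u) - read_len + 1, size=c)
            for i, start in enumerate(starts):
                rid = f"{tag}_{u.id}_{i}"
                rseq = u.sequence[start : start + read_len]
                reads.append(SequencedRead(rid, rseq, (40,) * read_len))
                qual = "I" * read_len
                lines.append(
                    f"{rid}\t0\t{u.id}\t{start + 1}\t60\t{read_len}M\t*\t0\t0"
                    f"\t{rseq}\t{qual}\tNM:i:0"
                )
                if multimap and u.id in family_of:
                    for other in members_of[family_of[u.id]]:
                        if other == u.id:
                            continue
                        assert seqs[other][start : start + read_len] == rseq
                        lines.append(
                            f"{rid}\t256\t{other}\t{start + 1}\t0\t{read_len}M\t*\t0\t0"
                            f"\t{rseq}\t{qual}\tNM:i:0"
                        )
        return reads, "\n".join(lines) + "\n"

    reads_f, sam_f = make_reads_and_sam(fruiting, counts_f, "f", multimap=True)
    reads_m, sam_m = make_reads_and_sam(mycelia, counts_m, "m", multimap=False)
    N_f, N_m = len(reads_f), len(reads_m)

    # Expected mapped count: planted reads, plus within a homolog family
    # the reads of every other (exact-copy) member.
    def mapped_count(uid: str, counts: dict[str, int]) -> int:
        if not uid or uid not in counts:
            return 0
        if uid in family_of:
            return sum(counts[m] for m in members_of[family_of[uid]])
        return counts[uid]

    truth["count_fruiting"] = truth.fruiting_id.map(lambda u: mapped_count(u, counts_f)).astype(
        "Int64"
    )
    truth["count_mycelia"] = truth.mycelia_id.map(lambda u: mapped_count(u, counts_m)).astype(
        "Int64"
    )
    truth["rpkm_fruiting"] = [
        1e9 * c / (L * N_f) if fid else np.nan
        for fid, c, L in zip(truth.fruiting_id, truth.count_fruiting, truth.length_fruiting)
    ]
    truth["rpkm_mycelia"] = [
        1e9 * c / (L * N_m) if mid else np.nan
        for mid, c, L in zip(truth.mycelia_id, truth.count_mycelia, truth.length_mycelia)
    ]
    ratio = np.where(
        truth.fruiting_id.ne("") & truth.mycelia_id.ne(""),
        truth.rpkm_fruiting / truth.rpkm_mycelia,
        np.nan,
    )
    truth["ratio"] = ratio
    truth["true_class"] = [
        _classify_ratio(x) if s else "" for x, s in zip(ratio, truth.shared)
    ]

    return TranscriptomeSimulation(
        unigenes_fruiting=fruiting,
        unigenes_mycelia=mycelia,
        reads_fruiting=reads_f,
        reads_mycelia=reads_m,
        sam_fruiting=sam_f,
        sam_mycelia=sam_m,
        truth=truth,
        library_size_fruiting=N_f,
        library_size_mycelia=N_m,
    )


# ---------------------------------------------------------------------------
# FASTQ with planted QC failures


@dataclass
class FastqSimulation:
    reads: list[SequencedRead]
    truth: pd.DataFrame  # read_id, kept, trimmed_bases

    def write(self, fastq_path: str | Path, truth_path: str | Path | None = None) -> None:
        write_fastq(self.reads, fastq_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def simulate_fastq(
    n_reads: int = 1000,
    read_len: int = 100,
    quality_profile: Sequence[float] | float = 35.0,
    quality_sd: float = 3.0,
    low_quality_run_rate: float = 0.3,
    ambiguous_rate: float = 0.01,
    quality_threshold: int = 20,
    min_len: int = 5,
    seed: int = 0,
) -> FastqSimulation:
    """Reads with planted low-quality runs and ambiguous sites, plus truth.

    Per-base qualities are normal around `quality_profile` (a scalar or a
    per-position vector of Phred means), clipped to [2, 40]. With
    probability `low_quality_run_rate` a read receives one contiguous run
    of sub-threshold qualities at a random position; each base is
    independently replaced by an ambiguous character ('.' or 'N') with
    probability `ambiguous_rate`. The sidecar truth table replays the QC
    rules (longest high-quality run, minimum length, no ambiguity) on
    each read.
    """
    if not 0 <= ambiguous_rate <= 1 or not 0 <= low_quality_run_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    means = np.broadcast_to(np.asarray(quality_profile, dtype=float), (read_len,))
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)

    reads: list[SequencedRead] = []
    rows = []
    for i in range(n_reads):
        bases = lut[rng.integers(0, 4, size=read_len)].tobytes().decode("ascii")
        quals = np.clip(rng.normal(means, quality_sd), 2, 40).astype(int)
        lowq_start, lowq_len = -1, 0
        if rng.random() < low_quality_run_rate:
            lowq_len = int(rng.integers(1, read_len + 1))
            lowq_start = int(rng.integers(0, read_len - lowq_len + 1))
            quals[lowq_start : lowq_start + lowq_len] = rng.integers(
                2, quality_threshold, size=lowq_len
            )
        amb = rng.random(read_len) < ambiguous_rate
        if amb.any():
            chars = list(bases)
            for j in np.flatnonzero(amb):
                chars[j] = "." if rng.random() < 0.5 else "N"
            bases = "".join(chars)
        read = SequencedRead(f"read_{i:06d}", bases, tuple(int(q) for q in quals))
        reads.append(read)
        kept = qc_read(read, quality_threshold, min_len)
        rows.append(
            {
                "read_id": read.id,
                "planted_lowq_start": lowq_start,
                "planted_lowq_len": lowq_len,
                "planted_ambiguous": int(amb.sum()),
                "kept": kept is not None,
                "trimmed_bases": kept.bases if kept is not None else "",
            }
        )
    return FastqSimulation(reads=reads, truth=pd.DataFrame(rows))
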