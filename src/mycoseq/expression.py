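"""Cross-assembly expression comparison between two unigene sets.

Two de novo transcriptome assemblies (e.g. fruiting body vs mycelium of a
fungus) have no shared gene identifiers, so comparison proceeds by:

1. pairing unigenes across assemblies by reciprocal best local-alignment
   hit at identity >= 90% and coverage >= 50%;
2. counting perfect-match read alignments longer than 50 bp per unigene
   (multi-mapped reads contribute one count to every unigene they hit);
3. converting counts to RPKM (reads per kilobase per million mapped
   reads, 1e9 * C / (L * N));
4. classifying each pair by RPKM fold change: ratio > 2 up-regulated,
   < 0.5 down-regulated, otherwise equally expressed;
5. diagnosing unreliable counts via the unique/multi-mapped read
   partition and a homolog search (identity >= 90%, coverage >= 80%).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import Align, SeqIO

PAIR_MIN_IDENTITY = 90.0
PAIR_MIN_COVERAGE = 50.0
HOMOLOG_MIN_COVERAGE = 80.0
MIN_ALIGNED_LEN = 50
FOLD_CHANGE = 2.0


@dataclass(frozen=True)
class Unigene:
    """One assembled transcript contig."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"unigene {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    identity: float  # percent of aligned columns that match
    aln_len: int  # aligned columns (matches + mismatches + gaps)
    coverage: float  # percent of the shorter sequence covered
    score: float


@dataclass(frozen=True)
class UnigenePair:
    """Reciprocal-best-hit pair of unigenes across two assemblies."""

    id_a: str
    id_b: str
    identity: float
    coverage: float
    score: float


@dataclass(frozen=True)
class MappedRead:
    read_id: str
    unigene_id: str
    aligned_len: int
    mismatches: int
    clipped: bool = False


@dataclass(frozen=True)
class ExpressionRecord:
    unigene_id: str
    count: int  # C, reads mapped to this unigene
    length: int  # L, unigene length in bp
    library_size: int  # N, retained mapped reads in the library

    @property
    def rpkm(self) -> float:
        return rpkm(self.count, self.length, self.library_size)


@dataclass(frozen=True)
class PairClassification:
    fruiting_id: str
    mycelia_id: str
    ratio: float  # RPKM_fruiting / RPKM_mycelia (inf/nan at zero denominators)
    label: str  # up | down | equal | unclassified


@dataclass(frozen=True)
class MultimapDiagnostics:
    unigene_id: str
    unique_reads: int
    multi_reads: int
    homolog_ids: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return self.unique_reads + self.multi_reads


# ---------------------------------------------------------------------------
# Similarity search and pairing


def _as_unigenes(seqs) -> list[Unigene]:
    if isinstance(seqs, Mapping):
        return [Unigene(str(k), str(v)) for k, v in seqs.items()]
    out = []
    for item in seqs:
        if isinstance(item, Unigene):
            out.append(item)
        elif hasattr(item, "seq"):  # Bio.SeqRecord
            out.append(Unigene(item.id, str(item.seq)))
        else:
            uid, seq = item
            out.append(Unigene(str(uid), str(seq)))
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _seed_index(unigenes: Sequence[Unigene], k: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = defaultdict(set)
    for i, u in enumerate(unigenes):
        seq = u.sequence
        for pos in range(len(seq) - k + 1):
            index[seq[pos : pos + k]].add(i)
    return index


def similarity_search(
    queries,
    subjects,
    min_identity: float = PAIR_MIN_IDENTITY,
    min_coverage: float = PAIR_MIN_COVERAGE,
    seed_k: int | None = 15,
    coverage_denominator: str = "min",
) -> list[AlignmentHit]:
    """Local-alignment search of every query against the subject set.

    Alignment scoring: match +1, mismatch -2, gap open -5, gap extend -2.
    Identity is the percentage of aligned columns that match; coverage is
    the alignment length as a percentage of the shorter sequence (or of
    the query with ``coverage_denominator="query"``). The best hit per
    (query, subject) is kept; hits below either threshold are dropped.

    ``seed_k`` enables a shared-k-mer prefilter (seed-and-extend style):
    only subjects sharing at least one exact ``seed_k``-mer with the
    query are aligned. At the default of 15, unrelated kilobase-scale
    sequences almost never share a seed while sequences above the 90%
    identity threshold essentially always do. Set to None for an
    exhaustive all-vs-all search.
    """
    qs, ss = _as_unigenes(queries), _as_unigenes(subjects)
    if not qs or not ss:
        raise ValueError("query and subject sets must be non-empty")
    if coverage_denominator not in ("min", "query"):
        raise ValueError("coverage_denominator must be 'min' or 'query'")
    aligner = _make_aligner()
    index = _seed_index(ss, seed_k) if seed_k is not None else None

    hits: list[AlignmentHit] = []
    for q in qs:
        if index is None:
            candidates: Iterable[int] = range(len(ss))
        else:
            cand: set[int] = set()
            seq = q.sequence
            for pos in range(len(seq) - seed_k + 1):
                cand |= index.get(seq[pos : pos + seed_k], set())
            candidates = sorted(cand)
        for j in candidates:
            s = ss[j]
            alignments = aligner.align(q.sequence, s.sequence)
            if len(alignments) == 0 or alignments.score <= 0:
                continue
            aln = alignments[0]
            counts = aln.counts()
            aln_len = counts.identities + counts.mismatches + counts.gaps
            if aln_len == 0:
                continue
            identity = 100.0 * counts.identities / aln_len
            denom = min(len(q), len(s)) if coverage_denominator == "min" else len(q)
            coverage = min(100.0, 100.0 * aln_len / denom)
            if identity >= min_identity and coverage >= min_coverage:
                hits.append(
                    AlignmentHit(q.id, s.id, identity, int(aln_len), coverage, float(aln.score))
                )
    return hits


def _best_by_query(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Top-scoring hit per query; ties broken by subject id for determinism."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.score > cur.score or (
            h.score == cur.score and h.subject_id < cur.subject_id
        ):
            best[h.query_id] = h
    return best


def pair_unigenes(
    hits_ab: Iterable[AlignmentHit],
    hits_ba: Iterable[AlignmentHit],
    min_identity: float = PAIR_MIN_IDENTITY,
    min_coverage: float = PAIR_MIN_COVERAGE,
) -> list[UnigenePair]:
    """Reciprocal best hits across two assemblies, one pair per unigene.

    A pair (a, b) is formed when b is a's top-scoring hit in the A->B
    search and a is b's top-scoring hit in the B->A search, and the A->B
    hit passes the identity/coverage thresholds. Reciprocity guarantees
    each unigene appears in at most one pair.
    """
    best_ab = _best_by_query(h for h in hits_ab)
    best_ba = _best_by_query(h for h in hits_ba)
    pairs = []
    for a, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.subject_id)
        if back is None or back.subject_id != a:
            continue
        if hit.identity < min_identity or hit.coverage < min_coverage:
            continue
        pairs.append(UnigenePair(a, hit.subject_id, hit.identity, hit.coverage, hit.score))
    return pairs


def find_homologs(
    focal: Unigene,
    pool,
    min_identity: float = PAIR_MIN_IDENTITY,
    min_coverage: float = HOMOLOG_MIN_COVERAGE,
    seed_k: int | None = 15,
) -> list[str]:
    """Unigenes in the pool highly similar to the focal one (self excluded)."""
    pool_u = [u for u in _as_unigenes(pool) if u.id != focal.id]
    if not pool_u:
        return []
    hits = similarity_search([focal], pool_u, min_identity, min_coverage, seed_k=seed_k)
    return sorted({h.subject_id for h in hits})


# ---------------------------------------------------------------------------
# Read counting from SAM


def _load_reference(reference) -> dict[str, str] | None:
    if reference is None:
        return None
    if isinstance(reference, Mapping):
        return {str(k): str(v) for k, v in reference.items()}
    if isinstance(reference, (str, Path)):
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(reference), "fasta")}
    return {u.id: u.sequence for u in _as_unigenes(reference)}


_ALIGNED_OPS = {0, 7, 8}  # M, =, X
_CLIP_OPS = {4, 5}  # S, H


def filter_mappings(
    sam: str | Path,
    min_len: int = MIN_ALIGNED_LEN,
    reference=None,
) -> list[MappedRead]:
    """Perfect-match mappings longer than `min_len` from a SAM file.

    A record is retained iff it is mapped, its aligned length (sum of
    M/=/X CIGAR operations) is strictly greater than `min_len`, it has
    zero mismatches, and it is not soft- or hard-clipped. Mismatches are
    taken from the NM tag; when NM is absent they are recomputed against
    `reference` (a FASTA path or an id -> sequence mapping), and a record
    with neither is an error.
    """
    out: list[MappedRead] = []
    ref = _load_reference(reference)
    with pysam.AlignmentFile(str(sam), "r") as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            cig = rec.cigartuples or []
            if any(op in _CLIP_OPS for op, _ in cig):
                continue
            aligned_len = sum(n for op, n in cig if op in _ALIGNED_OPS)
            if aligned_len <= min_len:
                continue
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                nm = _recompute_nm(rec, ref)
            if nm != 0:
                continue
            out.append(
                MappedRead(rec.query_name, rec.reference_name, aligned_len, nm, clipped=False)
            )
    return out


def _recompute_nm(rec: pysam.AlignedSegment, ref: dict[str, str] | None) -> int:
    if ref is None or rec.reference_name not in ref:
        raise ValueError(
            f"record {rec.query_name!r}: no NM tag and no reference sequence "
            f"to recompute the mismatch count from"
        )
    seq = rec.query_sequence
    if seq is None:
        raise ValueError(f"record {rec.query_name!r}: no sequence to recompute mismatches")
    refseq = ref[rec.reference_name]
    nm = 0
    qpos, rpos = 0, rec.reference_start
    for op, n in rec.cigartuples or []:
        if op in _ALIGNED_OPS:
            nm += sum(
                1 for a, b in zip(seq[qpos : qpos + n], refseq[rpos : rpos + n]) if a.upper() != b.upper()
            )
            qpos += n
            rpos += n
        elif op == 1:  # insertion
            nm += n
            qpos += n
        elif op in (2, 3):  # deletion / skip
            if op == 2:
                nm += n
            rpos += n
        elif op == 4:
            qpos += n
    return nm


def count_reads(
    mapped: Iterable[MappedRead],
) -> tuple[dict[str, int], dict[str, MultimapDiagnostics]]:
    """Per-unigene read counts and the unique/multi-mapped partition.

    A read aligning to m distinct unigenes contributes one count to each
    of them; it is multi-mapped when m >= 2. Per unigene,
    unique_reads + multi_reads equals its total count.
    """
    targets: dict[str, set[str]] = defaultdict(set)
    for m in mapped:
        targets[m.read_id].add(m.unigene_id)
    counts: Counter[str] = Counter()
    unique: Counter[str] = Counter()
    multi: Counter[str] = Counter()
    for uids in targets.values():
        bucket = unique if len(uids) == 1 else multi
        for uid in uids:
            counts[uid] += 1
            bucket[uid] += 1
    diagnostics = {
        uid: MultimapDiagnostics(uid, unique[uid], multi[uid]) for uid in counts
    }
    return dict(counts), diagnostics


# ---------------------------------------------------------------------------
# RPKM and classification


def rpkm(count: int, length: int, library_size: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length <= 0:
        raise ValueError("unigene length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return 1e9 * count / (length * library_size)


def expression_records(
    counts: Mapping[str, int], lengths: Mapping[str, int], library_size: int
) -> dict[str, ExpressionRecord]:
    """ExpressionRecord per unigene that appears in `lengths`.

    Unigenes with no mapped read get count 0.
    """
    return {
        uid: ExpressionRecord(uid, int(counts.get(uid, 0)), int(L), int(library_size))
        for uid, L in lengths.items()
    }


def classify_pair(
    rpkm_fruiting: float,
    rpkm_mycelia: float,
    fruiting_id: str = "",
    mycelia_id: str = "",
    fold: float = FOLD_CHANGE,
) -> PairClassification:
    """Fold-change class of a unigene pair from its two RPKM values.

    ratio = RPKM_fruiting / RPKM_mycelia; strictly more than `fold` is
    up-regulated (in the fruiting body), strictly less than 1/fold is
    down-regulated, the closed band [1/fold, fold] is equally expressed.
    A pair expressed only in the fruiting body is up, only in the
    mycelium is down; a pair with both RPKM zero is unclassifiable.
    """
    if rpkm_fruiting < 0 or rpkm_mycelia < 0:
        raise ValueError("RPKM values must be non-negative")
    if rpkm_mycelia == 0:
        if rpkm_fruiting == 0:
            return PairClassification(fruiting_id, mycelia_id, math.nan, "unclassified")
        return PairClassification(fruiting_id, mycelia_id, math.inf, "up")
    ratio = rpkm_fruiting / rpkm_mycelia
    if ratio > fold:
        label = "up"
    elif ratio < 1.0 / fold:
        label = "down"
    else:
        label = "equal"
    return PairClassification(fruiting_id, mycelia_id, ratio, label)


def sufficiency_check(counts: Mapping[str, int], focal: str) -> bool:
    """True iff the focal unigene's read count exceeds the median count.

    Used to judge whether read depth on a unigene is sufficient to trust
    its expression estimate relative to the rest of the library.
    """
    if focal not in counts:
        raise KeyError(f"unknown unigene id {focal!r}")
    med = float(np.median(list(counts.values())))
    return counts[focal] > med
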