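"""Alignment-free genome comparison via tetranucleotide signatures.

A genome signature is the vector of relative frequencies of all k-mers
(tetranucleotides by default) in a genome. Genomes are compared by
correspondence analysis (CA) of the genomes x k-mers count table: CA is
the chi-square-metric ordination of a contingency table, obtained from
the singular value decomposition of the matrix of standardized Pearson
residuals. Euclidean distance between genome coordinates over *all*
retained dimensions equals the chi-square distance between k-mer
profiles, so neighbor ranking in the full CA space is an exact
profile-distance ranking rather than a low-dimensional approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import reverse_complement
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

BASES = "ACGT"


def kmer_labels(k: int) -> list[str]:
    """All 4^k words over {A,C,G,T} in lexicographic order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


@dataclass(frozen=True)
class KmerProfile:
    """k-mer counts for one genome, indexed lexicographically."""

    genome_id: str
    k: int
    counts: np.ndarray  # shape (4**k,), non-negative ints

    def __post_init__(self) -> None:
        if self.counts.shape != (4**self.k,):
            raise ValueError(f"counts must have length 4^{self.k}")

    @property
    def n_windows(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Relative frequencies (profile); zeros if no valid window."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


@dataclass
class SignatureTable:
    """Genomes x k-mers count table with all-zero columns removed."""

    genome_ids: list[str]
    kmer_labels: list[str]
    matrix: np.ndarray  # shape (n_genomes, n_retained_kmers)
    k: int
    dropped_labels: list[str] = field(default_factory=list)

    def profiles(self) -> np.ndarray:
        """Row-normalised relative frequencies."""
        sums = self.matrix.sum(axis=1, keepdims=True)
        return self.matrix / sums

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.genome_ids, columns=self.kmer_labels)


@dataclass
class CAResult:
    """Correspondence-analysis output for a signature table."""

    genome_ids: list[str]
    genome_scores: np.ndarray  # principal coordinates, genomes x D
    singular_values: np.ndarray  # length D, non-increasing
    inertia: float
    row_masses: np.ndarray
    col_masses: np.ndarray

    @property
    def n_dimensions(self) -> int:
        return int(self.singular_values.size)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # square, symmetric, zero diagonal

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# k-mer counting

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def _count_one(seq: str, k: int) -> np.ndarray:
    """Count k-mer windows in one sequence; windows with non-ACGT skipped."""
    counts = np.zeros(4**k, dtype=np.int64)
    if len(seq) < k:
        return counts
    codes = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return counts
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = windows[valid] @ powers
    return np.bincount(idx, minlength=4**k).astype(np.int64)


def count_kmers(
    sequences: Iterable[str],
    k: int = 4,
    genome_id: str = "",
    add_revcomp: bool = False,
) -> KmerProfile:
    """k-mer profile over a set of sequences (e.g. one genome's scaffolds).

    Windows slide with step 1 within each sequence only (never across
    record boundaries); any window containing a non-ACGT character is
    skipped. Sequences are counted as given; with ``add_revcomp`` the
    reverse complement of each sequence is counted as well (strand-
    symmetric signatures).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4**k, dtype=np.int64)
    for seq in sequences:
        counts += _count_one(seq, k)
        if add_revcomp:
            counts += _count_one(reverse_complement(seq), k)
    return KmerProfile(genome_id=genome_id, k=k, counts=counts)


def profile_fasta(
    fasta: str | Path, k: int = 4, genome_id: str | None = None, add_revcomp: bool = False
) -> KmerProfile:
    """k-mer profile of all records in a FASTA file (one genome)."""
    seqs = (str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta"))
    return count_kmers(seqs, k=k, genome_id=genome_id or Path(fasta).stem, add_revcomp=add_revcomp)


def build_table(profiles: Sequence[KmerProfile]) -> SignatureTable:
    """Stack per-genome profiles into a signature table.

    k-mers absent from every genome carry no information and would make
    the chi-square metric degenerate, so their columns are dropped (and
    recorded in ``dropped_labels``).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two genomes")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise ValueError(f"profiles mix k values: {sorted(ks)}")
    k = ks.pop()
    matrix = np.vstack([p.counts for p in profiles]).astype(float)
    labels = np.array(kmer_labels(k))
    keep = matrix.sum(axis=0) > 0
    return SignatureTable(
        genome_ids=[p.genome_id for p in profiles],
        kmer_labels=list(labels[keep]),
        matrix=matrix[:, keep],
        k=k,
        dropped_labels=list(labels[~keep]),
    )


# ---------------------------------------------------------------------------
# Correspondence analysis


class CorrespondenceAnalysis(TransformerMixin, BaseEstimator):
    """Correspondence analysis of a non-negative contingency table.

    Fits the chi-square-metric SVD ordination: with ``P`` the table
    divided by its grand total, ``r``/``c`` the row and column masses,
    the standardized residuals ``S = (P - r c^T) / sqrt(r c^T)`` are
    decomposed as ``S = U diag(s) V^T``. Row principal coordinates are
    ``diag(1/sqrt(r)) U diag(s)``; squared singular values sum to the
    total inertia (Pearson chi-square / grand total). Dimensions with a
    singular value below ``tol`` times the largest are discarded as
    numerically null; at most ``min(n_rows, n_cols) - 1`` dimensions are
    kept (the trivial dimension is always null).

    Parameters
    ----------
    tol : float
        Relative singular-value cutoff for the numerical rank.

    Attributes
    ----------
    row_coordinates_ : (n_rows, D) principal coordinates of the rows.
    column_coordinates_ : (n_cols, D) principal coordinates of the columns.
    singular_values_ : (D,) non-increasing positive singular values.
    inertia_ : total inertia of the table.
    row_masses_, col_masses_ : marginal probability vectors.
    n_components_ : D, the number of retained dimensions.
    """

    def __init__(self, tol: float = 1e-12):
        self.tol = tol

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2, ensure_min_features=2)
        if (X < 0).any():
            raise ValueError("contingency table entries must be non-negative")
        total = X.sum()
        if total <= 0:
            raise ValueError("grand total must be positive")
        row_sums = X.sum(axis=1)
        col_sums = X.sum(axis=0)
        if (row_sums == 0).any():
            bad = int(np.flatnonzero(row_sums == 0)[0])
            raise ValueError(f"row {bad} has zero total")
        if (col_sums == 0).any():
            bad = int(np.flatnonzero(col_sums == 0)[0])
            raise ValueError(f"column {bad} has zero total; drop empty columns first")

        P = X / total
        r = row_sums / total
        c = col_sums / total
        expected = np.outer(r, c)
        S = (P - expected) / np.sqrt(expected)
        U, s, Vt = np.linalg.svd(S, full_matrices=False)

        max_rank = min(X.shape) - 1
        # relative cutoff for the numerical rank, plus an absolute floor so
        # an exactly-independent table (all-noise spectrum) keeps nothing
        floor = max(X.shape) * np.finfo(float).eps
        cutoff = max(self.tol * (s[0] if s.size else 0.0), floor)
        keep = s > cutoff
        keep[max_rank:] = False
        U, s, Vt = U[:, keep], s[keep], Vt[keep]

        # SVD axis signs are arbitrary; fix each axis so its largest-
        # magnitude row loading is positive (distances are unaffected).
        for j in range(s.size):
            i = int(np.argmax(np.abs(U[:, j])))
            if U[i, j] < 0:
                U[:, j] = -U[:, j]
                Vt[j] = -Vt[j]

        self.row_masses_ = r
        self.col_masses_ = c
        self.singular_values_ = s
        self.inertia_ = float((s**2).sum())
        self.row_coordinates_ = (U * s) / np.sqrt(r)[:, None]
        self.column_coordinates_ = (Vt.T * s) / np.sqrt(c)[:, None]
        self._col_standard = Vt.T / np.sqrt(c)[:, None]
        self.n_components_ = int(s.size)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Principal coordinates of (supplementary) rows of counts."""
        check_is_fitted(self, "row_coordinates_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from the fitted table")
        sums = X.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValueError("supplementary rows must have positive totals")
        return (X / sums) @ self._col_standard

    def fit_transform(self, X, y=None):
        return self.fit(X).row_coordinates_


def correspondence_analysis(table: SignatureTable, tol: float = 1e-12) -> CAResult:
    """Run CA on a signature table, reporting genome principal coordinates.

    The analysis is performed on relative tetranucleotide frequencies
    (each genome's counts divided by its window total), so every genome
    carries equal mass and coordinates are invariant to genome size:
    multiplying one genome's counts by a constant changes nothing.
    """
    row_sums = table.matrix.sum(axis=1)
    if (row_sums == 0).any():
        bad = table.genome_ids[int(np.flatnonzero(row_sums == 0)[0])]
        raise ValueError(f"genome {bad!r} has no counted k-mer windows")
    ca = CorrespondenceAnalysis(tol=tol).fit(table.profiles())
    return CAResult(
        genome_ids=list(table.genome_ids),
        genome_scores=ca.row_coordinates_,
        singular_values=ca.singular_values_,
        inertia=ca.inertia_,
        row_masses=ca.row_masses_,
        col_masses=ca.col_masses_,
    )


def pairwise_distances(ca: CAResult, dims: int | str = "all") -> DistanceMatrix:
    """Euclidean distances between genome scores over the chosen dimensions.

    Over all dimensions (the default) this equals the chi-square distance
    between the genomes' k-mer profiles.
    """
    if dims == "all":
        ndim = ca.n_dimensions
    else:
        ndim = int(dims)
        if ndim < 1 or ndim > ca.n_dimensions:
            raise ValueError(f"dims must be in [1, {ca.n_dimensions}]")
    d = squareform(pdist(ca.genome_scores[:, :ndim], metric="euclidean"))
    return DistanceMatrix(ids=list(ca.genome_ids), d=d)


def rank_neighbors(dm: DistanceMatrix, focal: str) -> list[tuple[str, float]]:
    """All other genomes ordered by ascending distance to `focal`.

    Ties are broken lexicographically by genome id; the focal genome is
    excluded from the output.
    """
    if focal not in dm.ids:
        raise KeyError(f"unknown genome id {focal!r}")
    i = dm.ids.index(focal)
    others = [(gid, float(dm.d[i, j])) for j, gid in enumerate(dm.ids) if j != i]
    return sorted(others, key=lambda t: (t[1], t[0]))
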