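# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Read quality control

The QC model is a three-rule filter applied per read, in order:

1. **Quality trimming.** "Remove low-quality regions below Phred 20" is
   operationalised as: keep the longest contiguous run of bases with
   quality ≥ threshold, taking the leftmost run on ties. This is a
   deliberate design choice — end-trimming and windowed trimming are
   equally defensible readings — picked because it is deterministic,
   order-free and easy to verify against brute-force enumeration of all
   contiguous runs. A read with no base at the threshold becomes empty.
2. **Length filter.** Drop trimmed reads shorter than 5 bp ("less than
   5 bp", so an exactly-5 bp read is kept).
3. **Ambiguity filter.** Drop reads containing `N`, `n` or `.`. The dot is
   the ambiguity symbol used by older Illumina base callers; `N` covers
   modern FASTQ dialects.

Paired-end fragments are retained only when both mates pass
(`require_both=True`), since downstream paired assembly needs intact
pairs; `require_both=False` keeps passing orphans. Retention percentages
are reported per read, not per pair, rounded half-away-from-zero to one
decimal.

Quality encoding defaults to auto-detection: any quality character below
`chr(59)` proves Phred+33; a file whose minimum character is at or above
`chr(64)` is taken as Phred+64 (Illumina 1.3–1.7 era); ambiguous files
fall back to Phred+33. An explicit `offset` override is available.

The filters are idempotent (a retained read passes again unchanged), and
retention is monotone non-increasing in both the quality threshold and
the minimum length — both are property-tested.

## Assembly statistics

N50 uses the inclusive convention: sort lengths descending, accumulate,
and report the length at which the cumulative sum first reaches **at
least** half the total. The exclusive (">") convention differs only when
half the total falls exactly on a boundary; the inclusive form is the one
most assembly tools implement. Mean lengths and depth estimates are
rounded to the nearest integer, halves away from zero, matching how such
tables are conventionally printed. The depth estimate is simply total
high-quality bases divided by an assumed genome size; it is a planning
number, not a measured alignment depth.

## Genome signatures and correspondence analysis

**Counting.** Tetranucleotide (k = 4 by default) windows slide with step 1
within each FASTA record; windows containing any non-ACGT character are
skipped, and windows never span record boundaries (scaffold junctions are
not real sequence). Sequences are counted as given — no reverse-complement
addition — because assemblies are compared in the orientation they are
distributed; `add_revcomp=True` gives strand-symmetric signatures when
wanted. k-mers absent from every genome are dropped before ordination
(they would make the chi-square metric degenerate) and recorded.

**Ordination.** Correspondence analysis of the genomes × k-mers table is
computed from first principles: with `P` the table over its grand total,
`r`/`c` the row/column masses, the standardized residuals
`S = (P − r cᵀ)/√(r cᵀ)` are decomposed by SVD; row principal coordinates
are `diag(1/√r) U Σ`. Total inertia `Σ σ²` equals Pearson's chi-square
statistic divided by the grand total — this identity against an
independent chi-square computation is the module's primary correctness
oracle. The genome-level wrapper feeds CA the **relative frequencies**
(each genome's counts normalised to sum 1) rather than raw counts, so
every genome carries equal mass and coordinates are exactly invariant to
genome size; this matches analysing "relative frequencies of
tetranucleotides" and makes the scale-invariance property exact rather
than approximate.

Internally genomes are rows and k-mers columns; by CA row/column duality
this is mathematically identical to the transposed orientation.

**Numerical choices.** Dimensions with a singular value below
`1e-12 × σ_max` (or below `max(n_rows, n_cols) × eps` absolutely, so an
exactly independent table retains nothing) are discarded; at most
`min(rows, cols) − 1` dimensions are kept since the trivial dimension is
always null. SVD axis signs are fixed by forcing the largest-magnitude
row loading on each axis positive; distances are sign-invariant either
way.

**Distances.** Genome distances default to Euclidean distance over *all*
retained principal coordinates. Principal (not standard) coordinates are
used because only they satisfy the classical identity with the chi-square
distance between profiles, making "distance in the full CA space" an
exact, ordination-free quantity. Neighbor ranking sorts ascending with
lexicographic tie-breaks and excludes the focal genome.

## Expression comparison

**Pairing.** The published criterion (identity ≥ 90%, coverage ≥ 50%)
does not state a pairing rule, so reciprocal best hit (RBH) by alignment
score is used: it yields one-to-one pairs, which is what "unigene pairs"
requires, and is the standard cross-assembly orthology heuristic. Local
alignment uses match +1, mismatch −2, gap open −5, gap extend −2 (BLASTN-
like defaults; the original search tool's parameters are not recoverable,
so these are a documented stand-in). Identity is matches over aligned
columns (gaps included); coverage is alignment length over the *shorter*
sequence — the more permissive symmetric reading, with a
`coverage_denominator="query"` alternative. A shared-15-mer prefilter
(seed-and-extend style) keeps the all-vs-all search near-linear: at 90%
identity over hundreds of bases the probability of sharing no exact
15-mer is negligible, while unrelated kilobase sequences almost never
share one. `seed_k=None` forces the exhaustive search; the two modes are
tested to agree.

**Perfect-match filter.** "Over 50 bp reads mapped with perfect matches"
is read strictly: aligned length (M/=/X CIGAR ops) > 50 — a 50 bp
alignment is dropped — NM = 0, and no soft or hard clipping. When a SAM
record lacks NM, the mismatch count is recomputed from the reference;
with neither available the record is an error rather than a silent guess.

**Counting.** A read aligned to m unigenes contributes one full count to
each (fractional weighting is deliberately not used: the multi-mapped
diagnostic is about exposing this inflation, not hiding it). Library size
N is the number of distinct retained reads in the library — reads, not
pairs, and post-filter, not raw.

**Classification.** ratio = RPKM_fruiting / RPKM_mycelia; "more than
2-fold" is strict, so the equal band is the closed interval [0.5, 2.0].
Zero denominators: expressed only in the fruiting body → up; both zero →
unclassified. Up/down are antisymmetric under swapping the tissues
(property-tested). The median sufficiency check is strict
("more than the median").

## Synthetic data: what it emulates, what it does not

**Genomes.** Order-1 Markov chains are the minimal model giving groups
distinguishable tetranucleotide signatures while staying analytically
transparent; group members share a transition matrix (rows drawn
Dirichlet(2) per group) and differ only in sampling noise. Real genomes
add repeats, GC isochores, coding constraint and higher-order structure —
so planted-group recovery demonstrates the method's mechanics, not its
power on real assemblies.

**Transcriptomes.** Genes are i.i.d. random sequences (uniform length
300–1500 bp); a shared fraction (default 0.8) appears in both tissues
with point substitutions at 2% in one copy; expression levels are
log-normal(μ = 3, σ = 1) — median ≈ 20 reads per gene, a realistic
dynamic range of ~3 orders of magnitude — and the planted count is
max(1, round(level)). Reads are noiseless exact substrings at uniform
positions with SAM records at the true coordinates, so counting, RPKM and
classification recover truth *exactly*; this is the intended acceptance
surface. Homolog families are exact copies, the worst case for
multi-mapping. Not emulated: sequencing error, coverage bias, chimeric or
fragmented unigenes, alternative transcripts, and assembly itself
(unigene sets are generated directly). Passing these tests therefore
verifies the analysis logic, not robustness to assembler artifacts.

**FASTQ.** Per-base qualities are normal around a configurable profile
(default mean 35, sd 3, clipped to [2, 40]); planted failures are one
sub-threshold run per affected read plus i.i.d. ambiguous sites. The
sidecar truth replays the three filter rules per read; the test suite
additionally re-derives the retained set by independent brute force.

All generators are bit-reproducible from (parameters, seed), using
numpy's PCG64 streams.

## Problem sizes and defaults

The shipped verification runs use 3 groups × 4 genomes × 100 kb for
signature recovery, 200 genes (80% shared, 2% divergence, one 4-member
homolog family) for the expression study, and 10⁴ reads for QC
equivalence — sizes at which every planted structure is recovered
deterministically while the full suite runs in well under a minute.
Generator defaults are these same values.

## Known limitations

- The trimming rule is one defensible reading of "low-quality regions
  were trimmed"; pipelines that end-trim only will retain different reads
  at the margins.
- Alignment-based pairing assumes near-global similarity between true
  pairs; paralog families above both thresholds can in principle displace
  a true pair from RBH status (they do not at the default simulation
  settings).
- Distances between genome signatures quantify compositional similarity,
  not phylogeny; no tree inference is attempted.
- Fold-change classification has no significance model — it is a
  threshold rule on RPKM ratios, as specified, with no replicate-based
  variance estimate.
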