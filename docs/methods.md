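# Methods

This note records the scientific and numerical choices behind `conscore`:
what each component computes, where the formulation was genuinely open,
and what the synthetic validation does and does not establish.

## Column filtering and orientation

A column is *analyzable* iff no sequence carries a gap (`-`, `.`) or an
ambiguity code (B, X, Z) at that position; all scores, sequence weights,
percent distances and alignment-level background distributions are
computed over analyzable columns only. Catalytic annotations falling on a
filtered column are dropped, so ROC positives are counted only among
analyzable columns.

Scores whose native formulation grows with *variability* (wu70, taylor86,
shannon(w), mirny99, caffrey04w, thompson97, mihalek04, zhang08) are
negated at the reporting boundary so every stored value is a conservation
score; `raw=True` recovers native values. Negation is a strictly monotone
transform, so it is invisible to everything downstream (Spearman
correlation, rank normalization, ROC/AUC are all rank-based).

## The matrix family

All matrix scores derive from BLOSUM62. The integer half-bit log-odds
`M` ships as package data and is cross-checked against Biopython in the
test suite. The target-frequency matrix `M_f` ships as a reconstruction
of the published table: each 4-decimal cell was validated against the
integer matrix through the defining relation
`s = round(2·log₂(q_ab/(p_a·p_b)))` with a per-cell tolerance of
0.5 (integer rounding) + `2·log₂(1 + 0.00005/q)` (4-decimal rounding of
the cell) + 0.2 (marginal rounding); cells outside that band were replaced
by the nearest in-band 4-decimal value. Its marginals reproduce the
published background frequencies `q` to 4 decimals, and the matrix is
positive definite (smallest eigenvalue ≈ 0.0031), which guarantees
non-negative von Neumann eigenvalues.

Derived matrices:

* `M_K(a,b) = M(a,b)/√(M(a,a)·M(b,b))` — unit diagonal, so every fully
  conserved column scores exactly 1 under the sum-of-pairs scores that
  use it.
* `M_V` — linear map of `M` onto [0, 1] (global min → 0, global max → 1).
  The diagonal keeps the self-similarity spread: conserved Trp scores
  1.0, conserved Ala 0.53 under valdar01.
* `M_M` — `M_f` balanced by Sinkhorn iterations with a symmetrization
  (average with the transpose) each round; tolerance 1e-6 on the largest
  row/column-sum deviation, cap 1000 iterations. Exact double
  stochasticity is incompatible with symmetry, hence "approximately 1".
* `M_L` — affine map of `M_K` with the unit diagonal pinned to 10 and the
  off-diagonal range mapped into [2, 10]. An affine map of `M` itself
  cannot satisfy the diagonal constraint because the BLOSUM62 diagonal
  varies (4..11); mapping the already diagonal-normalized `M_K` is the
  minimal construction meeting both stated constraints.

## Sequence weighting and distances

Henikoff-Henikoff position-based weights: in each analyzable column a
residue type observed `s` times among `r` distinct types contributes
`1/(r·s)` to each carrier; sequence weights are the sums over analyzable
columns, normalized to 1. Weights are computed once per alignment and
reused by every `w`-suffixed method. Percent distance between two
sequences is `100·(1 − fraction identical)` over analyzable columns; it
feeds the sander91sp pair weights (`w_ij ∝ d_ij`, equal weights in the
all-identical degenerate case), the valdar01 sequence weights
(`w_i ∝ mean distance to the others`), and the UPGMA tree.

## Entropy bases and smoothing

Bases are chosen so each score's natural range is [0, 1]-like, and are
config arguments where the literature is silent: Shannon and von Neumann
use base 20, the Jensen-Shannon divergence base 2 (required for the [0,1]
bound), mirny99 base 6 (six groups), williamson95 and the evolutionary-
trace sums natural log. Any base change is a monotone rescaling and
leaves every within-alignment ranking unchanged, which is all the
pipeline consumes. The williamson95 grouped alignment background receives
add-ε smoothing (ε = 1e-6, renormalized) so a group present in a column
but absent from the pooled alignment cannot divide by zero.

`caffrey04w` computes the von Neumann entropy of `ω = diag(p_k)·M_f`
rescaled to trace 1. Implementation: `ω` is similar (via `diag(√p)`) to
the symmetric matrix `diag(√p)·M_f·diag(√p)` restricted to the support of
`p_k`, so eigenvalues are obtained from a small symmetric eigenproblem —
numerically stable, exactly equal to the full non-symmetric spectrum (a
test checks this against `numpy.linalg.eigvals` of the full `ω`), and
non-negative because `M_f` is positive definite. Eigenvalues below
−1e-10 raise; smaller rounding noise is clipped to 0.

`lockless99` evaluates binomial probabilities in log space
(`scipy.stats.binom.logpmf`); the reference count for each residue is the
probability mass at the integer nearest `N·q(a)`.

`mihalek07` uses the unordered-pair background `b(a,b) ∝ M_M(a,b)·(2−δ_ab)`,
renormalized to a distribution over unordered pairs. A consequence worth
recording: because the background's diagonal varies strongly across
residues, the score's "rare substitutions score higher" behaviour is only
guaranteed when the majority residue is held fixed; comparing a W-among-C
column against an I-among-V column mixes the substitution-rarity effect
with the C/V diagonal background difference and can reverse the naive
expectation. The tests therefore pin the claim with the majority residue
controlled.

## Evolutionary trace

`build_upgma` is a hand-rolled UPGMA (average linkage on the percent
distances, heights = half the merge distance) with a documented
deterministic tie-break — among equally close pairs, the one containing
the smallest leaf indices merges first — so bootstrap runs and tests are
exactly reproducible; it is cross-checked against
`scipy.cluster.hierarchy.linkage` on random matrices. `cut(n)` partitions
the leaves by undoing the `n−1` highest merges; an independent test
oracle rebuilds the cuts from cophenetic distances.

The real-valued trace is
`r(k) = Σ_{n=1}^{N−1} (1/n) Σ_{g∈cut(n)} S(p_g(k))`. Each tree node is a
group of a contiguous range of cuts, so the implementation precomputes a
per-node coefficient `Σ 1/n` over that range and sums `coefficient ×
group entropy` over the 2N−1 nodes — mathematically identical to the cut
sum (tested term-by-term for N ≤ 8) and far cheaper. The original
formulation's additive constant 1 and the optional `/(N−1)` rescaling are
monotone transforms; the constant is dropped and the rescaling is a flag.
`zhang08` substitutes the von Neumann group entropy. The external
Rate4Site adapter (`mayrose04`) registers only when an executable is
supplied; otherwise the registry holds 23 methods and the pipeline runs
without it.

## Comparison pipeline

Scores are compared only within alignments: several methods depend
directly on alignment size (the binomial-surprise score grows with N; the
trace scores sum over N−1 cuts), which the size-dependency harness
(Pearson correlation of N against per-alignment mean score) makes
visible. Per alignment, a Spearman matrix over methods; alignments with
fewer than 3 analyzable columns are excluded (configurable), and pairs
involving a constant score vector are undefined for that alignment and
excluded pairwise from the average rather than imputed. `D = 1 − C̄`;
agglomerative clustering by average (default), single or complete
linkage; dendrogram heights are reported alongside `acc = 1 − height`.
Bootstrap support resamples the alignment set with replacement
(precomputed per-alignment correlation matrices make this cheap),
reclusters, and counts, per original node, the percentage of bootstrap
trees containing a node with the identical leaf-name set; samples with an
everywhere-undefined pair are redrawn and logged.

## Evaluation and normalization

Per-alignment ROC/AUC (scikit-learn, midrank tie convention) with
catalytic columns as positives; alignments lacking either class are
skipped; mean AUC over alignments is unweighted, optionally restricted to
`N ≤ cap`. Within-alignment normalization is fractional rank with ties
sharing the maximal rank of their group, so the most conserved tie group
maps to exactly 1.0 and an all-tied alignment normalizes to all 1.0 —
rank-based (not min-max) because every comparison in the pipeline is a
ranking, and idempotent/monotone-invariant by construction.

## Synthetic data

The generator emulates the statistical shape of the catalytic-site
benchmark data: 455 alignments (default) of 10–168 sequences and 150–250
columns (≈ 200 analyzable sites per alignment), 1.3% catalytic columns.
Catalytic columns draw a catalytically common residue (H, D, E, K, S, C,
R, T, N, Y, linearly decaying weights — cosmetic realism) and follow the
conservation profile: 60% fully conserved, 79% with ≥ 90% one residue;
the remaining 21% keep a 60–90% majority. Conservative-mutation columns
(5% of columns) draw a ~40/20/20/20 profile inside one stereochemical
group — the feature that separates the substitution-matrix cluster from
the frequency cluster. Background columns evolve from a root residue
drawn from `q` by per-sequence multinomial substitution (rate 0.35), with
30% of sequences forming a slowly diverging clade to create the
taxonomic bias that Henikoff weighting corrects; a small fraction of
columns (2%) receives injected gaps/ambiguities to exercise the filter.
No phylogenetic sequence simulation is attempted: none of the implemented
scores assumes an explicit evolutionary model (only the excluded external
Rate4Site does).

What passing synthetic tests show — and what they do not: the pipeline
recovers planted structure (rank-identical methods merge at distance 0
with 100% bootstrap support; fully conserved planted sites are retrieved
with mean AUC ≥ 0.95 by background-relative scores, exactly 1.0 when they
are the only conserved columns; the conservative-mutation contrast
reproduces the cluster-A-above-cluster-B ranking). They do not establish
the quantitative method-similarity structure of real curated enzyme
alignments, whose residue composition, site-to-site rate variation and
phylogenetic depth the generator only caricatures.

## Validation scale

The test suite validates at reduced problem sizes chosen for tight
feedback: pipeline-recovery runs use 30–50 alignments and 200 bootstrap
resamples; oracle equivalences use exhaustive or brute-force checks at
N ≤ 6 (sum-of-pairs), N ≤ 8 (trace term-by-term), N ≤ 12 (tree cuts).
The generator's defaults keep the full study scale.

## Known limitations

* The Taylor set system and the BLOSUM62 frequency table are documented
  reconstructions (see the package-data file headers), not byte copies of
  the original artifacts; scores depending on them are exact with respect
  to the shipped tables.
* Gap handling is filtering-only by design; no score is extended with a
  gap penalty.
* `mayrose04` output parsing targets a plain per-site rate table and has
  only been exercised against synthetic adapter outputs, not a real
  Rate4Site build.
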