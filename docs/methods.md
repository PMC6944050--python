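# Methods

## Model

A *heterogeneous sequence-set* is a set of sequences over a finite alphabet
Σ that share no assumed ancestry or composition — the motivating example is
a segmented viral genome, whose segments encode different proteins with
different nucleotide compositions.  Treating the set as one composite data
point, each sequence is mapped to a count vector X over a word set Ω
(default: all 1-grams of Σ; arbitrary n-grams and explicit word lists are
supported, with overlapping occurrence counting for words longer than one
symbol), a transformation function φ: ℝ^p → ℝ^{p′} is applied per sequence,
and the set is summarized by the covariance structure Ψ(φ(X)) of its
transformed vectors.  The distance between two sets is

δ(Ψ₁, Ψ₂) = max over unit κ of |κ′(Ψ₁ − Ψ₂)κ|,

the largest-magnitude eigenvalue of the symmetric difference, i.e. its
spectral norm.  Under this reading δ is rigorously a metric (the triangle
inequality follows from the norm property; an eigenvector-reuse argument
would not be valid), it never inverts a matrix, and singular structures —
routine when sets have few sequences — need no special handling.

## Estimators and conventions

- **Covariance estimator.**  Default `centered=True`: sample covariance
  with mean subtraction and divisor n − 1.  Count features have a large
  nonzero mean, so centering implements "variance–covariance" literally.
  The uncentered second moment (1/n) Σ φ(X)φ(X)′ — the exact algebra of a
  zero-mean model — is kept as an option.  A singleton set yields the zero
  matrix rather than an error, so single-sequence sets stay comparable.
  Note the centered structure is blind to between-set differences of the
  *mean* count vector; what it sees is within-set heterogeneity, which is
  precisely the property that distinguishes composite data points.
- **Eigensolve.**  The difference matrix is explicitly symmetrized and its
  sign canonicalized (first nonzero entry made positive) before calling the
  symmetric eigensolver, so δ(A, B) and δ(B, A) execute the identical
  computation and agree bitwise.  An exactly diagonal difference
  short-circuits to its diagonal entries, making the diagonal closed form
  δ = max_l |ψ₁,ll − ψ₂,ll| exact.  On a magnitude tie between the extreme
  eigenvalues the positive eigenvalue's pair is reported; the eigenvector's
  first nonzero component is made positive.
- **Decision rules.**  mean / min / median of the query's δ sample per
  class, argmin over classes, ties (within 1e-12) broken to the first class
  in input order with an explicit flag.  The sample variance ϑ̂ uses
  divisor n − 1; the median of an even sample averages the two middle order
  statistics.  The Chebyshev bounds exposed by `chebyshev_bound` are
  1 − ϑ/(nρ²) for the mean and 1 − ϑ/ρ² for min/median; the latter two are
  the stated comparison formulas, not sharp order-statistic results, and
  are labeled as such.
- **Clustering.**  Agglomerative clustering (scipy) on the precomputed δ
  matrix; average linkage by default as the conservative choice for a
  precomputed metric.  Inputs are pre-sorted lexicographically by label so
  tied merges break deterministically, and the k-cluster cut uses the first
  n − k merges, which guarantees k nonempty clusters even under tied
  heights (an all-zero matrix still splits).  The 2D view is classical
  (Torgerson) MDS — double-centered squared distances, top-2 eigenpairs,
  axes scaled by √eigenvalue, non-positive eigenvalues zeroed, orientation
  fixed by making each axis's first nonzero coordinate positive — so any
  exactly 2-embeddable matrix is reproduced to numerical precision.
  Dispersion maps are made concrete as medoid-referenced distances: the
  medoid minimizes the summed within-cluster δ (ties to the
  lexicographically smallest id), and the spread is the mean and max of the
  member-to-medoid distances.

## Simulator

The generator emulates composition-driven heterogeneity and nothing else:
each sequence of a generated set is drawn i.i.d. from its prototype
sequence's multinomial base composition, at length round(n′ × original
length) (floored at 1).  This is the minimal model consistent with the
limiting-distribution requirement — the empirical composition of a
generated sequence converges to the prototype composition as n′ grows, at
the O(1/√(n′·length)) multinomial rate, which `convergence_diagnostic`
measures as the total-variation distance between generated and prototype
base frequencies (mean over sequences per replicate, median over
replicates per factor).  It does **not** emulate positional structure,
codon bias, local composition drift along a sequence (which
`sliding_window_composition` exposes in real data), mutation processes or
phylogeny; passing tests therefore demonstrate recoverability of
composition-structured classes, not of evolutionarily structured ones.

Randomness is keyed by (seed, replicate index, sequence index) through
numpy's SeedSequence, so any single sequence is reproducible in isolation,
collections are order-independent, and all output (including FASTA at a
fixed 60-column wrap) is byte-deterministic under a fixed seed.

`sample_profile` constructs synthetic heterogeneous prototypes: per-sequence
compositions drawn by multinomial sampling of the stated depth around a
base composition, standing in for the per-segment compositions one would
estimate from a real segmented genome.  Defaults — 8 sequences per set,
base length 1000, m = 20 generated sets per prototype, length factors 1
(worst case) to 100 (best case), 200 for limiting-map work — are the
canonical study conditions of an influenza-like scenario.

## Reference experiments and problem sizes

`classification_recovery` uses two prototypes with base compositions
(0.4, 0.3, 0.2, 0.1) and (0.1, 0.2, 0.3, 0.4), 10 training sets and 10
queries per class at factor 100; `clustering_recovery` adds a uniform third
prototype with 10 sets each, average linkage cut at k = 3, scored by the
adjusted Rand index against the generating classes.  At factor 100 the
covariance structures concentrate around each prototype's realized
composition scatter and both experiments recover the truth exactly; at
factor 1 the multinomial noise of base-length sequences dominates and
clustering recovery is not expected.  These sizes keep a full run of the
suite and of `scripts/acceptance.py` under a minute or two each while
leaving the qualitative contrast between the factor regimes unambiguous.

## Known limitations

- The centered default means two sets whose sequences are internally
  homogeneous but differ in average composition are near-indistinguishable
  (both structures ≈ sampling noise); the uncentered option or frequency
  features address such cases.
- δ compares second-order structure only; sets with identical covariance
  but different higher-order word dependence are equidistant.
- The min/median Chebyshev comparisons are bounds in form only (see above).
- MDS coordinates are a visualization aid; when δ is not 2-embeddable the
  projection distorts distances and only the dispersion-map numbers are
  exact.
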