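# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic cohort generator does and does not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Uncertainty decomposition

Each of M ensemble members emits a coding probability `p_m ∈ [0,1]`
(members whose positive class is lncRNA are oriented by `p = 1 − raw`, with
the threshold inverted accordingly; a score exactly at the threshold is
labelled coding — a documented tie rule).  Per transcript:

- `H_pred = H(p̄)`, the binary Shannon entropy of the ensemble mean, in
  bits, with `0·log₂0 := 0`.  Bounds are exact: 0 at `p̄ ∈ {0,1}`, 1 at
  `p̄ = 0.5`.
- `H_exp = mean_m H(p_m)`.
- `I_dis = H_pred − H_exp`.  By concavity of `H` this is nonnegative, zero
  iff all members emit the same probability, and 1 in the maximal
  disagreement configuration (half the members at 1.0, half at 0.0).

Transcripts missing any member's probability are excluded before profiling
(with a per-member missingness report), since every statistic above is
defined over the complete ensemble.

### Stratification

Percentiles are computed per reference class with linear interpolation over
order statistics (the q-th percentile sits at fractional index `q·(N−1)`).
A transcript is **low** uncertainty iff `H_pred < q10` of its class and
**high** iff `H_pred > q90` *and* `I_dis > q90` of its class; everything
else is intermediate.  Both inequalities are strict, so a value exactly at
a threshold is intermediate.  On tie-free data this convention puts exactly
`⌈0.1·(N−1)⌉` transcripts in the low group — e.g. 6,638 of 66,376 and
4,528 of 45,276 — which is the check used in the acceptance suite.

Agreement is categorized against the reference label as unanimously
correct, unanimously incorrect, or discordant, with a near-consensus flag
when exactly one or two members dissent.  Global metrics are macro-averaged
(balanced accuracy = mean per-class recall; a class with zero predicted
positives gets precision 0 and is flagged).

## Cohort construction

- **Label stability**: a transcript is retained iff present in both
  annotation releases with the same biotype, and that biotype is
  protein_coding or lncRNA.  Duplicated ids within a release are an error.
- **Redundancy reduction**: CD-HIT `.clstr` files are parsed (clustering
  itself is external); the longest member per cluster is kept, ties broken
  by lexicographically smallest id.
- **Folds**: the minority class (lncRNA) is shuffled (seeded) and
  partitioned into k folds, remainder to the lowest-index folds.  Fold f
  trains on the other k−1 minority partitions plus an equal-size seeded
  sample of the majority class drawn outside fold f's majority partition;
  the test set is the held-out minority partition plus every unsampled
  majority transcript.  Each transcript therefore has exactly one *strict*
  held-out fold, and out-of-fold analyses use only that fold's model.
  With 66,703 + 45,561 transcripts and k = 5 this yields the balanced
  72,896-transcript training set and 39,368-transcript test set per fold.
  `k = 1` is rejected (no held-out partition exists).

## Repeat features

RepeatMasker `.out` files are parsed from the standard 15-column layout
(1-based inclusive coordinates, kept internally; `class/family` split on
`/`, optional trailing `*` captured).  Overlaps on a transcript are
resolved greedily in Smith–Waterman-score order (ties: longer span, then
smaller begin): a candidate fully covered by accepted spans is dropped, a
partial overlap is trimmed to its largest single uncovered segment.  The
rule is deterministic and idempotent, and after resolution the summed span
lengths equal coverage × length exactly.  *The trim-versus-drop choice for
partial overlaps is this package's codification — the upstream convention
is not fully specified — so it is isolated behind one function and the
feature schema is versioned.*

Fragments sharing a RepeatMasker element ID are aggregated into elements
(summed length, fragment count, class/family from the top-scoring
fragment, conflicting classes logged).  The per-transcript vector covers
counts, per-kb normalized counts, coverage fractions, per-class
counts/coverage/presence for the ten repeat classes, per-family counts,
fragmentation statistics, inter-hit gap statistics and the longest
repeat-free stretch (flanks included).  The catalogue implements the named
feature groups rather than chasing a fixed feature count; the machine-
readable schema sidecar is the source of truth.

## Non-B DNA features

Motif calls (APR, DR, IR, MR, STR, Z-DNA, triplex, G4) are 0-based
half-open BED intervals.  A call is assigned to every gene body it overlaps
by ≥1 bp (strand ignored, the intersector's default behaviour) and clipped
to the gene for length statistics; a call may serve several genes.  Unlike
repeats, overlapping calls are retained without resolution, so total
coverage may exceed 1.  TRI is carried as its own type and not
double-counted as MR.  Per-type presence/count/length/gap statistics plus
diversity (distinct types present, ≤ 8), total count and total coverage
form the fixed, versioned schema.

## Feature statistics

Preprocessing removes constant and all-missing features (reported) and
one-hot encodes categoricals without dropping a reference level.
Continuous features are clustered on `d = 1 − |ρ_Spearman|` — the absolute
value because anti-correlated features are equally redundant — with Ward
linkage on the precomputed distance (Ward formally assumes Euclidean
distances; used here as an agglomeration criterion, a documented caveat).
The cut is chosen by maximizing the mean silhouette (computed on `d`) over
25 evenly spaced cut heights between the smallest and largest merge
heights, ties toward fewer clusters; grid size is a config knob.  With no
correlation structure the best achievable silhouette is near zero and the
chosen cut is arbitrary — the tests assert exactly this contrast against
planted blocks, where recovery is exact.

One representative is kept per cluster: a forced feature (transcript
length, given its established relevance) wins its cluster; otherwise the
largest |effect| (ties: lexicographic) for the univariate stage, or a
seeded random draw for the forest stage.

Continuous comparisons use the Mann–Whitney U test with
`cVDA = A − 0.5`, where `A = (#{x>y} + 0.5·#{x=y})/(n_x n_y)` computed via
the rank-sum identity (the p-value is exact by enumeration when
`n_x·n_y ≤ 400` and tie-free, otherwise normal approximation with tie
correction).  Categorical comparisons use chi-squared without continuity
correction (one formula across table shapes), Cramér's
`V = √(χ²/(n·min(r−1,c−1)))`, and for 2×2 tables an odds ratio with the
Haldane +0.5 adjustment only when a cell is zero.  Benjamini–Hochberg
correction is applied within each comparison family separately;
significance is `p_adj < 0.01` and a non-negligible association is
`|cVDA| > 0.1` (or `V > 0.1`), with 0.15 available as a config
alternative.

## Forest attribution

One random forest per fold (defaults: 500 trees in the library, 300 in the
pipeline; sqrt feature subsampling; min leaf 1; seeded) is trained on the
fold's balanced training ids and explains its strict held-out transcripts.
Attribution uses path-dependent tree Shapley values computed on the class-1
probability output, authored in `treeshap.py` and validated against a
brute-force Shapley enumeration of the conditional-expectation tree game;
additivity `baseline + Σφ = f(x)` holds to ~1e-9 and is enforced at 1e-6.
The baseline is the cover-weighted expected forest output.  Global
importance is mean |φ| over pooled out-of-fold transcripts with the s.d. of
per-fold means; transcript-level views report the top-10 features plus one
aggregated remainder term.  An optional Youden-J threshold recalibration on
the training fold is available; the default decision threshold is 0.5.
The 2-D t-SNE embedding (perplexity 30, 1000 iterations, seeded) is
inspection plumbing only.

## The synthetic cohort

Defaults (the study conditions, fixed once): 3,000 coding + 2,040 lncRNA
transcripts (lncRNA/PC = 0.68, the benchmark's class ratio), M = 8 tools,
per-tool gains 0.8–1.3 and noises 0.4–1.2 spanning a strong-to-weak tool
range, signal scale κ = 5, boundary fraction 0.08, missingness 0.5%
(mirroring the ~0.5% of transcripts unclassifiable by a full real
ensemble), 12 correlated feature blocks (40 features, class shifts 0–2) +
8 independent + 6 categoricals, 5% label churn between releases, 10%
near-duplicate cluster members, repeat presence 30% (coding) / 70%
(lncRNA), non-B motif rates higher in coding gene bodies, lognormal
lengths with medians 1,620 / 1,028 nt.

Tool m emits `p = logistic(λ_m·s + ε)`, `ε ~ N(0, σ_m)`, with latent
signal `s = (2c−1)·κ·u`; core transcripts draw `u ~ U(0.3, 1)`, boundary
transcripts `u ~ U(0, 0.1)`.  Boundary transcripts are modelled with
near-zero signal rather than label noise: this is the minimal mechanism
that produces both a calibrated consensus on core transcripts and
entropy/disagreement concentrated at the class boundary.  All randomness
flows from one seed through `SeedSequence` spawn keys, so artifacts are
independently reproducible and identical configurations are byte-identical.

What the generator does **not** emulate, and therefore what passing tests
do not show about real data:

- sequence composition is uniform random; no k-mer, ORF or conservation
  structure exists, so no claim is made about real sequence-derived
  features;
- entropy and the feature blocks are independent by construction; the
  low-vs-high-entropy enrichment is a true null in the synthetic cohort
  (and is used as a calibration check), whereas in real data low-entropy
  transcripts carry distinctive signatures;
- the default ensemble is more concordant than a real tool panel
  (discordance ~12% at the default noise levels versus ~45% reported for
  real ensembles); the headline agreement percentages of a real benchmark
  are inputs-dependent and are not reproduction targets here;
- the eight real tools' idiosyncrasies (length limits, ORF requirements,
  custom thresholds) are reduced to per-tool gain/noise/missingness.

## Problem sizes

The shipped analysis and acceptance runs use the desk-scale defaults above
(~5,000 transcripts, 150 features, 5 folds, 300-tree forests); all
statistics scale to larger cohorts linearly in transcripts and the
attribution in O(trees · leaves · depth²) per explained transcript.

## Known limitations

- Ward linkage on a non-Euclidean precomputed distance (above).
- Overlap-resolution trim rule is a codified choice, not an upstream
  convention (above).
- Per-tool custom decision thresholds are accepted as inputs; their
  tool-specific recalculation is out of scope.
- The interventional (background-data) attribution variant is not
  implemented; attributions are tree-path-dependent, which is the variant
  whose baseline and additivity are stated in probability space.
- BH families: correction is applied within each comparison; a global
  family across comparisons would be more conservative.
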