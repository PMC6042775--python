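# Methods

## The model

`mpmap` treats an author's documents as repeated multivariate measurements
of one person. Dictionary-derived language variables (percent-of-words
scores plus 0–100 summary scores) are grouped into 13 named clusters of
psychological processes — Style, Complexity, Function Words, Emotional,
Social, Cognitive, Perceptual, Biological, Motivational, Temporal,
Relational, Personal, Utterances. A variable may sit in more than one
cluster (Analytic contributes to both Style and Complexity).

For each cluster the author's *psychological center* is estimated from the
documents currently in the map:

* **center** μ: the mean over B bootstrap resamples (rows drawn with
  replacement at the original sample size; default B = 1000) of the
  resample mean. This equals the sample mean in expectation; the bootstrap
  is kept for fidelity to the procedure the method was introduced with and
  is fully determined by the seed.
* **covariance** Σ: the plain sample covariance (n−1 denominator) of the
  original rows. The covariance is *not* bootstrapped.

Each document's squared Mahalanobis distance from the center,
D² = (x − μ)ᵀ Σ⁺ (x − μ), is mapped onto a 0–100 score through the upper
tail of a chi-square distribution with df equal to the cluster's
dimensionality:

    score = 100 · P(χ²_df > D²)

so a document exactly at the center scores 100, scores decrease strictly
with distance, and under a well-specified Gaussian model scores are
approximately Uniform(0, 100). The median of a document's 13 cluster
scores (the 7th order statistic) is its **grand score**; the median is
preferred over the mean so one superficially extreme cluster cannot
dominate. Documents with grand scores near 0 are atypical of the author
across the board.

Supporting outputs: Cronbach's alpha over the 13 score columns (raw,
covariance-based by default; the standardized variant is exposed as an
option), the Pearson correlation between per-document mean and median
scores, and a 2-D map: PCA of the column-standardized score matrix, signs
fixed so each component's largest-magnitude loading is positive.
Collinear score matrices project with a zero second coordinate; only a
matrix with no variation at all refuses to project.

### Numerical choices

* Σ is inverted with a Moore–Penrose pseudo-inverse (hermitian,
  relative eigenvalue tolerance 1e−8), because typical corpora have
  16–21 works against clusters of up to 13 variables, leaving Σ close to
  singular. An optional ridge term (λ · mean diagonal · I, default λ = 0)
  is available.
* Negative D² from rounding is clamped to 0 with a warning.
* Per-cluster bootstrap streams are spawned from one seed sequence, so a
  whole map run is reproducible from a single integer and independent of
  cluster evaluation order.

### Leave-in convention

The document being scored participates in center and covariance
estimation. This matches the insertion workflow the method exists for: a
questioned work is *inserted* into the candidate author's corpus and the
whole map recomputed, under the working assumption that the candidate
wrote it. A consequence worth knowing: leave-in caps the largest
attainable D² at (n−1)²/n, so with 17 works even an arbitrarily distant
insertion cannot reach a score of exactly 0 — it reaches the floor the
cap implies, which is ample for ranking it last.

## Insertion analysis

`insert_and_score` recomputes the joint map over base ∪ {candidate} and
reports the candidate's rank by grand score (1 = lowest). Ties rank the
inserted work *after* equal-scoring base works, so ties never inflate
apparent detection. A base-only reference map (same seed) is always
computed alongside; `average_runs` averages base works' grand scores
across several insertion runs and correlates them with the base-only
analysis. Because the inserted work moves the centers, base works'
joint-map scores differ slightly from their base-only scores, and that
correlation is below 1 even for identical repeated runs.

## Unmasking

The baseline verifier asks how *deep* the difference between two segment
sets is. Per comparison:

1. features are standardized and segment rows canonically ordered (so
   results are invariant to segment order);
2. for each of f = 10 iterations, stratified 5-fold CV accuracy of a
   linear SVM (C = 1) separating the sets is recorded, then the k = 2
   most positive and k = 2 most negative weights of an SVM refit on all
   current data are removed (4 features per iteration);
3. the curve is summarized by its f accuracies, the slope of a degree-1
   least-squares fit, the (quadratic, linear) coefficients of a degree-2
   fit, and lag-1/lag-2 accuracy differences — a 3f-length feature
   vector.

Same-author pairs differ mainly through a handful of superficial features
(themes, characters), so their accuracy collapses once those are removed;
different-author pairs stay separable. A linear-SVM meta-classifier over
curve features, with Platt-scaled probabilities (sigmoid calibration on
held-out folds of the training curves), converts a questioned-work curve
into a Match/Different verdict; verdict probabilities are averaged over
20 reseeded repetitions.

Comparison sides are balanced by subsampling the larger side to the
smaller. Without balancing, a 12-segment work against an 84-segment
rest-of-author corpus gives CV accuracies pinned near the 87.5%
majority-class rate, and degradation is invisible. Training curves are
built leave-one-work-out: each work vs a size-matched sample of the rest
of its author (same) and vs a size-matched amalgam of other authors'
segments (different).

Exact duplicates are a degenerate input worth noting: when the two sets
are identical multisets, each CV test point's twin trains under the
opposite label and accuracy falls *below* chance. The informative
statement of "no signal" is that duplicates never beat chance, and two
i.i.d. draws from one distribution sit at chance.

## Synthetic data

Generators draw per-document cluster values from author-specific
multivariate normals, clipped to [0, 100]; all are deterministic given a
seed, and corpus writers emit a `_metadata.json` sidecar with their
parameters.

* **Map benchmark**: 6 authors × 15 documents; cluster means
  N(50, 10²) per variable, within-author exchangeable covariance with
  SD 5 and correlation 0.3 (between-author spread twice within-author
  spread). SD 5 on a 0–100 percent-of-words scale is typical of the
  work-to-work variation of dictionary categories in long texts.
* **Unmasking benchmark**: 6 authors × 8 works × 12 segments × 48
  features; author means N(50, 10²) per feature, each work carrying a
  ±12-point superficial offset on 4 randomly chosen features, segments
  N(work mean, 5²). 8 works per author keeps the 20-iteration held-out
  evaluation fast while leaving 96 curves per corpus.
* **Token generator**: emits documents whose dictionary category rates
  hit specified targets in expectation (words chosen so they score as
  exactly one category under the matching rules), for end-to-end tests
  of tokenization → scoring → mapping.
* **Published fixture**: the 21-play score matrix (16 verified + 5
  questioned works, 13 cluster scores + grand median each) ships as a
  checksummed CSV; loading recomputes every row median and the verified
  rows' grand-score mean/SD (48.56 / 16.41) and refuses to load on any
  mismatch.

What the generators do *not* emulate: real dictionary scores are
bounded, skewed, zero-inflated for rare categories, and correlated
across clusters; documents by one author drift over a career; segment
scores within a work are autocorrelated. Passing tests on this synthetic
regime show the machinery is correct and well-calibrated under its own
assumptions, not that any particular verdict on real texts is right.

## Validation experiments and their sizes

The standing experiments (in `mpmap.experiments`, re-run by
`scripts/acceptance.py`) use sizes chosen to give stable rates at
interactive cost: 100 seeded insertion runs (16-work base, candidate
offset 3 pooled SD per variable), 50 same/different curve pairs, 20
randomized benchmark iterations with a stratified 75/25 curve split, and
a 500-document single-author null for the uniformity (Kolmogorov–
Smirnov) check. At these sizes the full battery completes in a few
minutes on one core.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| B | 1000 | bootstrap resamples for each cluster center |
| df | cluster size | chi-square degrees of freedom in the score map |
| ridge λ | 0 | optional covariance regularization (fraction of mean diagonal) |
| threshold | 20 | "highly discrepant" cut for cluster decomposition |
| f, k | 10, 2 | elimination iterations; features removed per sign per iteration |
| cv_folds | 5 | stratified folds per accuracy estimate |
| n_randomized_iterations | 20 | reseeded repetitions averaged into verdicts |
| C | 1 | SVM regularization (curves and meta-learner) |
| segment target | 250 | tokens per segment; a remainder < target/2 merges backward |

## Known limitations

* Summary variables (Analytic, Clout, Authentic, Tone) have proprietary
  formulas; they are accepted as externally supplied columns, and
  clusters silently shed missing variables only down to 2 members —
  below that the scheme refuses to run rather than silently change
  meaning.
* With ~17 documents and 13-variable clusters the covariance is barely
  estimable; the pseudo-inverse (or ridge) keeps D² finite but the
  Function Words cluster's scores are the least stable.
* The chi-square mapping assumes approximate normality of cluster
  scores; heavy skew in real dictionary data makes per-cluster scores
  only approximately uniform under the null.
* A low grand score flags atypicality; it is not, by itself, evidence of
  non-authorship. The tool reports scores and ranks only.
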