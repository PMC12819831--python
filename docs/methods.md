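# Methods

`orientq` implements an *objective* Q-methodology workflow for typing the
built-environment orientations that long-term-care institutions project
through their published imagery.  The classical Q study has three
human-driven stages — statement construction, sorting, and interpretation —
and this package replaces the first two with data-driven procedures so that
the whole chain from audit text to factor interpretation is reproducible
from a seed.

## The model

Q methodology is an inverted (by-person) factor analysis.  The observation
unit is a whole Q-sort: one participant's forced ranking of every statement
in the Q sample.  Here the "participants" (P set) are institutions, and a
sort expresses which environmental features an institution's published
imagery emphasizes.  Factoring the institution-by-institution correlation
matrix of sorts yields *shared viewpoints*: groups of institutions whose
rankings covary, interpreted through the statements their idealized sort
places at the extremes.

### Statement construction (`statements`)

1. Audit texts are split into sentences on terminal punctuation
   (`. ! ? ;` and the CJK equivalents), trimmed, and de-duplicated only of
   exact repeats within one record.
2. Sentences are embedded.  The default backend hashes lowercased word
   tokens into 4096 bins (scikit-learn murmurhash, fixed seed 0), applies
   TF-IDF weighting computed over the batch, and L2-normalizes rows.  It is
   deterministic and needs no model download; a sentence-transformer
   backend can be registered when richer semantics are wanted — backend
   choice is configuration, not core behavior.
3. PCA reduces the embedding to the smallest leading subspace holding 90%
   of variance by default (a noise filter; the exact target is a free
   parameter).
4. K-means (k-means++, 10 restarts, tol 1e-6, max 300 iterations) clusters
   the reduced sentences.  K can be fixed (default 18, three statements
   each → a 54-statement Q sample) or chosen on a grid by the joint rank of
   mean silhouette (descending) and Davies–Bouldin index (ascending), ties
   to the smaller K; the inertia elbow is reported as a diagnostic but does
   not drive the choice.
5. From each cluster the statements are the `per_cluster` sentences closest
   to their centroid that are *discriminative* — the margin (distance to
   the nearest other centroid minus distance to the own centroid) must be
   strictly positive — with near-duplicates (cosine > 0.95 in the original
   embedding space) dropped in favor of the more central sentence.

### Objective sorting (`qsort`)

Statements and record texts are embedded in one joint batch (so TF-IDF
document frequencies are frozen once per run), each institution is
represented by the L2-normalized mean of its record vectors, and the
institution-by-statement cosine matrix is computed.  Each institution's
scores are then forced into the fixed quasi-normal grid: the top
`count(+5)` scores receive +5, the next block +4, and so on down to −5.
The default 54-statement grid uses column counts `[2,3,5,6,7,8,7,6,5,3,2]`
over levels −5…+5; other statement counts get a rounded discretized-normal
grid, and any symmetric grid can be supplied.  Scores are used *only
ordinally* — any strictly increasing transform of a score row yields the
identical sort — so no calibration of cosine magnitudes is implied.  Ties
are broken by ascending statement index, making every sort bit-reproducible.

### Inverted factor analysis (`factors`)

* **Correlation.** Pearson correlations of the integer sort columns; the
  forced grid gives every column identical mean and variance by
  construction.
* **Extraction.** Eigendecomposition of the correlation matrix; the
  loading of sort *i* on factor *f* is `eigvec_if * sqrt(eigval_f)`.  Each
  column is sign-fixed so its largest-magnitude loading is positive
  (eigenvector sign is arbitrary; reports must be stable).  Explained
  variance per factor is `100 * eigenvalue / n_institutions`.
* **Loading significance.** `z / sqrt(n_statements)` with z = 2.58
  (two-sided P < 0.01) by default — 0.351 for a 54-statement sample.
* **Factor count.** The Kaiser–Guttman screen: candidate factors are the
  leading ones with eigenvalue strictly above 1.0 and at least two
  nominally significant loadings.  Candidates are then examined from the
  largest count down, and the admitted count is the largest k whose
  varimax-rotated k-factor solution keeps at least two *defining* sorts on
  every factor.  The refinement matters: when the panel is much larger
  than the statement count, sampling-noise eigenvalues of the correlation
  matrix sit well above 1.0 (a Marchenko–Pastur effect), so the raw
  eigenvalue rule alone always over-extracts; noise factors do not survive
  the defining-sort requirement.
* **Rotation.** Kaiser-normalized varimax via pairwise Jacobi sweeps
  (criterion non-decreasing; convergence when one sweep gains < 1e-8; the
  normalization can be disabled).  Optional manual Givens rotations of one
  factor pair by a stated angle (counterclockwise positive, the first
  factor of the pair on the abscissa) support the small judgmental
  adjustments customary in Q studies; both rotation kinds are appended to a
  rotation log so an analysis is replayable.  Communalities are invariant
  under all rotations (checked to 1e-9).
* **Defining sorts.** Sort *i* defines factor *f* iff `|loading| >
  threshold` and `loading² > communality/2` (strict).  The strict majority
  rule means a sort can define at most one factor.
* **Factor scores.** Brown's weights `w = f/(1−f²)` over a factor's
  defining sorts; the weighted statement averages are standardized to mean
  0, sd 1 across statements.  Factor arrays re-impose the forced grid on
  the z-scores.
* **Reliability.** Spearman–Brown composite
  `CR = r·p / (1 + (p−1)·r)` with per-sort reliability r = 0.80 and p the
  defining-sort count.  CR is rounded to 3 decimals *before* the standard
  error `SE = sqrt(1 − CR)` is taken; the unrounded form does not reproduce
  the conventional printed CR/SE tables, the rounded form does.
* **Distinguishing and consensus statements.** A statement distinguishes
  factor f at level α iff its z-score differs from *every* other factor's
  by more than `z_α · sqrt(SE_f² + SE_g²)` (z = 1.96 at 0.05, 2.58 at
  0.01; the stronger level is annotated, the D/D\* convention).  Consensus
  statements differ significantly between no pair of factors at 0.05.

## The synthetic study design (`synthetic`)

The generator emulates a panel of institutions publishing image-audit
texts under a planted orientation-type mixture:

* 18 statement categories, each with four slot-filled sentence templates
  sharing a category-specific anchor vocabulary (so a lexical embedding
  separates categories, by design — tests must not require model
  downloads).
* Four orientation types, each concentrating 70% of its sentence-category
  mass uniformly on its own block — interior comfort/safety (6
  categories), site layout and access (5), landscape/greenery (3),
  rehabilitation function (4) — and spreading 30% over the rest:
  facilities of every type still publish some images of everything.
* Default panel: `records_per_institution` uniform on 6–12 (matching a
  scraped-portal scale of roughly nine images per facility) and
  `sentences_per_record` uniform on 6–10, the size of a structured
  multi-indicator audit of one image.  With these defaults the four-type
  structure carries ~84–86% of the Q-sort correlation variance in the top
  four factors, the regime the method is designed for.  Shorter records
  (e.g. 3–6 sentences) leave category profiles so noisy that the type
  structure weakens to ~75% and small sub-factors appear.
* Type labels are balanced exactly (n/4 each) and shuffled; noise mixes
  each sentence's category with a uniform draw at rate 0.1 by default.
* Ground truth (labels + emphasis matrix + realized category counts)
  travels beside the corpus, never inside it.

What the generator does *not* emulate: natural-language variety beyond
slot filling, institution-level style, correlated noise across sentences
of one record, or mislabeled/mixed-type institutions.  Passing recovery
tests therefore show that the pipeline recovers a planted block structure
under realistic sampling noise — not that it would recover types from
arbitrary real-world text, where embedding quality becomes the binding
constraint.

## Numerical choices

* Eigen-decomposition is `numpy.linalg.eigh`; tiny negative eigenvalues of
  an (up to rounding) PSD correlation matrix are clipped at 0.
* PCA drops all-zero embedding columns first (a no-op on the result) and
  uses a full SVD up to 1024 effective dimensions, randomized SVD above.
* All K-means runs take an explicit seed; two runs with one config are
  bit-identical, which the run manifest's artifact checksums verify.
* Forced-distribution ties, statement-extraction ties and factor-array
  ties all break by ascending index; boundary cases use strict
  inequalities (margin ≤ 0 excluded; exactly half the communality not
  defining; eigenvalue exactly 1.0 not admitted).
* Brown weights clip |loading| at 0.999999 to avoid division blow-up for
  near-unit loadings.

## Problem sizes

The shipped tests and the acceptance script run the full synthetic study
at 200 institutions × 5 seeds (roughly 14,000 sentences per corpus, a few
seconds per seed), the scale at which the four-type recovery property is
calibrated; the oracle checks (varimax angle grid, characteristic
polynomial roots, grid conservation) use small matrices where brute force
is exact.

## Known limitations

* The Kaiser–Guttman refinement can admit a small extra factor (3–5
  defining sorts) on occasional seeds when sampling noise aligns a handful
  of same-type institutions with a statement-cluster split — the same kind
  of small factor real Q studies keep or merge by judgment.  It is
  reported honestly rather than suppressed.
* K-means clusters need not align one-to-one with the planted categories;
  blocks can receive unequal statement counts, which weakens (but in
  practice does not break) the corresponding factor's contrast.
* Parallel analysis, Humphrey's rule, centroid extraction, oblique
  rotations and bipolar factor splitting are deliberately out of scope.
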