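# Methods

## Normalization model

Expression values are log2-scale throughout. Normalization is two-stage,
both stages mapping values to *standard-deviation-from-the-median* units:

* **Stage 1 (per profile).** For each sample, x′ = (x − median)/SD over the
  profile's non-missing values. This removes per-sample location/scale
  effects (laboratory batch, loading differences). Profiles need ≥3
  non-missing values; a constant profile is a hard error naming the sample.
* **Stage 2 (per gene, within cancer type).** For each gene, within each
  cancer type's samples, x″ = (x′ − median)/SD. This removes
  tissue-dominant expression differences so that pan-cancer structure, not
  lineage, drives clustering. Genes with <3 values in a type become missing
  there; a zero-SD gene within a type is set to missing and logged rather
  than raising, because a bulk run must not die on one flat gene.

"SD" is the classical sample standard deviation (n−1 denominator) about the
mean; the phrase names the *unit*, not a robust estimator. A MAD-based
scale (×1.4826) is selectable via `scale="mad"` for heavy-tailed data.
External datasets to be classified get stage 2 only, applied to their raw
log2 values within their own cancer types: the classifier lives in
within-type-normalized coordinates, so the target must too.

Duplicate profiles of the same sample (e.g. the same tumor measured by two
laboratories) are averaged after normalization, missing-aware.

**Top-variable ranking** uses stage-1 (profile-normalized) values: per gene,
the SD across samples within each type where the gene is detected, averaged
over detected types. Stage-2 values cannot be used here — per-gene
standardization forces every SD to 1 and the ranking would be degenerate.
This resolution of the stage ambiguity is a deliberate design choice; the
alternative is selectable by passing stage-2 matrices explicitly.

## Synthetic study conditions

The generator's defaults are the package's study conditions: five cancer
types of 125/97/100/110/100 samples (532 total), 12 000 genes, ten
subtypes, 120 disjoint marker genes per subtype (strictly more than the 100
selected per subtype, so marker selection is well-posed), marker effect
+2.0 noise-SD units, per-(gene, type) tissue effects ~N(0, 1), per-sample
affine distortion with shift ∈ [−2, 2] and scale ∈ [0.5, 2] (exactly what
stage-1 normalization must undo), 10% per-(gene, type) dropout, and two
tissue-restricted subtypes (one breast-only, one renal-only, mirroring
basal-like-breast and clear-cell-renal-specific classes). Subtypes are
drawn uniformly over the subtypes allowed for each sample's type, so the
restricted subtypes are small (~10–15 cases). Noise is Gaussian; effect
sizes and mRNA–protein correlation magnitudes are calibration choices — no
published values exist for them — chosen so that markers are individually
detectable (t ≈ 10 for type-spanning subtypes) without making the
clustering trivial at the sample level (within-subtype sample correlation
≈ 0.12 over the top-2000 genes).

What the generator does *not* emulate: correlated gene modules beyond the
planted blocks, heavy-tailed or missing-not-at-random measurement error,
isoform/phospho-site structure, tumor purity gradients, or continuous
subtype boundaries. Passing tests therefore demonstrate the pipeline's
correctness and its robustness to the distortions modeled here — not
performance on real tumor cohorts.

The mRNA view is y = r·x + √(1−r²)·z per gene (z standard normal), giving
expected protein–mRNA correlation r (default 0.7); the RPPA view restricts
to a uniformly random panel of 169 genes. Real antibody panels are curated
toward informative proteins, so the random panel understates real RPPA
transfer performance; panel-classifier tests account for this.

## Consensus clustering

Monti-style resampling consensus: in each of `reps` iterations, a fraction
`p_item` = 0.8 of samples (and `p_feature` = 1.0 of features) is drawn
without replacement, pairwise distances 1 − Pearson (pairwise-complete over
shared non-missing features; degenerate pairs get distance 1) are clustered
by Ward linkage, and the tree is cut at every k in the scan range (the
resampling scheme is identical across k, so one tree serves all k).
Consensus M(i,j) = co-clustered / co-sampled; never-co-sampled pairs get 0
and are logged; the diagonal is 1. `reps`, `p_item`, `p_feature` are not
published values; 500/0.8/1.0 are the conventional defaults and all are
configurable. Ward runs on the Lance–Williams recurrence (scipy's
implementation); merge ties follow scipy's nearest-neighbor-chain order,
which is deterministic.

Final labels cluster 1 − M by Ward and renumber clusters by decreasing
size (ties: smallest member index); subtype names are `k1..kK`.

**k selection.** The per-k area under the empirical CDF of off-diagonal
consensus values is computed exactly (step-function integral), with delta
area the relative increase over k−1. The chosen k is configuration
(default 10); with `--auto-k` the elbow is the **argmin of delta area over
the interior of the scanned range**. Rationale: at the true cluster count
consensus is maximally stable and the marginal area gain collapses, while
past it inconsistent over-segmentation re-introduces area; on the default
synthetic conditions the delta curve falls monotonically to a sharp global
minimum at the planted k = 10 (delta ≈ 0.001 vs ≈ 0.009 at k = 9 and
k = 11) across seeds. This rule assumes the scan extends beyond the true
count and is reported as a diagnostic, never silently overriding the
configured k.

## Classifier

Marker selection ranks genes per subtype by the pooled-variance
subtype-vs-rest t statistic (candidates must have positive mean
difference); fold change is not used — t is consistent with the t-test
usage elsewhere in the pipeline and is configurable. A gene claimed by
several subtypes' top lists is awarded to the subtype with the larger t
(ties: earlier subtype in label order) and displaced subtypes refill from
their next candidates, so K subtypes × n markers yield exactly K·n unique
features when enough positive candidates exist. Centroids are missing-aware
means of normalized values per subtype.

Assignment computes Pearson correlation between a profile and each centroid
over mutually non-missing features and takes the argmax (ties: lower
subtype index). A profile becomes `unclassified` when fewer than
`min_overlap` = 10 features are usable or it has zero variance on the
shared features. A best-correlation threshold (default 0.05) additionally
routes patternless profiles to `unclassified`, but only when explicitly
enabled (`apply_fallback`): the rule belongs to reclassification against a
reference class system that contains a "patternless" class, not to
ordinary k-subtype assignment. The inequality direction (best r *below*
threshold → fallback) is the only reading consistent with a patternless
catch-all class; the opposite direction appears in print but would send the
*best-fitting* profiles to the patternless class.

Panel classifiers (RPPA-style) keep panel genes with subtype-vs-rest
p < 0.001 for ≥1 subtype and attribute each to its most over-expressed
subtype; with ~169 random panel genes this leaves ~15–20 features, so
`min_overlap` should be lowered accordingly.

## Statistics

* **t-tests**: pooled-variance Student t by default (the plain reading of
  "t-test"); Welch via flag. Zero pooled variance: t = 0, p = 1 at equal
  means, ±inf with p = 0 otherwise (logged).
* **q-values**: π̂0(λ) = #{p>λ}/(m(1−λ)) over λ = 0, 0.05, …, 0.90;
  the spline method smooths π̂0(λ) with a least-squares cubic polynomial
  evaluated at λ = 0.90 (the deterministic analogue of the customary
  df = 3 smoothing spline), clamped to (0, 1]; q(i) = π̂0·p(i)·m/i with
  step-up monotonization. π0 ≡ 1 reproduces Benjamini–Hochberg exactly.
  Multiple-testing universes are per contrast table (each subtype-vs-rest
  comparison is corrected on its own).
* **Enrichment**: one-sided hypergeometric tail P(X ≥ overlap) against an
  explicit background — by default the detection-filtered gene universe,
  never the whole genome.
* **Overlap significance**: per cell of the K×K co-assignment table, a
  one-sided Fisher test of (in a)×(in b) over the shared samples.
* **Permutation validation**: statistic = mean best-centroid correlation
  over samples; null = re-assignment after permuting gene labels of the
  target matrix within each cancer type (preserves per-sample value
  distributions while destroying gene identity — an interpretation, since
  the original construction is not printed; sample-label permutation is
  selectable); p = (1 + #{null ≥ observed})/(n_perm + 1).

## Signatures

Mean scores average the available normalized values of a set's genes per
sample. The composite pathway score (used for WNT) sums the antagonist,
agonist, and target component means; an unmatched component contributes 0
and is flagged. The t-score metric is a within-profile Welch t contrasting
up-set values against down-set values (against all remaining genes when no
down set exists), with a 1e-8 variance floor; the exact construction of
this metric is defined in prior literature available only by reference, so
both this up-vs-down form and a correlation-with-template alternative are
defensible — the up-vs-down form is implemented as the standard reading.
Signature gene lists are user-supplied as GMT (+ optional polarity table);
no curated lists are bundled. Display normalization maps each signature's
scores to SD-from-median units across samples.

## Numerical choices and degenerate inputs

Pairwise-complete Pearson is computed with masked matrix products (no pair
loops); correlations are clipped to [−1, 1] and non-finite values (too few
shared features, zero variance) become 0 → distance 1. Gene ids are opaque
strings matched exactly after optional alias-map translation. Missing
values are empty TSV cells, never sentinels. Matrices are genes-in-rows by
contract, not sniffed. All randomness flows from explicit integer seeds;
consensus resampling derives independent per-resample substreams from the
root seed so any resample is replayable by index.

## Problem sizes

The default test-suite discovery run uses the full 532-sample cohort with
100 consensus repetitions over k = 2..15; the acceptance script uses 50
repetitions at k = 10 only. Both recover the planted partition exactly at
the default effect size; repetitions in the hundreds mainly tighten the
consensus-CDF diagnostics, which the k-recovery test already passes at 100.

## Known limitations

Tied merge order in Ward follows scipy, so exact label permutations may
differ from other Lance–Williams implementations on tied inputs. The
elbow rule assumes the k scan brackets the true count. q-value estimation
is unreliable for very small m (<~50 tests), as is inherent to π0
estimation. The permutation scheme destroys gene–gene correlation, so its
null is conservative for strongly co-expressed panels. Phospho-site-level
analysis is out of scope; phospho data are treated as gene-level features
with their own detection rule (>50% of cases in ≥3 types).
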