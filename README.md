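# pancanproteo

Pan-cancer molecular subtyping from proteomic expression data: cohort
normalization, consensus-clustering subtype discovery, a nearest-centroid
correlation classifier for transferring subtypes across platforms and
cohorts, and the statistics used to characterize the resulting subtypes.

## The problem

Mass-spectrometry proteomics of hundreds of tumors across several
tissue-based cancer types makes it possible to ask which molecular classes
cut *across* tumor lineages at the protein level. Doing that credibly
requires a chain of specific methodology:

1. **Within-type normalization.** Log2 expression is normalized to
   *standard deviations from the median* — first within each sample profile
   (x′ = (x − median)/SD over the profile), then per gene across the samples
   of each cancer type — so that neither tissue-dominant differences nor
   per-sample location/scale batch effects drive unsupervised analysis.
2. **Subtype discovery.** Ward-linkage consensus clustering (resampled
   hierarchical clustering on 1 − Pearson distance) of the top 2000 most
   variable proteins, scanned over k = 2..15 with consensus-CDF diagnostics,
   with k = 10 the conventional choice at this cohort scale.
3. **Cross-platform classification.** For each subtype, the top 100
   over-expressed proteins (subtype-vs-rest t-tests, disjoint across
   subtypes with refill — 1000 features for 10 subtypes) define centroid
   profiles; any external profile (proteome, mRNA, or a small RPPA-style
   antibody panel), normalized within its own cancer types, is assigned to
   the subtype whose centroid it best correlates with (Pearson, pairwise-
   complete, with an "unclassified" fallback for degenerate profiles).
4. **Characterization and validation.** Subtype-vs-rest differential
   expression with Storey–Tibshirani q-values, one-sided Fisher-exact
   category enrichment against an explicit detection-filtered background,
   gene-signature scoring (mean scores, composite pathway scores, and a
   within-profile t-score), Fisher-exact overlap between labelings, and a
   permutation test of overall assignment strength.

Because consortium-scale tumor data cannot ship with a package, a
first-class synthetic-cohort generator reproduces the *structure* of such a
compendium — five cancer types of 125/97/100/110/100 cases, ten planted
subtypes (two tissue-restricted), disjoint marker blocks, tissue main
effects, per-sample affine batch distortions, per-(gene, type) dropout, and
attenuated mRNA / panel-restricted RPPA views — so every stage is testable
end to end against known ground truth.

## Worked example

Run the discovery arm on a small simulated three-subtype cohort:

```python
from pancanproteo.pipeline import PipelineConfig, run_discovery_pipeline

config = PipelineConfig(
    out_dir="demo",
    simulate=dict(type_sizes={"breast": 40, "colon": 32, "renal": 36},
                  n_genes=600, n_subtypes=3, markers_per_subtype=40,
                  effect_size=2.5, type_restricted_subtypes={},
                  missing_type_prob=0.05),
    k_min=2, k_max=6, chosen_k=3, reps=50,
    n_top_variable=200, markers_per_subtype=20, seed=7,
)
bundle = run_discovery_pipeline(config)
print(bundle["labels"].value_counts())
```

prints the discovered subtype sizes

```
k1    39
k2    38
k3    31
```

and writes `labels.tsv`, `model.json` (the centroid classifier: 60 features
= 3 subtypes × 20 markers), `diffexp.tsv`, `consensus_diagnostics.tsv`, and
a `manifest.json` hashing every output. On this run the consensus-CDF area
rises 0.471 → 0.670 from k = 2 to k = 3 and flattens beyond (delta area
0.086 at k = 4), the labels match the planted partition exactly
(adjusted Rand index 1.0), and the top k1 marker (`G00045`, t ≈ 15.8,
q ≈ 7e-27) is a planted k1 block gene. Deriving an mRNA view with per-gene
correlation attenuation r = 0.7, re-normalizing it within type, and
classifying it with the saved model reproduces 100% of the proteome
assignments — the cross-platform transfer the classifier exists for.

The same steps are available from the shell:

```bash
pancanproteo simulate --seed 7 --out-prefix sim/
pancanproteo normalize --input sim/expression.tsv --annotation sim/annotation.tsv --out norm.tsv
pancanproteo discover --input norm.tsv --annotation sim/annotation.tsv --k 10 --reps 500 --seed 1 --out labels.tsv
pancanproteo classify --model model.json --input external.tsv --annotation external_ann.tsv --out assignments.tsv
```

(plus `diffexp`, `enrich`, `signatures`, `overlap`, `permtest`, `run-all`).

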