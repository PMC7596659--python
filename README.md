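# chipbiome

Quantitative gut-microbiome profiling from **two-channel 16S rRNA
microarrays**, with the full downstream case/control analysis battery.

Phylogenetic microarrays hybridize a Cy5-labeled test sample against a
Cy3-labeled reference pool on an array whose oligo probes (printed in
triplicate) cover far more bacterial species than any one gut community
contains. `chipbiome` implements the spot-level quantification chain for
such arrays and everything a case/control microbiome study needs on top
of it — built for studies comparing patient and control cohorts (e.g.,
pediatric leukemia patients vs healthy children), and exercisable end to
end on synthetic cohorts with planted ground truth.

## The quantification rule

For each array, per species *s* with triplicate spot intensities:

- channel means: x̄₅(s), x̄₃(s); ratio r(s) = x̄₅(s)/x̄₃(s)
- background B = mean of x̄₅ over the lowest 30% of species ranked by
  mean signal intensity
- baseline ratio R = mean of the lower half of the r(s) ranking
- **positive detection** ⇔ x̄₅(s) > 5·B **and** r(s) > 5·R (both strict;
  the 5-fold factor is a parameter)
- relative abundance: a(s) = r(s) / Σ_{positive} r(t) for positive
  species, else 0

Background and baseline are per-array statistics — every hybridization
has its own reference mix.

## Downstream stages

| stage | method |
| --- | --- |
| `diversity` | Chao1, ACE, Shannon, Simpson + Wilcoxon rank-sum; Bray-Curtis → PCoA, NMDS (Kruskal stress-1), PERMANOVA |
| `differential` | LEfSe-style cascade: Kruskal-Wallis screen, bootstrap two-class LDA effect size (log₁₀, threshold 2.0) over the taxonomy |
| `classify` | random forest, leave-one-out CV, rank-formulation AUC with DeLong 95% CI, species/genus/family/order comparison, impurity importances |
| `validation` | qPCR ΔCt quantification 2^(Ct_universal − Ct_specific)×10⁴, array/qPCR concordance, species-cytokine Spearman correlations |
| `synthetic_data` | cohorts with log-normal communities, planted fold-changes, triplicate scanner noise, coupled cytokines, invertible Ct tables |

## Worked example

```python
from chipbiome import SimulationConfig, simulate_cohort
from chipbiome import array_quant, diversity, differential, classify

config = SimulationConfig(n_all=30, n_nc=20, n_species=80, n_differential=8,
                          fold_min=4.0, fold_max=4.0, seed=42)
cohort = simulate_cohort(config)
matrix = array_quant.quantify_cohort(cohort.spot_tables, cohort.manifest, fold=5.0)

dist = diversity.bray_curtis(matrix)
perm = diversity.permanova(dist, cohort.metadata.groups, n_permutations=999, seed=0)
lefse = differential.run_lefse(matrix, cohort.metadata.groups, seed=0)
scores = classify.loocv_scores(matrix, cohort.metadata.groups, n_trees=200, seed=0)
report = classify.roc_auc(scores, cohort.metadata.groups)
```

prints (via the obvious `print` statements):

```
detected species per sample (mean): 40.0
PERMANOVA pseudo-F = 53.67, p = 0.001
LEfSe reported 13 taxa; 8/8 planted species recovered
       taxon    rank         kw_p  lda_score enriched_group
Species_0045 species 3.198297e-09  -4.809719             NC
Species_0006 species 3.606936e-09   4.735324            ALL
Species_0013 species 3.606936e-09  -4.665121             NC
species-level LOOCV AUC = 1.000 (95% CI 1.000-1.000)
```

The cohort plants 8 species at a 4-fold group difference; the pipeline
separates the groups (PERMANOVA p = 0.001 at 999 permutations, the
smallest attainable), recovers all 8 planted species with the correct
direction of enrichment, and classifies the cohort perfectly — stronger
than a real study because the synthetic noise model is benign.

The same run is available as a CLI:

```bash
chipbiome run --out myrun          # full pipeline with default config
chipbiome simulate --out data --seed 1
chipbiome quantify --spots data/spots --manifest data/manifest.tsv --out quant
```

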