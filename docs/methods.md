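# Methods

## Detection calling and relative abundance

The quantification chain treats each hybridized array independently.
Triplicate spots of a species are averaged per channel and the species
ratio is the ratio of channel means (not the mean of spot ratios, which
would weight noisy dim spots equally). Two per-array statistics set the
detection floor:

- **background** — mean Cy5 of the dimmest `floor(0.3·S)` species
  (minimum 1), ranked by mean Cy5. The Cy3 channel is a reference pool
  that lights up every spot, so "signal intensity" for backgrounding is
  a test-channel notion.
- **baseline ratio** — mean of the lowest `floor(S/2)` defined ratios.

A species is positive when its mean Cy5 strictly exceeds `fold`×
background *and* its ratio strictly exceeds `fold`× baseline
(`fold = 5` by default, exposed as a parameter). Set sizes round down;
ranking ties break by species label, which fixes the selected set
reproducibly and can only matter when ties straddle the cut. Species
whose reference channel averages to zero have an undefined ratio, fail
the ratio pass, and are excluded from the baseline ranking. Relative
abundance renormalizes the ratios of positive species to 1; an array
with no positive call yields an all-zero row and a logged warning.

Consequences worth knowing: the chain is invariant to a common rescaling
of both channels (all comparisons are against per-array statistics), and
raising one species' Cy5 can never turn its own call negative. No
spot-level outlier rejection is applied; median aggregation was
considered and rejected to keep the chain identical to the mean-based
description it implements.

## Alpha and beta diversity

Shannon (natural log) and Simpson (1 − Σp²) are computed on the
compositional rows directly. Chao1 — S_obs + F1²/(2F2), with the
bias-corrected S_obs + F1(F1−1)/2 branch when F2 = 0 — and ACE (rare
cutoff 10, via scikit-bio) need singleton/doubleton counts, so rows are
rescaled to integer pseudo-counts (default total 10,000, rounded). The
pseudo-count total is a presentation choice, not an inference: it caps
how small a fraction can still register as a singleton. Group
differences per index use the two-sided Wilcoxon rank-sum test, exact
for small untied samples and tie-corrected normal otherwise.

Bray-Curtis distances feed three views: classical PCoA
(eigendecomposition of the double-centered −½D²; negative eigenvalues
are reported, not corrected, and excluded from the explained-variance
denominator), non-metric MDS (SMACOF majorization of Kruskal stress-1,
20 random starts by default, best solution kept), and PERMANOVA
(pseudo-F over free label permutations, p = (1+exceedances)/(1+perms),
999 permutations by default). PERMANOVA runs once, on the distance
matrix — it is a property of the distances, not of any ordination drawn
from them. A pair of all-zero samples has an undefined Bray-Curtis
quotient; it is defined as 0 (identical blanks) and flagged.

## Differential abundance (LEfSe cascade)

Two-class design: the Kruskal-Wallis screen (tie-corrected H, chi-square
p; for two groups this is the rank-sum test) at `alpha = 0.05`, then
bootstrap LDA effect sizes on taxa passing the screen. Abundances are
rescaled so each sample totals 10⁶; each of 30 rounds subsamples 2/3 of
every class (at least 2) without replacement and fits a joint LDA over
the screened taxa. A taxon's per-round effect is the mean of its
absolute raw between-class difference and its share of the class
separation along the unit discriminant axis; the reported score is
log₁₀(1 + mean effect), signed toward the group with the higher mean,
thresholded at 2.0. Subsampling is keyed by per-sample uniform draws, so
relabelling the groups changes nothing but the sign. Singular
within-class scatter falls back to shrinkage LDA and is flagged. With no
subclass structure the subclass Wilcoxon step of the published cascade
is an identity pass-through (a hook exists for subclasses). No
multiple-testing correction by default (cascade convention); a
Benjamini-Hochberg screen is available. The cladogram table re-runs the
cascade on abundances aggregated to genus, family and order and
annotates species-level hits with their lineage.

## Classification

Supervised random forests (500 trees by default, √p feature
subsampling) under leave-one-out cross-validation; the out-of-fold score
is the fraction of trees voting for the case class, with the same forest
seed in every fold. AUC uses the rank (Mann-Whitney) formulation with
ties counted ½, and its 95% CI the DeLong structural-components
estimator (validated against an independent reference implementation on
a frozen instance). Rank comparison repeats the full procedure per
taxonomic level; importances are mean decrease in impurity from a forest
on all samples. The published description of the classifier as
"unsupervised" is not implementable alongside ROC evaluation; labels are
used for training.

## qPCR and cytokine validation

ΔCt relative abundance is 2^(Ct_universal − Ct_specific) × 10⁴: equal
cycles mean the target is one part in 10⁴ of total 16S copies, and each
cycle of difference doubles or halves that share. Censored reactions
(no amplification by the cycle ceiling, 45) report 0 and are excluded
from platform correlations rather than imputed. Platform concordance
reports per-target group p-values on each platform, the sign agreement
of group-median differences, and the cross-sample Spearman correlation.
Species-cytokine associations are Spearman correlations (average-rank
ties, two-sided t-approximation p) computed within the case group by
default, starred at p < 0.05 / p < 0.01 with a BH-adjusted column
alongside — raw p is the display convention, the adjusted column the
honest one.

## Synthetic cohorts

The generator emulates the observable structure of a two-channel array
study; one integer seed drives stage-keyed RNG streams, so a
configuration reproduces byte-identical artifacts.

- **Design**: 58 cases ("ALL") vs 23 controls ("NC") by default.
- **Community**: the array has `n_species` probes (default 150) but the
  community populates only `present_fraction` of them (default 0.5,
  log-normal σ = 1 over present species, normalized). The structural
  zeros matter: real arrays probe ~1,500 species while a gut community
  holds a few hundred, and it is those absent probes that make the
  lowest-30% statistic estimate true background. With every probe
  populated, the background absorbs dim real species and detection
  collapses — a property of the calling rule, not a bug.
- **Group effect**: `n_differential` species (default 15) drawn from the
  better-represented half of the community, fold-changes uniform on
  [2, 8] by default, enriched group alternating; applied before
  per-sample renormalization, so the effect is compositional. Per-sample
  dispersion is log-normal (σ = 0.4).
- **Spots**: triplicate printing; Cy5 = background (100) + signal scale
  (10⁶) × abundance, each term with unit-mean multiplicative log-normal
  noise at the configured CV (default 0.15); Cy3 = reference level (500)
  with the same noise model. Absent species are background-only.
- **Cytokines**: value = serum baseline + slope × coupled-species
  abundance + Gaussian noise (30% of baseline by default); slopes are
  scaled so a doubling of the species moves the cytokine by its
  baseline. Couplings default to the planted differential species.
- **Ct tables**: Ct_specific = Ct_universal − log₂(abundance) + noise,
  averaged over two replicate wells, censored at cycle 45 — constructed
  so the ΔCt formula inverts exactly to the planted abundance at zero
  noise.

What the generator does *not* emulate: cross-hybridization between
probes, scanner saturation, compositional count noise (sequencing-style
sampling), covariate structure (age, diet), or batch effects. Passing
tests therefore demonstrate correctness of the algorithms under a clean
noise model, not robustness to every artifact of real arrays.

## Verification design and problem sizes

The detection chain is checked for exact equivalence (flags and
abundances to 1e-12) against an independently coded plain-loop
transcription on 200 random ≤12-species instances, and at the exact
5-fold boundaries (strictly negative at the bound, positive just above).
Null calibration uses cohorts with no planted effect at the 58v23
design: the KW screen pooled over 200 cohorts and PERMANOVA over 1,000
random label assignments hold a 5% ± 2 points rejection rate, and mean
LOOCV AUC over 50 cohorts stays within 0.5 ± 0.05 (60-species arrays,
25-tree forests — forest size affects cost, not the null). Signal
recovery runs 50 cohorts at 150 species / 15 differential at fold 4 /
CV 0.15: PERMANOVA rejects in ≥95% of seeds, the LEfSe stage recovers
≥80% of planted species with the correct direction, and species-level
AUC reaches 0.80 in ≥90% of seeds and is not beaten by the genus level
when opposite fold-changes are planted on species pairs sharing a genus.

## Known limitations

- The "third pass" of the published positivity description is taken to
  be the conjunction of the two described filters; no third criterion is
  defined anywhere.
- Chao1/ACE on pseudo-counts are rank-preserving transforms of the
  composition, not true richness inference from counts.
- DeLong intervals degenerate (width 0) when LOOCV separates the classes
  perfectly; they are clipped to [0, 1].
- The LEfSe effect-size magnitude depends on the 10⁶ rescaling
  convention; scores are comparable within a run, not across rescalings.
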