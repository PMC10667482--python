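# Methods

This note documents the statistical procedures `microconfig` implements, the
generative model behind its synthetic cohorts, the defaults and why they were
chosen, and the package's numerical conventions and limitations.

## The analysis model

**Genus-level scope and prevalence filtering.** All analysis operates on a
genus-by-sample table; working at the genus level suppresses dataset-specific
noise when cohorts from different sequencing runs are pooled. Genera present
(count strictly > 0) in fewer than 10% of samples are removed; the boundary is
inclusive, so a genus in exactly 10% of samples survives. The filter is
idempotent and by default pools all samples (a per-study option exists, since
either reading of "present in 10% of samples" is defensible when two studies
are merged).

**Rank normalisation.** Wherever abundances enter a procedure that should be
insensitive to their heavy-tailed scale (stratification, the random forest,
the differential screen), each genus is transformed by
`(rank(x) − min rank(x)) / (max rank(x) − min rank(x))` with average ranks for
ties, mapping every non-constant vector onto [0, 1]. A constant vector has
zero rank range; it maps to all-zeros with a warning rather than halting a
pipeline on a degenerate simulated genus.

**Dissimilarities.** Community dissimilarity is Bray–Curtis,
`Σ|x−y| / Σ(x+y)` over genera, computed on per-sample proportions by default
(a flag allows raw counts; the choice is a convention, not a claim about which
is "right"). Dietary dissimilarity is `(1 − τ_b)/2` over the food items of a
sample pair; τ_b (tie-corrected) is used because food-frequency data are
heavily tied, and the affine map puts the distance in [0, 1]. The pairwise
τ_b matrix is computed through item-pair sign vectors
(`τ_b(i,j) = ⟨s_i, s_j⟩ / √(‖s_i‖²‖s_j‖²)` with
`s_i[ab] = sign(x_i[a] − x_i[b])`), which is exactly tie-corrected τ_b and
turns the all-pairs computation into one matrix product.

**PCoA.** Classical metric scaling: Gower double-centering
`B = −½ J D² J`, eigendecomposition, coordinates scaled by the square root of
positive eigenvalues. Bray–Curtis and Kendall distances are non-Euclidean, so
negative eigenvalues occur; they are excluded from the explained-variance
denominator (fractions stay in [0, 1]) and reported. Axis signs are fixed by
making the largest-magnitude loading positive, so results are deterministic.

**The median-centroid distance.** For a reference group, the coordinate-wise
median of its samples on the first two principal coordinates defines a robust
centroid; every sample's statistic is its Euclidean distance to that point in
the PCo1–PCo2 plane (reference samples included). The first two axes are used
because that is the plane in which the ordination is interpreted; a flag
allows k-axis distances. Group differences in the distance are tested
nonparametrically (Kruskal–Wallis + Dunn, BH-corrected; Wilcoxon for two
groups).

**PERMANOVA.** Sequential (Type-I) partitioning of the Gower-centred matrix:
confounders enter before the term of interest, each term's sum of squares is
`tr((H_j − H_{j−1}) G)` with hat matrices from QR decompositions, and the
pseudo-F of the term of interest is referred to free permutations of the
samples, `p = (1 + #{F* ≥ F}) / (1 + n_perm)` so p can never be exactly zero.
Two adjustment mechanisms are provided, because "controlling for" a covariate
in PERMANOVA is ambiguous: (i) the covariate as a df-consuming term entered
first, and (ii) the covariate as a permutation stratum. When a term saturates
the design — the canonical case is the patient identifier with group constant
within patient, which drives the group term to zero df — it is demoted from
(i) to (ii) automatically with a warning. Stratified permutation exchanges
samples within strata when the term of interest varies within them; when it
is constant within strata (group within patient), whole strata of equal size
are exchanged instead, preserving the within-patient correlation structure.

**Co-abundance groups.** Genus–genus Spearman correlation, dissimilarity
`1 − ρ`, Ward-D2 agglomeration (scipy's `linkage(method="ward")` on the
precomputed dissimilarity, the same update rule as R's `hclust(…, "ward.D2")`
on the same input), dendrogram cut at k = 4. Ward on this non-Euclidean
dissimilarity is accepted as-is, mirroring common practice; a square-root
pre-transform option restores Euclidean validity. Cluster ids are renumbered
in order of first appearance along the genus list, so the assignment is
deterministic; biological naming is left to the user via an optional label
map. CAG–centroid association defaults to member-wise correlations (one ρ per
genus, grouped by CAG, suitable for distributional comparison); a summed
per-CAG mode exists.

**Stratification.** Within one group: rank-normalise each genus across the
subgroup, compute sample–sample Spearman correlation of the profiles, cluster
`1 − ρ` with Ward-D2, cut at k = 2. k is fixed at two (the configuration
dichotomy is the hypothesis under test); a gap-statistic diagnostic is
reported but never changes k. The cluster whose members lie closer (smaller
mean, ties by median, a further tie is an error) to the control median
centroid of the full-cohort ordination is labelled NM-like, the other
CDM-like. Mean rather than median distance is the primary criterion because
it is strictly ordered in practice at the n≈20–35 cluster sizes involved. A
silhouette width below 0.3 triggers a warning that the split may be
arbitrary; the threshold was calibrated on single-configuration null
simulations, whose silhouettes stay in 0.10–0.29 (n = 30–55) while planted
two-configuration cohorts sit above 0.40. Replication on an external cohort
reuses the identical clustering and labels the clusters by the summed
relative abundance of user-supplied marker-genus sets (normal-associated vs
CD-associated; each set must overlap the external genus universe by ≥ 50%),
with Wilcoxon comparisons of both sets between clusters.

**Classification and covariate screening.** The random forest trains on
rank-normalised abundances; the error rate is reported as out-of-bag error
(a cross-validation alternative exists), held-out samples are assigned by
majority vote at threshold 0.5, and importance is mean impurity decrease
signed by which class has the higher mean abundance. The
differential-abundance screen is a per-genus Wilcoxon/Kruskal–Wallis on
rank-normalised proportions with BH correction — deliberately simple, clearly
labelled "NOT ANCOMBC" in every output, with an importer for externally
computed bias-corrected results. Covariate models are one logistic fit per
exposure: outcome = configuration label, fixed adjusters (age, age at
diagnosis, gender, Hurley score, surgery, antibiotics, current/previous
anti-TNFα, immunomodulator), per-term likelihood-ratio p, BH q across the
model's terms. Binary exposures require ≥ 20% prevalence; continuous (diet)
exposures require |Cohen's d| ≥ 0.5 between the outcome groups.
Quasi-separation (|estimate| > 10 with SE > 100) is flagged rather than
reported as a stable estimate, with an optional L2-penalised refit supplying
a finite coefficient. Note that with n≈55 and eleven parameters the LR
chi-square approximation is mildly anticonservative — a small-sample property
of any maximum-likelihood fit, visible in calibration simulations at that
size and absent by n = 200.

**Marker associations.** Linear regression marker ~ genus for every pair in
the differential set (pairwise-complete, n per edge, BH across the grid), and
a compositionality-corrected correlation in the ReBoot/CCREPE spirit:
observed measure Spearman ρ between the ranked marker and the genus
proportion; null from permuting the genus across samples and renormalising
every composition to sum 1; p from a two-sided normal tail of the observed ρ
against the null mean and sd. This is a simplification of the full
bootstrap-plus-permutation procedure of the original package — the permutation
half only — documented as a variant. Only the permuted genus's renormalised
column `x_perm / (1 − x + x_perm)` is needed for the correlation, which keeps
the null vectorised; the full renormalised matrix is exposed separately for
invariant checks. For a genus that dominates the community the null mean is
materially nonzero — that offset is precisely the compositional correction —
while for genera under a few percent of the community it vanishes
(|mean| < 0.02 at n_perm = 1000, n = 55). Spearman is the similarity measure
because the markers enter ranked.

**Multiple testing.** All families are corrected with Benjamini–Hochberg
step-up. Families are: Dunn pairwise comparisons within one omnibus test;
genera within one differential screen; terms within one logistic model; the
full item×pair grid for dietary tests; the full marker×genus grid for
associations. Each function documents its family.

## The synthetic-cohort generator

The generator exists so that every stage can be tested against known ground
truth without any sequence download. It emulates the pooled-study design the
pipeline targets; all planted quantities are recorded in a `TruthRecord`.

**Counts.** Genera belong to `n_blocks = 4` co-abundance blocks. For sample
*i* and genus *g* in block *b*:

```
log λ_ig = base_g + latent_sd · (√ρ · z_ib + √(1−ρ) · ε_ig)
         + effect_g · [configuration_i = CD-like]
         + patient_ig + study_ig
```

with `ρ = block_corr = 0.7`, `z_ib ~ N(0,1)` the per-sample block factor,
`base_g ~ N(0, 1.5)` a log-normal abundance spectrum, patient and study
effects `N(0, 0.25²)` and `N(0, 0.2²)` per genus. Compositions
`p_i = softmax(log λ_i)` are converted to multinomial counts at a log-normal
depth (median 20 000, σ = 0.35, floor 1 000), so per-sample depth matches the
drawn depth exactly. Longitudinal replicates share the patient effect, which
is what makes the patient-identifier confounder in PERMANOVA meaningful.

**Configurations.** Controls carry the normal configuration, CD patients the
CD-like one, and each HS patient is CD-like with probability 0.4. The
configuration effect shifts 30 "CD-associated" genera up and 30
"normal-associated" genera down by `config_effect = 2.5` natural-log units
(~12-fold). Defaults were chosen once for realism and recoverability: roughly
half the genera differing between configurations matches what genus-level
dysbiosis comparisons report, ~10-fold shifts are typical of hallmark taxa
(*Faecalibacterium* depletion, Enterobacteriaceae expansion), pathogen genera
are rare at baseline (−1.5 on the base log-mean) and the informative
commensals common (+0.5) — in a healthy community pathogens are minority
members, and this asymmetry is what makes a CD-like bloom conspicuous.

**Diet, covariates, markers.** Food frequencies are log-normal per item, with
ten "Western" items shifted +1 noise-sd in both disease groups and carbonated
soft drinks additionally tracking the CD-like configuration; 15% of
item×person cells are zeroed (never consumed). Binary drug covariates follow
logistic links to the configuration with planted odds ratios — antibiotics OR
4 (base rate 0.35; antibiotics are first-line HS therapy, so a high
background rate is the realistic regime) and cardiovascular drugs OR 0.25
(higher in NM patients, who are also planted 8 years older). Ten inflammatory
markers are generated for HS samples; six are latently coupled (|r| = 0.6) to
chosen genera or to the summed normal-genus abundance (Gas6 positively — so
lower in CD-like patients; IL-12 negatively to a commensal), the rest are
noise, and all are exponentiated to positive assay-like scales.

**What the generator does not emulate.** Real 16S data have sparser, more
overdispersed counts than a multinomial over log-normal intensities,
phylogenetic correlation between genera, ecological successions over time
(replicates here differ only by noise around a patient effect), measurement
batch effects beyond a per-study genus shift, and any relationship between
diet and the microbiota itself (diet and community composition are coupled
only through the shared configuration label). Passing the recovery tests
therefore shows the procedures are implemented correctly and behave sanely at
realistic effect sizes — not that they would achieve the same accuracy on
real cohorts.

## Numerical conventions

- Presence for the prevalence filter is count > 0; no pseudo-counts.
- Constant vectors: rank normalisation returns zeros with a warning; Spearman
  correlations involving a constant vector are set to 0 with a warning and a
  unit diagonal; constant genera are excluded from the differential screen;
  constant covariates/food items are dropped from correlation grids.
- Wilcoxon rank-sum uses exact enumeration when n₁+n₂ ≤ 12 and the data are
  tie-free, otherwise the normal approximation with tie and continuity
  correction. Simpson diversity is the Gini–Simpson index 1 − Σp². Alpha
  diversity is computed without rarefaction by default; a fixed-seed
  rarefaction option exists.
- Eigenvalues below `1e-10 · max(λ)` are treated as zero in PCoA; design
  ranks in PERMANOVA use the analogous QR tolerance.
- Ward agglomeration tie-breaking follows scipy's deterministic
  lowest-index-first order; cluster ids are stable by first appearance.
- One global seed expands to per-stage seeds via
  `SeedSequence(seed, spawn_key=(stage_index,))`; every stochastic output is
  bit-reproducible under a fixed configuration, and each stage re-run
  standalone with its manifest seed reproduces its output.

## Known limitations

- The differential-abundance screen does not correct compositional bias; it
  is a transparent rank-based stand-in and labels itself as such.
- The CCREPE-style null uses the permutation–renormalisation half of the
  original procedure with a normal tail; extremely non-normal null shapes
  (tiny n, extreme dominance) would distort tail p-values.
- The logistic LR p is anticonservative at n≈55 with the full adjuster set
  (see above); at that size the q-values should be read as approximate, and
  detection power for a single OR-4 binary exposure at q < 0.1 is
  intrinsically limited (~0.5 in simulation).
- PERMANOVA's stratified block exchange requires same-size strata to swap;
  cohorts where every patient has a unique replicate count would leave few
  exchangeable blocks and a coarse permutation null.
- Stratification fixes k = 2 by design; cohorts with more than two genuine
  configurations will be forced into a dichotomy (the silhouette warning and
  gap diagnostic are the guards).
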