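# Methods

This note documents the statistical procedures, the synthetic-data models
behind the test suite, and the numerical/design choices where the
literature or common practice leaves the design open.

## Screen effect estimation

For each (strain, feature) cell the effect is the robust standardized
median difference θ = (median_strain − median_NB) / MAD_NB, with the MAD
scaled by 1.4826 to be SD-consistent under normality. A zero control MAD
falls back to the pooled SD of both arms (with a warning); if both are
zero the data are all tied and θ = 0. θ was preferred over a log median
ratio because screen features mix signed quantities (angles, distances)
with counts.

P-values come from the two-sided rank-sum (Mann–Whitney) test. The
experimental design — independent plants in the strain and control arms —
is unpaired, so the unpaired test is the default even though paired
("signed-rank") testing of strain values against the control median is
available as an option. With both arms ≤ 8 observations the p-value is
computed by exact enumeration of all C(n1+n2, n1) arm assignments over
pooled midranks (ties exact); larger arms use the tie-corrected normal
approximation with continuity correction. The two-sided p doubles the
smaller tail and caps at 1.

BH correction is applied jointly across all (strain, feature) cells — one
screen, one family. Direction (+/−/0) is the sign of θ gated at q < α.

**Recovery metrics.** Screen recovery is reported at the two levels at
which such screens are read: *sensitivity at the strain level* (an active
strain is recovered iff at least one feature is significant — the unit in
which "fraction of strains altering the root" is stated) and *empirical
FDR at the cell level*, where the q-values are defined and BH control
holds. A strain-level FDR of the "any of 21 features" call is not
controlled by cell-level BH (no procedure that corrects per cell bounds
it), and a cell-level sensitivity is not a meaningful target under the
latent-effect generator, where a random latent direction necessarily
leaves some features with near-zero planted shift regardless of effect
size.

## Feature deduplication and strain clustering

Pearson correlations between features are computed across per-strain mean
feature values (control included), since strain-level response — not
plant-level noise — is what makes two features redundant. Features are
clustered with average linkage on distance 1 − r and the tree is cut at
0.3 (config); within each cluster the feature with the highest
coefficient of variation (SD/|mean| of per-strain means; error if
|mean| < 1e-12) is the marker, ties broken lexicographically. Constant
features get singleton clusters with a warning. Strains are then
clustered on the marker-effect matrix (Euclidean distance, average
linkage, tree cut to exactly k clusters; default k = 24). All clustering
is deterministic given the input.

## PERMANOVA

Pseudo-F on Euclidean distances between strain effect vectors, with
R² = SS_between / SS_total and a label-permutation p-value using the
convention p = (1 + #{F* ≥ F}) / (1 + n_perm), explicit seed, default
n_perm = 999. Groups with one member are dropped with a warning. The
implementation is in-repo (~40 lines) so the permutation convention and
seeding are under the package's control; it is cross-checked against
scikit-bio's PERMANOVA in the test suite.

## Dunnett many-to-one comparisons

Studentized mean differences against the control under the one-way model
(pooled residual variance, df = N − g). The family-wise adjustment is
Monte-Carlo rather than numeric multivariate-t integration: the null
distribution of max|t| is simulated at the observed arm sizes and df
(group means ~ N(0, 1/n_j), variance ~ χ²_df/df), and the adjusted p is
(1 + #{max|t*| ≥ |t_i|}) / (1 + n_mc) with an explicit seed
(n_mc = 100,000 for analysis, 10,000 in tests). The MC estimate is
floored at the analytic pooled-t p, which makes the single-comparison
reduction exact and enforces adjusted ≥ unadjusted against MC noise.
Zero pooled variance is handled as exact ties (p = 1 when the difference
is 0, minimal p otherwise). When several families (e.g. genotypes) are
analyzed together, BH runs across the pooled adjusted p-values. Count
responses (bifurcations, primordia totals) enter the same machinery on
raw counts — the analysis mirrors how such panels are reported, not a
count GLM.

Compact letter displays use all-pairs Tukey HSD (scipy) followed by
insert-and-absorb lettering with groups processed in descending-mean
order, so letters are invariant to input order and two groups share a
letter iff their Tukey-adjusted p ≥ α.

## Differential expression

Counts are normalized to log2 CPM, log2((c + 0.5)/(lib + 1) × 1e6). Per
gene and contrast, a moderated two-sample t: the pooled variance s² (d
residual df) is shrunk toward s0², the median of all gene variances, as
s̃² = (d0·s0² + d·s²)/(d0 + d), with p from a t on d0 + d df. The prior
weight d0 defaults to 4; d0 = 0 recovers the ordinary pooled t. BH runs
within each (genotype, treatment) contrast, matching per-bacterium
comparisons. "Differentially expressed" defaults to q < 0.05 and
|log2FC| ≥ 1. The moderated test is implemented in-repo so the pipeline
is self-contained and the shrinkage is exactly the documented formula.

Total-count normalization carries the usual composition caveat: if an
unbalanced fraction of the library shifts, log2 CPM fold changes absorb
a small offset (≈ log2 of the library inflation). The planted designs
used in validation are composition-balanced (induced and repressed
modules of equal size), as is typical of genuine transcriptomes.

## Hierarchical gene filter

Stage 1: union over treatments of wild-type DEG sets (both signs).
Stage 2: keep genes significant (direction-agnostic) in ≥ m mutant
genotypes for ≥ s treatments (defaults m = s = 1). The retained set is
the genes whose response does *not* require the mutated auxin-signaling
components — the biological target of the filter; the complement rule is
available as `exclude-shared`. Stage 3: per gene, Pearson r between the
wild-type log2FC vector across treatments and the per-treatment LR
phenotype; keep |r| ≥ 0.5 with BH q < 0.05 across the stage-2 genes, and
split by sign into induced/repressed panels. Genes with constant log2FC
are excluded with a warning; a constant phenotype vector is an error.
A FilterTrace records (stage, count, gene set) and enforces that each
stage is a subset of the previous one.

Note that on cleanly planted data stage 3 may remove nothing (every
module gene's log2FC vector is proportional to the strain-effect vector),
so trace counts are nonincreasing but not necessarily strictly
decreasing between stages 2 and 3.

Final-panel utilities: two-way average-linkage clustering on 1 − Pearson
distance (gene tree cut at k = 2, induced/repressed), the high-fold
subset (max wild-type log2FC ≥ 3, inclusive), and standardized panel
summaries (per-gene z-scores across samples, control vs bacteria-average
group means, and the panel-level mean μ per group).

## Enrichment

Hypergeometric tails: enrichment P(overlap ≥ k), depletion
P(overlap ≤ k), given universe, set, and query sizes; expected overlap
|q||s|/|U| and fold k/expected. The universe defaults to all genes in the
expression matrix; BH runs across the whole (query × set) panel, and the
reported percentage is 100·k/|query|. GMT reading validates the 3-field
minimum per line with line-numbered errors.

## Synthetic data

All generators take one explicit seed, use one private RNG stream, and
are byte-deterministic. The control condition is always "NB" and always
simulated.

* **Screen** (`simulate_screen`): plant feature vectors are
  baseline + Λ(e_s·u_s) + ε with loadings Λ (features × latents,
  N(0, loading_scale²), fixed per seed), a random unit latent direction
  u_s per active strain, and N(0, noise_sd²) residuals. Defaults emulate
  the study scale: 391 strains × 21 features × 10 plants, 3 latent
  factors (feature redundancy), active fraction 0.5, effect 2 in residual
  SD units, noise SD 1. The latent-factor construction yields correlated
  features and heterogeneous per-feature effects; it does not emulate
  feature-specific units, plate/batch structure, or non-Gaussian tails,
  so passing tests demonstrate recovery of the planted low-rank effect
  structure, not robustness to those real-data features.
* **Genotype panel** (`simulate_genotype_panel`): Gaussian responses
  (e.g. LR density) with additive strain shifts, or Poisson counts (e.g.
  bifurcations) with shifts on the log mean; only responsive genotypes
  see the shift. A companion `simulate_primordia` generates per-stage
  Poisson counts (stages I–VII/E) where active strains multiply the
  early-stage and emergence rates.
* **Expression** (`simulate_expression`): NB(mean, dispersion φ) with
  variance μ + φμ², so planted log2 fold changes are exact on the mean
  scale (φ = 0.05, baseline mean 200, log-normal library factors
  σ = 0.3 to make normalization non-trivial). Planted modules:
  `independent` (log2FC a_g·e_s in all genotypes), `wt_only` (wild type
  only), `defense` (−a_g·e_s everywhere); gene sensitivities a_g uniform
  in [0.75, 1.25] by default. The default design is 2,000 genes with
  40/40/40 modules, 16 strains + NB, wild type + 4 mutants, 3 replicates.
* **Gene sets** (`simulate_gene_sets`): per planted module, a "core" set
  with configurable recall and precision (true members sampled at the
  recall rate, non-members spiked to hit the precision); decoy sets are
  drawn uniformly from the whole universe so decoy–module overlap has the
  calibrated hypergeometric null — drawing decoys only from non-module
  genes would make decoy tests trivially conservative.
* **Taxonomy** (`simulate_taxonomy`): balanced groups and a regenerated
  strain-effect vector e = √s·m_group + √(1−s)·z with standardized group
  means and residuals, so the between-group variance share is the planted
  `group_signal` (exactly 1 when s = 1). Regeneration, rather than
  relabeling fixed effects, is what makes an exact planted variance
  fraction possible. An independent binary operon label is emitted with
  no association to the effects.

## Pipeline and reproducibility

`run-all` executes simulate → screen → genotype → de → filter → enrich
from a YAML config (all thresholds in config, none hard-coded), validates
every input table first (schema, control presence, duplicates), and
writes a manifest with version, seed, parameters and stage counts.
Reruns with the same config are byte-identical for every artifact except
the manifest timestamp; floats are serialized at full precision
(`%.17g`).

Validation problem sizes are chosen to keep the full suite and the
acceptance script fast on a single CPU: calibration simulations use
vectorized implementations at the study-scale designs (391 × 21 screen,
2,000-gene expression bundles, 2,000-seed Dunnett null), with permutation
counts reduced where the measured quantity (e.g. PERMANOVA R²) does not
depend on them.

## Known limitations

* The screen statistics treat replicates as independent plants (the
  panels are reported that way); no mixed-effects or plate-blocking
  model is fitted.
* Total-count normalization is the only option; strongly unbalanced
  transcriptional shifts would bias log2FC as noted above.
* Dunnett adjustment is Monte-Carlo: adjusted p-values carry O(1/√n_mc)
  noise and a resolution floor of 1/(n_mc + 1).
* The hierarchical filter's stage-2/3 thresholds are screen-design
  choices; the package makes them explicit config rather than claiming
  canonical values.
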