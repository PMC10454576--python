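# Methods

## Composite salt-tolerance evaluation

Per-trait salt tolerance indices STI = mean(salt) / mean(control) are
computed after arithmetic averaging of biological replicates (the
convention for n = 3 replicate designs; no other aggregation is supported).
Traits whose control mean is zero have no defined ratio and are dropped
with a warning, so the STI matrix entering PCA is complete.

PCA is run on the column-standardized STI matrix, i.e. on the trait
correlation matrix: the composite must not depend on trait units, and
min–max membership plus correlation-PCA makes the whole index invariant
under positive affine rescaling of any trait (a property the test suite
asserts). Components are retained up to an 80% cumulative contribution
(smallest k with Σ P_i ≥ 0.80) and weighted W_i = P_i / Σ_{j≤k} P_j.
Renormalizing over the retained components — rather than over all
components — keeps CSTI a convex combination of memberships and hence in
[0, 1].

Eigenvector sign is arbitrary, so two deterministic conventions are
applied: each component is oriented so its largest-magnitude loading is
positive, and then each retained component is given a tolerance direction —
positive if the signed sum of its loadings (positive-direction traits minus
negative-direction traits) is nonnegative, else its membership is inverted.
Trait directions default to negative for Na content and Na-numerator ratios
(Na accumulation correlates negatively with tolerance) and positive
otherwise, fully overridable. A degenerate membership range
(x_max = x_min) is defined as 0.5: a constant axis carries no ranking
information and must not push any genotype toward either extreme.

Two readings of the composite exist in the crop-phenotyping literature.
The default (`membership_level="component"`) applies membership to the
retained principal-component scores — the D-value method. The alternative
(`membership_level="trait"`) applies membership per trait and weights
traits by their PCA-contribution-weighted squared loadings,
W_t ∝ Σ_{k≤K} P_k L_tk², normalized to 1; squared loadings are used because
they are the trait's share of the component's variance, keeping the
trait-level composite a convex combination too. Both are exposed because
published descriptions of the method drift between the two; the default is
the component-score reading.

Grading uses agglomerative clustering (Euclidean, Ward by default;
average/complete selectable) of the 1-D CSTI values into three classes,
labelled by descending class mean: salt-resistant > salt-tolerant >
salt-sensitive. All-equal CSTI values are rejected as degenerate rather
than broken arbitrarily. Ties are resolved by processing genotypes in
identifier order.

## DEG screen

A DEG is FDR ≤ 0.05 and |log2FC| ≥ 1. Thresholds are inclusive — the
boundary convention has to be fixed somewhere, and inclusive matches the
"at least 2-fold" phrasing — and both are configurable. The four rules per
timepoint t (tolerant genotype T, sensitive genotype S, baseline 0):

* R1: DEG in S-t vs T-t;
* R2: DEG in T-t vs T-0;
* R3: up-DEG in both T-t vs T-0 and S-t vs S-0, with
  log2FC_T − log2FC_S > δ (δ = 0.6);
* R4: down-DEG in both, with log2FC_S − log2FC_T < −δ.

The combined result defaults to the union of the enabled rules with
per-gene provenance flags; the Boolean connective is configurable because
the source description of the screen does not pin it down. Monotonicity
(growing δ never grows R3/R4; relaxing the FDR cap never shrinks any rule
set) and equivalence to a per-gene brute-force loop are asserted in tests.
Intersection accounting enumerates all exclusive Venn regions for up to six
labelled sets and falls back to pairwise plus full intersection beyond
that.

## Co-expression stage

This is a deliberately lightweight construction, not a WGCNA
reimplementation: no topological overlap matrix, no dynamic tree cut, no
scale-free fit for power selection. With the soft power fixed at β = 12,
adjacency a_ij = |pearson|^β on log2(FPKM+1) already separates planted
blocks from background at desk scale, so module formation is
average-linkage clustering on 1 − a_ij with a static cut at 0.99 of the
maximum merge height, a minimum module size of 30 (smaller clusters go to
grey), and iterative merging of modules whose eigengene dissimilarity
1 − cor(ME_i, ME_j) is below 0.25. The cut fraction is the one genuinely
free parameter; 0.99 works because soft-powering pushes between-module
dissimilarities to ≈ 1 while within-module merges happen well below it.

Eigengenes are PC1 of the gene-standardized module block, unit-variance,
oriented to correlate nonnegatively with the module's mean standardized
profile (deterministic sign). Module–group association is the Pearson
correlation of each eigengene with each one-hot sample-group indicator and
its two-sided t-distribution p-value (n − 2 df); modules pass at |r| > 0.6
and p < 0.05. Hubs are the genes with maximal intramodular connectivity
k_i = Σ_j a_ij within each selected module, ties broken by identifier
order; each gene's five strongest intramodular edges are exported for
graph tools.

The gene filter keeps genes with max FPKM ≥ 5 (an FPKM > 1 variant exists
in practice; the threshold is a config value) and can be restricted to a
DEG set.

## qPCR validation

2^−ΔΔCt with ΔCt = Ct_target − Ct_reference and ΔΔCt relative to a
calibrator condition. Technical triplicates are expected to be averaged on
the Ct scale upstream. The calibrator ΔCt is the mean over calibrator
samples by default; `calibration="replicate1"` uses the first calibrator
row instead (the normalize-one-replicate-to-1 variant). Concordance with
RNA-seq is the Pearson correlation of paired log2 fold changes (≥ 3
pairs).

## Synthetic data

The generators emulate the statistical structure each stage assumes, with
planted truth returned in sidecars the pipeline never reads.

* **Trait panel**: 46 genotypes split 2/19/25
  resistant/tolerant/sensitive, 12 directional traits (biomass, RWC,
  root–shoot ratio, K/Na and Mg/Na ratios, an ISC, and three Na contents)
  with field-realistic control baselines, 3 replicates. Class structure is
  planted on the STI scale: adjacent classes are separated by
  `class_effect` (default 3) noise-SDs (noise_sd default 0.08 — roughly
  the replicate-to-replicate spread of trait ratios in seedling assays),
  with inverted ordering for Na traits; STI draws are truncated to (0, 2]
  to keep trait values physical. Replicate noise scales with noise_sd so a
  zero-noise panel is exactly separable; the separation step falls back to
  the default SD at noise_sd = 0 so "zero noise" does not collapse the
  classes. A real 34-trait panel has block-correlated traits, shared
  measurement error and occasional missing cells, none of which the
  generator emulates, so recovery results certify the evaluation machinery
  — not field performance.
* **DE tables**: 200 genes × 4 timepoints × 3 contrasts. Planted rule-3
  genes are up in both genotype-vs-baseline contrasts with a
  tolerant-minus-sensitive gap ≥ 1.0 (safely above δ = 0.6); rule-4 genes
  mirror that downward; rule-1 genes are DEGs only in the between-genotype
  contrast; null genes get log2FC ~ N(0, 0.2) and FDR ~ U(0.2, 1). Margins
  are chosen so no value sits on a threshold; exact precision/recall on
  this input checks the screen logic, not the DE model upstream.
* **Expression matrix**: modules as latent per-sample factors mixed to a
  target within-block correlation (x = √ρ z + √(1−ρ) ε), one module's
  factor shifted (+2.5 on the log2 scale) in its linked sample group,
  background genes independent; FPKM = 2^(μ_g + x) with gene means
  μ_g ~ U(3, 6) keeps values nonnegative and above the expression filter.

Problem sizes throughout (46 genotypes, 200 screen genes, 2 × 40-gene
modules over 12 samples, 20/10-seed replications) are chosen as the
smallest panels at which the planted structure is comfortably resolvable,
keeping the full suite and the acceptance script in seconds.

## Known limitations

* Module detection's static cut is tuned for well-separated planted
  blocks; weakly separated or nested modules need the full dynamic
  tree-cut machinery this package intentionally omits.
* The CSTI component-direction rule (signed loading sum) can misorient a
  component whose loadings are balanced between positive- and
  negative-direction traits; explicit direction overrides are the escape
  hatch.
* No enrichment analysis, no homeolog pairing, no upstream DE model: the
  pipeline consumes log2FC/FDR tables as given.
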