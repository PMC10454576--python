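# saltpipe

Salt-tolerance evaluation and transcriptomic screening for plant stress
panels, built for seedling-stage salinity experiments in cotton and similar
crops. Given (a) a genotype × trait table of control and salt-treatment
measurements, (b) differential-expression tables contrasting a salt-tolerant
and a salt-sensitive genotype over a salt-stress time course, and (c) an
FPKM expression matrix, the pipeline

1. derives physiological traits — relative water content
   RWC = (FW − DW)/FW × 100, root–shoot ratio DW_root/DW_shoot, ion
   selective coefficients ISC = (K/Na)_dest / (K/Na)_source — and per-trait
   **salt tolerance indices** STI = value_salt / value_control;
2. computes a **comprehensive salt tolerance index**: PCA on the
   column-standardized STI matrix; components kept to an 80% cumulative
   contribution, weighted W_i = P_i / Σ_{j≤k} P_j; each retained component
   score mapped through the min–max membership function
   μ = (x − x_min)/(x_max − x_min) (inverted for axes aligned with Na
   accumulation); CSTI = Σ_i μ_i W_i ∈ [0, 1]; genotypes are ranked and
   graded salt-resistant / salt-tolerant / salt-sensitive by 1-D Ward
   clustering;
3. screens for salt-tolerance-related DEGs with four genotype-contrast
   rules (DEG = FDR ≤ 0.05 and |log2FC| ≥ 1): between-genotype DEGs,
   tolerant-vs-baseline DEGs, both-up genes with
   log2FC_tolerant − log2FC_sensitive > 0.6, and both-down genes with
   log2FC_sensitive − log2FC_tolerant < −0.6, plus cross-timepoint
   intersection accounting;
4. runs a lightweight co-expression stage: adjacency a_ij = |cor|^β with
   β = 12, module formation (minimum size 30, eigengene merge cutoff 0.25),
   module eigengenes (PC1), module–group correlation screening at |r| > 0.6
   and p < 0.05, and hub genes by intramodular connectivity;
5. validates expression by the 2^−ΔΔCt method and qPCR/RNA-seq concordance.

A synthetic-data module generates all three inputs with planted ground
truth (tolerance classes, screen-positive genes, co-expression blocks), so
the full pipeline is testable end to end without downloads.

## Worked example

`analysis/` holds numbered drivers that run the whole study flow on
synthetic data:

```sh
python analysis/01_simulate.py --seed 1     # writes results/sim/
python analysis/02_evaluate_panel.py
python analysis/03_screen_degs.py
python analysis/04_coexpression.py
python analysis/05_qpcr_validation.py --seed 1
```

which prints (seed 1):

```
2 components reach the 80% contribution target; CSTI in [0.017, 0.975]
class split: {'salt-sensitive': 25, 'salt-tolerant': 19, 'salt-resistant': 2}
agreement with planted classes: 100.0%
salt-tolerance DEGs per timepoint: {'05': 40, '3': 40, '12': 40, '24': 40}
module sizes: {'M1': 40, 'M2': 40, 'grey': 20}
adjusted Rand agreement with planted blocks: 1.000
qPCR vs RNA-seq concordance on log2 fold changes: r = 0.975 (p = 1.88e-26, n = 40)
```

Two principal components explain ≥ 80% of the STI variance of the
46-genotype panel; the composite index separates the planted
2/19/25 resistant/tolerant/sensitive split exactly. All 40 planted
screen genes are recovered at every timepoint with no false positives, the
two planted 40-gene co-expression blocks are recovered exactly (background
genes stay grey, module M1 is the one tied to the NY2-24 sample group), and
qPCR fold changes agree with matched RNA-seq values.

The same stages are available as subcommands of the `saltpipe` CLI
(`simulate`, `derive-traits`, `csti`, `classify`, `screen`, `coexpress`,
`validate-qpcr`, `demo`); `saltpipe demo --seed 1` chains them and writes a
checksum manifest, byte-identical across reruns of the same seed.

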