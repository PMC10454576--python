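"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the structure of a seedling salt-tolerance study:

* a 46-genotype trait panel with three planted tolerance classes
  (2 resistant / 19 tolerant / 25 sensitive by default, mirroring the kind
  of panel the evaluation is designed for);
* a two-genotype x four-timepoint differential-expression contrast set with
  genes planted to satisfy specific screen rules by a safe margin;
* an FPKM expression matrix with planted co-expression modules, optionally
  tied to sample groups.

Each generator is a pure function of its spec (seed included): the same
spec reproduces the same bytes.  Planted truth is returned separately and
is never consumed by the pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .screen import ContrastSpec

# (trait name, direction, control baseline) — biomass in g, RWC in %,
# ion contents in mg/g DW, ratios dimensionless
DEFAULT_TRAITS = (
    ("FW_shoot", "positive", 2.5),
    ("DW_shoot", "positive", 0.45),
    ("FW_root", "positive", 0.8),
    ("DW_root", "positive", 0.12),
    ("RWC_leaf", "positive", 85.0),
    ("RS_ratio", "positive", 0.27),
    ("ratio_K_Na_leaf", "positive", 2.0),
    ("ratio_Mg_Na_leaf", "positive", 0.8),
    ("ISC_K_root_stem", "positive", 1.4),
    ("Na_leaf", "negative", 8.0),
    ("Na_shoot", "negative", 10.0),
    ("Na_root", "negative", 14.0),
)

CLASS_ORDER = ("salt-resistant", "salt-tolerant", "salt-sensitive")


@dataclass
class PanelSpec:
    """Trait-panel generator settings.

    ``class_effect`` is the mean STI separation between adjacent tolerance
    classes in units of ``noise_sd``; classes are planted on the STI scale
    and salt values derived as control x STI.
    """

    n_genotypes: int = 46
    class_sizes: tuple = (2, 19, 25)       # resistant, tolerant, sensitive
    traits: tuple = DEFAULT_TRAITS
    class_effect: float = 3.0
    noise_sd: float = 0.08
    replicates: int = 3
    timepoint: str = "24h"
    seed: int = 0


@dataclass
class ScreenSpec:
    """DE-table generator settings; planted genes clear every threshold by
    a margin so the screen's expected outcome is exact."""

    n_genes: int = 200
    timepoints: tuple = ("05", "3", "12", "24")
    n_planted_r1: int = 10
    n_planted_r3: int = 15
    n_planted_r4: int = 15
    delta_gap: float = 1.0
    tolerant: str = "NY2"
    sensitive: str = "GP2"
    baseline: str = "00"
    seed: int = 0


@dataclass
class NetworkSpec:
    """Expression-matrix generator settings.

    Module genes share a latent per-sample factor mixed to the target
    within-block correlation; a module linked to a sample group has its
    latent factor shifted in that group's samples.
    """

    module_sizes: tuple = (40, 40)
    n_background: int = 20
    group_labels: tuple = ("NY2-00", "NY2-24", "GP2-00", "GP2-24")
    samples_per_group: int = 3
    block_cor: float = 0.9
    background_cor: float = 0.0
    group_linked: dict = field(default_factory=lambda: {"B1": "NY2-24"})
    link_shift: float = 2.5
    seed: int = 0


def gen_trait_panel(spec: PanelSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a replicated control/salt trait table with planted classes.

    Returns (trait table, genotype -> planted class).  Per positive trait
    the planted mean STI rises from salt-sensitive to salt-resistant by
    ``class_effect * noise_sd`` per class; negative-direction traits get
    the inverted ordering (resistant genotypes accumulate less Na).  STI
    draws are truncated to (0, 2]; replicate noise scales with noise_sd so
    a zero-noise panel is exactly separable.
    """
    if sum(spec.class_sizes) != spec.n_genotypes:
        raise ValueError("class sizes must sum to n_genotypes")
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genotypes))
    genotypes = [f"G{i + 1:0{width}d}" for i in range(spec.n_genotypes)]
    class_idx = np.repeat(np.arange(3), spec.class_sizes)  # 0=resistant
    rng.shuffle(class_idx)
    truth = pd.Series([CLASS_ORDER[c] for c in class_idx], index=genotypes,
                      name="class")

    # class separation is defined in noise-SD units; a noise-free panel keeps
    # the default scale so classes stay separated (and exactly recoverable)
    step = spec.class_effect * (spec.noise_sd if spec.noise_sd > 0 else 0.08)
    rep_sd = 0.25 * spec.noise_sd
    rows = []
    for g, cls in zip(genotypes, class_idx):
        tier = 2 - cls  # 2 best (resistant) ... 0 worst
        for trait, direction, baseline in spec.traits:
            if direction == "positive":
                mean_sti = 0.55 + tier * step
            else:
                mean_sti = 1.05 + (2 - tier) * step
            sti = float(np.clip(rng.normal(mean_sti, spec.noise_sd), 1e-3, 2.0))
            control = baseline * float(np.exp(rng.normal(0.0, 0.08)))
            for cond, base_value in (("control", control), ("salt", control * sti)):
                for rep in range(1, spec.replicates + 1):
                    noise = float(np.exp(rng.normal(0.0, rep_sd))) if rep_sd > 0 else 1.0
                    rows.append({"genotype": g, "trait": trait, "condition": cond,
                                 "timepoint": spec.timepoint, "replicate": rep,
                                 "value": base_value * noise})
    table = pd.DataFrame(rows, columns=["genotype", "trait", "condition",
                                        "timepoint", "replicate", "value"])
    return table, truth


def panel_directions(spec: PanelSpec) -> dict:
    return {t: d for t, d, _ in spec.traits}


def gen_de_tables(spec: ScreenSpec) -> tuple[pd.DataFrame, dict]:
    """Generate the three contrasts per timepoint with planted screen genes.

    Planted rule-3 genes are up in both genotype-vs-baseline contrasts with
    a tolerant-minus-sensitive gap of at least ``delta_gap``; rule-4 genes
    mirror that downward; rule-1 genes are DEGs only in the between-genotype
    contrast.  Null genes get small fold changes and FDR >= 0.2, keeping
    every planted margin free of boundary cases.
    """
    n_planted = spec.n_planted_r1 + spec.n_planted_r3 + spec.n_planted_r4
    if n_planted > spec.n_genes:
        raise ValueError("planted counts exceed n_genes")
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"g{i + 1:04d}" for i in range(spec.n_genes)])
    chosen = rng.choice(genes, size=n_planted, replace=False)
    r3 = set(chosen[: spec.n_planted_r3])
    r4 = set(chosen[spec.n_planted_r3: spec.n_planted_r3 + spec.n_planted_r4])
    r1 = set(chosen[spec.n_planted_r3 + spec.n_planted_r4:])
    cspec = ContrastSpec(tolerant=spec.tolerant, sensitive=spec.sensitive,
                         timepoints=spec.timepoints, baseline=spec.baseline)

    def null_row():
        return float(rng.normal(0.0, 0.2)), float(rng.uniform(0.2, 1.0))

    def sig_fdr():
        return float(rng.uniform(1e-6, 0.01))

    rows = []
    for t in spec.timepoints:
        names = {"tol": cspec.tolerant_vs_baseline(t),
                 "sen": cspec.sensitive_vs_baseline(t),
                 "cross": cspec.sensitive_vs_tolerant(t)}
        for g in genes:
            if g in r3:
                sen = float(rng.uniform(1.2, 1.8))
                tol = sen + spec.delta_gap + float(rng.uniform(0.2, 1.0))
                entries = {"tol": (tol, sig_fdr()), "sen": (sen, sig_fdr()),
                           "cross": null_row()}
            elif g in r4:
                tol = -float(rng.uniform(1.2, 1.8))
                sen = tol - spec.delta_gap - float(rng.uniform(0.2, 1.0))
                entries = {"tol": (tol, sig_fdr()), "sen": (sen, sig_fdr()),
                           "cross": null_row()}
            elif g in r1:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                entries = {"tol": null_row(), "sen": null_row(),
                           "cross": (sign * float(rng.uniform(1.5, 3.0)), sig_fdr())}
            else:
                entries = {"tol": null_row(), "sen": null_row(),
                           "cross": null_row()}
            for role, (l2fc, fdr) in entries.items():
                rows.append({"contrast": names[role], "gene": g,
                             "log2fc": l2fc, "fdr": fdr})
    de = pd.DataFrame(rows, columns=["contrast", "gene", "log2fc", "fdr"])
    truth = {"r1": r1, "r3": r3, "r4": r4, "all": r1 | r3 | r4,
             "contrast_spec": cspec}
    return de, truth


def gen_expression(spec: NetworkSpec) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate an FPKM matrix with planted co-expression blocks.

    Gene profiles on the log2 scale are mu_g + sqrt(rho) z_s +
    sqrt(1-rho) eps, so within-block pairwise correlation targets
    ``block_cor``; FPKM = 2^log-expression keeps values nonnegative.
    Returns (matrix, gene -> planted module label; 'background' for free
    genes).
    """
    if not 0 <= spec.block_cor <= 1:
        raise ValueError("block_cor must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    samples, groups = [], []
    for grp in spec.group_labels:
        for rep in range(1, spec.samples_per_group + 1):
            samples.append(f"{grp}_r{rep}")
            groups.append(grp)
    groups = pd.Series(groups, index=samples, name="group")
    n_samples = len(samples)

    gene_rows, labels, profiles = [], [], []
    rho = spec.block_cor
    for b, size in enumerate(spec.module_sizes):
        label = f"B{b + 1}"
        z = rng.normal(0.0, 1.0, n_samples)
        if label in spec.group_linked:
            z = z + spec.link_shift * (groups.values == spec.group_linked[label])
        z = (z - z.mean()) / z.std()
        for i in range(size):
            gene_rows.append(f"{label}_g{i + 1:03d}")
            labels.append(label)
            eps = rng.normal(0.0, 1.0, n_samples)
            profiles.append(np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps)
    for i in range(spec.n_background):
        gene_rows.append(f"bg_g{i + 1:03d}")
        labels.append("background")
        profiles.append(rng.normal(0.0, 1.0, n_samples))

    mu = rng.uniform(3.0, 6.0, len(gene_rows))
    logexpr = np.asarray(profiles) + mu[:, None]
    fpkm = pd.DataFrame(2.0 ** logexpr, index=gene_rows, columns=samples)
    truth = pd.Series(labels, index=gene_rows, name="module")
    return ExpressionMatrix(fpkm=fpkm, groups=groups), truth
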