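"""Lightweight weighted co-expression analysis.

Implements the construction choices of the full WGCNA workflow that this
pipeline relies on — soft-power adjacency a_ij = |cor|^beta (beta = 12),
average-linkage module formation with a minimum module size of 30,
eigengene-similarity module merging at cutoff 0.25, module eigengenes as
PC1 of the standardized module block, module-group correlation screening at
|r| > 0.6 and p < 0.05, and hub extraction by intramodular connectivity —
without the topological overlap matrix, dynamic tree cut, or scale-free
power selection of the full method.  Module detection here is a static cut
of the adjacency dendrogram; this is a deliberate simplification suited to
desk-scale networks where the soft power is fixed in advance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .io import ExpressionMatrix

GREY = "grey"


def filter_expression(expr: ExpressionMatrix, fpkm_min: float = 5.0,
                      deg_set: set | None = None) -> ExpressionMatrix:
    """Drop genes whose maximum FPKM never reaches ``fpkm_min`` and,
    optionally, genes outside a supplied DEG set."""
    keep = expr.fpkm.max(axis=1) >= fpkm_min
    if deg_set is not None:
        keep &= expr.fpkm.index.isin(deg_set)
    if not keep.any():
        raise ValueError("empty expression set after filtering")
    return ExpressionMatrix(fpkm=expr.fpkm.loc[keep], groups=expr.groups)


def log_transform(expr: ExpressionMatrix) -> pd.DataFrame:
    """log2(FPKM + 1) gene x sample matrix used for all correlations."""
    return np.log2(expr.fpkm + 1.0)


@dataclass
class CoexpressionNetwork:
    adjacency: pd.DataFrame   # gene x gene, symmetric, in [0, 1]
    soft_power: int


def build_adjacency(expr: ExpressionMatrix, soft_power: int = 12) -> CoexpressionNetwork:
    """Soft-threshold adjacency: a_ij = |pearson(g_i, g_j)|^beta.

    Computed on log2(FPKM+1); zero-variance genes cannot be correlated and
    are dropped with a warning.
    """
    if expr.fpkm.shape[1] < 4:
        raise ValueError("need >= 4 samples to estimate correlations")
    x = log_transform(expr)
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance gene(s) dropped")
        x = x.loc[sd > 0]
    cor = np.corrcoef(x.values)
    adj = np.abs(cor) ** soft_power
    np.fill_diagonal(adj, 1.0)
    return CoexpressionNetwork(
        adjacency=pd.DataFrame(adj, index=x.index, columns=x.index),
        soft_power=soft_power)


@dataclass
class ModuleSet:
    """Partition of genes into modules; undersized clusters go to 'grey'."""

    assignments: pd.Series                      # gene -> module label
    eigengenes: pd.DataFrame = field(default=None)  # sample x module

    def modules(self) -> dict:
        out = {}
        for g, m in self.assignments.items():
            out.setdefault(m, set()).add(g)
        return out


def eigengene(block: pd.DataFrame) -> pd.Series:
    """Module eigengene: PC1 of the standardized gene x sample block.

    Scaled to unit variance and oriented so it correlates nonnegatively
    with the module's mean standardized expression, making the sign
    deterministic.
    """
    if block.shape[0] < 1 or block.shape[1] < 2:
        raise ValueError("module block needs >= 1 gene and >= 2 samples")
    sd = block.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("constant module block")
    z = block.loc[sd > 0]
    z = z.sub(z.mean(axis=1), axis=0).div(z.std(axis=1, ddof=1), axis=0)
    # SVD of sample x gene matrix; PC1 over samples
    u, s, _ = np.linalg.svd(z.values.T, full_matrices=False)
    me = u[:, 0]
    mean_profile = z.values.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    me = me / me.std(ddof=1)
    return pd.Series(me, index=block.columns, name="ME")


def detect_modules(net: CoexpressionNetwork, expr: ExpressionMatrix,
                   min_module_size: int = 30, merge_cutoff: float = 0.25,
                   cut_height_frac: float = 0.99) -> ModuleSet:
    """Form modules from the adjacency matrix.

    Average-linkage clustering on dissimilarity 1 - a_ij, static cut at
    ``cut_height_frac`` of the maximum merge height; clusters smaller than
    ``min_module_size`` are relegated to grey; modules whose eigengene
    dissimilarity 1 - cor(ME_i, ME_j) falls below ``merge_cutoff`` are
    merged iteratively until stable.  Module labels are ``M1, M2, ...`` in
    order of decreasing size (ties by first gene id).
    """
    genes = list(net.adjacency.index)
    dissim = 1.0 - net.adjacency.values
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    tree = linkage(squareform(dissim, checks=False), method="average")
    cut = cut_height_frac * tree[:, 2].max() if len(tree) else 0.0
    raw = fcluster(tree, t=cut, criterion="distance")

    x = log_transform(expr).loc[genes]
    labels = pd.Series(raw, index=genes)
    # size filter
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = -1
    if (labels == -1).all():
        warnings.warn("no module survives the size filter; all genes grey")
        return ModuleSet(assignments=pd.Series(GREY, index=genes),
                         eigengenes=pd.DataFrame(index=x.columns))

    # iterative eigengene merge
    while True:
        mods = sorted(set(labels) - {-1},
                      key=lambda m: (-int((labels == m).sum()),
                                     min(labels.index[labels == m])))
        mes = {m: eigengene(x.loc[labels.index[labels == m]]) for m in mods}
        merged = False
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                d = 1.0 - np.corrcoef(mes[mods[i]], mes[mods[j]])[0, 1]
                if d < merge_cutoff and (best is None or d < best[0]):
                    best = (d, mods[i], mods[j])
        if best is not None:
            _, a, b = best
            labels[labels == b] = a
            merged = True
        if not merged:
            break

    final = sorted(set(labels) - {-1},
                   key=lambda m: (-int((labels == m).sum()),
                                  min(labels.index[labels == m])))
    rename = {m: f"M{i + 1}" for i, m in enumerate(final)}
    assignments = labels.map(lambda m: rename.get(m, GREY))
    eig = pd.DataFrame(
        {rename[m]: eigengene(x.loc[assignments.index[assignments == rename[m]]])
         for m in final})
    eig.index = x.columns
    return ModuleSet(assignments=assignments, eigengenes=eig)


def module_trait_correlation(modules: ModuleSet, groups: pd.Series,
                             r_min: float = 0.6, p_max: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each one-hot
    sample-group indicator, with its two-sided t-distribution p-value.

    Groups with fewer than 2 samples cannot anchor a correlation and are
    excluded with a warning.  ``selected`` flags |r| > r_min and p < p_max.
    """
    rows = []
    counts = groups.value_counts()
    usable = [g for g in sorted(counts.index) if counts[g] >= 2]
    dropped = sorted(set(counts.index) - set(usable))
    if dropped:
        warnings.warn(f"group(s) with < 2 samples excluded: {dropped}")
    aligned = groups.loc[modules.eigengenes.index]
    for module in modules.eigengenes.columns:
        me = modules.eigengenes[module].values
        for grp in usable:
            indicator = (aligned == grp).astype(float).values
            if indicator.std() == 0:
                continue
            r, p = pearsonr(me, indicator)
            rows.append({"module": module, "group": grp, "r": r, "p": p,
                         "selected": bool(abs(r) > r_min and p < p_max)})
    return pd.DataFrame(rows, columns=["module", "group", "r", "p", "selected"])


def hub_genes(net: CoexpressionNetwork, modules: ModuleSet,
              selected_modules: list | None = None,
              top_edges: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hub gene per module by intramodular connectivity k_i = sum_j a_ij.

    Returns (hubs, edges): one hub row per module (ties broken by gene id,
    which keeps repeated runs identical) and each gene's ``top_edges``
    strongest intramodular edges for export to graph tools.  Modules of
    size 1 have no internal edges and are skipped with a warning.
    """
    mods = modules.modules()
    mods.pop(GREY, None)
    if selected_modules is not None:
        mods = {m: g for m, g in mods.items() if m in selected_modules}
    hub_rows, edge_rows = [], []
    for module in sorted(mods):
        members = sorted(mods[module])
        if len(members) < 2:
            warnings.warn(f"module {module} has a single gene; skipped")
            continue
        sub = net.adjacency.loc[members, members].values.copy()
        np.fill_diagonal(sub, 0.0)
        k = sub.sum(axis=1)
        hub_idx = int(np.lexsort((members, -k))[0])
        hub_rows.append({"module": module, "hub": members[hub_idx],
                         "connectivity": float(k[hub_idx]),
                         "module_size": len(members)})
        for i, g in enumerate(members):
            order = np.argsort(-sub[i])
            for j in order[:top_edges]:
                if sub[i, j] <= 0:
                    break
                edge_rows.append({"module": module, "source": g,
                                  "target": members[j],
                                  "weight": float(sub[i, j])})
    hubs = pd.DataFrame(hub_rows, columns=["module", "hub", "connectivity", "module_size"])
    edges = pd.DataFrame(edge_rows, columns=["module", "source", "target", "weight"])
    return hubs, edges
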