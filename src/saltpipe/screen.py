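"""Genotype-contrast screen for salt-tolerance-related DEGs.

A gene is a DEG in a contrast when FDR <= 0.05 and |log2FC| >= 1 (2-fold).
The screen compares a salt-tolerant and a salt-sensitive genotype at each
salt-treatment timepoint against a shared baseline, with four rules:

1. differentially expressed between the two genotypes at that timepoint;
2. differentially expressed in the tolerant genotype vs its baseline;
3. up-regulated vs baseline in BOTH genotypes, with the tolerant genotype's
   log2FC exceeding the sensitive one's by more than delta (default 0.6);
4. down-regulated in both, with the sensitive genotype's log2FC below the
   tolerant one's by more than delta (sensitive - tolerant < -delta).

The default result per timepoint is the union of the enabled rule sets,
with per-gene provenance flags.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ContrastMissing(KeyError):
    pass


@dataclass
class ContrastSpec:
    """Naming scheme for the three contrasts required per timepoint."""

    tolerant: str = "NY2"
    sensitive: str = "GP2"
    timepoints: tuple = ("05", "3", "12", "24")
    baseline: str = "00"

    def __post_init__(self):
        if self.tolerant == self.sensitive:
            raise ValueError("tolerant and sensitive genotypes must differ")
        if self.baseline in self.timepoints:
            raise ValueError("baseline cannot be among treatment timepoints")

    def tolerant_vs_baseline(self, t: str) -> str:
        return f"{self.tolerant}-{t}_vs_{self.tolerant}-{self.baseline}"

    def sensitive_vs_baseline(self, t: str) -> str:
        return f"{self.sensitive}-{t}_vs_{self.sensitive}-{self.baseline}"

    def sensitive_vs_tolerant(self, t: str) -> str:
        return f"{self.sensitive}-{t}_vs_{self.tolerant}-{t}"


def call_degs(table: pd.DataFrame, fdr_max: float = 0.05,
              min_abs_log2fc: float = 1.0) -> pd.DataFrame:
    """Select DEGs from a single-contrast table; thresholds are inclusive.

    Returns a frame indexed by gene with ``log2fc`` and ``sign`` (+1 up,
    -1 down).  An empty table yields an empty selection.
    """
    if fdr_max <= 0 or min_abs_log2fc < 0:
        raise ValueError("thresholds must be positive")
    hit = (table["fdr"] <= fdr_max) & (table["log2fc"].abs() >= min_abs_log2fc)
    out = table.loc[hit, ["gene", "log2fc"]].copy()
    out["sign"] = np.sign(out["log2fc"]).astype(int)
    return out.set_index("gene")


@dataclass
class ScreenResult:
    """Per-timepoint screened genes with rule provenance, plus counts and
    cross-timepoint intersections."""

    per_timepoint: dict = field(default_factory=dict)  # t -> DataFrame
    counts: dict = field(default_factory=dict)
    intersections: pd.DataFrame | None = None

    def gene_sets(self) -> dict:
        return {t: set(df.index) for t, df in self.per_timepoint.items()}


def salt_tolerance_screen(de: pd.DataFrame, spec: ContrastSpec,
                          fdr_max: float = 0.05, min_abs_log2fc: float = 1.0,
                          delta: float = 0.6,
                          rules: tuple = (1, 2, 3, 4)) -> ScreenResult:
    """Run the four-rule screen on a combined DE table.

    ``de`` holds all contrasts (columns contrast/gene/log2fc/fdr); the three
    contrasts named by ``spec`` must be present for every timepoint.
    """
    bad = set(rules) - {1, 2, 3, 4}
    if bad:
        raise ValueError(f"unknown rule(s): {sorted(bad)}")
    by_contrast = {c: g.reset_index(drop=True) for c, g in de.groupby("contrast")}
    result = ScreenResult()
    for t in spec.timepoints:
        names = {"tol": spec.tolerant_vs_baseline(t),
                 "sen": spec.sensitive_vs_baseline(t),
                 "cross": spec.sensitive_vs_tolerant(t)}
        for role, name in names.items():
            if name not in by_contrast:
                raise ContrastMissing(f"required contrast missing: {name}")
        tol = by_contrast[names["tol"]].set_index("gene")
        sen = by_contrast[names["sen"]].set_index("gene")
        deg_tol = call_degs(by_contrast[names["tol"]], fdr_max, min_abs_log2fc)
        deg_sen = call_degs(by_contrast[names["sen"]], fdr_max, min_abs_log2fc)
        deg_cross = call_degs(by_contrast[names["cross"]], fdr_max, min_abs_log2fc)

        r1 = set(deg_cross.index)
        r2 = set(deg_tol.index)
        both_up = set(deg_tol.index[deg_tol["sign"] > 0]) & set(deg_sen.index[deg_sen["sign"] > 0])
        both_dn = set(deg_tol.index[deg_tol["sign"] < 0]) & set(deg_sen.index[deg_sen["sign"] < 0])
        r3 = {g for g in both_up
              if deg_tol.at[g, "log2fc"] - deg_sen.at[g, "log2fc"] > delta}
        r4 = {g for g in both_dn
              if deg_sen.at[g, "log2fc"] - deg_tol.at[g, "log2fc"] < -delta}

        rule_sets = {1: r1, 2: r2, 3: r3, 4: r4}
        selected = sorted(set().union(*(rule_sets[r] for r in rules)) if rules else set())
        rows = []
        for g in selected:
            l2_tol = tol.at[g, "log2fc"] if g in tol.index else np.nan
            l2_sen = sen.at[g, "log2fc"] if g in sen.index else np.nan
            ref = l2_tol if np.isfinite(l2_tol) and l2_tol != 0 else (
                deg_cross.at[g, "log2fc"] if g in deg_cross.index else np.nan)
            rows.append({
                "gene": g,
                "rule1": g in r1, "rule2": g in r2,
                "rule3": g in r3, "rule4": g in r4,
                "direction": "up" if (np.isfinite(ref) and ref > 0) else
                             ("down" if np.isfinite(ref) else "na"),
                "log2fc_tolerant": l2_tol,
                "log2fc_sensitive": l2_sen,
            })
        cols = ["gene", "rule1", "rule2", "rule3", "rule4", "direction",
                "log2fc_tolerant", "log2fc_sensitive"]
        frame = (pd.DataFrame(rows, columns=cols).set_index("gene")
                 if rows else pd.DataFrame(columns=cols[1:],
                                           index=pd.Index([], name="gene")))
        result.per_timepoint[t] = frame
        result.counts[t] = len(frame)
    if len(spec.timepoints) >= 2:
        result.intersections = intersect_across(result.gene_sets())
    return result


def intersect_across(sets: dict) -> pd.DataFrame:
    """Exclusive Venn-region cardinalities of labelled gene sets.

    For up to 6 sets all 2^k - 1 regions are enumerated (membership pattern
    -> count of genes in exactly those sets); for larger collections only
    pairwise and full intersections are reported.
    """
    labels = list(sets)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate set labels")
    if len(labels) < 2:
        raise ValueError("need >= 2 sets to intersect")
    rows = []
    if len(labels) <= 6:
        for r in range(1, len(labels) + 1):
            for combo in itertools.combinations(labels, r):
                inside = set.intersection(*(sets[l] for l in combo))
                outside = set().union(*(sets[l] for l in labels if l not in combo)) \
                    if len(combo) < len(labels) else set()
                rows.append({"region": "&".join(combo),
                             "exclusive_count": len(inside - outside),
                             "intersection_count": len(inside)})
    else:
        for a, b in itertools.combinations(labels, 2):
            rows.append({"region": f"{a}&{b}",
                         "exclusive_count": np.nan,
                         "intersection_count": len(sets[a] & sets[b])})
        rows.append({"region": "&".join(labels),
                     "exclusive_count": np.nan,
                     "intersection_count": len(set.intersection(*sets.values()))})
    return pd.DataFrame(rows)
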