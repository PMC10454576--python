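"""Derived physiological traits of the seedling salt-stress panel.

Relative water content, root-shoot ratio, the ion-selective transport
coefficient between adjacent compartments, and the per-trait salt tolerance
index (salt/control ratio) that feeds the composite evaluation.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd


class DomainError(ValueError):
    """Input outside the physical domain of a trait formula."""


def relative_water_content(fw: float, dw: float, clip: bool = False) -> float:
    """Percent water in fresh tissue: (FW - DW) / FW x 100.

    ``dw > fw`` is nonphysical; it raises unless ``clip`` is set, in which
    case the value is clipped to 0 with a warning (weighing noise on very
    dry samples).
    """
    if fw <= 0:
        raise DomainError(f"fresh weight must be positive, got {fw}")
    if dw < 0:
        raise DomainError(f"dry weight must be nonnegative, got {dw}")
    if dw > fw:
        if not clip:
            raise DomainError(f"dry weight {dw} exceeds fresh weight {fw}")
        warnings.warn(f"dry weight {dw} > fresh weight {fw}; RWC clipped to 0")
        return 0.0
    return (fw - dw) / fw * 100.0


def root_shoot_ratio(dw_root: float, dw_shoot: float) -> float:
    """Dry-weight root/shoot biomass allocation ratio."""
    if dw_shoot <= 0:
        raise DomainError(f"shoot dry weight must be positive, got {dw_shoot}")
    if dw_root < 0:
        raise DomainError(f"root dry weight must be nonnegative, got {dw_root}")
    return dw_root / dw_shoot


def ion_selective_coefficient(k_source: float, na_source: float,
                              k_dest: float, na_dest: float) -> float:
    """Selectivity of ion transport between adjacent compartments.

    The ratio of the destination compartment's K/Na (or any ion pair passed
    as the k/na arguments, e.g. Mg/Na) to the source compartment's, e.g.
    root -> stem or stem -> leaf.  Values > 1 mean the plant preferentially
    moves K over Na towards the destination.
    """
    for name, v in (("k_source", k_source), ("na_source", na_source),
                    ("k_dest", k_dest), ("na_dest", na_dest)):
        if v <= 0:
            raise DomainError(f"{name} must be positive, got {v}")
    return (k_dest / na_dest) / (k_source / na_source)


def salt_tolerance_index(value_salt: float, value_control: float) -> float:
    """Per-trait ratio of the salt-treated value to the control value."""
    if value_control == 0:
        raise DomainError("control value is zero; STI undefined")
    return value_salt / value_control


# ---------------------------------------------------------------------------
# table-level derivation


_NEGATIVE_PATTERNS = (
    re.compile(r"^na(_|$)", re.I),           # Na content (Na, Na_leaf, ...)
    re.compile(r"_na$", re.I),               # Na content, organ-first naming
    re.compile(r"^ratio_na_", re.I),         # Na-numerator ratios (Na/K, ...)
    re.compile(r"^isc_na_", re.I),           # Na-selectivity coefficients
)


def infer_direction(trait: str) -> str:
    """Default tolerance direction for a trait name.

    Sodium accumulation correlates negatively with tolerance, so Na-content
    traits and ratios with Na in the numerator default to ``negative``;
    everything else (biomass, water content, K/Na, Mg/Na) to ``positive``.
    Overridable via an explicit direction map everywhere it is consumed.
    """
    if any(p.search(trait) for p in _NEGATIVE_PATTERNS):
        return "negative"
    return "positive"


def direction_map(traits, overrides: dict | None = None) -> dict:
    dmap = {t: infer_direction(t) for t in traits}
    if overrides:
        for t, d in overrides.items():
            if d not in ("positive", "negative"):
                raise ValueError(f"direction must be positive|negative, got {d}")
            dmap[t] = d
    return dmap


def sti_matrix(trait_table: pd.DataFrame, timepoint: str | None = None) -> pd.DataFrame:
    """Genotype x trait matrix of salt tolerance indices.

    Replicates are averaged (arithmetic mean) per genotype/trait/condition
    cell before the salt/control ratio.  Traits with any zero control mean
    are excluded with a warning (the ratio is undefined); the result has no
    missing entries.
    """
    df = trait_table
    if timepoint is not None:
        df = df[df["timepoint"] == timepoint]
    means = (df.groupby(["genotype", "trait", "condition"])["value"]
               .mean().unstack("condition"))
    if "control" not in means or "salt" not in means:
        raise ValueError("both control and salt conditions are required")
    if means[["control", "salt"]].isna().any().any():
        bad = means[means[["control", "salt"]].isna().any(axis=1)].index[0]
        raise ValueError(f"incomplete condition pair for {bad}")
    zero_ctrl = means.index[means["control"] == 0].get_level_values("trait").unique()
    if len(zero_ctrl):
        warnings.warn(f"trait(s) with zero control mean excluded from STI: {list(zero_ctrl)}")
        means = means[~means.index.get_level_values("trait").isin(zero_ctrl)]
    sti = (means["salt"] / means["control"]).unstack("trait")
    if sti.isna().any().any():
        raise ValueError("STI matrix has missing entries after aggregation")
    return sti.sort_index().sort_index(axis=1)


def derive_traits(trait_table: pd.DataFrame, clip: bool = False) -> pd.DataFrame:
    """Append derived trait records computed from raw organ measurements.

    Expects raw traits named ``FW_<organ>``, ``DW_<organ>`` and
    ``<Ion>_<organ>`` (e.g. ``K_root``, ``Na_stem``).  Emits, where the
    inputs exist within each (genotype, condition, timepoint, replicate)
    cell: ``RWC_<organ>``, ``RS_ratio``, ``ratio_<A>_<B>_<organ>`` for
    K/Na and Mg/Na, and ``ISC_<ion>_<src>_<dst>`` for root->stem and
    stem->leaf.
    """
    records = []
    keys = ["genotype", "condition", "timepoint", "replicate"]
    wide = trait_table.pivot_table(index=keys, columns="trait", values="value")

    def have(*cols):
        return all(c in wide.columns for c in cols)

    for idx, row in wide.iterrows():
        out = {}
        organs = {c.split("_", 1)[1] for c in wide.columns if c.startswith("FW_")}
        for organ in sorted(organs):
            if have(f"FW_{organ}", f"DW_{organ}"):
                out[f"RWC_{organ}"] = relative_water_content(
                    row[f"FW_{organ}"], row[f"DW_{organ}"], clip=clip)
        if have("DW_root", "DW_shoot"):
            out["RS_ratio"] = root_shoot_ratio(row["DW_root"], row["DW_shoot"])
        ion_organs = {c.split("_", 1)[1] for c in wide.columns if c.startswith("Na_")}
        for organ in sorted(ion_organs):
            for num in ("K", "Mg"):
                if have(f"{num}_{organ}", f"Na_{organ}"):
                    out[f"ratio_{num}_Na_{organ}"] = row[f"{num}_{organ}"] / row[f"Na_{organ}"]
        for src, dst in (("root", "stem"), ("stem", "leaf")):
            for num in ("K", "Mg"):
                cols = (f"{num}_{src}", f"Na_{src}", f"{num}_{dst}", f"Na_{dst}")
                if have(*cols):
                    out[f"ISC_{num}_{src}_{dst}"] = ion_selective_coefficient(
                        *(row[c] for c in cols))
        for trait, value in out.items():
            records.append(dict(zip(keys, idx)) | {"trait": trait, "value": value})
    if not records:
        return trait_table
    derived = pd.DataFrame.from_records(records)[
        ["genotype", "trait", "condition", "timepoint", "replicate", "value"]]
    return pd.concat([trait_table, derived], ignore_index=True)
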