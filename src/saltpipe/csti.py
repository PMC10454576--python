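"""Comprehensive salt tolerance index (CSTI) and genotype grading.

The evaluation follows the membership-function / PCA-weight composite-index
method standard in crop stress phenotyping:

1. per-trait salt tolerance indices (STI = salt/control) form a genotype x
   trait matrix;
2. PCA on the column-standardized STI matrix (correlation-matrix PCA) gives
   eigenvalue contribution rates P_i; components are kept up to a cumulative
   contribution target (default 80%) and weighted W_i = P_i / sum_{j<=k} P_j;
3. each retained component score is mapped through a min-max membership
   function mu in [0, 1] (inverted for components aligned with traits that
   correlate negatively with tolerance, e.g. Na accumulation);
4. CSTI = sum_i mu_i W_i, a convex combination, hence in [0, 1];
5. genotypes are ranked by CSTI and graded into salt-resistant /
   salt-tolerant / salt-sensitive classes by 1-D hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .traits import direction_map

CLASS_LABELS = ["salt-resistant", "salt-tolerant", "salt-sensitive"]


class DegenerateInput(ValueError):
    pass


def membership(x: float, xmin: float, xmax: float, direction: str = "positive") -> float:
    """Min-max membership of ``x`` within [xmin, xmax], in [0, 1].

    Positive direction rewards large values, negative rewards small ones;
    the two are complementary (mu_pos + mu_neg = 1).  A degenerate range
    (xmax == xmin) returns 0.5: the axis carries no ranking information.
    """
    if xmax < xmin:
        raise ValueError(f"xmax {xmax} < xmin {xmin}")
    if direction not in ("positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    if not (xmin <= x <= xmax):
        raise ValueError(f"x={x} outside [{xmin}, {xmax}]")
    if xmax == xmin:
        return 0.5
    mu = (x - xmin) / (xmax - xmin)
    return mu if direction == "positive" else 1.0 - mu


def _membership_vector(values: np.ndarray, direction: str) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, 0.5, dtype=float)
    mu = (values - lo) / (hi - lo)
    return mu if direction == "positive" else 1.0 - mu


@dataclass
class PCAModel:
    """Correlation-matrix PCA of an STI matrix.

    ``contribution`` sums to 1 over all components; ``k_selected`` is the
    smallest k whose cumulative contribution reaches the variance target.
    Loadings are deterministically signed: each component is oriented so its
    largest-magnitude loading is positive.
    """

    eigenvalues: np.ndarray
    contribution: np.ndarray
    loadings: pd.DataFrame    # trait x component
    scores: pd.DataFrame      # genotype x component
    k_selected: int


def pca_weights(sti: pd.DataFrame, variance_target: float = 0.80) -> PCAModel:
    """PCA on the column-standardized STI matrix, with component selection.

    Constant trait columns carry no variance under standardization and are
    dropped with a warning; at least 2 varying traits and 3 genotypes are
    required.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    if sti.shape[0] < 3:
        raise DegenerateInput("need >= 3 genotypes for PCA")
    sd = sti.std(axis=0, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        warnings.warn(f"constant trait column(s) dropped: {list(constant)}")
        sti = sti.drop(columns=constant)
    if sti.shape[1] < 2:
        raise DegenerateInput("need >= 2 varying traits for PCA")
    z = (sti - sti.mean(axis=0)) / sti.std(axis=0, ddof=1)
    corr = np.corrcoef(z.values, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[pivot, j] < 0:
            eigvec[:, j] *= -1
    contribution = eigval / eigval.sum()
    k = int(np.searchsorted(np.cumsum(contribution), variance_target - 1e-12) + 1)
    k = min(k, len(eigval))
    comp_names = [f"PC{j + 1}" for j in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=sti.columns, columns=comp_names)
    scores = pd.DataFrame(z.values @ eigvec, index=sti.index, columns=comp_names)
    return PCAModel(eigenvalues=eigval, contribution=contribution,
                    loadings=loadings, scores=scores, k_selected=k)


def _component_directions(model: PCAModel, directions: dict) -> list[str]:
    """Orient each retained component towards tolerance.

    A component score has no intrinsic direction; it is treated as positive
    if the loadings of positive-direction traits outweigh those of
    negative-direction traits (signed sum >= 0), else the membership is
    inverted.
    """
    out = []
    for comp in model.loadings.columns[: model.k_selected]:
        s = sum(model.loadings.at[t, comp] * (1 if directions.get(t, "positive") == "positive" else -1)
                for t in model.loadings.index)
        out.append("positive" if s >= 0 else "negative")
    return out


def csti_scores(sti: pd.DataFrame, directions: dict | None = None,
                variance_target: float = 0.80,
                membership_level: str = "component") -> tuple[pd.DataFrame, PCAModel]:
    """Compute CSTI for every genotype.

    Returns a result frame (genotype index; membership columns, csti, rank)
    and the fitted :class:`PCAModel`.  ``membership_level='component'`` is
    the composite-PC-score reading (membership applied to retained component
    scores); ``'trait'`` applies membership per trait first and weights
    traits by their PCA-contribution-weighted squared loadings.
    """
    directions = direction_map(sti.columns, overrides=directions)
    model = pca_weights(sti, variance_target)
    k = model.k_selected
    weights = model.contribution[:k] / model.contribution[:k].sum()

    if membership_level == "component":
        comp_dirs = _component_directions(model, directions)
        mu = np.column_stack([
            _membership_vector(model.scores.iloc[:, j].values, comp_dirs[j])
            for j in range(k)])
        mu_cols = [f"mu_{c}" for c in model.scores.columns[:k]]
        weight_map = dict(zip(mu_cols, weights))
    elif membership_level == "trait":
        traits = list(model.loadings.index)
        mu = np.column_stack([
            _membership_vector(sti[t].values, directions[t]) for t in traits])
        load = model.loadings.values[:, :k]
        trait_w = (load ** 2) @ weights
        weights = trait_w / trait_w.sum()
        mu_cols = [f"mu_{t}" for t in traits]
        weight_map = dict(zip(mu_cols, weights))
    else:
        raise ValueError("membership_level must be 'component' or 'trait'")

    csti = mu @ weights
    result = pd.DataFrame(mu, index=sti.index, columns=mu_cols)
    result["csti"] = csti
    order = result["csti"].rank(ascending=False, method="first").astype(int)
    result["rank"] = order
    result.attrs["weights"] = weight_map
    return result, model


def classify(csti: pd.Series, n_classes: int = 3, linkage: str = "ward") -> pd.Series:
    """Grade genotypes by 1-D hierarchical clustering of CSTI values.

    Clusters (Euclidean distance, Ward linkage by default) are labelled by
    descending mean CSTI: salt-resistant > salt-tolerant > salt-sensitive.
    All-equal CSTI values make the cut meaningless and raise.
    """
    if len(csti) < n_classes:
        raise DegenerateInput(f"need >= {n_classes} genotypes")
    values = csti.sort_index()  # deterministic tie-break by genotype id
    if values.nunique() == 1:
        raise DegenerateInput("degenerate clustering: all CSTI values equal")
    model = AgglomerativeClustering(n_clusters=n_classes, linkage=linkage)
    raw = model.fit_predict(values.values.reshape(-1, 1))
    means = pd.Series(values.values).groupby(raw).mean().sort_values(ascending=False)
    if n_classes == 3:
        labels = CLASS_LABELS
    else:
        labels = [f"grade_{i + 1}" for i in range(n_classes)]
    mapping = {cluster: labels[i] for i, cluster in enumerate(means.index)}
    out = pd.Series([mapping[c] for c in raw], index=values.index, name="class")
    return out.loc[csti.index]


def evaluate_panel(sti: pd.DataFrame, directions: dict | None = None,
                   variance_target: float = 0.80, n_classes: int = 3,
                   linkage: str = "ward",
                   membership_level: str = "component") -> tuple[pd.DataFrame, PCAModel]:
    """STI matrix -> CSTI -> ranked, graded genotype table."""
    result, model = csti_scores(sti, directions, variance_target, membership_level)
    result["class"] = classify(result["csti"], n_classes=n_classes, linkage=linkage)
    return result.sort_values("rank"), model


def pca_summary(model: PCAModel) -> pd.DataFrame:
    """Eigenvalues, contribution rates and loadings as one tidy frame."""
    head = pd.DataFrame(
        {"component": model.loadings.columns,
         "eigenvalue": model.eigenvalues,
         "contribution": model.contribution,
         "selected": [j < model.k_selected for j in range(len(model.eigenvalues))]})
    return head
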