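"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written by a different route than the
package: explicit loops, a Jacobi eigensolver instead of LAPACK wrappers,
and per-gene rule evaluation instead of vectorized set algebra.
"""

from __future__ import annotations

import math

import numpy as np


def correlation_matrix_loops(x: np.ndarray) -> np.ndarray:
    """Pearson correlation of columns via the textbook formula, with loops."""
    n, p = x.shape
    corr = np.empty((p, p))
    means = [sum(x[:, j]) / n for j in range(p)]
    for a in range(p):
        for b in range(p):
            num = sum((x[i, a] - means[a]) * (x[i, b] - means[b]) for i in range(n))
            da = math.sqrt(sum((x[i, a] - means[a]) ** 2 for i in range(n)))
            db = math.sqrt(sum((x[i, b] - means[b]) ** 2 for i in range(n)))
            corr[a, b] = num / (da * db)
    return corr


def jacobi_eigh(a: np.ndarray, tol: float = 1e-14, max_sweeps: int = 100):
    """Eigen-decomposition of a symmetric matrix by cyclic Jacobi rotations.

    Returns (eigenvalues desc, eigenvectors as columns).
    """
    a = a.copy().astype(float)
    n = a.shape[0]
    v = np.eye(n)
    for _ in range(max_sweeps):
        off = math.sqrt(sum(a[i, j] ** 2 for i in range(n) for j in range(n) if i != j))
        if off < tol:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if abs(a[p, q]) < tol / n:
                    continue
                theta = (a[q, q] - a[p, p]) / (2.0 * a[p, q])
                t = math.copysign(1.0, theta) / (abs(theta) + math.sqrt(theta ** 2 + 1.0))
                c = 1.0 / math.sqrt(t ** 2 + 1.0)
                s = t * c
                rot = np.eye(n)
                rot[p, p] = rot[q, q] = c
                rot[p, q] = s
                rot[q, p] = -s
                a = rot.T @ a @ rot
                v = v @ rot
    eigvals = np.diag(a).copy()
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], v[:, order]


def pearson_loops(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n))) * \
        math.sqrt(sum((y[i] - my) ** 2 for i in range(n)))
    return num / den


def csti_oracle(sti: np.ndarray, directions: list[str],
                variance_target: float = 0.80) -> dict:
    """Full composite-index pipeline recomputed with loops + Jacobi PCA."""
    n, p = sti.shape
    z = np.empty_like(sti, dtype=float)
    for j in range(p):
        col = sti[:, j]
        mean = sum(col) / n
        sd = math.sqrt(sum((c - mean) ** 2 for c in col) / (n - 1))
        z[:, j] = (col - mean) / sd
    corr = correlation_matrix_loops(sti)
    eigval, eigvec = jacobi_eigh(corr)
    eigval = np.clip(eigval, 0.0, None)
    for j in range(eigvec.shape[1]):
        pivot = max(range(p), key=lambda i: abs(eigvec[i, j]))
        if eigvec[pivot, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    contrib = eigval / eigval.sum()
    cum, k = 0.0, 0
    for c in contrib:
        cum += c
        k += 1
        if cum >= variance_target - 1e-12:
            break
    scores = z @ eigvec
    weights = contrib[:k] / contrib[:k].sum()
    csti = np.zeros(n)
    for j in range(k):
        signed = sum(eigvec[t, j] * (1 if directions[t] == "positive" else -1)
                     for t in range(p))
        s = scores[:, j] if signed >= 0 else -scores[:, j]
        lo, hi = s.min(), s.max()
        mu = (s - lo) / (hi - lo) if hi > lo else np.full(n, 0.5)
        csti += mu * weights[j]
    return {"eigenvalues": eigval, "contribution": contrib, "k": k,
            "scores": scores, "weights": weights, "csti": csti}


def screen_bruteforce(de_rows: list[dict], spec, fdr_max=0.05,
                      min_abs_log2fc=1.0, delta=0.6,
                      rules=(1, 2, 3, 4)) -> dict:
    """Per-gene, per-rule loop over raw DE records; returns t -> gene set."""
    table = {}
    genes = set()
    for r in de_rows:
        table[(r["contrast"], r["gene"])] = (r["log2fc"], r["fdr"])
        genes.add(r["gene"])

    def is_deg(contrast, gene):
        rec = table.get((contrast, gene))
        return rec is not None and rec[1] <= fdr_max and abs(rec[0]) >= min_abs_log2fc

    def l2fc(contrast, gene):
        return table[(contrast, gene)][0]

    out = {}
    for t in spec.timepoints:
        ct = spec.tolerant_vs_baseline(t)
        cs = spec.sensitive_vs_baseline(t)
        cx = spec.sensitive_vs_tolerant(t)
        hits = set()
        for g in genes:
            picked = False
            if 1 in rules and is_deg(cx, g):
                picked = True
            if 2 in rules and is_deg(ct, g):
                picked = True
            if 3 in rules and is_deg(ct, g) and is_deg(cs, g) \
                    and l2fc(ct, g) > 0 and l2fc(cs, g) > 0 \
                    and l2fc(ct, g) - l2fc(cs, g) > delta:
                picked = True
            if 4 in rules and is_deg(ct, g) and is_deg(cs, g) \
                    and l2fc(ct, g) < 0 and l2fc(cs, g) < 0 \
                    and l2fc(cs, g) - l2fc(ct, g) < -delta:
                picked = True
            if picked:
                hits.add(g)
        out[t] = hits
    return out


def venn_regions_bruteforce(sets: dict) -> dict:
    """Exclusive region counts by per-gene membership enumeration."""
    labels = list(sets)
    universe = set().union(*sets.values())
    regions = {}
    for g in universe:
        pattern = tuple(l for l in labels if g in sets[l])
        regions[pattern] = regions.get(pattern, 0) + 1
    return regions
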