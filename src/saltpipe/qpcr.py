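"""qRT-PCR relative expression (2^-ddCt) and RNA-seq concordance."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


def ddct(ct_target: float, ct_reference: float,
         ct_target_cal: float, ct_reference_cal: float) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference, ddCt = dCt - dCt_calibrator;
    the fold change vs the calibrator sample is 2^-ddCt.
    """
    dct = ct_target - ct_reference
    dct_cal = ct_target_cal - ct_reference_cal
    return float(2.0 ** -(dct - dct_cal))


def relative_expression(qpcr: pd.DataFrame, calibration: str = "mean") -> pd.DataFrame:
    """Per-sample fold changes for every gene in a qPCR table.

    ``qpcr`` columns: gene, sample, ct_target, ct_reference, is_calibrator.
    Technical replicates should already be averaged on the Ct scale.  The
    calibrator dCt per gene is the mean over calibrator samples
    (``calibration='mean'``) or the first calibrator sample in table order
    (``'replicate1'``, the per-replicate normalization variant).
    """
    required = {"gene", "sample", "ct_target", "ct_reference", "is_calibrator"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qpcr table missing column(s): {sorted(missing)}")
    if calibration not in ("mean", "replicate1"):
        raise ValueError("calibration must be 'mean' or 'replicate1'")
    if not ((qpcr["ct_target"] > 0) & (qpcr["ct_reference"] > 0)).all():
        raise ValueError("Ct values must be positive")
    rows = []
    for gene, sub in qpcr.groupby("gene", sort=True):
        cal = sub[sub["is_calibrator"].astype(bool)]
        if cal.empty:
            raise ValueError(f"gene {gene} has no calibrator sample")
        dct = sub["ct_target"] - sub["ct_reference"]
        dct_cal_all = cal["ct_target"] - cal["ct_reference"]
        dct_cal = dct_cal_all.mean() if calibration == "mean" else dct_cal_all.iloc[0]
        fold = 2.0 ** -(dct - dct_cal)
        for (_, r), f in zip(sub.iterrows(), fold):
            rows.append({"gene": gene, "sample": r["sample"], "fold_change": float(f)})
    return pd.DataFrame(rows, columns=["gene", "sample", "fold_change"])


def concordance(qpcr_fc: pd.Series, rnaseq_fc: pd.Series) -> dict:
    """Agreement between qPCR and RNA-seq fold changes.

    Pairs the two series on their shared index, takes log2, and returns the
    Pearson r with its two-sided p-value plus the paired scatter table.
    Needs at least 3 shared observations.
    """
    shared = qpcr_fc.index.intersection(rnaseq_fc.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 paired observations, have {len(shared)}")
    x = np.log2(qpcr_fc.loc[shared].astype(float))
    y = np.log2(rnaseq_fc.loc[shared].astype(float))
    r, p = pearsonr(x, y)
    pairs = pd.DataFrame({"log2_qpcr": x, "log2_rnaseq": y})
    return {"r": float(r), "p": float(p), "n": int(len(shared)), "pairs": pairs}
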