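"""Unsupervised descriptor reduction: variance filter and V-WSP.

The variance filter removes static descriptors (sd below 1e-4 by
default). V-WSP removes collinear descriptors on the calibration set:
starting from the descriptor most correlated with the first principal
axis, every descriptor whose absolute Pearson correlation with a
retained descriptor exceeds the threshold is discarded, recursing on the
survivors, so every retained pair satisfies |r| <= threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..descriptor_table import DescriptorTable
from ..errors import AllRemoved, TooFewSamples
from .scaling import autoscale_full


def variance_filter(table: DescriptorTable | pd.DataFrame,
                    sd_threshold: float = 1e-4
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Drop descriptors with sd < threshold; sd exactly at the threshold
    is kept. Returns (reduced frame, removed names)."""
    frame = table.data if isinstance(table, DescriptorTable) else table
    if len(frame) < 2:
        raise TooFewSamples("variance filter needs >= 2 samples")
    sds = frame.std(ddof=1)
    keep = sds[sds >= sd_threshold].index.tolist()
    removed = [c for c in frame.columns if c not in keep]
    if not keep:
        raise AllRemoved("variance filter removed every descriptor")
    return frame[keep], removed


def vwsp_reduce(calibration: pd.DataFrame,
                correlation_threshold: float = 0.95) -> list[str]:
    """Greedy V-WSP collinearity reduction on the calibration set.

    Returns the retained descriptor names, in selection order. A
    threshold of 1.0 retains everything (|r| can only exceed 1 by
    rounding noise, guarded below).
    """
    scaled = autoscale_full(calibration)
    x = scaled.to_numpy()
    names = list(calibration.columns)
    if len(names) <= 1:
        return names

    # correlation of each descriptor with the first principal axis
    u, s, vt = np.linalg.svd(x - x.mean(0), full_matrices=False)
    pc1 = u[:, 0] * s[0]
    corr = np.corrcoef(x.T)
    corr = np.nan_to_num(corr, nan=0.0)
    with np.errstate(invalid="ignore"):
        pc1_corr = np.abs(np.array(
            [np.corrcoef(pc1, x[:, j])[0, 1] for j in range(x.shape[1])]))
    pc1_corr = np.nan_to_num(pc1_corr, nan=0.0)

    pool = list(range(len(names)))
    retained: list[int] = []
    while pool:
        # next seed: survivor most correlated with the first principal axis
        seed = max(pool, key=lambda j: (pc1_corr[j], -j))
        retained.append(seed)
        pool = [j for j in pool
                if j != seed and abs(corr[seed, j]) <= correlation_threshold]
    return [names[j] for j in retained]
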