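"""Kennard–Stone (CADEX) calibration/test splitting.

The deterministic max–min procedure: start from the two mutually most
distant samples, then repeatedly add the sample whose minimum Euclidean
distance to the already-selected set is largest. Distances are computed
on autoscaled descriptors so the split is scale-free. The selected
samples form the calibration set (the most structurally dissimilar
samples), guaranteeing test samples fall inside the calibration set's
descriptor domain. Stratified mode runs the procedure per label group to
retain the label ratio in both sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from ..descriptor_table import DescriptorTable
from ..errors import EmptyStratum, TooFewSamples
from .scaling import autoscale_full


@dataclass
class SplitResult:
    calibration_ids: list[str]
    test_ids: list[str]
    selection_order: list[str]

    def __post_init__(self):
        overlap = set(self.calibration_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"calibration/test overlap: {sorted(overlap)}")


def _kennard_stone_order(dist: np.ndarray) -> list[int]:
    """Full selection order by max–min; ties broken by lowest index."""
    n = dist.shape[0]
    # seed: most distant pair, lower indices on ties (argmax is row-major)
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    while remaining:
        best = max(remaining, key=lambda k: (min_dist[k], -k))
        selected.append(best)
        remaining.remove(best)
        min_dist = np.minimum(min_dist, dist[best])
    return selected


def kennard_stone_split(table: DescriptorTable | pd.DataFrame,
                        calibration_fraction: float = 0.8,
                        stratify_by: pd.Series | None = None) -> SplitResult:
    """Deterministic 80/20 (by default) calibration/test partition."""
    frame = table.data if isinstance(table, DescriptorTable) else table
    n = len(frame)
    if n < 5:
        raise TooFewSamples(f"need >= 5 samples, got {n}")
    scaled = autoscale_full(frame).to_numpy()
    ids = list(frame.index)

    if stratify_by is not None:
        stratify_by = stratify_by.loc[frame.index]
        cal, test, order = [], [], []
        for label in pd.unique(stratify_by):
            members = [i for i, s in enumerate(ids) if stratify_by.iloc[i] == label]
            if not members:
                raise EmptyStratum(str(label))
            if len(members) < 2:
                cal.extend(ids[i] for i in members)
                order.extend(ids[i] for i in members)
                continue
            sub = scaled[members]
            dist = squareform(pdist(sub))
            sel = _kennard_stone_order(dist)
            n_cal = int(round(calibration_fraction * len(members)))
            n_cal = max(2, min(n_cal, len(members)))
            chosen = [ids[members[k]] for k in sel]
            order.extend(chosen)
            cal.extend(chosen[:n_cal])
            test.extend(chosen[n_cal:])
        return SplitResult(calibration_ids=cal, test_ids=test,
                           selection_order=order)

    dist = squareform(pdist(scaled))
    sel = _kennard_stone_order(dist)
    n_cal = int(round(calibration_fraction * n))
    n_cal = max(2, min(n_cal, n))
    chosen = [ids[k] for k in sel]
    return SplitResult(calibration_ids=chosen[:n_cal],
                       test_ids=chosen[n_cal:],
                       selection_order=chosen)
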