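"""Exploratory analysis: hierarchical clustering and PCA.

Used to probe sample separation in descriptor space (e.g. whether
conformational outliers segregate from the main body of samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from ..errors import TooFewSamples


def hca_complete_linkage(frame: pd.DataFrame) -> pd.DataFrame:
    """Agglomerative clustering, farthest-neighbour (complete) linkage,
    Euclidean metric.

    Returns the merge list: columns left, right (cluster indices; leaves
    are 0..n-1, merges continue from n), height (Å-equivalent descriptor
    distance) and size. Heights are non-decreasing.
    """
    if len(frame) < 2:
        raise TooFewSamples("clustering needs >= 2 samples")
    z = linkage(pdist(frame.to_numpy(dtype=float)), method="complete")
    return pd.DataFrame({
        "left": z[:, 0].astype(int), "right": z[:, 1].astype(int),
        "height": z[:, 2], "size": z[:, 3].astype(int),
    })


def pca_explore(frame: pd.DataFrame, n_components: int | None = None
                ) -> dict[str, np.ndarray | pd.DataFrame]:
    """PCA of an autoscaled descriptor matrix via SVD.

    Returns orthonormal loadings, scores and explained variances
    (descending, summing to the total variance at full rank).
    """
    x = frame.to_numpy(dtype=float)
    centred = x - x.mean(0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(len(s), n_components or len(s))
    explained = (s ** 2) / max(len(x) - 1, 1)
    scores = u[:, :k] * s[:k]
    return {
        "scores": pd.DataFrame(scores, index=frame.index,
                               columns=[f"PC{i+1}" for i in range(k)]),
        "loadings": pd.DataFrame(vt[:k].T, index=frame.columns,
                                 columns=[f"PC{i+1}" for i in range(k)]),
        "explained_variance": explained[:k],
    }
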