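"""Ward.D2 clustering and PCA of S-IR length-frequency profiles.

The input is a matrix of per-kbp S-IR frequencies: one row per genome
or group, one column per arm length 6..30, a pooled ">30" bin, and the
8+/10+/12+ aggregates. Clustering uses Euclidean distances with the
Ward.D2 criterion (squared distances inside the Lance–Williams update,
heights reported on the distance scale), matching R's
``hclust(method = "ward.D2")``. PCA centers and unit-scales columns by
default; zero-variance columns are left unscaled with a warning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import ValidationError
from .stats import LengthProfile, LENGTH_CLASSES, CLASS_THRESHOLDS

log = logging.getLogger(__name__)

PROFILE_COLUMNS = tuple(str(L) for L in range(6, 31)) + (">30", "8+", "10+", "12+")


def profile_matrix(profiles: Sequence[LengthProfile]) -> pd.DataFrame:
    """Stack profiles into a row-per-owner frequency matrix.

    Columns are fixed: per-length frequencies for arms 6..30, the pooled
    ">30" bin, and the 8+/10+/12+ aggregate frequencies (all per kbp).
    """
    rows = {}
    for p in profiles:
        f = p.freq_per_kbp
        agg = p.agg_counts
        row = [f.get(L, 0.0) for L in range(6, 31)]
        row.append(1000.0 * p.over30 / p.seq_bp)
        row.extend(1000.0 * agg[c] / p.seq_bp for c in ("8+", "10+", "12+"))
        rows[p.owner] = row
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(PROFILE_COLUMNS))


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result.

    ``merges`` lists (left, right, height) with scipy node numbering:
    leaves are 0..n-1 in ``leaves`` order, merge k creates node n+k.
    Heights are non-decreasing (Ward monotonicity).
    """
    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def linkage(self) -> np.ndarray:
        """scipy-format linkage matrix (with cluster sizes recomputed)."""
        n = len(self.leaves)
        sizes = {i: 1 for i in range(n)}
        z = np.zeros((len(self.merges), 4))
        for k, (a, b, h) in enumerate(self.merges):
            sizes[n + k] = sizes[a] + sizes[b]
            z[k] = (a, b, h, sizes[n + k])
        return z


def ward_cluster(m: pd.DataFrame) -> Dendrogram:
    """Hierarchical clustering with Euclidean distance and Ward.D2 linkage."""
    if len(m) < 2:
        raise ValidationError("ward_cluster requires at least 2 rows")
    z = hierarchy.linkage(m.to_numpy(dtype=float), method="ward")
    merges = tuple((int(a), int(b), float(h)) for a, b, h, _ in z)
    heights = [h for _, _, h in merges]
    assert all(h2 >= h1 - 1e-9 for h1, h2 in zip(heights, heights[1:]))
    return Dendrogram(leaves=tuple(str(i) for i in m.index), merges=merges)


def to_newick(d: Dendrogram) -> str:
    """Serialise a dendrogram as Newick with ultrametric branch lengths.

    Node depths are merge height / 2, so two leaves merged at height h
    sit h/2 from their parent and leaf-to-leaf path lengths equal the
    merge heights.
    """
    n = len(d.leaves)
    if n == 1 and not d.merges:
        return f"{d.leaves[0]};"
    depth = {i: 0.0 for i in range(n)}
    label = {i: d.leaves[i] for i in range(n)}
    for k, (a, b, h) in enumerate(d.merges):
        node = n + k
        depth[node] = h / 2.0
        la = f"{label[a]}:{depth[node] - depth[a]:.6g}"
        lb = f"{label[b]}:{depth[node] - depth[b]:.6g}"
        label[node] = f"({la},{lb})"
    return f"{label[n + len(d.merges) - 1]};"


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame        # rows × components
    loadings: pd.DataFrame      # variables × components, orthonormal
    explained_variance: np.ndarray
    explained_ratio: np.ndarray


def pca(m: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA of a frequency matrix via SVD of the processed data.

    Columns are centered and unit-scaled (sample sd, ddof=1) by default;
    zero-variance columns are skipped by the scaling with a warning. The
    sign of each component is fixed so its largest-magnitude loading is
    positive, making outputs deterministic. Explained variances over all
    retained components sum to the total variance of the processed
    matrix.
    """
    if len(m) < 2 or m.shape[1] < 2:
        raise ValidationError("pca requires at least 2 rows and 2 columns")
    x = m.to_numpy(dtype=float).copy()
    if center:
        x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            log.warning("pca: %d zero-variance column(s) left unscaled",
                        int(zero.sum()))
        sd[zero] = 1.0
        x /= sd
    if not np.any(x):
        raise ValidationError("pca: matrix is constant after processing")
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n - 1, x.shape[1])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    var = s ** 2 / (n - 1)
    comps = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=m.columns, columns=comps),
        explained_variance=var,
        explained_ratio=var / var.sum(),
    )
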