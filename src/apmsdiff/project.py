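"""Uncentered PCA of median interaction profiles and agglomerative clustering.

Because every column of the median-profile matrix derives from the same
background-referenced processing, the projection deliberately skips centering
and scaling: it is a plain singular value decomposition of the raw matrix.
Explained fractions therefore refer to the total sum of squares, not variance
about the mean — for matrices with a large common offset the first component
absorbs that offset, which differs from centered-PCA conventions.

Protein clustering uses average-linkage hierarchical agglomeration on
Euclidean distances, with nested cuts across a range of partition sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .quant import column_floors
from .tables import DataError


@dataclass
class ProjectionResult:
    """Scores, explained fractions, loadings and cluster labels."""

    scores: pd.DataFrame          # protein x component
    explained_fraction: np.ndarray
    loadings: pd.DataFrame        # condition x component ("arrows")
    cluster_labels: pd.Series | None = None
    k: int | None = None


def median_profile_matrix(medians: dict[str, pd.Series], fill: str = "floor",
                          floors: pd.Series | None = None) -> pd.DataFrame:
    """Assemble per-condition median series into a complete profile matrix.

    Proteins missing from a condition are filled with that column's floor
    when ``fill='floor'`` (an explicit per-condition ``floors`` series if
    given, else the column minimum), or dropped entirely with
    ``fill='drop'``.
    """
    m = pd.DataFrame(medians)
    if fill == "drop":
        return m.dropna()
    if fill == "floor":
        fill_values = m.min(axis=0) if floors is None else floors
        return m.fillna(fill_values)
    raise DataError(f"unknown fill policy {fill!r}")


def pca_uncentered(m: pd.DataFrame, n_components: int | None = None) -> ProjectionResult:
    """Singular value decomposition of the raw (uncentered, unscaled) matrix.

    Explained fractions are sigma_i^2 / sum(sigma^2) and sum to 1; the input
    is reconstructed exactly by scores @ loadings.T over all components.
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise DataError("pca_uncentered needs at least a 2x2 matrix")
    x = m.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise DataError("median profile matrix contains missing values; fill upstream")
    if not x.any():
        raise DataError("rank-0 (all-zero) matrix has no principal components")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    explained = s ** 2 / np.sum(s ** 2)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=m.index, columns=comp_names)
    loadings = pd.DataFrame(vt[:k].T, index=m.columns, columns=comp_names)
    return ProjectionResult(scores=scores, explained_fraction=explained[:k],
                            loadings=loadings)


def _linkage(m: pd.DataFrame, method: str, metric: str) -> np.ndarray:
    if m.shape[0] < 2:
        raise DataError("clustering needs at least 2 rows")
    return linkage(pdist(m.to_numpy(dtype=float), metric=metric), method=method)


def hac_cluster(m: pd.DataFrame, k: int, method: str = "average",
                metric: str = "euclidean") -> pd.Series:
    """Cut an average-linkage dendrogram of the profile rows into k clusters.

    Labels are renumbered 1..k in order of first appearance, so equal inputs
    yield identical labelings regardless of scipy's internal ordering.
    """
    if not 2 <= k <= m.shape[0]:
        raise DataError(f"k={k} out of range [2, {m.shape[0]}]")
    z = _linkage(m, method, metric)
    return _cut(z, k, m.index)


def _cut(z: np.ndarray, k: int, index: pd.Index) -> pd.Series:
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        labels[i] = relabel.setdefault(lab, len(relabel) + 1)
    return pd.Series(labels, index=index, name="cluster")


def sweep_partitions(m: pd.DataFrame, k_range: range = range(3, 13),
                     method: str = "average", metric: str = "euclidean"
                     ) -> dict[int, pd.Series]:
    """Nested cuts of one dendrogram across a range of partition sizes."""
    ks = [k for k in k_range if 2 <= k <= m.shape[0]]
    if not ks:
        raise DataError("k_range contains no feasible partition size")
    z = _linkage(m, method, metric)
    return {k: _cut(z, k, m.index) for k in ks}
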