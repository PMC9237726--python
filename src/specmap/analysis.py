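"""Dimensionality reduction and clustering of pixel spectra.

PCA produces eigen-spectra (loading vectors over the wavenumber axis),
per-pixel scores and explained-variance ratios; clustering builds a
k-nearest-neighbor graph on the PCA scores and partitions it with the
Leiden community-detection algorithm.  Region selection restricts the
spectral range before either step.
"""

from __future__ import annotations

from typing import Optional

import igraph
import leidenalg
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core import ClusterAssignment, PCAResult, SpectralMap
from .errors import DataError, IncompatibleAxesError, ParameterError, WindowError
from .io import AXIS_ATOL

__all__ = [
    "select_region",
    "fit_pca",
    "cumulative_variance",
    "project",
    "cluster",
    "relabel_by_size",
]


def select_region(smap: SpectralMap, lo: float, hi: float) -> SpectralMap:
    """Restrict the map to wavenumbers in the closed interval [lo, hi]."""
    if not lo < hi:
        raise ParameterError(f"need lo < hi, got [{lo}, {hi}]")
    cols = (smap.axis >= lo) & (smap.axis <= hi)
    if not cols.any():
        below = smap.axis[smap.axis < lo]
        above = smap.axis[smap.axis > hi]
        nearest = []
        if below.size:
            nearest.append(f"{below[-1]:g}")
        if above.size:
            nearest.append(f"{above[0]:g}")
        raise WindowError(
            f"region [{lo}, {hi}] cm^-1 selects no axis points; nearest available: "
            + ", ".join(nearest)
        )
    return smap.with_data(
        absorbance=smap.absorbance[:, cols],
        axis=smap.axis[cols],
        log_entry=f"select_region: [{lo}, {hi}] cm^-1, {int(cols.sum())} points",
    )


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> None:
    """Make each loading's largest-magnitude entry positive (in place)."""
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1.0
            scores[:, k] *= -1.0


def fit_pca(smap: SpectralMap, n_components: int) -> PCAResult:
    """Fit PCA on mean-centered spectra (no variance scaling).

    Eigen-spectra are the unit-norm eigenvectors of the sample covariance
    of the pixel spectra; explained-variance ratios are fractions of the
    total centered variance.  The sign convention (largest-magnitude entry
    of each eigen-spectrum positive) makes output reproducible across
    eigensolvers.
    """
    if smap.n_pixels < 2:
        raise DataError("PCA needs at least 2 pixels")
    if not 1 <= n_components <= min(smap.n_pixels, smap.n_wavenumbers):
        raise ParameterError(
            f"n_components must be in [1, {min(smap.n_pixels, smap.n_wavenumbers)}], "
            f"got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(smap.absorbance)
    components = pca.components_.copy()
    _fix_signs(components, scores)
    return PCAResult(
        mean_spectrum=pca.mean_,
        eigen_spectra=components,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        explained_variance=pca.explained_variance_,
        axis=smap.axis.copy(),
    )


def cumulative_variance(pca: PCAResult) -> np.ndarray:
    """Running sum of the explained-variance ratios."""
    return np.cumsum(pca.explained_variance_ratio)


def project(smap: SpectralMap, pca: PCAResult) -> np.ndarray:
    """Project spectra onto fitted eigen-spectra: (x - mean) @ loadings.T.

    The map's axis must be identical to the axis the PCA was fitted on.
    """
    if smap.axis.size != pca.axis.size or np.any(np.abs(smap.axis - pca.axis) > AXIS_ATOL):
        raise IncompatibleAxesError("map axis differs from the axis the PCA was fitted on")
    return (smap.absorbance - pca.mean_spectrum) @ pca.eigen_spectra.T


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel communities so cluster 0 is the largest, descending by size;
    ties broken by the cluster's first-occurrence pixel index."""
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    first_seen = {int(u): int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-int((labels == u).sum()), first_seen[int(u)]))
    mapping = {int(old): new for new, old in enumerate(order)}
    return np.array([mapping[int(v)] for v in labels], dtype=int)


def cluster(
    scores: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 0.5,
    seed: int = 0,
    compute_embedding: bool = False,
) -> ClusterAssignment:
    """Leiden community detection on a k-nearest-neighbor graph of scores.

    The kNN graph (Euclidean distances on the supplied score matrix) is
    symmetrized by the union of directed edges and kept unweighted; Leiden
    optimizes RB-configuration modularity at the given resolution with the
    given random seed.  Labels are relabeled descending by cluster size.

    The default resolution (0.5) targets tissue-region granularity: at
    resolution 1.0 the modularity null model's resolution limit makes
    plain modularity split spatially coherent regions of more than a few
    hundred pixels even when they are perfectly separated in score space,
    so a coarser default is appropriate for maps of ~10^3 pixels.  Raise
    the resolution to look for finer substructure.
    If requested, a 2-D UMAP embedding of the scores (same ``n_neighbors``,
    seeded) is attached for visualization only; it never feeds clustering.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ParameterError("scores must be a 2-D matrix")
    n = scores.shape[0]
    if n_neighbors < 2:
        raise ParameterError("n_neighbors must be >= 2")
    if n_neighbors >= n:
        raise ParameterError(f"n_neighbors={n_neighbors} must be < n_pixels={n}")
    if resolution <= 0:
        raise ParameterError("resolution must be positive")

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:  # drop self
            a, b = (i, int(j)) if i < j else (int(j), i)
            edges.add((a, b))
    graph = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = relabel_by_size(np.array(partition.membership))

    embedding: Optional[np.ndarray] = None
    if compute_embedding:
        import umap  # deferred: heavy import, visualization only

        reducer = umap.UMAP(n_neighbors=n_neighbors, n_components=2, random_state=seed)
        embedding = np.asarray(reducer.fit_transform(scores), dtype=float)

    return ClusterAssignment(
        labels=labels,
        embedding=embedding,
        params={"n_neighbors": n_neighbors, "resolution": resolution, "seed": seed},
    )
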