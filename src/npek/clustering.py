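"""Structural clustering of molecules via k-means on folded bit fingerprints.

The molecule collection is partitioned into homogeneous structural classes by
k-means over the 1024-bit, radius-3, non-chiral folded encoding.  The number
of clusters is a user judgement supported by the exported inertia (elbow)
curve; no automatic kink detection is performed.  A 2-component PCA projection
is provided for visual inspection of the classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ParameterError
from .fingerprints import CLUSTERING_PARAMS, FingerprintParams, FoldedBitFingerprint

DEFAULT_K = 8
DEFAULT_N_INIT = 10


@dataclass
class ClusterModel:
    """Fitted k-means centroids over folded bit fingerprints."""

    k: int
    centroids: np.ndarray  # shape (k, n_bits), real-valued
    inertia: float  # sum of squared sample-to-assigned-centroid distances
    params: FingerprintParams
    seed: int

    def assign(self, bits: np.ndarray) -> np.ndarray:
        """Nearest-centroid (Euclidean) assignment; ties go to the lowest index."""
        bits = np.atleast_2d(np.asarray(bits, dtype=np.float64))
        if bits.shape[1] != self.centroids.shape[1]:
            raise ParameterError(
                f"fingerprint length {bits.shape[1]} != centroid length {self.centroids.shape[1]}"
            )
        d2 = ((bits[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def fit_kmeans(
    bit_matrix: np.ndarray,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_init: int = DEFAULT_N_INIT,
    params: FingerprintParams = CLUSTERING_PARAMS,
) -> ClusterModel:
    """Best-of-``n_init`` k-means fit; deterministic for a fixed seed."""
    X = np.asarray(bit_matrix, dtype=np.float64)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} must satisfy 1 <= k <= n={n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        params=params,
        seed=seed,
    )


def inertia_curve(
    bit_matrix: np.ndarray,
    k_values: list[int],
    seed: int = 0,
    n_init: int = DEFAULT_N_INIT,
) -> list[tuple[int, float]]:
    """(k, inertia) table over independent best-of-n_init fits, for elbow plots."""
    if sorted(k_values) != list(k_values):
        raise ParameterError("k_values must be sorted ascending")
    return [(k, fit_kmeans(bit_matrix, k=k, seed=seed, n_init=n_init).inertia) for k in k_values]


def assign_cluster(model: ClusterModel, fp: FoldedBitFingerprint | np.ndarray) -> int:
    """Cluster id (nearest centroid) of one folded fingerprint."""
    bits = fp.bits if isinstance(fp, FoldedBitFingerprint) else np.asarray(fp)
    return int(model.assign(bits)[0])


def project_pca(bit_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Top-two principal components of the fingerprint matrix.

    Returns (n x 2 coordinates, explained-variance fractions).  For degenerate
    input with zero total variance all coordinates and fractions are 0.
    """
    X = np.asarray(bit_matrix, dtype=np.float64)
    if X.shape[0] < 3:
        raise ParameterError("PCA projection requires at least 3 samples")
    if np.allclose(X.var(axis=0), 0):
        return np.zeros((X.shape[0], 2)), np.zeros(2)
    n_comp = min(2, min(X.shape) - 0)
    pca = PCA(n_components=2 if min(X.shape) >= 2 else 1)
    coords = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    if coords.shape[1] < 2:  # rank-1 input
        coords = np.hstack([coords, np.zeros((X.shape[0], 1))])
        frac = np.append(frac, 0.0)
    return coords, frac
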