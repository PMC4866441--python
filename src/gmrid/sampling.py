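"""Landmark voxel selection and approximation-quality scoring.

The Nystrom approximation stands or falls with the l landmark voxels
whose kernel columns are actually computed.  MRI volumes are dominated
by background voxels whose patches are all alike, so uniform sampling
wastes landmarks on duplicate columns; clustering the patch features
with k-means (k = l) and taking one real voxel per cluster concentrates
landmarks in the informative tissue while still covering the full
dynamic range.

Approximation quality is scored by relative accuracy: the Frobenius
error of the optimal rank-r truncation divided by that of the
approximant, times 100, so the optimum scores 100 and every rank-<=r
approximant scores at most 100 (Eckart-Young).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .patch_kernel import KernelSpec, patch_matrix
from .volume_io import Volume

log = logging.getLogger("gmrid")


@dataclass
class SampleSet:
    """The l landmark voxels and how they were chosen.

    indices are distinct linear voxel indices; the same
    (volume, scheme, l, seed) always reproduces the same set.
    cluster_labels is the per-voxel cluster id (k-means scheme only).
    """

    indices: np.ndarray
    scheme: str
    l: int
    seed: int
    cluster_labels: np.ndarray | None = None

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if self.indices.size != self.l:
            raise ValueError("l must equal the number of indices")
        if np.unique(self.indices).size != self.l:
            raise ValueError("landmark indices must be distinct")


def uniform_sample(vol: Volume, l: int, seed: int) -> SampleSet:
    """l distinct voxels drawn uniformly without replacement."""
    n = vol.n
    if not 1 <= l <= n:
        raise ValueError(f"l={l} outside [1, n={n}]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=l, replace=False)
    return SampleSet(indices=np.sort(idx), scheme="uniform", l=l, seed=seed)


def kmeans_sample(vol: Volume, l: int, spec: KernelSpec, seed: int) -> SampleSet:
    """k-means landmarks: cluster patch features with k = l, then return
    the real voxel nearest each centroid.

    Features are the same patch vectors the kernel compares (radius-0
    patches reduce this to intensity clustering).  k-means++ init, at
    most 100 Lloyd iterations, tolerance 1e-4, fixed seed.  Clusters
    that end up empty or collide on the same nearest voxel are refilled
    from the farthest unassigned feature, so exactly l distinct voxels
    are always returned.
    """
    n = vol.n
    if not 1 <= l <= n:
        raise ValueError(f"l={l} outside [1, n={n}]")
    if l == n:
        return SampleSet(
            indices=np.arange(n, dtype=np.intp),
            scheme="kmeans",
            l=l,
            seed=seed,
            cluster_labels=np.arange(n, dtype=np.intp),
        )

    X = patch_matrix(vol, spec.patch_radius)
    with warnings.catch_warnings():
        # duplicate background patches trigger a distinct-cluster warning
        warnings.simplefilter("ignore")
        km = KMeans(
            n_clusters=l,
            init="k-means++",
            n_init=1,
            max_iter=100,
            tol=1e-4,
            random_state=seed,
        ).fit(X)
    labels = km.labels_.astype(np.intp)
    centers = km.cluster_centers_

    chosen: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for c in range(l):
        members = np.flatnonzero((labels == c) & ~taken)
        if members.size == 0:
            continue  # refilled below
        d2 = np.einsum("ij,ij->i", X[members] - centers[c], X[members] - centers[c])
        pick = int(members[np.argmin(d2)])
        chosen.append(pick)
        taken[pick] = True

    missing = l - len(chosen)
    if missing > 0:
        # farthest-point refill: deterministic, keeps exactly l landmarks
        log.warning("kmeans_sample: refilling %d empty/collided clusters", missing)
        for _ in range(missing):
            cur = X[np.asarray(chosen, dtype=np.intp)]
            free = np.flatnonzero(~taken)
            # distance of each free voxel to its nearest chosen landmark
            d2 = np.min(
                ((X[free][:, None, :] - cur[None, :, :]) ** 2).sum(-1), axis=1
            )
            pick = int(free[np.argmax(d2)])
            chosen.append(pick)
            taken[pick] = True

    idx = np.sort(np.asarray(chosen, dtype=np.intp))
    return SampleSet(indices=idx, scheme="kmeans", l=l, seed=seed, cluster_labels=labels)


def relative_accuracy(K: np.ndarray, r: int, K_approx: np.ndarray) -> float:
    """100 * ||K - K_(r)||_F / ||K - K_approx||_F.

    K_(r) is the exact best rank-r approximation (truncated
    eigendecomposition).  Equals 100 when K_approx attains the optimum;
    lies in [0, 100] for any approximant of rank <= r.  If both errors
    vanish (K itself has rank <= r and is matched) returns 100.
    """
    K = np.asarray(K, dtype=np.float64)
    K_approx = np.asarray(K_approx, dtype=np.float64)
    if K.shape != K_approx.shape or K.shape[0] != K.shape[1]:
        raise ValueError(f"shape mismatch: K {K.shape}, approx {K_approx.shape}")
    if not 1 <= r <= K.shape[0]:
        raise ValueError(f"rank r={r} outside [1, {K.shape[0]}]")
    w, U = eigh(K)
    order = np.argsort(w)[::-1][:r]
    K_r = (U[:, order] * w[order]) @ U[:, order].T
    num = float(np.linalg.norm(K - K_r, "fro"))
    den = float(np.linalg.norm(K - K_approx, "fro"))
    if den == 0.0:
        return 100.0
    return 100.0 * num / den
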