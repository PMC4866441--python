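"""3D patch extraction and the NLM-style similarity kernel.

The global filter's affinity matrix M has entries
``M_ij = exp(-||p_i - p_j||^2 / (L h^2))`` where p_i is the
(2r+1)^3 patch around voxel i (mirror-padded at the borders) and L is
the patch length.  Normalizing the squared distance by L makes the
bandwidth h comparable across patch radii.  Only the landmark rows
[M1 M12] are ever computed; the dense matrix exists only in test
oracles and the exact (--exact) route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .volume_io import Volume, grid_index

log = logging.getLogger("gmrid")

#: registry of kernel families; each maps squared patch distances
#: (already normalized by patch length) to similarities in (0, 1].
KERNEL_FAMILIES = {
    "nlm_gaussian": lambda d2_over_L, h: np.exp(-d2_over_L / (h * h)),
}


@dataclass
class KernelSpec:
    """Parameters of the patch-similarity kernel.

    patch_radius
        Neighborhood radius in voxels; patches are (2r+1)^3 cubes.
    bandwidth_h
        Kernel bandwidth in intensity units on the rescaled [0,1] range.
    kernel_family
        Name in :data:`KERNEL_FAMILIES` (pluggable; only the NLM
        Gaussian-of-Euclidean-distance kernel ships).
    """

    patch_radius: int = 1
    bandwidth_h: float = 0.4
    kernel_family: str = "nlm_gaussian"

    def __post_init__(self):
        if self.patch_radius < 0:
            raise ValueError("patch_radius must be non-negative")
        if self.bandwidth_h <= 0:
            raise ValueError("bandwidth_h must be positive")
        if self.kernel_family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.kernel_family!r}")

    @property
    def patch_length(self) -> int:
        w = 2 * self.patch_radius + 1
        return w * w * w


@dataclass
class KernelBlocks:
    """Sampled blocks of the affinity matrix M.

    M1 is the l-by-l landmark block, M12 the l-by-(n-l) block against
    the remaining voxels; the lower-right (n-l)^2 block is never
    materialized.  ``sample_order`` is the permutation placing landmark
    voxels first (sample_order[pos] = linear voxel index).
    """

    M1: np.ndarray
    M12: np.ndarray
    sample_order: np.ndarray

    @property
    def l(self) -> int:
        return self.M1.shape[0]

    @property
    def n(self) -> int:
        return self.M1.shape[0] + self.M12.shape[1]

    def validate(self, tol: float = 1e-12) -> None:
        if self.M1.shape[0] != self.M1.shape[1]:
            raise ValueError("M1 must be square")
        if self.M12.shape[0] != self.M1.shape[0]:
            raise ValueError("M12 row count must match M1")
        if np.max(np.abs(self.M1 - self.M1.T)) > tol:
            raise ValueError("M1 must be symmetric")
        if np.max(np.abs(np.diag(self.M1) - 1.0)) > tol:
            raise ValueError("M1 must have unit diagonal")


def _mirror(idx: np.ndarray, size: int) -> np.ndarray:
    """Mirror reflection about the edge sample (edge not repeated)."""
    if size == 1:
        return np.zeros_like(idx)
    period = 2 * size - 2
    idx = np.abs(idx) % period
    return np.where(idx >= size, period - idx, idx)


def extract_patch(vol: Volume, index: int, radius: int) -> np.ndarray:
    """The (2r+1)^3 neighborhood of one voxel as a flat vector.

    Offsets scan in C-order; out-of-bounds neighbors are filled by
    mirror reflection.  Radius 0 returns the voxel's own intensity.
    """
    n = vol.n
    if not 0 <= index < n:
        raise ValueError(f"voxel index {index} out of range [0, {n})")
    ci, cj, ck = (int(c) for c in grid_index(index, vol.shape))
    offs = np.arange(-radius, radius + 1)
    ii = _mirror(ci + offs, vol.shape[0])
    jj = _mirror(cj + offs, vol.shape[1])
    kk = _mirror(ck + offs, vol.shape[2])
    return vol.data[np.ix_(ii, jj, kk)].reshape(-1)


def patch_matrix(vol: Volume, radius: int) -> np.ndarray:
    """All patches at once: n-by-L matrix, row i = extract_patch(vol, i).

    Built from one mirror-padded copy with a sliding window; memory is
    n * (2r+1)^3 doubles.
    """
    if radius == 0:
        return vol.flat()[:, None].copy()
    pad = [(radius, radius)] * 3
    padded = np.pad(vol.data, pad, mode="reflect")
    w = 2 * radius + 1
    win = sliding_window_view(padded, (w, w, w))
    return win.reshape(vol.n, w * w * w).astype(np.float64, copy=True)


def kernel_weight(p: np.ndarray, q: np.ndarray, spec: KernelSpec) -> float:
    """Similarity exp(-||p-q||^2 / (L h^2)) in (0, 1]; 1 iff p == q."""
    p = np.asarray(p, dtype=np.float64).reshape(-1)
    q = np.asarray(q, dtype=np.float64).reshape(-1)
    if p.shape != q.shape:
        raise ValueError(f"patch length mismatch: {p.shape} vs {q.shape}")
    fam = KERNEL_FAMILIES[spec.kernel_family]
    d2 = float(np.dot(p - q, p - q))
    return float(fam(d2 / p.size, spec.bandwidth_h))


def compute_kernel_blocks(
    vol: Volume,
    samples,
    spec: KernelSpec,
    chunk: int = 8192,
) -> KernelBlocks:
    """Evaluate the landmark rows [M1 M12] of the affinity matrix.

    M12 columns are computed in chunks of ``chunk`` voxels so the
    working set stays at l * chunk doubles.  Deterministic given inputs.
    """
    idx = np.asarray(samples.indices, dtype=np.intp)
    l = idx.size
    n = vol.n
    if not 1 <= l <= n:
        raise ValueError(f"landmark count {l} outside [1, {n}]")
    if np.unique(idx).size != l:
        raise ValueError("landmark indices must be distinct")

    P = patch_matrix(vol, spec.patch_radius)
    L = P.shape[1]
    fam = KERNEL_FAMILIES[spec.kernel_family]
    PL = P[idx]

    d2 = cdist(PL, PL, "sqeuclidean")
    M1 = fam(d2 / L, spec.bandwidth_h)
    M1 = 0.5 * (M1 + M1.T)
    np.fill_diagonal(M1, 1.0)

    rest = np.setdiff1d(np.arange(n, dtype=np.intp), idx, assume_unique=False)
    M12 = np.empty((l, rest.size), dtype=np.float64)
    for s in range(0, rest.size, chunk):
        cols = rest[s : s + chunk]
        M12[:, s : s + cols.size] = fam(cdist(PL, P[cols], "sqeuclidean") / L, spec.bandwidth_h)

    order = np.concatenate([idx, rest])
    return KernelBlocks(M1=M1, M12=M12, sample_order=order)
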