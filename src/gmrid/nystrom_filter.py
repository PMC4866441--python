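"""Nystrom spectrum of the global filter: extension, Sinkhorn scaling,
and one-shot orthogonalization.

Given the sampled affinity blocks M1 (landmarks) and M12 (landmarks vs
rest), the eigenvectors of the full n-by-n affinity are approximated by
eigendecomposing M1 and extending via ``M12ᵀ γ1 ε1⁻¹``, which implies
the rank-l surrogate ``[[M1, M12], [M12ᵀ, M12ᵀ M1⁻¹ M12]]``.  A
symmetric Sinkhorn iteration drives the implied row sums to 1 so the
filter is doubly stochastic (unit leading eigenvalue, mean-preserving),
and the final orthonormal spectrum comes from the one-shot
decomposition of ``O = W1 + W1^{-1/2} W12 W12ᵀ W1^{-1/2}``, whose
eigenpairs reproduce the surrogate exactly while giving ṼᵀṼ = I by
construction.

A dense route (:func:`dense_filter_spectrum`) builds the full matrix
for small volumes; it backs the ``--exact`` CLI flag and serves as the
oracle the approximate pipeline is tested against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

from .patch_kernel import KERNEL_FAMILIES, KernelBlocks, KernelSpec, patch_matrix
from .volume_io import Volume

log = logging.getLogger("gmrid")

DENSE_LIMIT = 5000  # max n for any operation that materializes n x n


@dataclass
class NystromFactors:
    """Approximated leading eigenpairs of the affinity matrix M.

    eigvecs is n-by-r in sample-first ordering (landmark rows first),
    eigvals descending.
    """

    eigvecs: np.ndarray
    eigvals: np.ndarray
    l: int
    r: int

    def __post_init__(self):
        if self.r > self.l:
            raise ValueError("retained rank r cannot exceed landmark count l")
        if np.any(np.diff(self.eigvals) > 0):
            raise ValueError("eigvals must be sorted descending")
        if not (np.all(np.isfinite(self.eigvecs)) and np.all(np.isfinite(self.eigvals))):
            raise ValueError("non-finite entries in Nystrom factors")


@dataclass
class FilterSpectrum:
    """Orthonormal spectrum (Ṽ, Ẽ) of the symmetrized global filter.

    eigvecs: n-by-m with ṼᵀṼ = I (1e-8); eigvals in [0, 1], descending,
    leading value 1 within Sinkhorn tolerance for a converged filter.
    sample_order maps spectrum rows back to voxel order
    (sample_order[pos] = voxel index).
    """

    eigvecs: np.ndarray
    eigvals: np.ndarray
    sample_order: np.ndarray

    @property
    def n(self) -> int:
        return self.eigvecs.shape[0]

    @property
    def m(self) -> int:
        return self.eigvecs.shape[1]


@dataclass
class ScaledBlocks:
    """Sinkhorn-scaled filter blocks plus convergence diagnostics."""

    W1: np.ndarray
    W12: np.ndarray
    residual: float
    iterations: int
    converged: bool


def _eigh_desc(A: np.ndarray):
    w, U = eigh(A)
    return w[::-1].copy(), U[:, ::-1].copy()


def _spd_inv_factor(A: np.ndarray, floor_rel: float = 1e-10):
    """Eigendecomposition of a symmetric PSD matrix with a relative
    eigenvalue floor; returns (w_clipped, U) for forming A^{-1}, A^{-1/2}."""
    w, U = _eigh_desc(A)
    wmax = max(w[0], 0.0)
    if wmax <= 0:
        raise np.linalg.LinAlgError("matrix is not positive semidefinite")
    floor = floor_rel * wmax
    if w[-1] < floor:
        log.debug("eigenvalue floor applied: min %.3e -> %.3e", w[-1], floor)
    return np.maximum(w, floor), U


def nystrom_eigs(blocks: KernelBlocks, r: int, ridge_rel: float = 1e-10,
                 indefinite_tol: float = 1e-8) -> NystromFactors:
    """Approximate the top-r eigenpairs of M from its sampled blocks.

    M1 = γ1 ε1 γ1ᵀ; the retained eigenvectors are extended to the
    unsampled voxels by M12ᵀ γ1 ε1⁻¹.  If the smallest retained
    eigenvalue falls below ridge_rel times the largest, a ridge of that
    size is added before inversion (logged).
    """
    l = blocks.l
    if r > l:
        raise ValueError(f"rank r={r} exceeds landmark count l={l}")
    w, U = _eigh_desc(blocks.M1)
    if w[-1] < -indefinite_tol * max(abs(w[0]), 1.0):
        raise np.linalg.LinAlgError(
            f"M1 numerically indefinite: minimum eigenvalue {w[-1]:.3e}"
        )
    w_r = w[:r].copy()
    U_r = U[:, :r]
    ridge = ridge_rel * w[0]
    if w_r[-1] < ridge:
        log.warning(
            "nystrom_eigs: smallest retained eigenvalue %.3e < %.3e; adding ridge",
            w_r[-1], ridge,
        )
        w_r = w_r + ridge
    ext = blocks.M12.T @ (U_r / w_r)
    vecs = np.vstack([U_r, ext])
    return NystromFactors(eigvecs=vecs, eigvals=w_r, l=l, r=r)


def reconstruct_kernel(factors: NystromFactors, dense_limit: int = DENSE_LIMIT) -> np.ndarray:
    """Dense surrogate γ̃ ε1 γ̃ᵀ (test-scale only).

    With r = l this equals [[M1, M12], [M12ᵀ, M12ᵀ M1⁻¹ M12]] up to
    the ridge floor.
    """
    n = factors.eigvecs.shape[0]
    if n > dense_limit:
        raise ValueError(
            f"refusing to materialize {n}x{n} kernel (dense limit {dense_limit}); "
            "reconstruct_kernel is an oracle-scale operation"
        )
    return (factors.eigvecs * factors.eigvals) @ factors.eigvecs.T


def one_shot_spectrum(A: np.ndarray, B: np.ndarray, m: int, floor_rel: float = 1e-10):
    """Top-m orthonormal eigenpairs of the Nystrom surrogate
    [[A, B], [Bᵀ, Bᵀ A⁻¹ B]] without forming it.

    Eigendecomposes O = A + A^{-1/2} B Bᵀ A^{-1/2} (l-by-l); the
    eigenvalues of O are exactly those of the surrogate and
    Ṽ = [A; Bᵀ] A^{-1/2} V_O E_O^{-1/2} are its orthonormal
    eigenvectors.  Unlike the spectrum of A alone, this weights each
    direction by its total column energy, which is what makes rank-r
    truncation meaningful for *non-uniform* (e.g. k-means) landmarks:
    a single landmark standing for a huge duplicate-patch background
    cluster still produces the dominant eigenvalue it should.

    Returns (eigvals descending, eigvecs n-by-m, sample-first order).
    """
    l = A.shape[0]
    if m > l:
        raise ValueError(f"rank m={m} exceeds landmark count l={l}")
    w1, U1 = _spd_inv_factor(A, floor_rel=floor_rel)
    inv_sqrt = (U1 / np.sqrt(w1)) @ U1.T
    S = inv_sqrt @ B
    O = A + S @ S.T
    O = 0.5 * (O + O.T)
    e, Q = _eigh_desc(O)
    e_m, Q_m = e[:m], Q[:, :m]
    e_safe = np.maximum(e_m, floor_rel * max(abs(e[0]), 1.0))
    core = inv_sqrt @ (Q_m / np.sqrt(e_safe))
    vecs = np.vstack([A @ core, B.T @ core])
    return e_m, vecs


def nystrom_rank_r_kernel(blocks: KernelBlocks, r: int,
                          dense_limit: int = DENSE_LIMIT) -> np.ndarray:
    """Rank-r Nystrom approximation of the kernel in *voxel* order
    (test-scale only): top-r spectrum of the surrogate, reassembled
    dense for comparison against the exact kernel."""
    n = blocks.n
    if n > dense_limit:
        raise ValueError(f"refusing dense {n}x{n} reconstruction (limit {dense_limit})")
    vals, vecs = one_shot_spectrum(blocks.M1, blocks.M12, r)
    approx = (vecs * vals) @ vecs.T
    inv = np.argsort(blocks.sample_order)
    return approx[np.ix_(inv, inv)]


def sinkhorn_symmetrize(
    blocks: KernelBlocks,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ScaledBlocks:
    """Symmetric Sinkhorn scaling of the sampled filter representation.

    Each step rescales W <- D^{-1/2} W D^{-1/2} with D the implied row
    sums of the full Nystrom surrogate (landmark rows: W1·1 + W12·1;
    extension rows: W12ᵀ(1 + W1⁻¹ W12·1)), computed without forming the
    n-by-n matrix.  Stops when every implied row sum is within tol of 1.
    Already doubly stochastic inputs are returned unchanged.  On
    non-convergence the best iterate is returned with converged=False
    (warning, not an exception).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    A = blocks.M1.astype(np.float64, copy=True)
    B = blocks.M12.astype(np.float64, copy=True)
    have_rest = B.shape[1] > 0

    def row_sums(A, B):
        rB = B.sum(axis=1)
        sA = A.sum(axis=1) + rB
        if have_rest:
            w, U = _spd_inv_factor(A)
            t = U @ ((U.T @ rB) / w)  # A^{-1} (B 1)
            sB = B.T @ (1.0 + t)
        else:
            sB = np.empty(0)
        return sA, sB

    best = None
    for it in range(max_iter + 1):
        sA, sB = row_sums(A, B)
        resid = float(max(np.max(np.abs(sA - 1.0)),
                          np.max(np.abs(sB - 1.0)) if have_rest else 0.0))
        if best is None or resid < best.residual:
            best = ScaledBlocks(W1=A.copy(), W12=B.copy(), residual=resid,
                                iterations=it, converged=resid <= tol)
        if resid <= tol:
            return best
        if it == max_iter:
            break
        s = np.concatenate([sA, sB])
        s = np.maximum(s, 1e-300)
        d = 1.0 / np.sqrt(s)
        dA, dB = d[: A.shape[0]], d[A.shape[0]:]
        A *= np.outer(dA, dA)
        if have_rest:
            B *= np.outer(dA, dB)
    log.warning(
        "sinkhorn_symmetrize: residual %.3e after %d iterations (tol %.1e)",
        best.residual, max_iter, tol,
    )
    return best


def orthogonalize_filter(
    W1: np.ndarray,
    W12: np.ndarray,
    m: int,
    sample_order: np.ndarray | None = None,
    floor_rel: float = 1e-10,
) -> FilterSpectrum:
    """One-shot orthogonalized spectrum of the Nystrom filter surrogate.

    O = W1 + W1^{-1/2} W12 W12ᵀ W1^{-1/2} = V_O E_O V_Oᵀ and
    Ṽ = [W1; W12ᵀ] W1^{-1/2} V_O E_O^{-1/2} (top-m columns); then
    Ṽ Ẽ Ṽᵀ reproduces [[W1, W12], [W12ᵀ, W12ᵀ W1⁻¹ W12]] and ṼᵀṼ = I
    algebraically.  Stored eigenvalues are clipped into [0, 1]: values
    marginally above 1 are approximation error and would amplify noise
    under the λ^k diffusion.
    """
    e_m, vecs = one_shot_spectrum(W1, W12, m, floor_rel=floor_rel)
    vals = np.clip(e_m, 0.0, 1.0)
    n = vecs.shape[0]
    if sample_order is None:
        sample_order = np.arange(n, dtype=np.intp)
    return FilterSpectrum(eigvecs=vecs, eigvals=vals, sample_order=np.asarray(sample_order, dtype=np.intp))


# ---------------------------------------------------------------------------
# dense route (exact filter for small volumes; oracle for the approximation)

def dense_affinity(vol: Volume, spec: KernelSpec, dense_limit: int = DENSE_LIMIT) -> np.ndarray:
    """Full n-by-n patch affinity matrix (small volumes only)."""
    n = vol.n
    if n > dense_limit:
        raise ValueError(f"volume has {n} voxels; dense route limited to {dense_limit}")
    P = patch_matrix(vol, spec.patch_radius)
    fam = KERNEL_FAMILIES[spec.kernel_family]
    M = fam(cdist(P, P, "sqeuclidean") / P.shape[1], spec.bandwidth_h)
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 1.0)
    return M


def dense_filter_spectrum(
    vol: Volume,
    spec: KernelSpec,
    m: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    dense_limit: int = DENSE_LIMIT,
) -> tuple[FilterSpectrum, float]:
    """Exact global filter spectrum via the dense matrix.

    Runs the same symmetric Sinkhorn scaling on the full affinity and
    eigendecomposes the result directly.  Returns (spectrum, sinkhorn
    residual).
    """
    M = dense_affinity(vol, spec, dense_limit=dense_limit)
    n = M.shape[0]
    W = M.copy()
    resid = np.inf
    for _ in range(max_iter + 1):
        s = W.sum(axis=1)
        resid = float(np.max(np.abs(s - 1.0)))
        if resid <= tol:
            break
        d = 1.0 / np.sqrt(np.maximum(s, 1e-300))
        W *= np.outer(d, d)
    w, U = _eigh_desc(W)
    if m is None:
        m = n
    vals = np.clip(w[:m], 0.0, 1.0)
    spectrum = FilterSpectrum(
        eigvecs=U[:, :m].copy(), eigvals=vals, sample_order=np.arange(n, dtype=np.intp)
    )
    return spectrum, resid
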