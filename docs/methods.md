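# Methods

## Model and pipeline

`gmrid` implements global spectral denoising of a 3D scalar volume.
Writing the volume as a vector `y` of length `n` (0-based, C-order,
last axis fastest — one shared pair of index functions in
`volume_io` keeps eigenvectors and voxels aligned), the stages are:

1. **Rescale** intensities to [0, 1] by the volume's min/max. All noise
   levels and bandwidths below live on this scale; the map is undone on
   output. Compute precision is float64 throughout; NIfTI output is
   stored float32.
2. **Stabilize** (Rician only): apply the variance-stabilizing
   transform (below) so the noise is approximately additive with
   constant sd σ.
3. **Landmarks**: choose `l = max(ceil(rate·n), rank)` voxels, either
   uniformly at random or (default) as k-means cluster representatives
   of the patch feature vectors.
4. **Kernel blocks**: evaluate the NLM affinity
   `M_ij = exp(−‖p_i − p_j‖²/(L h²))` on the landmark rows only
   (`M1`: l×l, `M12`: l×(n−l)), with mirror-reflected patches at the
   borders. The (n−l)² block is never formed.
5. **Sinkhorn scaling**: symmetric iteration `W ← D^{-1/2} W D^{-1/2}`
   where `D` holds the row sums of the implied Nyström surrogate
   `[[W1, W12], [W12ᵀ, W12ᵀ W1⁻¹ W12]]`, computed from the blocks
   alone. Stops when every implied row sum is within `tol` of 1
   (default 1e-6, max 200 iterations; non-convergence returns the best
   iterate with a flag rather than raising).
6. **Orthogonalization**: the one-shot decomposition of
   `O = W1 + W1^{-1/2} W12 W12ᵀ W1^{-1/2}` yields the top-m orthonormal
   eigenpairs (Ṽ, Ẽ) of the surrogate exactly; `ṼᵀṼ = I` holds by
   construction. Eigenvalues marginally above 1 (approximation error)
   are clipped to 1, since λ > 1 would amplify noise under λ^k.
7. **Selection and filtering**: project `b̂ = Ṽᵀ y`, estimate signal
   energies `b̂_j² − σ²` (clipped at 0), minimize
   `R(k, m) = Σ_{j≤m}((λ_j^{2k} − 2λ_j^k) b̂_j² + σ² λ_j^{2k})` over a
   grid, and apply `x̂ = V_m E_m^k V_mᵀ y`. Ties break toward smaller
   k, then smaller m. The constant `Σ x_i²` term of the underlying MSE
   is dropped (argmin-invariant).
8. **Invert the VST** (Rician only) with the exact *unbiased* inverse,
   then restore the original intensity scale.

### Why the MSE estimate is unbiased

For orthonormal `v_j` and white noise of variance σ²,
`E[(v_jᵀ y)²] = b_j² + σ²`, so `max((v_jᵀ y)² − σ², 0)` estimates the
clean projection energy `b_j²`. Substituting it into the filter MSE
`Σ_{j≤m}((λ_j^k − 1)² b_j² + σ² λ_j^{2k}) + Σ_{j>m} b_j²` and dropping
constants yields `R(k, m)` above.

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| patch radius `r` | 1 (3³ patches) | the common 3D non-local-means choice; keeps the feature dimension at 27 |
| bandwidth `h` | `max(σ, 0.1)` in `denoise()`; 0.4 in a bare `KernelSpec` | the per-element patch distance between same-tissue voxels concentrates around 2σ², so `h ≈ σ` keeps same-tissue weights near `exp(−2)` while cross-tissue weights (contrast Δ) fall off like `exp(−Δ²/h²)`. A bandwidth several times σ flattens the kernel: at `h = 4σ` the same/cross-tissue weight ratio is only ~1.8 and even the *exact* global filter over-smooths enough to lose PSNR. Tying `h` to σ follows standard NLM practice. |
| sampling rate | 0.01 | at desk scale (16³–32³) this gives l in the low hundreds; large clinical volumes can go far lower because `l = max(ceil(rate·n), rank)` never drops below the rank |
| rank (spectrum size) | 100 | captures the dominant modes of a few-tissue volume with room to spare; with rank ≲ 20 the MSE selector saturates `m` at the available spectrum, i.e. the filter is truncation-starved |
| diffusion grid `k` | {0, 0.5, …, 8} | `k = 0` makes the filter a pure rank-m truncation (hard threshold); it is the limit the selector must be able to reach as σ → 0, where the full-rank filter degenerates to the identity. Larger k smooths more; beyond ~8 the filter is already essentially the leading-mode projection |
| k-means | k-means++ init, ≤ 100 iterations, tol 1e-4, fixed seed | reproducible standard settings; landmark = the real voxel nearest each centroid (Nyström needs actual kernel columns); empty or collided clusters are refilled by farthest-point selection so exactly l distinct landmarks always return |
| Sinkhorn | tol 1e-6, ≤ 200 iterations | the tolerance directly bounds `max_i |Σ_j W_ij − 1|`; tighten it (e.g. 1e-9) when mean preservation at 1e-6 *relative* is needed on low-mean volumes |
| `W1^{-1/2}` / `ε⁻¹` floors | 1e-10 relative | sampled kernels are routinely numerically semidefinite; the floor (or ridge, logged) keeps the square roots and inversions defined without visibly perturbing retained modes |

## Rank-r truncation of the Nyström approximation

Two decompositions coexist deliberately:

* `nystrom_eigs` is the classical extension: eigendecompose `M1`, keep
  the top r, extend by `M12ᵀ γ1 ε1⁻¹`. At `r = l` it reproduces the
  full surrogate exactly and is what the block-structure algebra tests
  exercise.
* `one_shot_spectrum` eigendecomposes the *surrogate itself* (via `O`)
  and is what both the filter and the rank-r relative-accuracy scoring
  use. The distinction matters precisely for non-uniform landmarks:
  with one landmark per k-means cluster, `M1` is near-identity and its
  spectrum is flat, so "top r of `M1`" ignores cluster sizes and scores
  *worse* than uniform sampling; the surrogate's spectrum weights each
  direction by its total column energy, and k-means then dominates
  uniform at every tested rate, as it should — a single landmark
  standing for the huge duplicate-patch background still yields the
  dominant eigenvalue.

Relative accuracy is `100·‖K − K_(r)‖_F / ‖K − K̃_(r)‖_F` with `K_(r)`
the optimal rank-r truncation; by Eckart–Young it is ≤ 100 for any
rank-≤r approximant, and 100 only at the optimum (the 0/0 case, a
kernel of rank ≤ r matched exactly, is defined as 100).

## The Rician VST

The forward transform is built numerically from the exact Rician
moments `m(ν) = E[Y|ν]` (half-order Laguerre form, evaluated with
exponentially scaled Bessel functions) and `s²(ν) = ν² + 2σ² − m²`:
`f` solves `f'(m(ν)) = σ/s(ν)`, integrated on a dense grid, pinned to
the asymptote `f(y) → sqrt(y² − σ²)` at high SNR, and extended linearly
below the Rayleigh mean. The construction is scale-invariant, so one
unit-σ table is cached. Monte-Carlo checks show the stabilized sd
within ~6% of σ for SNR ≥ 1 (contract: 15%).

Two inverses:

* **algebraic** (default): the exact inverse of `f` (piecewise-linear
  interpolation on the same knots, so the round trip is exact to
  rounding). Appropriate when the stabilized values are individual
  noisy draws.
* **unbiased** (`unbiased=True`): inverts `ν ↦ E[f(Y)|ν]`, tabulated by
  Gauss–Hermite quadrature, with a closed-form asymptote beyond the
  table. The *filtered* stabilized volume approximates the mean of the
  stabilized data, not a draw, so this is the inverse the pipeline
  applies; it removes the Rician bias (e.g. `E[Y] ≈ 1.06·x` at
  SNR 3) that a plain round trip would keep. Values below the
  invertible range clamp to 0.

These two demands — an exact per-sample round trip and mean-unbiased
recovery — cannot be met by a single inverse function: the first forces
the recovered per-sample mean to equal the Rician mean, which is biased
by ~6% at SNR 3. Splitting them is the principled resolution.

## The synthetic phantom

`generate_phantom` produces an ellipsoidal "head" (jittered center and
semi-axes) holding `n_tissues` piecewise-constant classes, partitioned
by the quantiles of a Gaussian-smoothed random field (smooth
boundaries, every class nonempty), over an **exact-zero background**
occupying 50–90% of the voxels. The exact-zero background is the point:
it creates the large duplicate-patch block that makes adaptive landmark
sampling outperform uniform sampling, mirroring real MRI backgrounds.
Noise generators add Gaussian or Rician noise at a percentage of the
maximum intensity and are deterministic per seed.

What the phantom does **not** emulate: anatomical texture, partial
volume ramps, bias fields, spatially varying noise, or multi-coil
(non-central chi) statistics. Passing tests on these phantoms
demonstrates the algebra, the selection machinery, and the ordering of
sampling schemes — not clinical image quality.

Quality metrics: PSNR (`10·log10(peak²/MSE)`, capped at 999 for
identical inputs) and 3D SSIM (scikit-image, 7³ Gaussian-weighted
windows, K1 = 0.01, K2 = 0.03).

## Problem sizes

Desk-scale sizes are used throughout: 12³ for exact-vs-approximate
filter comparisons and the sampling-scheme sweep (dense 1728² matrices
are cheap), 32³ for Gaussian denoising quality, 24³ for the Rician
pipeline, 10⁵ draws for VST Monte-Carlo. The dense oracle route
(`--exact`, `dense_filter_spectrum`) refuses volumes above 5000 voxels.

## Known limitations

* σ is user-supplied; no noise estimation is included.
* One global σ: spatially varying noise (parallel imaging) is out of
  scope, as are 4D series, DICOM, and complex/multi-coil data.
* The percentage noise scale uses the per-volume maximum; volumes with
  hot outlier voxels will under-noise relative to a nominal modality
  maximum.
* The k-grid is a finite grid, not a continuous optimizer; the MSE
  surface is cheap to evaluate, so refining the grid is the intended
  escape hatch.
* `kmeans_sample` clusters all n patch vectors; for clinical-scale n
  (~10⁷) a mini-batch or subsampled clustering would be the natural
  extension.
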