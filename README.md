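# gmrid — global Nyström-approximated denoising for 3D MRI

`gmrid` denoises 3D MRI volumes with a *global* non-local filter: every
voxel is estimated from a similarity-weighted combination of **all**
voxels in the volume, not just a local search window. It is aimed at
researchers who need a patch-based denoiser whose behaviour does not
depend on hand-tuned search-window compromises — e.g. for multimodal
data with differing SNR and resolution — and at methodologists studying
landmark-based low-rank kernel approximation.

## The model

The observation is `y = x + n` (additive Gaussian noise), or the Rician
magnitude `y = sqrt((x + n1)² + n2²)` for MRI. The global filter is the
row-normalized patch-affinity matrix

    M_ij = exp(−‖p_i − p_j‖² / (L h²)),      W = D⁻¹ M,

with `p_i` the (2r+1)³ patch around voxel `i`, `L` the patch length and
`h` the bandwidth. `W` is driven to a symmetric doubly stochastic
matrix by Sinkhorn scaling, eigendecomposed `W = V E Vᵀ`
(`1 = λ₁ ≥ λ₂ ≥ … ≥ 0`), and applied spectrally with iterated
eigenvalue diffusion and truncation:

    x̂ = V_m E_m^k V_mᵀ y.

The pair `(k, m)` is selected by exhaustive minimization of the
unbiased MSE estimate

    R(k, m) = Σ_{j≤m} ( (λ_j^{2k} − 2 λ_j^k) b̂_j² + σ² λ_j^{2k} ),
    b̂_j² = max((v_jᵀ y)² − σ², 0).

Because the n×n matrix is far too large to build (n = nx·ny·nz), its
leading eigenvectors are approximated from `l ≪ n` landmark voxels by
the Nyström extension; landmarks are the per-cluster representatives of
a k-means clustering of patch features, which avoids wasting samples on
the large duplicate-patch background. Rician data is variance-stabilized
before filtering and mapped back with an exact unbiased inverse.

## Worked example

```python
import numpy as np
from gmrid import (NoiseModel, add_gaussian_noise, denoise,
                   generate_phantom, psnr, ssim)

phantom = generate_phantom((32, 32, 32), n_tissues=3, seed=0)
noisy = add_gaussian_noise(phantom.truth, sigma_pct=10.0, seed=1)   # 10% of max
result = denoise(noisy, NoiseModel("gaussian", sigma=0.1), seed=0)

print(f"PSNR  {psnr(phantom.truth, noisy):.2f} -> {psnr(phantom.truth, result.volume):.2f} dB")
print(f"SSIM  {ssim(phantom.truth, noisy):.4f} -> {ssim(phantom.truth, result.volume):.4f}")
print(f"selected k={result.k_hat}, m={result.m_hat}")
```

prints

```
PSNR  20.08 -> 25.23 dB
SSIM  0.7299 -> 0.9455
selected k=0.0, m=97
```

i.e. the filter gains ~5 dB PSNR at 10% noise; the selector chose pure
rank-97 truncation (`k = 0`) of the 100 available eigenmodes. On the
same phantom with 15% Rician noise, the VST-wrapped pipeline raises
PSNR from ~14 dB to ~21.5 dB.

The same pipeline is available from the shell:

```bash
gmrid phantom --shape 32,32,32 --tissues 3 --noise gaussian --sigma-pct 10 \
      --seed 0 --out noisy.nii.gz --truth clean.nii.gz
gmrid denoise --input noisy.nii.gz --output denoised.nii.gz \
      --noise gaussian --sigma 0.1 --seed 0 --save-report report.json
gmrid sweep --shape 12,12,12 --rates 0.05,0.1,0.2 --seeds 10 --out sweep.csv
```

`gmrid sweep` reports the relative accuracy (Eckart–Young-normalized
Frobenius score, 100 = optimal rank-r approximation) of k-means vs
uniform landmark sampling.

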