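# bregrestore

Restoration of blurred, noisy grayscale images — deconvolution microscopy
frames, remote-sensing tiles, degraded photographs — by total-variation (TV)
regularization driven by Bregman iteration, with an adaptive nonlocal-TV
variant that preserves texture.

## The model

The observation is assumed to follow

    f = A u + n

where `u` is the ideal image, `A` a spatially invariant blur (a small
normalized point-spread function, applied with periodic boundaries) and `n`
zero-mean Gaussian white noise of standard deviation σ.  Direct inversion is
ill-posed, so the estimate minimizes a TV-regularized energy.  The unknown is
split into a fidelity carrier `u` and a regularity carrier `g`, coupled
quadratically:

    min_{u,g}  λ/2 ‖A u − f‖² + TV(g) + γ/2 ‖u − g‖²

Each outer (Bregman) step alternates between the two easy sub-problems —

* **deblur**: `(λ AᵀA + γ I) u = λ Aᵀ f_k + γ g`, solved exactly by FFT
  diagonalization (or conjugate gradients),
* **denoise**: `min_g TV(g) + γ/2 ‖g − u‖²`, solved by Chambolle's dual
  projection iteration,

— and then feeds the data residual back, `f_{k+1} = f_k + (f − A u)`,
progressively returning the signal the regularizer removed.  On noiseless
data the residual `‖f − A u^k‖` decreases monotonically to zero.

The **nonlocal variant** replaces TV by nonlocal TV on a patch-similarity
graph with NL-means weights `w(x,y) = exp(−d_a(x,y)/h(x)²)`, rebuilt each
outer step from the current *deblurred* iterate.  The bandwidth `h` is set
per pixel from the local power `P(x)` — a Gaussian-windowed mean-square
deviation between the iterate and a precomputed oversmoothed TV reference —
as `h(x) = clip(c·√P(x), h_floor, h_ceiling)`, so texture and edge regions
(large mismatch with the cartoon reference) get a larger bandwidth and flat
regions a smaller one, without ever estimating a global noise level.

## Worked example

```python
import numpy as np
from bregrestore import (DegradationSpec, degrade, gaussian_kernel,
                         make_phantom, psnr, restore_tv, ssim)

truth = make_phantom("piecewise", 64, seed=0)          # 3-level cartoon
kernel = gaussian_kernel(5, 1.5)                       # 5x5 PSF, sigma 1.5
observed = degrade(truth, DegradationSpec(kernel, noise_sigma=0.01, seed=0))
result = restore_tv(observed, kernel)

print(f"degraded : PSNR = {psnr(truth, observed):.2f} dB")
print(f"restored : PSNR = {psnr(truth, result.restored):.2f} dB")
```

prints

```
degraded : PSNR = 23.44 dB
restored : PSNR = 27.98 dB
```

a 4.5 dB gain over the degraded input (SSIM rises from 0.836 to 0.910); the
recorded residual history `result.state.residual_history` starts at 0.641
and decreases every outer iteration.  `restore_nltv_adaptive` takes the same
arguments plus nonlocal/bandwidth configurations and is preferred on
textured content.

The same pipelines are available from the shell:

```sh
bregrestore degrade --input u.tif --kernel gaussian:5:1.5 --sigma 0.01 --seed 0 --out f.tif
bregrestore restore-tv --input f.tif --kernel gaussian:5:1.5 --out g.tif --history hist.csv
bregrestore evaluate --reference u.tif --test g.tif
bregrestore benchmark --images piecewise:64 --kernels gaussian:5:1.5 \
    --sigmas 0.01 --algorithms tv --algorithms nltv --out results.csv
```

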