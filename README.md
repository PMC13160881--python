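# hbmfit

Hierarchical Bayesian fitting of voxelwise diffusion-MRI microstructure
models with per-region shrinkage priors, alongside the conventional
multistart least-squares (LSQ) baseline, synthetic phantoms and an
evaluation suite.

## The problem

Voxel-by-voxel nonlinear fitting of diffusion-MRI signal models is
noise-limited: for hard-to-estimate parameters (the mean-signal
kurtosis *K*, or the apparent exchange rate AXR of filter exchange
imaging) independent fits routinely land on the fitting bounds,
producing speckled, low-contrast parameter maps. Voxels within a
tissue region, however, share statistics. A hierarchical model places
a Gaussian *shrinkage prior* over each region's voxel parameters,

    y_i | θ_i        ~  N(g(θ_i, t), s² I)            (signal model)
    θ_i | μ_k, Σ_k   ~  N(μ_k, Σ_k)   for voxel i in ROI k
    (μ_k, Σ_k)       ~  noninformative normal–inverse-Wishart,

and infers the prior's mean vector μ_k and covariance Σ_k *from the
data* jointly with all voxel parameters. Sampling is by
Metropolis–Hastings-within-Gibbs: (μ_k, Σ_k) have exact conjugate
Gibbs updates, each θ_i gets component-wise Gaussian random-walk
updates in an unbounded (scaled-logit) space so that arbitrary box
constraints are respected by construction. The per-voxel noise
variance is marginalised under a Jeffreys prior, giving the likelihood
`log p(y|θ) = −(N/2) ln RSS(θ) + const`. Posterior-mean maps are
running averages of the post-burn-in native-space samples.

Two signal models ship with the package:

* **Mean-signal DKI** — `S/S0 = exp(−bD + b²D²K/6)` with
  D ∈ (0.1, 3.5) μm²/ms, K ∈ (0, 3);
* **FEXI AXR** — `S = exp(−b·D′(t_m))`,
  `D′(t_m) = D(1 − σ·exp(−t_m·AXR))`, with D ∈ (0.1, 3.5) μm²/ms,
  σ ∈ (0, 1), AXR ∈ (0, 50) s⁻¹.

The `ModelSpec` contract (parameter names, units, bounds, vectorised
predictor) makes additional models drop-in.

## Worked example

Generate a synthetic two-region DKI phantom (50×50, SNR 20), fit it
both ways and compare against the ground truth:

```python
import numpy as np
from hbmfit import (build_paper_phantom, fit_volume, run_chain,
                    ChainConfig, get_model, rmse, extreme_fit_fraction)

model = get_model("dki")
ph = build_paper_phantom("dki", seed=1)          # SNR 20, b = 0,1,2,3
lsq = fit_volume(ph.noisy, ph.labels, ph.scheme, model)
hbm = run_chain(ph.noisy, ph.labels, ph.scheme, model,
                ChainConfig(n_steps=100_000, seed=1001), init=lsq)

mask = ph.labels > 0
for tag, maps in [("LSQ", lsq.maps), ("HBM", hbm.mean_maps)]:
    ex, _ = extreme_fit_fraction({k: v[mask] for k, v in maps.items()}, model)
    print(f"{tag}: K RMSE {rmse(ph.truth_maps['K'][mask], maps['K'][mask]):.3f}, "
          f"K extreme fits {ex['K']:.2f}%")
```

prints (chain ≈ 2–3 min on one core):

```
LSQ: K RMSE 0.194, K extreme fits 1.80%
HBM: K RMSE 0.148, K extreme fits 0.04%
```

i.e. the shrinkage prior cuts the kurtosis error by ~25% and removes
the bound-stuck fits. The same pipeline is available from the shell:

```bash
hbmfit simulate --experiment dki --seed 1 --out ph/
hbmfit fit-lsq  --data ph/noisy.nii.gz --scheme ph/scheme.txt \
                --model dki --labels ph/labels.nii.gz --out lsq/
hbmfit fit-hbm  --data ph/noisy.nii.gz --scheme ph/scheme.txt \
                --model dki --labels ph/labels.nii.gz --steps 100000 --out hbm/
hbmfit evaluate --truth ph/ --fits hbm/ --model dki --out eval/
```

`hbmfit experiment` chains all stages over an SNR sweep and
regional-prior configurations and writes a metrics CSV, parameter maps
and histogram data.

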