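# Methods

## Model

For each voxel *i* with signal vector `y_i` (length N) and a forward
model `g(θ_i, t)` over acquisition parameters `t`, the package fits
the hierarchical model

    y_i | θ_i       ~ N(g(θ_i, t), s_i² I)
    θ_i | μ_k, Σ_k  ~ N(μ_k, Σ_k) restricted to the bounds, i in ROI k
    (μ_k, Σ_k)      ~ NIW-limit hyperprior (see below)

The voxel noise variance `s_i²` is never sampled: it is marginalised
under a Jeffreys scale prior, leaving `log p(y_i|θ_i) =
−(N/2)·ln RSS(θ_i) + const`. The RSS is floored at `1e-12·N` to guard
exact fits.

### Constraint handling and the prior's space

Every parameter carries box bounds (D ∈ (0.1, 3.5) μm²/ms, K ∈ (0, 3),
σ ∈ (0, 1), AXR ∈ (0, 50) s⁻¹). Sampling runs in an unbounded space
via a per-parameter scaled-logit transform, so proposals can never
leave the box and all posterior summaries respect the bounds.

The Gaussian shrinkage prior itself is defined on the **native**
(physical-unit) parameters — equivalently, a bound-truncated Gaussian
— and the MH acceptance ratio therefore carries the transform
Jacobian. This choice is load-bearing. If the Gaussian is instead
placed on the logit-transformed parameters, voxels whose likelihood
pins them at a bound (one third of least-squares AXR fits at SNR 30)
sit tens of prior standard deviations out in the transformed space;
they dominate the Gibbs covariance update, the inferred Σ_k explodes,
the prior flattens, and the sampler settles into a stable
no-shrinkage equilibrium in which the regional prior does nothing. In
native space the same voxels deviate by at most the bound range, Σ_k
stays on the physical scale, and the prior retains its pull.

### Gibbs and MH updates

Each step performs, in order:

1. **Gibbs, per ROI k**: μ_k ~ N(θ̄_k, Σ_k/I_k) (flat mean hyperprior),
   then Σ_k ~ InvWishart(ν₀ + I_k, Ψ₀ + Σ_i(θ_i−μ_k)(θ_i−μ_k)ᵀ) with
   ν₀ = p+1 and Ψ₀ = 10⁻⁶·I — the noninformative normal–inverse-
   Wishart limit, kept just proper so the conditionals remain valid
   for tiny or degenerate ROIs.
2. **MH, per voxel and per parameter** (all voxels vectorised):
   a symmetric Gaussian random-walk proposal in the transformed space,
   accepted with likelihood ratio × native-prior ratio × Jacobian
   ratio. Component-wise updates keep the acceptance geometry simple
   for strongly correlated parameters.

The truncation of the native-space Gaussian is not renormalised in the
Gibbs step; for the phantoms studied here the prior mass outside the
bounds is negligible (< 10⁻³), and the MH step targets the truncated
density exactly regardless.

### Chain schedule

Chains run `n_steps` (default 10⁵) with burn-in `n_steps/2`. Per-voxel
per-parameter proposal widths start at 0.1× the per-ROI SD of the
transformed least-squares fits and are rescaled every 100 steps during
the **first half of burn-in** by `(acceptance + 0.1)/(0.25 + 0.1)`,
clipped to [0.5, 2] per update, then frozen — so every retained sample
comes from a fixed kernel. The achieved post-adaptation acceptance
lies in [0.1, 0.5] for ≥90% of voxels. Summaries are running means of
native-space samples (posterior-mean maps, posterior SD maps, per-ROI
prior means and SDs); no sample storage is needed, memory stays at a
few (voxels × p) arrays. Chains are bit-reproducible given the seed.

### Initialisation

Voxel parameters start at the multistart least-squares fit (non-finite
fits replaced by their ROI mean); μ_k and Σ_k at the mean and diagonal
covariance of each ROI's fits, variance-floored for degenerate ROIs.

## Least-squares baseline

Each voxel is fitted independently by bounded Nelder–Mead simplex
search through a sin² reparameterisation (the classic bounded-simplex
wrapper), from 25 (two-parameter models, 5×5 lattice) or 27
(three-parameter, 3×3×3 lattice) start points spaced uniformly
strictly inside the box; the minimum-RSS start wins, ties broken by
lattice order. Tolerances 10⁻⁸ on parameters and objective, 2000
iterations cap. The search itself is a *batched* Nelder–Mead running
all voxels × starts in lockstep with identical update rules to the
scipy reference implementation, which the test suite uses as a
per-start cross-check; a volume fit takes seconds instead of minutes.

Because the start lattice is deterministic, LSQ results are exactly
reproducible; because the transform reaches the bounds, degenerate
voxels legitimately converge onto them — the "extreme fits" (values
within 1% of the bound range of either bound) that the evaluation
counts.

## Signal normalisation and the likelihood's N

Both models predict amplitude-normalised signals (no S0 parameter).
Before any fit, DKI data are divided voxelwise by the mean b = 0
signal; FEXI data are divided block-by-block by each (b_f, t_m)
block's mean b = 0 signal, matching an analysis in which D′(t_m) is
derived from within-block signal ratios. After normalisation the
reference rows are identically 1 and carry no residual; the
likelihood exponent nevertheless counts all N volumes. Three
candidate conventions were evaluated against the published simulation
metrics (raw signals; normalised with full N; normalised with
informative-rows-only N): full-N normalised form reproduces the
reported AXR-row error metrics closely, while both alternatives
over-shrink (posterior maps tighter and higher-contrast than
reported), and it is the convention the package uses everywhere.

## Synthetic phantoms

The generator reproduces the simulation design the evaluation relies
on: a 50×50 grid split into a 1204-voxel "WM" and a 1296-voxel "GM"
region (the split is by voxel count, row-major; only cardinalities
matter to the priors, so the geometry is deliberately simple and
configurable). Per-voxel ground truth is drawn independently from
region-specific Gaussians, redrawing any value outside the model
bounds (truncated sampling):

| model | region | D (μm²/ms) | K / σ | AXR (s⁻¹) |
|---|---|---|---|---|
| DKI | WM | N(0.87, 0.29) | K: N(1.04, 0.41) | — |
| DKI | GM | N(1.04, 0.30) | K: N(0.63, 0.22) | — |
| FEXI | WM | N(0.84, 0.04) | σ: N(0.14, 0.02) | N(2.00, 0.30) |
| FEXI | GM | N(1.09, 0.06) | σ: N(0.18, 0.03) | N(1.40, 0.35) |

The kurtosis, filter-efficiency and exchange-rate distributions follow
published healthy-tissue values. The two equilibrium-ADC
distributions (and the DKI GM diffusivity) had to be fixed by this
package; they were chosen to be literature-plausible and to reproduce
the published ground-truth and least-squares D-contrast figures, and
are recorded here as package constants.

Noise emulates magnitude MRI: zero-mean Gaussian noise of SD
(reference amplitude)/SNR is added independently to the real and
imaginary channel of each of the NSA acquisitions per volume, the
magnitude is taken, and the NSA magnitudes are arithmetically
averaged. The reference volume is the b = 0 volume (DKI; SNR default
20) or the equilibrium b = 0, b_f = 0, shortest-t_m volume (FEXI; SNR
default 30). Protocols: DKI b = 0,1,2,3 ms/μm² with NSA 2,9,9,9; FEXI
four (b_f, t_m) blocks (0,16), (0.25,16), (0.25,200), (0.25,400) ms
with b ∈ {0, 0.25} and NSA 6 (48 acquired volumes averaged to 8). A
lesion variant relabels a 10×10 block inside WM with elevated exchange
(AXR ~ N(4.0, 0.3) by default) to probe regional-prior configurations.

What the generator does *not* emulate: anatomy, partial-volume mixing,
eddy/susceptibility artefacts, spatially correlated noise, and Rician
likelihood mismatch at very low SNR (noise is simulated as magnitude
data but fitted under a Gaussian assumption, which is accurate for
the SNR ≥ 10 regimes studied). Passing tests therefore demonstrate
statistical correctness of the estimators under the stated generative
model, not robustness to acquisition artefacts.

## Evaluation metrics

Pooled over all labelled voxels: RMSE, signed bias, Pearson r against
ground truth, and percent-error maps (zero-truth voxels masked).
Between-ROI contrast-to-noise ratio is
`|median_a − median_b| / sqrt(IQR_a² + IQR_b²)` with type-7
(linearly interpolated) quartiles. A voxel-parameter is an *extreme
fit* if it lies within 1% of the bound range of either bound; the
"any" variant counts voxels with at least one extreme parameter.

## Problem sizes and defaults

The shipped studies use the 50×50 phantoms (2500 voxels) with
10⁵-step chains; at these sizes a full study (phantom + LSQ + chain)
runs in minutes on one core, and chain summaries are stable from
~2×10⁴ steps onward (doubling the chain changes the reported metrics
in the third decimal). Production FEXI runs in the source analysis
used 4×10⁵ steps; 10⁵ is used as the package default for both models
and is noted as a scaled-down surrogate where it matters.

## Known limitations

* The FEXI posterior retains a small fraction (~5% at SNR 30) of
  voxels whose posterior mean sits near the lower AXR bound: their
  noise realisation genuinely favours "no recovery" under the
  marginal likelihood, and the regional prior — wider than the
  ground-truth spread because it must accommodate them — does not
  overturn it. This is the model's honest stationary posterior, not a
  mixing failure (verified by chain-length doubling).
* Gaussian priors only; no Rician likelihood; no spatial smoothness
  beyond the exchangeable regional prior; ROI membership is fixed, so
  unmodelled focal pathology inside a region biases toward that
  region's prior (hence the dedicated-lesion-prior configuration).
* Single-chain inference with acceptance-rate diagnostics only; no
  cross-chain convergence statistics.
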