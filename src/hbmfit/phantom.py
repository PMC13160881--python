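"""Synthetic two-ROI phantoms with Rician (magnitude) noise.

The simulation study fits on a 50x50 grid split into two regions whose
ground-truth parameters are drawn from region-specific Gaussians
representative of healthy white matter (WM) and grey matter (GM).
Noise-free signals are computed per voxel from the forward model;
zero-mean Gaussian noise is then added independently to the real and
imaginary channels, magnitudes are taken, and the NSA acquisitions of
each volume are arithmetically averaged -- reproducing how multi-
direction magnitude data are averaged in practice.

Noise is *simulated* as magnitude (Rician) data but *fitted* under a
Gaussian-residual assumption, as is standard at the SNRs considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .signal_models import (
    AcquisitionScheme,
    ModelSpec,
    dki_scheme,
    fexi_scheme,
    get_model,
)

__all__ = [
    "PhantomSpec",
    "Phantom",
    "two_roi_labels",
    "reference_volume",
    "draw_ground_truth",
    "synthesize_signals",
    "add_noise_and_average",
    "generate_phantom",
    "build_paper_phantom",
    "GROUND_TRUTH_DISTRIBUTIONS",
]


# Ground-truth parameter distributions (mean, SD) per region, native units.
# DKI: diffusivity um^2/ms, kurtosis dimensionless; drawn from normal fits
# to healthy WM/GM.  FEXI: equilibrium ADC um^2/ms, filter efficiency
# dimensionless, AXR 1/s, from literature values for healthy subjects.
GROUND_TRUTH_DISTRIBUTIONS = {
    "dki": {
        1: {"D": (0.87, 0.29), "K": (1.04, 0.41)},  # "WM"
        2: {"D": (1.04, 0.30), "K": (0.63, 0.22)},  # "GM"
    },
    "axr": {
        1: {"D": (0.84, 0.04), "sigma": (0.14, 0.02), "AXR": (2.00, 0.30)},  # "WM"
        2: {"D": (1.09, 0.06), "sigma": (0.18, 0.03), "AXR": (1.40, 0.35)},  # "GM"
    },
}

#: default SNR at the reference (non-diffusion-weighted) volume
DEFAULT_SNR = {"dki": 20.0, "fexi": 30.0, "fexi_lesion": 30.0}

ROI_NAMES = {1: "WM", 2: "GM", 3: "lesion"}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom.

    ``distributions`` maps ROI label -> parameter name -> (mean, SD)
    in native units; every labelled pixel must have a complete set.
    ``snr`` is the target SNR at the reference volume (see
    :func:`reference_volume`).
    """

    labels: np.ndarray
    distributions: dict[int, dict[str, tuple[float, float]]]
    snr: float
    scheme: AcquisitionScheme
    model_name: str
    seed: int = 0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        model = get_model(self.model_name)
        roi_ids = [int(k) for k in np.unique(labels) if k != 0]
        for k in roi_ids:
            if k not in self.distributions:
                raise ValueError(f"no ground-truth distributions for ROI {k}")
            for p in model.param_names:
                if p not in self.distributions[k]:
                    raise ValueError(f"ROI {k} lacks a distribution for {p!r}")
                _, sd = self.distributions[k][p]
                if sd < 0:
                    raise ValueError(f"SD for {p!r} in ROI {k} must be >= 0")

    @property
    def roi_sizes(self) -> dict[int, int]:
        return {
            int(k): int(np.sum(self.labels == k))
            for k in np.unique(self.labels)
            if k != 0
        }


@dataclass
class Phantom:
    """Ground truth, labels and signal stacks of one synthetic dataset."""

    spec: PhantomSpec
    truth_maps: dict[str, np.ndarray]   # param name -> map, nan outside labels
    labels: np.ndarray
    clean: np.ndarray                   # (*grid, N) noise-free signals
    noisy: np.ndarray                   # (*grid, N) NSA-averaged magnitudes
    noise_sd: float                     # per-channel complex noise SD

    @property
    def scheme(self) -> AcquisitionScheme:
        return self.spec.scheme

    @property
    def model_name(self) -> str:
        return self.spec.model_name


def two_roi_labels(
    shape: tuple[int, int] = (50, 50),
    n_first: int = 1204,
    lesion: Optional[tuple[slice, slice]] = None,
) -> np.ndarray:
    """Two interlocking regions on a grid, by voxel count.

    The first ``n_first`` pixels in row-major order are labelled 1
    ("WM"), the remainder 2 ("GM"); on the default 50x50 grid this
    gives 1204 and 1296 pixels.  Only the cardinalities matter for the
    regional priors, so the geometry is deliberately simple.  An
    optional ``lesion`` slice pair relabels a block inside region 1 as
    label 3.
    """
    n_pix = int(np.prod(shape))
    if not 0 < n_first < n_pix:
        raise ValueError("n_first must split the grid in two")
    labels = np.full(n_pix, 2, dtype=int)
    labels[:n_first] = 1
    labels = labels.reshape(shape)
    if lesion is not None:
        block = labels[lesion]
        if not np.all(block == 1):
            raise ValueError("lesion block must lie inside region 1")
        labels[lesion] = 3
    return labels


def reference_volume(scheme: AcquisitionScheme) -> int:
    """Index of the volume defining the SNR: the non-weighted volume.

    For single-encoding protocols this is the first b = 0 volume; for
    FEXI schemes it is the equilibrium volume (filter inactive, b = 0,
    shortest mixing time).
    """
    b0 = scheme.b == 0
    if not b0.any():
        raise ValueError("scheme has no b = 0 volume to define the SNR")
    if np.all(~np.isfinite(scheme.tm)):
        return int(np.nonzero(b0)[0][0])
    eq = b0 & (scheme.bf == 0)
    if not eq.any():
        raise ValueError("FEXI scheme has no equilibrium (bf = 0, b = 0) volume")
    idx = np.nonzero(eq)[0]
    return int(idx[np.argmin(scheme.tm[idx])])


def draw_ground_truth(
    spec: PhantomSpec, rng: Optional[np.random.Generator] = None
) -> dict[str, np.ndarray]:
    """Draw per-pixel ground truth from the ROI Gaussians.

    Each labelled pixel receives an independent draw from its ROI's
    distribution; draws outside the model bounds are redrawn (truncated
    Gaussian), guaranteeing valid forward-model inputs.  Deterministic
    given the PhantomSpec seed (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    model = get_model(spec.model_name)
    labels = spec.labels
    maps: dict[str, np.ndarray] = {
        p.name: np.full(labels.shape, np.nan) for p in model.params
    }
    for k in sorted(spec.roi_sizes):
        mask = labels == k
        n = int(mask.sum())
        for p in model.params:
            mean, sd = spec.distributions[k][p.name]
            if sd == 0:
                if not (p.lb < mean < p.ub):
                    raise ValueError(f"mean of {p.name!r} in ROI {k} outside bounds")
                vals = np.full(n, float(mean))
            else:
                vals = rng.normal(mean, sd, size=n)
                for _ in range(1000):
                    bad = (vals <= p.lb) | (vals >= p.ub)
                    if not bad.any():
                        break
                    vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                else:
                    raise RuntimeError(
                        f"could not draw {p.name!r} inside bounds for ROI {k}"
                    )
            maps[p.name][mask] = vals
    return maps


def synthesize_signals(
    truth_maps: dict[str, np.ndarray],
    labels: np.ndarray,
    scheme: AcquisitionScheme,
    model: ModelSpec,
) -> np.ndarray:
    """Evaluate the forward model at every labelled pixel.

    Returns a ``(*grid, N)`` stack; background pixels are zero.
    """
    model.validate_scheme(scheme)
    missing = [p for p in model.param_names if p not in truth_maps]
    if missing:
        raise ValueError(f"truth maps missing parameters: {missing}")
    labels = np.asarray(labels)
    mask = labels > 0
    theta = np.stack([np.asarray(truth_maps[p])[mask] for p in model.param_names], axis=-1)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite ground truth in labelled pixels")
    lb, ub = model.lb, model.ub
    if np.any(theta <= lb) or np.any(theta >= ub):
        raise ValueError("ground truth outside model bounds")
    clean = np.zeros(labels.shape + (scheme.n_volumes,))
    clean[mask] = model.predict(theta, scheme)
    return clean


def add_noise_and_average(
    clean: np.ndarray,
    snr: float,
    scheme: AcquisitionScheme,
    rng: np.random.Generator | int,
    labels: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Complex Gaussian noise, magnitude, NSA arithmetic averaging.

    The per-channel noise SD is (reference-volume noise-free
    amplitude) / snr, the amplitude being averaged over labelled pixels
    (all nonzero pixels if no labels are given).  For each volume,
    ``nsa`` independent complex realisations are magnitudes and then
    averaged.  Returns the noisy stack and the realised noise SD.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    clean = np.asarray(clean, dtype=float)
    ref = reference_volume(scheme)
    ref_amp = clean[..., ref]
    sel = (np.asarray(labels) > 0) if labels is not None else (ref_amp > 0)
    amp = float(np.mean(ref_amp[sel])) if sel.any() else float(np.mean(ref_amp))
    if amp <= 0:
        raise ValueError("reference volume has no signal to define the SNR")
    sd = amp / snr
    noisy = np.empty_like(clean)
    for n in range(scheme.n_volumes):
        nsa = int(scheme.nsa[n])
        re = clean[..., n] + sd * rng.standard_normal((nsa,) + clean.shape[:-1])
        im = sd * rng.standard_normal((nsa,) + clean.shape[:-1])
        noisy[..., n] = np.hypot(re, im).mean(axis=0)
    return noisy, sd


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Ground truth -> noise-free signals -> noisy magnitudes.

    One master seed is split into independent streams for the truth
    draws and the noise, so either stage is reproducible on its own.
    """
    model = get_model(spec.model_name)
    ss = np.random.SeedSequence(spec.seed).spawn(2)
    truth = draw_ground_truth(spec, np.random.default_rng(ss[0]))
    clean = synthesize_signals(truth, spec.labels, spec.scheme, model)
    noisy, sd = add_noise_and_average(
        clean, spec.snr, spec.scheme, np.random.default_rng(ss[1]), spec.labels
    )
    return Phantom(
        spec=spec,
        truth_maps=truth,
        labels=spec.labels,
        clean=clean,
        noisy=noisy,
        noise_sd=sd,
    )


def build_paper_phantom(
    experiment: str,
    snr: Optional[float] = None,
    seed: int = 0,
    shape: tuple[int, int] = (50, 50),
    lesion_axr: tuple[float, float] = (4.0, 0.30),
) -> Phantom:
    """The canonical simulation phantoms.

    ``experiment`` is one of:

    * ``"dki"`` -- mean-signal DKI, b = 0,1,2,3 ms/um^2 with NSA
      2,9,9,9, default SNR 20;
    * ``"fexi"`` -- FEXI AXR, four (bf, tm) blocks with NSA 6, default
      SNR 30;
    * ``"fexi_lesion"`` -- as ``"fexi"`` plus a 10x10 lesion block
      inside the "WM" region whose AXR distribution is ``lesion_axr``
      (elevated exchange, emulating a white-matter hyperintensity).
    """
    if experiment not in ("dki", "fexi", "fexi_lesion"):
        raise ValueError(f"unknown experiment {experiment!r}")
    model_name = "dki" if experiment == "dki" else "axr"
    scheme = dki_scheme() if experiment == "dki" else fexi_scheme()
    snr = DEFAULT_SNR[experiment] if snr is None else float(snr)
    dists = {k: dict(v) for k, v in GROUND_TRUTH_DISTRIBUTIONS[model_name].items()}
    lesion = None
    if experiment == "fexi_lesion":
        lesion = (slice(5, 15), slice(5, 15))
        dists[3] = dict(dists[1])
        dists[3]["AXR"] = tuple(lesion_axr)
    labels = two_roi_labels(shape=shape, n_first=1204 if shape == (50, 50) else
                            int(np.prod(shape) * 1204 / 2500), lesion=lesion)
    spec = PhantomSpec(
        labels=labels,
        distributions=dists,
        snr=snr,
        scheme=scheme,
        model_name=model_name,
        seed=seed,
    )
    return generate_phantom(spec)
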