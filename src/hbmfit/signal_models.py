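"""Microstructure signal models and acquisition-scheme handling.

The package fits voxelwise microstructure models of the form
``S = S0 * g(theta, t)``, where ``theta`` are the model parameters and
``t`` the per-volume acquisition parameters.  Two exemplar models are
shipped:

* mean-signal diffusion kurtosis imaging (DKI),
  ``S = S0 * exp(-b*D + (1/6) b^2 D^2 K)``;
* the FEXI apparent-exchange-rate (AXR) model,
  ``S = exp(-b * D'(tm))`` with
  ``D'(tm) = D * (1 - sigma * exp(-tm * AXR))``.

Units follow the conventions used throughout: b and b_f in ms/um^2,
diffusivities in um^2/ms, mixing time t_m in ms, AXR in 1/s (so the
product ``tm * AXR`` divides ``tm`` by 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "Parameter",
    "ModelSpec",
    "dki_signal",
    "axr_adc",
    "axr_signal",
    "dki_model",
    "axr_model",
    "get_model",
    "dki_scheme",
    "fexi_scheme",
    "normalize_signals",
]

#: sentinel used in scheme files for "mixing time not applicable"
TM_NA = -1.0


# ---------------------------------------------------------------------------
# acquisition scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume diffusion-encoding descriptors.

    Parameters
    ----------
    b :
        Diffusion weighting of the readout block, ms/um^2.
    bf :
        Diffusion weighting of the filter block, ms/um^2 (0 when the
        filter is inactive or for single-encoding protocols).
    tm :
        Mixing time between filter and readout blocks, ms.  ``nan``
        where not applicable (single-encoding protocols).
    nsa :
        Number of signal averages acquired for this volume.  The noisy
        data fitted against this scheme are assumed to be the
        arithmetic mean of ``nsa`` magnitude acquisitions.

    The row order is the canonical volume order of any 4D data fitted
    against the scheme.
    """

    b: np.ndarray
    bf: np.ndarray
    tm: np.ndarray
    nsa: np.ndarray

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        bf = np.atleast_1d(np.asarray(self.bf, dtype=float))
        tm = np.atleast_1d(np.asarray(self.tm, dtype=float))
        nsa = np.atleast_1d(np.asarray(self.nsa, dtype=int))
        n = len(b)
        if not (len(bf) == len(tm) == len(nsa) == n):
            raise ValueError("scheme columns have unequal lengths")
        if np.any(b < 0) or np.any(bf < 0):
            raise ValueError("b and bf must be non-negative")
        finite_tm = tm[np.isfinite(tm)]
        if np.any(finite_tm <= 0):
            raise ValueError("tm must be positive where present")
        if np.any(nsa < 1):
            raise ValueError("nsa must be >= 1")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "bf", bf)
        object.__setattr__(self, "tm", tm)
        object.__setattr__(self, "nsa", nsa)

    def __len__(self) -> int:
        return len(self.b)

    @property
    def n_volumes(self) -> int:
        return len(self.b)

    # -- FEXI block structure -------------------------------------------------

    def blocks(self) -> list[tuple[tuple[float, float], np.ndarray]]:
        """Group volumes into (bf, tm) blocks, preserving first-seen order.

        Returns a list of ``((bf, tm), indices)`` pairs.  For FEXI
        schemes each block must contain both b = 0 and b > 0 volumes.
        """
        keys: list[tuple[float, float]] = []
        idx: dict[tuple[float, float], list[int]] = {}
        for i in range(len(self)):
            key = (float(self.bf[i]), float(self.tm[i]))
            if key not in idx:
                idx[key] = []
                keys.append(key)
            idx[key].append(i)
        return [(k, np.asarray(idx[k], dtype=int)) for k in keys]

    def validate_fexi(self) -> None:
        """Raise unless the scheme has FEXI block structure."""
        if np.any(~np.isfinite(self.tm)):
            raise ValueError("FEXI scheme requires a mixing time on every volume")
        blocks = self.blocks()
        if not any(bf == 0 for (bf, _tm), _ in blocks):
            raise ValueError("FEXI scheme requires a filter-inactive (bf = 0) block")
        for (bf, tm), ind in blocks:
            bb = self.b[ind]
            if not (np.any(bb == 0) and np.any(bb > 0)):
                raise ValueError(
                    f"FEXI block (bf={bf}, tm={tm}) must contain b = 0 and b > 0 volumes"
                )

    # -- text round-trip ------------------------------------------------------

    def to_file(self, path) -> None:
        """Write the scheme as whitespace-delimited text (columns b bf tm nsa)."""
        tm = np.where(np.isfinite(self.tm), self.tm, TM_NA)
        with open(path, "w") as fh:
            fh.write("# b bf tm nsa\n")
            for i in range(len(self)):
                fh.write(f"{self.b[i]:.10g} {self.bf[i]:.10g} {tm[i]:.10g} {self.nsa[i]:d}\n")

    @classmethod
    def from_file(cls, path) -> "AcquisitionScheme":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"scheme row must have 4 columns, got: {line!r}")
                rows.append([float(parts[0]), float(parts[1]), float(parts[2]), int(parts[3])])
        if not rows:
            raise ValueError(f"no scheme rows found in {path}")
        arr = np.asarray(rows, dtype=float)
        tm = arr[:, 2].copy()
        tm[tm == TM_NA] = np.nan
        return cls(b=arr[:, 0], bf=arr[:, 1], tm=tm, nsa=arr[:, 3].astype(int))


def dki_scheme() -> AcquisitionScheme:
    """The mean-signal DKI protocol: b = 0, 1, 2, 3 ms/um^2 with NSA 2, 9, 9, 9."""
    return AcquisitionScheme(
        b=[0.0, 1.0, 2.0, 3.0],
        bf=[0.0, 0.0, 0.0, 0.0],
        tm=[np.nan] * 4,
        nsa=[2, 9, 9, 9],
    )


def fexi_scheme() -> AcquisitionScheme:
    """The FEXI protocol: four (bf, tm) blocks, each with b in {0, 0.25} ms/um^2.

    Blocks: (bf, tm) = (0, 16), (0.25, 16), (0.25, 200), (0.25, 400) ms;
    NSA = 6 per volume (the six gradient directions averaged).
    """
    bf_tm = [(0.0, 16.0), (0.25, 16.0), (0.25, 200.0), (0.25, 400.0)]
    b, bf, tm = [], [], []
    for f, t in bf_tm:
        for bb in (0.0, 0.25):
            b.append(bb)
            bf.append(f)
            tm.append(t)
    return AcquisitionScheme(b=b, bf=bf, tm=tm, nsa=[6] * 8)


# ---------------------------------------------------------------------------
# scalar signal equations
# ---------------------------------------------------------------------------


def dki_signal(S0, D, K, b):
    """Mean-signal DKI decay: ``S0 * exp(-b D + (1/6) b^2 D^2 K)``."""
    S0, D, K, b = (np.asarray(x, dtype=float) for x in (S0, D, K, b))
    if not (np.all(np.isfinite(S0)) and np.all(np.isfinite(D)) and np.all(np.isfinite(K))):
        raise ValueError("non-finite model parameters")
    if np.any(S0 <= 0):
        raise ValueError("S0 must be positive")
    if np.any(b < 0) or np.any(~np.isfinite(b)):
        raise ValueError("b must be finite and non-negative")
    return S0 * np.exp(-b * D + (b * D) ** 2 * K / 6.0)


def axr_adc(D, sigma, axr, tm, filter_active=True):
    """Apparent diffusion coefficient after the exchange filter.

    With the filter active the ADC recovers from ``D (1 - sigma)``
    immediately after the filter toward the equilibrium value ``D``
    at rate AXR: ``D' = D (1 - sigma exp(-tm * AXR))`` (tm in ms,
    AXR in 1/s; the product converts tm to seconds).  With the filter
    inactive the equilibrium ADC ``D`` is returned.
    """
    D, sigma, axr = (np.asarray(x, dtype=float) for x in (D, sigma, axr))
    tm = np.asarray(tm, dtype=float)
    if np.any(sigma < 0) or np.any(sigma > 1):
        raise ValueError("sigma must lie in [0, 1]")
    if np.any(axr < 0):
        raise ValueError("AXR must be non-negative")
    if np.any(tm < 0):
        raise ValueError("tm must be non-negative")
    active = np.asarray(filter_active, dtype=bool)
    dprime = D * (1.0 - sigma * np.exp(-(tm / 1000.0) * axr))
    return np.where(active, dprime, D * np.ones_like(dprime))


def axr_signal(params, scheme: AcquisitionScheme):
    """FEXI signal vector ``exp(-b * D'(tm))`` for every scheme volume.

    ``params`` is ``(D, sigma, AXR)`` (array-like, last axis length 3).
    Volumes with b = 0 return 1 exactly (block-normalised signals).
    """
    scheme.validate_fexi()
    params = np.asarray(params, dtype=float)
    D, sigma, axr = params[..., 0:1], params[..., 1:2], params[..., 2:3]
    active = scheme.bf > 0
    dprime = axr_adc(D, sigma, axr, scheme.tm, active)
    return np.exp(-scheme.b * dprime)


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Parameter:
    name: str
    units: str
    lb: float
    ub: float

    def __post_init__(self) -> None:
        if not self.lb < self.ub:
            raise ValueError(f"bounds for {self.name} must satisfy lb < ub")


@dataclass(frozen=True)
class ModelSpec:
    """A named microstructure model.

    ``predict(theta, scheme)`` maps a parameter array of shape
    ``(..., n_params)`` (native, bounded space) to a signal array of
    shape ``(..., n_volumes)``; signals are strictly positive and
    finite for any parameter vector inside bounds.
    """

    name: str
    params: tuple[Parameter, ...]
    predict: Callable[[np.ndarray, AcquisitionScheme], np.ndarray]
    fraction_names: tuple[str, ...] = field(default=())

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    @property
    def lb(self) -> np.ndarray:
        return np.array([p.lb for p in self.params])

    @property
    def ub(self) -> np.ndarray:
        return np.array([p.ub for p in self.params])

    def validate_scheme(self, scheme: AcquisitionScheme) -> None:
        if self.name == "axr":
            scheme.validate_fexi()


def _dki_predict(theta: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    D, K = theta[..., 0:1], theta[..., 1:2]
    bD = scheme.b * D
    return np.exp(-bD + bD**2 * K / 6.0)


def dki_model() -> ModelSpec:
    """Mean-signal DKI with the fitting bounds D in (0.1, 3.5), K in (0, 3).

    Signals are normalised by the b = 0 mean, so S0 is fixed at 1 and
    only (D, K) are estimated.
    """
    return ModelSpec(
        name="dki",
        params=(
            Parameter("D", "um^2/ms", 0.1, 3.5),
            Parameter("K", "", 0.0, 3.0),
        ),
        predict=_dki_predict,
    )


def axr_model() -> ModelSpec:
    """FEXI AXR model with bounds D in (0.1, 3.5), sigma in (0, 1), AXR in (0, 50).

    The AXR upper bound is approximately the fastest exchange rate
    detectable given the shortest mixing time.  Signals are
    block-normalised, so no amplitude parameter is estimated.
    """
    return ModelSpec(
        name="axr",
        params=(
            Parameter("D", "um^2/ms", 0.1, 3.5),
            Parameter("sigma", "", 0.0, 1.0),
            Parameter("AXR", "1/s", 0.0, 50.0),
        ),
        predict=lambda theta, scheme: axr_signal(theta, scheme),
    )


def normalize_signals(
    data: np.ndarray, scheme: AcquisitionScheme, model: ModelSpec
) -> np.ndarray:
    """Normalise measured signals to the form the models predict.

    DKI data are divided voxelwise by the mean b = 0 signal (so S0 is
    fixed at 1 during fitting); FEXI data are divided block-by-block by
    each (bf, tm) block's mean b = 0 signal, matching the
    block-normalised AXR signal equation.  Voxels whose reference
    signal is not positive are left untouched (background).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[-1] != scheme.n_volumes:
        raise ValueError("data volume count does not match scheme")
    out = data.copy()
    if model.name == "axr":
        groups = [idx for _key, idx in scheme.blocks()]
    else:
        groups = [np.arange(scheme.n_volumes)]
    for idx in groups:
        b0 = idx[scheme.b[idx] == 0]
        if b0.size == 0:
            raise ValueError("cannot normalise: group lacks a b = 0 volume")
        ref = data[..., b0].mean(axis=-1)
        ok = ref > 0
        out[..., idx] = np.where(
            ok[..., None], data[..., idx] / np.maximum(ref, 1e-30)[..., None],
            data[..., idx],
        )
    return out


_MODELS: dict[str, Callable[[], ModelSpec]] = {"dki": dki_model, "axr": axr_model}


def get_model(name: str) -> ModelSpec:
    try:
        return _MODELS[name]()
    except KeyError:
        raise ValueError(f"unknown model {name!r}; available: {sorted(_MODELS)}") from None
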