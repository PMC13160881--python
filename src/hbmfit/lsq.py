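"""Voxel-by-voxel bounded multistart least-squares fitting.

The conventional baseline: each voxel's signal vector is fitted
independently by minimising the residual sum of squares from several
start points spread over the bounded parameter box.  Bounds are
enforced with a sin^2 reparameterisation (the simplex search runs in an
unbounded space and every evaluated point maps inside the box), so
degenerate voxels can and do converge onto the bounds themselves --
the "extreme fits" that the hierarchical method is designed to remove.

Besides serving as the comparison method, the per-ROI means and
standard deviations of these fits initialise the hierarchical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._neldermead import nelder_mead_batched
from .signal_models import AcquisitionScheme, ModelSpec, normalize_signals

__all__ = [
    "LsqConfig",
    "FitResult",
    "VolumeFitResult",
    "lattice_starts",
    "multistart_fit",
    "fit_volume",
    "block_adc",
]


_DEFAULT_STARTS = {2: 25, 3: 27}  # 5x5 lattice for 2 params, 3x3x3 for 3


@dataclass(frozen=True)
class LsqConfig:
    """Multistart least-squares settings.

    ``n_starts`` defaults per model dimensionality: 25 start points for
    two-parameter models (5x5 lattice) and 27 for three-parameter
    models (3x3x3 lattice), uniformly spaced strictly inside the
    bounds.
    """

    n_starts: Optional[int] = None
    xatol: float = 1e-8
    fatol: float = 1e-8
    maxiter: int = 2000

    def resolved_starts(self, n_params: int) -> int:
        if self.n_starts is not None:
            if self.n_starts < 1:
                raise ValueError("n_starts must be >= 1")
            return self.n_starts
        return _DEFAULT_STARTS.get(n_params, 3**n_params)


@dataclass
class FitResult:
    """Best-of-starts fit for one voxel."""

    params: np.ndarray       # (p,) native space, within bounds
    rss: float
    converged: bool
    start_rss: Optional[np.ndarray] = None  # (n_starts,) per-start minima


@dataclass
class VolumeFitResult:
    """Per-parameter maps plus per-ROI summaries for a fitted volume."""

    maps: dict[str, np.ndarray]       # param name -> map (nan outside labels)
    rss_map: np.ndarray
    converged_map: np.ndarray
    roi_summary: pd.DataFrame         # columns: roi, parameter, mean, sd, n
    model_name: str = ""


# ---------------------------------------------------------------------------
# bounded reparameterisation (sin^2), as used by bounded simplex wrappers
# ---------------------------------------------------------------------------


def _to_native(u: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    return lb + (ub - lb) * np.sin(u) ** 2


def _to_unbounded(x: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    frac = np.clip((x - lb) / (ub - lb), 0.0, 1.0)
    return np.arcsin(np.sqrt(frac))


def lattice_starts(lb: np.ndarray, ub: np.ndarray, n_starts: int) -> np.ndarray:
    """Start points on a regular lattice strictly inside the bounds.

    With ``m`` points per axis (the smallest m with m^p >= n_starts)
    placed at fractions (i+1)/(m+1), the first ``n_starts`` lattice
    points in row-major order are returned.  The defaults (25 for p=2,
    27 for p=3) use the full 5x5 and 3x3x3 lattices.
    """
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    p = len(lb)
    m = int(np.ceil(n_starts ** (1.0 / p)))
    while m**p < n_starts:  # guard against fp rounding in the root
        m += 1
    fracs = (np.arange(m) + 1.0) / (m + 1.0)
    axes = [lb[j] + (ub[j] - lb[j]) * fracs for j in range(p)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, p)
    return grid[:n_starts]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _check_signals(y: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"signal length {y.shape[-1]} does not match scheme "
            f"({scheme.n_volumes} volumes)"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("signals must be finite")
    return y


def _fit_batch(
    Y: np.ndarray,
    scheme: AcquisitionScheme,
    model: ModelSpec,
    config: LsqConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit every row of Y (V, N); returns (params (V,p), rss, converged, start_rss)."""
    V = Y.shape[0]
    lb, ub = model.lb, model.ub
    p = model.n_params
    n_starts = config.resolved_starts(p)
    starts = lattice_starts(lb, ub, n_starts)            # (S, p) native
    u_starts = _to_unbounded(starts, lb, ub)             # (S, p)

    # problem b = voxel * n_starts + start, so per-voxel starts are
    # contiguous and argmin ties resolve to the first lattice point
    u0 = np.tile(u_starts, (V, 1))
    vox_of = np.repeat(np.arange(V), n_starts)

    def objective(u: np.ndarray, idx: np.ndarray) -> np.ndarray:
        x = _to_native(u, lb, ub)
        pred = model.predict(x, scheme)
        r = Y[vox_of[idx]] - pred
        return np.einsum("ij,ij->i", r, r)

    res = nelder_mead_batched(
        objective, u0, xatol=config.xatol, fatol=config.fatol, maxiter=config.maxiter
    )
    rss_all = res.fun.reshape(V, n_starts)
    conv_all = res.converged.reshape(V, n_starts)
    x_all = _to_native(res.x, lb, ub).reshape(V, n_starts, p)
    best = np.argmin(rss_all, axis=1)
    rows = np.arange(V)
    return x_all[rows, best], rss_all[rows, best], conv_all[rows, best], rss_all


def multistart_fit(
    y: np.ndarray,
    scheme: AcquisitionScheme,
    model: ModelSpec,
    config: LsqConfig | None = None,
    keep_starts: bool = False,
    normalize: bool = True,
) -> FitResult:
    """Bounded multistart simplex fit of a single voxel's signal vector.

    The signal is first normalised to the model's amplitude convention
    (see :func:`~hbmfit.signal_models.normalize_signals`); the residual
    sum of squares is then minimised from ``n_starts`` lattice points
    inside the bounded box and the minimum-RSS solution returned; ties
    are broken by lattice order.  A result is flagged non-converged
    only if no start converged.
    """
    config = config or LsqConfig()
    y = _check_signals(np.atleast_1d(y), scheme)
    if normalize:
        y = normalize_signals(y, scheme, model)
    params, rss, conv, start_rss = _fit_batch(y[None, :], scheme, model, config)
    n_starts = config.resolved_starts(model.n_params)
    # converged if the selected start converged, or any start reached the
    # same minimum; all-starts failure is flagged but the best attempt kept
    return FitResult(
        params=params[0],
        rss=float(rss[0]),
        converged=bool(conv[0]),
        start_rss=start_rss[0] if keep_starts else None,
    )


def fit_volume(
    data: np.ndarray,
    labels: np.ndarray,
    scheme: AcquisitionScheme,
    model: ModelSpec,
    config: LsqConfig | None = None,
    normalize: bool = True,
) -> VolumeFitResult:
    """Independent multistart fits for every labelled voxel of a volume.

    ``data`` has shape ``(*grid, N)`` and ``labels`` shape ``(*grid,)``
    with 0 = background and positive integers naming ROIs.  Voxels with
    label 0 are not fitted (maps hold nan there).  Signals are
    normalised to the model's amplitude convention before fitting.
    The per-ROI summary gives mean, SD and count of the fitted
    parameters over each ROI.
    """
    config = config or LsqConfig()
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if data.shape[:-1] != labels.shape:
        raise ValueError(
            f"data grid {data.shape[:-1]} does not match labels {labels.shape}"
        )
    roi_ids = [int(k) for k in np.unique(labels) if k != 0]
    if not roi_ids:
        raise ValueError("no labelled voxels to fit")
    for k in roi_ids:
        if not np.any(labels == k):
            raise ValueError(f"ROI {k} is empty")

    mask = labels > 0
    Y = _check_signals(data[mask], scheme)
    if normalize:
        Y = normalize_signals(Y, scheme, model)
    params, rss, conv, _ = _fit_batch(Y, scheme, model, config)

    maps: dict[str, np.ndarray] = {}
    for j, name in enumerate(model.param_names):
        m = np.full(labels.shape, np.nan)
        m[mask] = params[:, j]
        maps[name] = m
    rss_map = np.full(labels.shape, np.nan)
    rss_map[mask] = rss
    conv_map = np.zeros(labels.shape, dtype=bool)
    conv_map[mask] = conv

    rows = []
    lab_v = labels[mask]
    for k in roi_ids:
        sel = lab_v == k
        for j, name in enumerate(model.param_names):
            vals = params[sel, j]
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "roi": k,
                    "parameter": name,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                }
            )
    summary = pd.DataFrame(rows)
    return VolumeFitResult(
        maps=maps,
        rss_map=rss_map,
        converged_map=conv_map,
        roi_summary=summary,
        model_name=model.name,
    )


def block_adc(y_block: np.ndarray, b: np.ndarray) -> float:
    """Data-derived apparent diffusion coefficient within one (bf, tm) block.

    Uses the mono-exponential inversion ``-ln(S(b+)/S(0)) / b+`` on the
    block means of the b = 0 and b > 0 signals.  A non-positive signal
    ratio has no defined ADC and returns nan; a ratio above 1 yields a
    negative ADC, which is returned as-is for the caller to flag.
    """
    y_block = np.asarray(y_block, dtype=float)
    b = np.asarray(b, dtype=float)
    if y_block.shape != b.shape:
        raise ValueError("y_block and b must align")
    low = b == 0
    high = ~low
    if not (low.any() and high.any()):
        raise ValueError("block must contain b = 0 and b > 0 entries")
    bplus = float(np.mean(b[high]))
    s0 = float(np.mean(y_block[low]))
    sb = float(np.mean(y_block[high]))
    if s0 <= 0 or sb <= 0:
        return float("nan")
    return -np.log(sb / s0) / bplus
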