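"""Evaluation metrics for fitted parameter maps.

Accuracy/precision against ground truth (RMSE, bias, percent-error
maps, Pearson correlation), between-ROI contrast-to-noise ratio, and
the extreme-fit rule that flags estimates stuck at the fitting bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr as _pearsonr

from .signal_models import ModelSpec

__all__ = [
    "rmse",
    "bias",
    "percent_error_map",
    "cnr",
    "extreme_fit_fraction",
    "pearson_r",
    "evaluate_maps",
]

#: estimates within this fraction of the bound *range* of either bound
#: count as extreme fits
EXTREME_FRACTION = 0.01


def _paired(truth, est) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=float).ravel()
    est = np.asarray(est, dtype=float).ravel()
    if truth.shape != est.shape:
        raise ValueError("truth and estimate must have equal length")
    if truth.size == 0:
        raise ValueError("empty input")
    keep = np.isfinite(truth) & np.isfinite(est)
    return truth[keep], est[keep]


def rmse(truth, est) -> float:
    """Root mean squared error, sqrt(mean((est - truth)^2))."""
    truth, est = _paired(truth, est)
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def bias(truth, est) -> float:
    """Signed mean error, mean(est - truth)."""
    truth, est = _paired(truth, est)
    return float(np.mean(est - truth))


def percent_error_map(truth_map, est_map) -> np.ndarray:
    """Voxelwise percent relative error, 100 (est - truth) / truth.

    Voxels with zero or non-finite truth are nan (masked), never
    infinite.
    """
    truth_map = np.asarray(truth_map, dtype=float)
    est_map = np.asarray(est_map, dtype=float)
    if truth_map.shape != est_map.shape:
        raise ValueError("maps must share a shape")
    out = np.full(truth_map.shape, np.nan)
    ok = np.isfinite(truth_map) & np.isfinite(est_map) & (truth_map != 0)
    out[ok] = 100.0 * (est_map[ok] - truth_map[ok]) / truth_map[ok]
    return out


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25.0, 75.0])  # linear interpolation (type 7)
    return float(q3 - q1)


def cnr(values_a, values_b) -> float:
    """Contrast-to-noise ratio between two ROIs' voxel values.

    ``|median_a - median_b| / sqrt(IQR_a^2 + IQR_b^2)`` with quartiles
    linearly interpolated between order statistics.  Undefined (nan)
    when both IQRs are zero.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both ROIs must be nonempty")
    denom = np.hypot(_iqr(a), _iqr(b))
    if denom == 0:
        return float("nan")
    return float(abs(np.median(a) - np.median(b)) / denom)


def extreme_fit_fraction(
    maps: dict[str, np.ndarray], model: ModelSpec
) -> tuple[dict[str, float], float]:
    """Percentage of voxels with estimates within 1% of the fitting bounds.

    A voxel-parameter is extreme if it lies within 1% of the bound
    *range* of either bound.  Returns (per-parameter %, % of voxels
    with at least one extreme parameter); both over voxels with finite
    estimates for every parameter.
    """
    stacked = np.stack(
        [np.asarray(maps[p.name], dtype=float).ravel() for p in model.params], axis=-1
    )
    finite = np.isfinite(stacked).all(axis=-1)
    stacked = stacked[finite]
    if stacked.size == 0:
        raise ValueError("no finite voxels to evaluate")
    lb, ub = model.lb, model.ub
    tol = EXTREME_FRACTION * (ub - lb)
    extreme = (stacked <= lb + tol) | (stacked >= ub - tol)
    per_param = {
        p.name: float(100.0 * extreme[:, j].mean())
        for j, p in enumerate(model.params)
    }
    any_pct = float(100.0 * extreme.any(axis=-1).mean())
    return per_param, any_pct


def pearson_r(truth, est) -> float:
    """Sample Pearson correlation between estimates and ground truth."""
    truth, est = _paired(truth, est)
    if truth.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.std(truth) == 0 or np.std(est) == 0:
        return float("nan")
    return float(_pearsonr(truth, est).statistic)


def evaluate_maps(
    truth_maps: dict[str, np.ndarray],
    est_maps: dict[str, np.ndarray],
    labels: np.ndarray,
    model: ModelSpec,
    method: str = "",
) -> pd.DataFrame:
    """Tabulated metrics for one set of fitted maps against ground truth.

    Pools all labelled voxels for RMSE/bias/correlation (matching how
    the simulation metrics aggregate over the full phantom) and reports
    CNR for every ROI pair.  Returns tidy rows
    (method, parameter, metric, value).
    """
    labels = np.asarray(labels)
    mask = labels > 0
    roi_ids = sorted(int(k) for k in np.unique(labels[mask]))
    rows = []
    per_param_ex, any_ex = extreme_fit_fraction(
        {name: np.asarray(est_maps[name])[mask] for name in model.param_names}, model
    )
    for name in model.param_names:
        truth_v = np.asarray(truth_maps[name])[mask]
        est_v = np.asarray(est_maps[name])[mask]
        rows.append((method, name, "rmse", rmse(truth_v, est_v)))
        rows.append((method, name, "bias", bias(truth_v, est_v)))
        rows.append((method, name, "pearson_r", pearson_r(truth_v, est_v)))
        rows.append((method, name, "extreme_pct", per_param_ex[name]))
        for ia, ka in enumerate(roi_ids):
            for kb in roi_ids[ia + 1:]:
                val = cnr(
                    np.asarray(est_maps[name])[labels == ka],
                    np.asarray(est_maps[name])[labels == kb],
                )
                rows.append((method, name, f"cnr_{ka}_{kb}", val))
    rows.append((method, "any", "extreme_any_pct", any_ex))
    return pd.DataFrame(rows, columns=["method", "parameter", "metric", "value"])
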