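"""NIfTI / scheme / config file handling.

Volumes are exchanged as NIfTI (via nibabel) with the affine respected
on write; acquisition schemes as whitespace-delimited text; configs as
YAML; run manifests as JSON.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import yaml

from .signal_models import AcquisitionScheme

__all__ = [
    "read_volume",
    "write_map",
    "read_labels",
    "load_config",
    "write_manifest",
    "save_phantom",
]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_map(data: np.ndarray, affine: Optional[np.ndarray], path) -> None:
    """Write an array as NIfTI; a 2D map is stored as a single slice."""
    data = np.asarray(data)
    if affine is None:
        affine = np.eye(4)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_labels(path) -> tuple[np.ndarray, np.ndarray]:
    """Load an integer ROI label map; returns (labels, affine)."""
    data, affine = read_volume(path)
    labels = np.rint(data).astype(int)
    if np.any(np.abs(data - labels) > 1e-6):
        raise ValueError(f"{path} does not contain integer labels")
    return labels, affine


def check_scheme_data(data: np.ndarray, scheme: AcquisitionScheme) -> None:
    if data.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"data has {data.shape[-1]} volumes but the scheme lists "
            f"{scheme.n_volumes}"
        )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_manifest(path, **entries) -> None:
    """JSON run manifest (config, seeds, versions) for bit reproducibility."""
    payload = dict(entries)
    payload.setdefault("versions", {})
    import hbmfit

    payload["versions"].setdefault("hbmfit", getattr(hbmfit, "__version__", "?"))
    payload["versions"].setdefault("numpy", np.__version__)
    blob = json.dumps(payload, sort_keys=True, default=_jsonify)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def save_phantom(phantom, outdir, affine: Optional[np.ndarray] = None) -> dict[str, Path]:
    """Write a phantom to ``outdir``: noisy/clean stacks, labels, truth maps,
    the scheme file and a JSON sidecar recording the generative settings."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_map(phantom.noisy, affine, outdir / "noisy.nii.gz")
    write_map(phantom.clean, affine, outdir / "clean.nii.gz")
    write_map(phantom.labels.astype(float), affine, outdir / "labels.nii.gz")
    paths["noisy"] = outdir / "noisy.nii.gz"
    paths["clean"] = outdir / "clean.nii.gz"
    paths["labels"] = outdir / "labels.nii.gz"
    for name, m in phantom.truth_maps.items():
        p = outdir / f"truth_{name}.nii.gz"
        write_map(m, affine, p)
        paths[f"truth_{name}"] = p
    phantom.scheme.to_file(outdir / "scheme.txt")
    paths["scheme"] = outdir / "scheme.txt"
    sidecar = {
        "model": phantom.model_name,
        "snr": phantom.spec.snr,
        "seed": phantom.spec.seed,
        "noise_sd": phantom.noise_sd,
        "roi_sizes": phantom.spec.roi_sizes,
        "distributions": {
            str(k): {p: list(v) for p, v in d.items()}
            for k, d in phantom.spec.distributions.items()
        },
    }
    with open(outdir / "phantom.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=_jsonify)
    paths["sidecar"] = outdir / "phantom.json"
    return paths
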