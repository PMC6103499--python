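"""Reading slices, writing masks, and serializing intermediate artifacts.

Slices are accepted as grayscale PNG/TIFF (intensities rescaled to [0, 1]
by the dtype maximum) or as single slices extracted from NIfTI volumes
(min-max rescaled, affine preserved for round-trip writing).  Intermediates
are written in plain formats: 16-bit PNG label images with JSON sidecars,
edge-list / feature CSVs, and JSON model files.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .crf import CRFModel
from .features import EdgeFeatures, FeatureTable
from .structure import IsingModel
from .superpixels import RegionGraph, SuperpixelMap

__all__ = [
    "read_slice",
    "write_mask",
    "save_superpixels",
    "load_superpixels",
    "save_graph",
    "save_features",
    "save_ising",
    "save_crf_model",
    "load_crf_model",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_SUFFIXES)


def read_slice(path, slice_index: int | None = None, to_gray: bool = False) -> np.ndarray:
    """Load a 2-D grayscale slice as floats in [0, 1].

    For NIfTI inputs ``slice_index`` picks a slice along the last axis; the
    slice is min-max rescaled.  RGB rasters are refused unless ``to_gray``
    asks for a luminance conversion.
    """
    path = Path(path)
    if _is_nifti(path):
        vol = nib.load(str(path))
        data = np.asanyarray(vol.dataobj).astype(float)
        if data.ndim == 2:
            img = data
        else:
            if slice_index is None:
                raise ValueError("NIfTI volume requires a slice index")
            if not (0 <= slice_index < data.shape[-1]):
                raise ValueError("slice index out of range")
            img = data[..., slice_index]
        lo, hi = img.min(), img.max()
        return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    raster = iio.imread(path)
    if raster.ndim == 3:
        if not to_gray:
            raise ValueError("RGB input: pass to_gray=True to convert")
        raster = raster[..., :3].mean(axis=2)
    if np.issubdtype(raster.dtype, np.integer):
        return raster.astype(float) / np.iinfo(raster.dtype).max
    return raster.astype(float)


def write_mask(path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a binary mask as 8-bit PNG {0, 255} or NIfTI uint8."""
    path = Path(path)
    binary = (np.asarray(mask) > 0).astype(np.uint8)
    if _is_nifti(path):
        aff = affine if affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(binary, aff), str(path))
    else:
        iio.imwrite(path, binary * np.uint8(255))


def save_superpixels(path_stem, sp: SuperpixelMap, params: dict | None = None) -> None:
    """16-bit PNG label image plus a JSON sidecar."""
    stem = Path(path_stem)
    if sp.n_regions > np.iinfo(np.uint16).max:
        raise ValueError("too many regions for a 16-bit label image")
    iio.imwrite(stem.with_suffix(".png"), sp.labels.astype(np.uint16))
    sidecar = {"n_regions": sp.n_regions, "params": params or {}}
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_superpixels(path_stem) -> SuperpixelMap:
    stem = Path(path_stem)
    labels = iio.imread(stem.with_suffix(".png")).astype(np.int64)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return SuperpixelMap(labels=labels, n_regions=int(meta["n_regions"]))


def save_graph(path, graph: RegionGraph, weights: np.ndarray | None = None) -> None:
    """Edge-list CSV: node_i, node_j, hops [, weight]."""
    df = pd.DataFrame({
        "node_i": graph.edges[:, 0] if graph.edges.size else [],
        "node_j": graph.edges[:, 1] if graph.edges.size else [],
        "hops": graph.hops if graph.edges.size else [],
    })
    if weights is not None:
        df["weight"] = weights
    df.to_csv(path, index=False)


def save_features(path_stem, table: FeatureTable) -> None:
    """Feature CSV (region_id + named columns) + standardization sidecar."""
    stem = Path(path_stem)
    table.data.to_csv(stem.with_suffix(".csv"))
    sidecar = {
        "center": None if table.center is None else list(map(float, table.center)),
        "scale": None if table.scale is None else list(map(float, table.scale)),
        "columns": list(table.data.columns),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def save_ising(path, model: IsingModel) -> None:
    payload = {
        "theta_node": list(map(float, model.theta_node)),
        "theta_edge": list(map(float, model.theta_edge)),
        "edges": [[int(i), int(j)] for i, j in model.edges],
        "lambda_struct": model.lambda_struct,
        "converged": bool(model.converged),
        "n_iterations": len(model.trace) - 1,
        "final_objective": float(model.trace[-1]) if model.trace else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def save_crf_model(path, model: CRFModel) -> None:
    payload = {
        "w_node": {"bias": float(model.w_node[0]),
                   **{n: float(w) for n, w in zip(model.feature_names, model.w_node[1:])}},
        "w_edge": list(map(float, model.w_edge)),
        "feature_names": model.feature_names,
        "center": None if model.center is None else list(map(float, model.center)),
        "scale": None if model.scale is None else list(map(float, model.scale)),
        "lambda1": model.lambda1,
        "lambda2": model.lambda2,
        "converged": bool(model.converged),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_crf_model(path) -> CRFModel:
    raw = json.loads(Path(path).read_text())
    names = raw["feature_names"]
    w_node = np.array([raw["w_node"]["bias"]] + [raw["w_node"][n] for n in names])
    return CRFModel(
        w_node=w_node,
        w_edge=np.array(raw["w_edge"], dtype=float),
        feature_names=names,
        center=None if raw["center"] is None else np.array(raw["center"]),
        scale=None if raw["scale"] is None else np.array(raw["scale"]),
        lambda1=raw["lambda1"],
        lambda2=raw["lambda2"],
    )
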