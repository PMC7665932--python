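"""Image readers/writers and model checkpoints.

Intensities live on a [0, 1] float scale inside the package.  8-bit files
are divided by 255 on read, 16-bit by 65535; writing quantizes back (with
clipping at export only — in-memory noisy images are never clipped).
NIfTI volumes are processed slice-wise along the last axis and normalized
by the volume maximum.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import tifffile

from .network import DenoisingNetwork, ModelSpec

__all__ = [
    "read_image",
    "write_image",
    "iter_nifti_slices",
    "save_checkpoint",
    "load_checkpoint",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def iter_nifti_slices(path: str | Path) -> Iterator[np.ndarray]:
    """Yield 2-D slices of a NIfTI volume, scaled to [0, 1] by the volume max."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if vol.ndim == 2:
        vol = vol[..., None]
    peak = vol.max()
    if peak > 0:
        vol = vol / peak
    vol = np.clip(vol, 0.0, 1.0)
    for k in range(vol.shape[-1]):
        yield vol[..., k]


def read_image(path: str | Path):
    """Read PNG/TIFF as a [0, 1] float image; NIfTI as a slice iterator.

    8-bit integer data is scaled by 1/255, 16-bit by 1/65535; float TIFF
    data is taken as already being on the internal scale.  Multi-channel
    images are converted to grayscale by channel averaging.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        return iter_nifti_slices(path)
    suffix = path.suffix.lower()
    if suffix not in (".png", ".tif", ".tiff"):
        raise ValueError(f"unsupported image format: {path.name}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.dtype == np.uint8:
        img = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        img = arr.astype(np.float64) / 65535.0
    else:
        img = arr.astype(np.float64)
    return img


def write_image(
    path: str | Path, img: np.ndarray, bit_depth: int = 8, clip: bool = True
) -> None:
    """Write a [0, 1] float image as 8-bit PNG or 8/16-bit TIFF.

    ``clip=False`` (TIFF only) stores raw float32 values, preserving
    out-of-range noisy intensities exactly.
    """
    path = Path(path)
    img = np.asarray(img, dtype=np.float64)
    suffix = path.suffix.lower()
    if not clip:
        if suffix not in (".tif", ".tiff"):
            raise ValueError("unclipped output requires a TIFF file")
        tifffile.imwrite(path, img.astype(np.float32))
        return
    clipped = np.clip(img, 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(clipped * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(clipped * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    if suffix == ".png":
        iio.imwrite(path, data)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def save_checkpoint(path: str | Path, network: DenoisingNetwork, extra: dict | None = None) -> None:
    """Save architecture spec (JSON) + all parameter tensors in one archive.

    Includes batch-norm running statistics so evaluation-mode behaviour is
    restored exactly.
    """
    arrays = {}
    for i, layer in enumerate(network.layers()):
        for name in sorted(layer.params):
            arrays[f"param_{i}_{name}"] = layer.params[name]
        if hasattr(layer, "running_mean"):
            arrays[f"running_{i}_mean"] = layer.running_mean
            arrays[f"running_{i}_var"] = layer.running_var
    meta = {"format_version": 1, "spec": json.loads(network.spec.to_json())}
    if extra:
        meta["extra"] = extra
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> DenoisingNetwork:
    """Restore a network saved by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec_d = meta["spec"]
        spec_d["kernel_plan"] = tuple(tuple(p) for p in spec_d["kernel_plan"])
        network = DenoisingNetwork(ModelSpec(**spec_d))
        for i, layer in enumerate(network.layers()):
            for name in sorted(layer.params):
                layer.params[name] = data[f"param_{i}_{name}"].copy()
            if hasattr(layer, "running_mean"):
                layer.running_mean = data[f"running_{i}_mean"].copy()
                layer.running_var = data[f"running_{i}_var"].copy()
    return network
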