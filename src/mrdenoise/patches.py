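"""Training-patch extraction, augmentation, and minibatch assembly.

Denoising networks train on small paired blocks cut from (noisy, clean)
image pairs.  Two sampling schemes are provided: a regular grid of
``patch_size`` blocks at a fixed ``stride`` (anchored at offset 0,
truncated at the border — no padded partial patches), and uniformly random
crops.  Augmentation adds horizontal/vertical mirror copies and small
cyclic translations; the identical transform is always applied to the
clean and noisy member of a pair so pairing integrity is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .phantom import ImagePair

__all__ = [
    "PatchSet",
    "grid_patch_count",
    "extract_patches",
    "random_crops",
    "augment",
    "save_patch_cache",
    "load_patch_cache",
    "minibatches",
]


@dataclass
class PatchSet:
    """Paired noisy/clean image blocks.

    ``noisy`` and ``clean`` are stacked as ``(n, patch_size, patch_size)``
    arrays; row i of each comes from identical source coordinates.
    """

    noisy: np.ndarray
    clean: np.ndarray
    patch_size: int
    stride: int | None = None
    source_count: int = 1

    def __post_init__(self) -> None:
        if self.noisy.shape != self.clean.shape:
            raise ValueError("noisy and clean patch stacks must share a shape")
        if self.noisy.ndim != 3:
            raise ValueError("patch stacks must be 3-D (n, h, w)")
        n, h, w = self.noisy.shape
        if n > 0 and (h != self.patch_size or w != self.patch_size):
            raise ValueError(
                f"patches are {h}x{w}, expected {self.patch_size}x{self.patch_size}"
            )

    def __len__(self) -> int:
        return self.noisy.shape[0]

    @staticmethod
    def concatenate(sets: "list[PatchSet]") -> "PatchSet":
        if not sets:
            raise ValueError("cannot concatenate an empty list of PatchSets")
        ps = sets[0].patch_size
        if any(s.patch_size != ps for s in sets):
            raise ValueError("all PatchSets must share patch_size")
        return PatchSet(
            noisy=np.concatenate([s.noisy for s in sets], axis=0),
            clean=np.concatenate([s.clean for s in sets], axis=0),
            patch_size=ps,
            stride=sets[0].stride,
            source_count=sum(s.source_count for s in sets),
        )


def grid_patch_count(dim: int, patch_size: int, stride: int) -> int:
    """Patches per axis for a grid anchored at 0, full patches only."""
    if dim < patch_size:
        return 0
    return (dim - patch_size) // stride + 1


def extract_patches(pair: ImagePair, patch_size: int = 32, stride: int = 10) -> PatchSet:
    """Extract paired blocks on a regular grid.

    Top-left offsets run over {0, stride, 2*stride, ...} in each axis
    wherever a full ``patch_size`` block fits.  An image smaller than
    ``patch_size`` in either axis yields an empty set.  The defaults
    (32x32 blocks, stride 10) are the standard dataset-statistics setting:
    a 180x215 image gives 15 x 19 = 285 blocks.
    """
    if patch_size < 1 or stride < 1:
        raise ValueError("patch_size and stride must be >= 1")
    h, w = pair.clean.shape
    ny = grid_patch_count(h, patch_size, stride)
    nx = grid_patch_count(w, patch_size, stride)
    noisy = np.empty((ny * nx, patch_size, patch_size))
    clean = np.empty_like(noisy)
    idx = 0
    for iy in range(ny):
        y0 = iy * stride
        for ix in range(nx):
            x0 = ix * stride
            clean[idx] = pair.clean[y0 : y0 + patch_size, x0 : x0 + patch_size]
            noisy[idx] = pair.noisy[y0 : y0 + patch_size, x0 : x0 + patch_size]
            idx += 1
    return PatchSet(noisy=noisy, clean=clean, patch_size=patch_size, stride=stride)


def random_crops(pair: ImagePair, crop_size: int = 45, n: int = 1, seed: int = 0) -> PatchSet:
    """Cut ``n`` uniformly positioned paired crops of ``crop_size``.

    This is the training-time sampling scheme (default 45x45 blocks).
    Reproducible for a fixed seed; ``crop_size`` equal to the image size
    degenerates to n copies of the full image.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    h, w = pair.clean.shape
    if crop_size > h or crop_size > w:
        raise ValueError(
            f"crop_size {crop_size} exceeds image dimensions {h}x{w}"
        )
    rng = np.random.default_rng(seed)
    y0s = rng.integers(0, h - crop_size + 1, size=n)
    x0s = rng.integers(0, w - crop_size + 1, size=n)
    noisy = np.empty((n, crop_size, crop_size))
    clean = np.empty_like(noisy)
    for i, (y0, x0) in enumerate(zip(y0s, x0s)):
        clean[i] = pair.clean[y0 : y0 + crop_size, x0 : x0 + crop_size]
        noisy[i] = pair.noisy[y0 : y0 + crop_size, x0 : x0 + crop_size]
    return PatchSet(noisy=noisy, clean=clean, patch_size=crop_size)


def augment(
    patches: PatchSet,
    flips: bool = True,
    translations: bool = False,
    seed: int = 0,
    max_shift: int = 5,
) -> PatchSet:
    """Enlarge a patch set with mirror and translation copies.

    ``flips`` adds the three mirror images of every patch (horizontal,
    vertical, both), quadrupling the set.  ``translations`` adds one
    cyclically shifted copy per patch with a seeded random offset up to
    ``max_shift`` pixels per axis.  The same transform is applied to the
    clean and noisy member of each pair.
    """
    if len(patches) == 0:
        raise ValueError("cannot augment an empty PatchSet")
    noisy_out = [patches.noisy]
    clean_out = [patches.clean]
    if flips:
        for op in (
            lambda a: a[:, :, ::-1],          # horizontal mirror
            lambda a: a[:, ::-1, :],          # vertical mirror
            lambda a: a[:, ::-1, ::-1],       # both
        ):
            noisy_out.append(op(patches.noisy))
            clean_out.append(op(patches.clean))
    if translations:
        rng = np.random.default_rng(seed)
        shifts = rng.integers(-max_shift, max_shift + 1, size=(len(patches), 2))
        tn = np.empty_like(patches.noisy)
        tc = np.empty_like(patches.clean)
        for i, (dy, dx) in enumerate(shifts):
            tn[i] = np.roll(patches.noisy[i], (dy, dx), axis=(0, 1))
            tc[i] = np.roll(patches.clean[i], (dy, dx), axis=(0, 1))
        noisy_out.append(tn)
        clean_out.append(tc)
    return PatchSet(
        noisy=np.ascontiguousarray(np.concatenate(noisy_out, axis=0)),
        clean=np.ascontiguousarray(np.concatenate(clean_out, axis=0)),
        patch_size=patches.patch_size,
        stride=patches.stride,
        source_count=patches.source_count,
    )


def save_patch_cache(path, patches: PatchSet, meta: dict | None = None) -> None:
    """Store a patch set on disk with a JSON sidecar of its provenance."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, noisy=patches.noisy, clean=patches.clean)
    sidecar = {
        "patch_size": patches.patch_size,
        "stride": patches.stride,
        "source_count": patches.source_count,
        "n_patches": len(patches),
    }
    if meta:
        sidecar.update(meta)
    Path(str(path.with_suffix("")) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_patch_cache(path) -> PatchSet:
    """Load a patch set saved by :func:`save_patch_cache`."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(Path(str(path.with_suffix("")) + ".json").read_text())
    with np.load(path) as data:
        return PatchSet(
            noisy=data["noisy"].copy(),
            clean=data["clean"].copy(),
            patch_size=sidecar["patch_size"],
            stride=sidecar["stride"],
            source_count=sidecar["source_count"],
        )


def minibatches(
    patches: PatchSet, batch_size: int, seed: int = 0
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (noisy, clean) minibatches in a seeded shuffled order.

    Each batch has shape ``(b, patch_size, patch_size)``; a final partial
    batch is dropped only if it holds a single patch (batch statistics
    need at least two samples).
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patches))
    for start in range(0, len(order), batch_size):
        sel = order[start : start + batch_size]
        if len(sel) < 2 and batch_size >= 2:
            continue
        yield patches.noisy[sel], patches.clean[sel]
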