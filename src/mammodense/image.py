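"""Core raster containers used by every image operator.

A :class:`MammogramImage` is a single-channel intensity raster with the
acquisition metadata the pipeline needs (bit depth, laterality, view).
Masks are plain boolean numpy arrays except for :class:`DenseMask`, which
remembers the thresholding method and threshold that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile


@dataclass
class MammogramImage:
    """Single-channel mammogram-like raster.

    Parameters
    ----------
    pixels
        2-D array.  Integers in ``[0, 2**bit_depth - 1]`` for raw images,
        floats in ``[0, 1]`` after intensity normalization.
    bit_depth
        Dynamic range of the original digitization (default 12 bit).
    laterality
        ``"left"`` or ``"right"``; by convention the chest wall lies along
        column 0 for a left image and along the last column for a right one.
    view
        Mammographic projection; only the mediolateral oblique view is used.
    id
        Opaque identifier carried through to feature tables.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    laterality: str = "left"
    view: str = "MLO"
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"unknown laterality {self.laterality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bit_depth - 1

    def with_pixels(self, pixels: np.ndarray) -> "MammogramImage":
        return replace(self, pixels=pixels)

    def mirrored(self) -> "MammogramImage":
        """Left/right mirror image with laterality flipped accordingly."""
        other = "right" if self.laterality == "left" else "left"
        return replace(self, pixels=self.pixels[:, ::-1].copy(),
                       laterality=other)


@dataclass
class DenseMask:
    """Dense-area mask for one thresholding method.

    ``mask`` is a boolean raster, a subset of the breast mask; dense pixels
    are exactly the breast pixels with intensity strictly above ``threshold``.
    The dense area need not be connected.
    """

    mask: np.ndarray
    method: str
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def save_image(image: MammogramImage, path: str | Path) -> None:
    """Write a raw image as 16-bit single-channel TIFF or PNG."""
    path = Path(path)
    arr = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "bit_depth": image.bit_depth,
        "laterality": image.laterality,
        "view": image.view,
        "id": image.id,
    }))


def load_image(path: str | Path) -> MammogramImage:
    """Read a 16-bit TIFF/PNG written by :func:`save_image`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return MammogramImage(np.asarray(arr),
                          bit_depth=int(meta.get("bit_depth", 12)),
                          laterality=meta.get("laterality", "left"),
                          view=meta.get("view", "MLO"),
                          id=meta.get("id", path.stem))


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Persist a boolean mask as an 8-bit 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127
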