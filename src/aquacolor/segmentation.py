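"""Per-pixel class masks and foam-region geometry.

The pipeline consumes externally produced segmentation masks (any
instance/semantic segmenter can provide them; the synthetic generator
writes exact ground-truth masks).  A mask is a single-channel indexed
PNG whose labels are:

====  ====================
0     background / excluded
1     water
2     waterwheel
3     checkerboard
4     foam
====  ====================

Foam regions are labeled with 8-connectivity; each component carries its
contour pixel set (component pixels adjacent to a non-component pixel),
which is what patch-to-foam distances are measured against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import MaskError

__all__ = [
    "CLASS_MAP",
    "LABEL_BACKGROUND",
    "LABEL_WATER",
    "LABEL_WATERWHEEL",
    "LABEL_CHECKERBOARD",
    "LABEL_FOAM",
    "ClassMask",
    "FoamComponent",
    "load_mask",
    "save_mask",
    "foam_components",
]

LABEL_BACKGROUND = 0
LABEL_WATER = 1
LABEL_WATERWHEEL = 2
LABEL_CHECKERBOARD = 3
LABEL_FOAM = 4

CLASS_MAP = {
    LABEL_BACKGROUND: "background",
    LABEL_WATER: "water",
    LABEL_WATERWHEEL: "waterwheel",
    LABEL_CHECKERBOARD: "checkerboard",
    LABEL_FOAM: "foam",
}

#: Display palette for the indexed PNG (background, water, wheel, board, foam).
_PALETTE = [0, 0, 0, 30, 90, 160, 90, 90, 90, 240, 240, 240, 255, 255, 200]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class ClassMask:
    """A validated per-pixel label image."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise MaskError(f"mask must be 2-D, got shape {self.labels.shape}")
        bad = np.setdiff1d(np.unique(self.labels), list(CLASS_MAP))
        if bad.size:
            raise MaskError(f"mask contains unknown labels {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def class_fraction(self, label: int) -> float:
        return float(np.mean(self.labels == label))

    def __eq__(self, other) -> bool:
        return isinstance(other, ClassMask) and np.array_equal(
            self.labels, other.labels
        )


def load_mask(path, expected_shape: tuple | None = None) -> ClassMask:
    """Read an indexed-PNG mask and validate labels (and shape if given)."""
    with Image.open(path) as img:
        labels = np.asarray(img)
    if labels.ndim == 3:
        raise MaskError(f"{path}: expected a single-channel indexed mask")
    if expected_shape is not None and labels.shape != tuple(expected_shape):
        raise MaskError(
            f"{path}: mask shape {labels.shape} does not match image "
            f"shape {tuple(expected_shape)}"
        )
    return ClassMask(labels)


def save_mask(mask: ClassMask, path) -> None:
    """Write a mask as an indexed (palette) PNG; round-trips bit-exactly."""
    img = Image.fromarray(mask.labels, mode="P")
    img.putpalette(_PALETTE + [0] * (768 - len(_PALETTE)))
    img.save(path)


@dataclass
class FoamComponent:
    """One 8-connected foam region."""

    label: int
    pixel_count: int
    pixels: np.ndarray  # (n, 2) int (row, col)
    contour: np.ndarray  # (m, 2) int (row, col) boundary pixels

    @property
    def contour_xy(self) -> np.ndarray:
        """Contour pixels in (x, y) order."""
        return self.contour[:, ::-1]


def foam_components(mask: ClassMask) -> list:
    """Label the foam class into 8-connected components with contours."""
    foam = mask.labels == LABEL_FOAM
    labeled, n = ndimage.label(foam, structure=_EIGHT)
    components = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        interior = ndimage.binary_erosion(comp, structure=_EIGHT, border_value=0)
        contour = comp & ~interior
        components.append(
            FoamComponent(
                label=lab,
                pixel_count=int(comp.sum()),
                pixels=np.argwhere(comp),
                contour=np.argwhere(contour),
            )
        )
    return components
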