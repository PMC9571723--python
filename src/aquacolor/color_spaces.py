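"""RGB <-> XYZ <-> CIE Lab conversions used throughout the pipeline.

The forward path scales 8-bit RGB to [0, 1], applies the fixed sRGB/D65
3x3 matrix to obtain XYZ tristimulus values, and maps those to CIE Lab
with the standard cube-root compression.  No gamma linearization is
applied: the correction model is estimated and applied in exactly this
Lab space, so the only requirement is that the forward and inverse paths
agree, which they do to better than one 8-bit level per channel.

All functions accept either a single color (shape ``(3,)``) or an array
of colors whose last axis has length 3 (e.g. an ``(H, W, 3)`` image) and
are fully vectorized.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "WHITE_POINT",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_lab",
    "lab_to_xyz",
    "xyz_to_rgb",
    "lab_to_rgb",
]

#: Fixed RGB -> XYZ matrix (rows X, Y, Z) for RGB scaled to [0, 1].
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)

_XYZ_TO_RGB_MATRIX = np.linalg.inv(RGB_TO_XYZ_MATRIX)

#: Reference white point (Xn, Yn, Zn).
WHITE_POINT = np.array([0.9515, 1.0, 1.0886])

#: Threshold between the cube-root and linear branches of f.
_F_THRESHOLD = 0.008856
#: Slope of the linear branch of f.
_F_SLOPE = 7.787037
#: f evaluated at the threshold; used to pick the branch of the inverse.
_FINV_THRESHOLD = _F_SLOPE * _F_THRESHOLD + 16.0 / 116.0


def _compress(v: np.ndarray) -> np.ndarray:
    """Lab compression f(v): cube root above the threshold, linear below."""
    v = np.asarray(v, dtype=float)
    return np.where(v > _F_THRESHOLD, np.cbrt(v), _F_SLOPE * v + 16.0 / 116.0)


def _decompress(f: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_compress`, branch chosen by f(threshold)."""
    f = np.asarray(f, dtype=float)
    return np.where(f > _FINV_THRESHOLD, f**3, (f - 16.0 / 116.0) / _F_SLOPE)


def rgb_to_xyz(rgb) -> np.ndarray:
    """Convert 8-bit RGB (0-255 per channel) to XYZ tristimulus values.

    Parameters
    ----------
    rgb : array-like, shape (..., 3)
        Channel intensities in [0, 255].

    Raises
    ------
    DomainError
        If any channel is outside [0, 255] or non-finite.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise DomainError(f"expected last axis of length 3, got shape {rgb.shape}")
    if not np.all(np.isfinite(rgb)) or rgb.min() < 0 or rgb.max() > 255:
        raise DomainError("RGB channels must be finite and within [0, 255]")
    return (rgb / 255.0) @ RGB_TO_XYZ_MATRIX.T


def xyz_to_lab(xyz) -> np.ndarray:
    """Convert XYZ to CIE Lab (L in [0, 100] for in-gamut input).

    Raises
    ------
    DomainError
        If any tristimulus value is negative or non-finite.
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise DomainError(f"expected last axis of length 3, got shape {xyz.shape}")
    if not np.all(np.isfinite(xyz)) or xyz.min() < 0:
        raise DomainError("tristimulus values must be finite and non-negative")
    f = _compress(xyz / WHITE_POINT)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack(
        [116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1
    )


def rgb_to_lab(rgb) -> np.ndarray:
    """8-bit RGB to CIE Lab through the XYZ intermediate."""
    return xyz_to_lab(rgb_to_xyz(rgb))


def lab_to_xyz(lab) -> np.ndarray:
    """Invert the Lab compression back to XYZ tristimulus values."""
    lab = np.asarray(lab, dtype=float)
    if lab.shape[-1] != 3:
        raise DomainError(f"expected last axis of length 3, got shape {lab.shape}")
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    return _decompress(f) * WHITE_POINT


def xyz_to_rgb(xyz) -> np.ndarray:
    """XYZ back to 8-bit RGB; out-of-gamut values are clamped, then rounded."""
    xyz = np.asarray(xyz, dtype=float)
    rgb = (xyz @ _XYZ_TO_RGB_MATRIX.T) * 255.0
    return np.clip(np.rint(rgb), 0, 255)


def lab_to_rgb(lab) -> np.ndarray:
    """CIE Lab to 8-bit RGB: exact inverse of the forward path with clamping."""
    return xyz_to_rgb(lab_to_xyz(lab))
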