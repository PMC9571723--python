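"""Checkerboard-based color correction in CIE Lab space.

A single 3x3 matrix ``M`` maps each measured Lab pixel back toward its
ideal value.  ``M`` is estimated from the 24 (measured, reference) block
pairs by stacking three block-diagonal rows per block into a 72x9 linear
system ``A m = d`` and solving it with the normal-equation pseudo-inverse
``m = (A^T A)^{-1} A^T d``.  The model is purely linear — no offset term —
and is applied per pixel: RGB -> Lab, left-multiply by M, Lab -> RGB with
gamut clamping at the final stage only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import color_spaces
from .checkerboard import (
    CheckerboardLayout,
    detect_markers,
    estimate_roi_homography,
    extract_block_colors,
)
from .errors import DomainError, EstimationError, LocalizationError

__all__ = [
    "BlockCorrespondence",
    "CorrectionModel",
    "build_lsq_system",
    "estimate_correction",
    "apply_correction",
    "correct_image",
    "LabColorCorrector",
]


@dataclass
class BlockCorrespondence:
    """Index-aligned measured vs. reference Lab colors of the 24 blocks."""

    measured: np.ndarray  # (24, 3) Lab
    reference: np.ndarray  # (24, 3) Lab

    def __post_init__(self):
        self.measured = np.asarray(self.measured, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.measured.shape != self.reference.shape or self.measured.ndim != 2:
            raise DomainError("measured and reference must be aligned (n, 3) arrays")
        if self.measured.shape[1] != 3:
            raise DomainError("Lab colors must have 3 components")

    @classmethod
    def from_rgb(cls, measured_rgb, reference_rgb) -> "BlockCorrespondence":
        return cls(
            color_spaces.rgb_to_lab(measured_rgb),
            color_spaces.rgb_to_lab(reference_rgb),
        )


@dataclass
class CorrectionModel:
    """The fitted 3x3 Lab correction matrix and its block RMS residual."""

    matrix: np.ndarray
    residual: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3) or not np.all(np.isfinite(self.matrix)):
            raise DomainError("correction matrix must be a finite 3x3 matrix")
        if self.residual < 0:
            raise DomainError("residual must be non-negative")

    @classmethod
    def identity(cls) -> "CorrectionModel":
        return cls(np.eye(3), 0.0)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"matrix": self.matrix.tolist(), "residual": float(self.residual)},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "CorrectionModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(np.asarray(d["matrix"]), float(d["residual"]))


def build_lsq_system(corr: BlockCorrespondence) -> tuple:
    """Stack the per-block rows of the linear system ``A m = d``.

    For each of the 24 blocks, three rows place the measured Lab triple on
    the block diagonal (one row per output component), so ``A`` is 72x9 and
    ``d`` stacks the reference Lab triples into a 72-vector.
    """
    n = corr.measured.shape[0]
    if n != 24:
        raise DomainError(f"expected 24 block pairs, got {n}")
    A = np.zeros((3 * n, 9))
    for i in range(n):
        for j in range(3):
            A[3 * i + j, 3 * j : 3 * j + 3] = corr.measured[i]
    d = corr.reference.reshape(-1)
    return A, d


def estimate_correction(corr: BlockCorrespondence) -> CorrectionModel:
    """Solve the stacked system with the normal-equation pseudo-inverse."""
    A, d = build_lsq_system(corr)
    if np.linalg.matrix_rank(A) < 9:
        raise EstimationError(
            "design matrix is rank-deficient: the 24 measured colors do not "
            "span Lab space (rank "
            f"{np.linalg.matrix_rank(A)} < 9)"
        )
    m = np.linalg.solve(A.T @ A, A.T @ d)
    M = m.reshape(3, 3)
    corrected = corr.measured @ M.T
    residual = float(np.sqrt(np.mean(np.sum((corrected - corr.reference) ** 2, axis=1))))
    return CorrectionModel(M, residual)


def apply_correction(image: np.ndarray, model: CorrectionModel) -> np.ndarray:
    """Apply the Lab correction matrix to every pixel of an 8-bit RGB image."""
    lab = color_spaces.rgb_to_lab(image)
    corrected = lab @ model.matrix.T
    return color_spaces.lab_to_rgb(corrected).astype(np.uint8)


def correct_image(
    image: np.ndarray, layout: CheckerboardLayout | None = None
) -> tuple:
    """Full correction pass: localize board, fit the model, correct the frame.

    Returns ``(corrected_image, model)``.  Raises :class:`LocalizationError`
    when the checkerboard cannot be found.
    """
    layout = layout or CheckerboardLayout()
    corrector = LabColorCorrector(layout=layout).fit(image)
    return corrector.transform(image), corrector.model_


class LabColorCorrector:
    """Estimator fitting the Lab correction matrix from a checkerboard image.

    Follows the scikit-learn estimator protocol: ``fit`` localizes the
    board in a scene and estimates the matrix, ``transform`` corrects
    images.  Fitted attributes carry a trailing underscore.

    Parameters
    ----------
    layout : CheckerboardLayout, optional
        Board geometry and reference colors; the package default when None.
    """

    def __init__(self, layout: CheckerboardLayout | None = None):
        self.layout = layout

    def get_params(self, deep: bool = True) -> dict:
        return {"layout": self.layout}

    def set_params(self, **params) -> "LabColorCorrector":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _resolved_layout(self) -> CheckerboardLayout:
        return self.layout or CheckerboardLayout()

    def fit(self, X, y=None) -> "LabColorCorrector":
        """Fit from a scene image containing the checkerboard.

        ``X`` may be an (H, W, 3) scene or a pre-extracted (24, 3) array of
        measured block RGB means (in which case no localization is run).
        """
        layout = self._resolved_layout()
        X = np.asarray(X)
        if X.ndim == 2 and X.shape == (layout.n_blocks, 3):
            measured_rgb = X.astype(float)
        elif X.ndim == 3:
            markers = detect_markers(X)
            if not markers:
                raise LocalizationError("no fiducial markers detected in the scene")
            h = estimate_roi_homography(markers, layout)
            measured_rgb = extract_block_colors(X, h, layout)
            self.homography_ = h
        else:
            raise DomainError(f"cannot fit from array of shape {X.shape}")
        corr = BlockCorrespondence.from_rgb(measured_rgb, layout.reference_colors)
        self.model_ = estimate_correction(corr)
        self.matrix_ = self.model_.matrix
        self.residual_ = self.model_.residual
        self.measured_rgb_ = measured_rgb
        return self

    def transform(self, X) -> np.ndarray:
        """Correct one image (H, W, 3) or a batch of Lab colors (n, 3)."""
        if not hasattr(self, "model_"):
            raise EstimationError("corrector is not fitted")
        X = np.asarray(X)
        if X.ndim == 2 and X.shape[1] == 3:  # Lab colors
            return X @ self.matrix_.T
        return apply_correction(X, self.model_)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
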