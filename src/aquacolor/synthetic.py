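"""Synthetic pond scenes with exact ground truth.

The renderer emulates the monitored-pond imagery the pipeline consumes:
a dominant water region of a known color code with a smooth spatial
gradient, bright irregular foam blobs, a striped waterwheel rectangle,
and the reference checkerboard (24 colors + 4 corner fiducials) embedded
under a known projective placement.  The whole frame is then passed
through a known invertible Lab distortion and i.i.d. per-channel
Gaussian noise, and an exact per-pixel class mask is emitted alongside.

Everything is deterministic under the scene seed, so every pipeline
stage can be tested against renderer-declared ground truth without any
field data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import ProjectiveTransform, warp

from . import color_spaces
from .checkerboard import CheckerboardLayout, render_board
from .classifier import PaletteConfig
from .errors import SceneSpecError
from .segmentation import (
    LABEL_CHECKERBOARD,
    LABEL_FOAM,
    LABEL_WATER,
    LABEL_WATERWHEEL,
    ClassMask,
    save_mask,
)

__all__ = [
    "SceneSpec",
    "SceneBundle",
    "default_distortion",
    "default_board_placement",
    "render_scene",
    "make_patch_dataset",
    "write_bundle",
]


def default_distortion() -> np.ndarray:
    """A mild invertible Lab distortion emulating a lighting shift.

    Chosen to keep all 24 reference colors inside the RGB gamut so the
    distortion is exactly invertible on the board (clipping would not be).
    """
    return np.array(
        [
            [0.95, 0.015, -0.01],
            [0.01, 0.93, 0.03],
            [-0.015, 0.01, 0.96],
        ]
    )


def default_board_placement(
    width: int, height: int, layout: CheckerboardLayout | None = None
) -> np.ndarray:
    """Canonical-board -> image homography placing the board top-right.

    The board is scaled to roughly a third of the image height and sits in
    the upper third of the frame, clear of the candidate-sampling band.
    """
    layout = layout or CheckerboardLayout()
    x0, y0, x1, _ = layout.board_extent
    size = x1 - x0
    scale = (height // 3 - 10) / size
    tx = width - size * scale - 12 - x0 * scale
    ty = 6 - y0 * scale
    return np.array([[scale, 0, tx], [0, scale, ty], [0, 0, 1]], dtype=float)


@dataclass
class SceneSpec:
    """Ground-truth description of one synthetic pond scene."""

    width: int = 640
    height: int = 480
    water_code: str = "001-003"
    gradient_amplitude: float = 3.0  # Lab units across the frame
    n_foam: int = 3
    foam_radius: int = 12
    foam_color: tuple = (236, 238, 242)
    waterwheel_rect: tuple | None = (40, 180, 150, 280)  # (x0, y0, x1, y1)
    board_homography: np.ndarray | None = None  # canonical -> image; None = default
    include_checkerboard: bool = True
    distortion: np.ndarray = field(default_factory=default_distortion)
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 200 or self.height < 200:
            raise SceneSpecError("scene must be at least 200x200 pixels")
        self.distortion = np.asarray(self.distortion, dtype=float)
        if self.distortion.shape != (3, 3) or abs(np.linalg.det(self.distortion)) < 1e-9:
            raise SceneSpecError("distortion must be an invertible 3x3 matrix")
        if self.board_homography is not None:
            self.board_homography = np.asarray(self.board_homography, dtype=float)

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "water_code": self.water_code,
            "gradient_amplitude": self.gradient_amplitude,
            "n_foam": self.n_foam,
            "foam_radius": self.foam_radius,
            "foam_color": list(self.foam_color),
            "waterwheel_rect": list(self.waterwheel_rect) if self.waterwheel_rect else None,
            "board_homography": self.board_homography.tolist()
            if self.board_homography is not None
            else None,
            "include_checkerboard": self.include_checkerboard,
            "distortion": self.distortion.tolist(),
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        for key in ("foam_color", "waterwheel_rect"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        for key in ("board_homography", "distortion"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass
class SceneBundle:
    """A rendered scene, its exact mask, and the spec that produced it."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: ClassMask
    spec: SceneSpec
    board_homography: np.ndarray  # canonical -> image, as actually used


def _paint_foam(rgb, labels, spec, rng, forbidden):
    """Place non-touching irregular foam blobs inside the lower-band water."""
    h, w = labels.shape
    r = spec.foam_radius
    band_top = h // 3
    centers: list[tuple] = []
    min_sep = 2 * (r + 4)
    attempts = 0
    while len(centers) < spec.n_foam and attempts < 2000:
        attempts += 1
        cx = int(rng.integers(r + 4, w - r - 4))
        cy = int(rng.integers(band_top + r + 4, h - r - 4))
        if forbidden[
            max(cy - r - 4, 0) : cy + r + 5, max(cx - r - 4, 0) : cx + r + 5
        ].any():
            continue
        if any(np.hypot(cx - px, cy - py) < min_sep for px, py in centers):
            continue
        centers.append((cx, cy))
    if len(centers) < spec.n_foam:
        raise SceneSpecError(
            f"could not place {spec.n_foam} foam blobs without overlap"
        )
    color = np.asarray(spec.foam_color, dtype=np.uint8)
    for cx, cy in centers:
        blob = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        for _ in range(5):  # union of jittered disks -> irregular outline
            ox, oy = rng.integers(-r // 2, r // 2 + 1, size=2)
            rr = rng.integers(r // 2, r + 1)
            blob |= (xx - ox) ** 2 + (yy - oy) ** 2 <= rr**2
        blob &= xx**2 + yy**2 <= r**2  # keep within the declared radius
        sl = (slice(cy - r, cy + r + 1), slice(cx - r, cx + r + 1))
        rgb[sl][blob] = color
        labels[sl][blob] = LABEL_FOAM


def render_scene(
    spec: SceneSpec,
    layout: CheckerboardLayout | None = None,
    palette: PaletteConfig | None = None,
) -> SceneBundle:
    """Render a scene and its exact class mask from a spec."""
    layout = layout or CheckerboardLayout()
    palette = palette or PaletteConfig()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # --- water field with a smooth Lab gradient ---------------------------
    base_lab = palette.centroids[spec.water_code]
    theta = rng.uniform(0, 2 * np.pi)
    ux, uy = np.cos(theta), np.sin(theta)
    gx, gy = np.meshgrid(np.linspace(-0.5, 0.5, w), np.linspace(-0.5, 0.5, h))
    g = gx * ux + gy * uy  # in [-~0.7, ~0.7]
    lab = np.empty((h, w, 3))
    lab[..., 0] = base_lab[0] + spec.gradient_amplitude * g
    lab[..., 1] = base_lab[1] + 0.3 * spec.gradient_amplitude * g
    lab[..., 2] = base_lab[2] + 0.3 * spec.gradient_amplitude * g
    rgb = color_spaces.lab_to_rgb(lab).astype(np.uint8)
    labels = np.full((h, w), LABEL_WATER, dtype=np.uint8)

    # --- waterwheel --------------------------------------------------------
    if spec.waterwheel_rect is not None:
        x0, y0, x1, y1 = spec.waterwheel_rect
        stripes = np.where((np.arange(y0, y1)[:, None] // 6) % 2 == 0, 70, 45)
        rgb[y0:y1, x0:x1] = stripes[..., None].astype(np.uint8)
        labels[y0:y1, x0:x1] = LABEL_WATERWHEEL

    # --- checkerboard ------------------------------------------------------
    board_h = (
        spec.board_homography
        if spec.board_homography is not None
        else default_board_placement(w, h, layout)
    )
    if spec.include_checkerboard:
        raster, (bx0, by0) = render_board(layout)
        shift = np.array([[1, 0, bx0], [0, 1, by0], [0, 0, 1]], dtype=float)
        raster_to_image = board_h @ shift  # raster (col,row) -> image (x,y)
        tform = ProjectiveTransform(matrix=np.linalg.inv(raster_to_image))
        warped = warp(
            raster.astype(float),
            inverse_map=tform,
            output_shape=(h, w),
            order=0,
            mode="constant",
            cval=-1.0,
            preserve_range=True,
        )
        footprint = warped[..., 0] >= 0
        if spec.waterwheel_rect is not None and (
            footprint & (labels == LABEL_WATERWHEEL)
        ).any():
            raise SceneSpecError("checkerboard placement overlaps the waterwheel")
        rgb[footprint] = warped[footprint].astype(np.uint8)
        labels[footprint] = LABEL_CHECKERBOARD

    # --- foam --------------------------------------------------------------
    if spec.n_foam > 0:
        forbidden = labels != LABEL_WATER
        _paint_foam(rgb, labels, spec, rng, forbidden)

    # --- global Lab distortion + sensor noise ------------------------------
    lab_all = color_spaces.rgb_to_lab(rgb)
    distorted = color_spaces.lab_to_rgb(lab_all @ spec.distortion.T)
    if spec.noise_sigma > 0:
        distorted = distorted + rng.normal(0, spec.noise_sigma, distorted.shape)
    image = np.clip(np.rint(distorted), 0, 255).astype(np.uint8)

    return SceneBundle(
        image=image, mask=ClassMask(labels), spec=spec, board_homography=board_h
    )


def make_patch_dataset(
    palette: PaletteConfig | None = None,
    n_per_class: int = 200,
    noise_sigma: float = 8.0,
    seed: int = 0,
    patch_side: int = 32,
    gradient_amplitude: float = 3.0,
    out_dir=None,
) -> tuple:
    """Labeled synthetic patches for all 19 color codes.

    Each patch is the class centroid color with a random linear Lab
    gradient plus i.i.d. Gaussian RGB noise, clipped to gamut.  Returns
    ``(patches, labels)`` with ``patches`` of shape (19 * n_per_class, w,
    w, 3) uint8 and ``labels`` the matching full-code strings; when
    ``out_dir`` is given the patches are also written as
    ``<code>/<NNNN>.png``.
    """
    palette = palette or PaletteConfig()
    if n_per_class < 1:
        raise SceneSpecError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    w = patch_side
    gx, gy = np.meshgrid(np.linspace(-0.5, 0.5, w), np.linspace(-0.5, 0.5, w))
    patches, labels = [], []
    for code in sorted(palette.centroids):
        base = palette.centroids[code]
        for _ in range(n_per_class):
            theta = rng.uniform(0, 2 * np.pi)
            g = gx * np.cos(theta) + gy * np.sin(theta)
            amp = rng.uniform(0, gradient_amplitude)
            lab = np.empty((w, w, 3))
            lab[..., 0] = base[0] + amp * g
            lab[..., 1] = base[1] + 0.3 * amp * g
            lab[..., 2] = base[2] + 0.3 * amp * g
            rgb = color_spaces.lab_to_rgb(lab)
            rgb = rgb + rng.normal(0, noise_sigma, rgb.shape)
            patches.append(np.clip(np.rint(rgb), 0, 255).astype(np.uint8))
            labels.append(code)
    patches = np.stack(patches)
    labels = np.array(labels)
    if out_dir is not None:
        out_dir = Path(out_dir)
        counters: dict[str, int] = {}
        for patch, code in zip(patches, labels):
            idx = counters.get(code, 0)
            counters[code] = idx + 1
            class_dir = out_dir / code
            class_dir.mkdir(parents=True, exist_ok=True)
            Image.fromarray(patch).save(class_dir / f"{idx:04d}.png")
    return patches, labels


def write_bundle(bundle: SceneBundle, out_dir, stem: str = "scene") -> dict:
    """Write image PNG, mask PNG and ground-truth JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image_path = out_dir / f"{stem}.png"
    mask_path = out_dir / f"{stem}.mask.png"
    truth_path = out_dir / f"{stem}.truth.json"
    Image.fromarray(bundle.image).save(image_path)
    save_mask(bundle.mask, mask_path)
    truth = bundle.spec.to_dict()
    truth["board_homography_used"] = bundle.board_homography.tolist()
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2)
    return {"image": image_path, "mask": mask_path, "truth": truth_path}
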