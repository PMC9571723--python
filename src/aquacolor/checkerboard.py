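"""Checkerboard geometry, localization and block-color extraction.

The reference board is a 4x6 grid of 24 known colors with a fiducial
marker at each corner.  Detection finds the four markers, a projective
homography maps the image onto the canonical 200x200-pixel region of
interest (ROI), and the mean RGB of the central window of each cell is
read off in row-major reading order.

Canonical board frame
---------------------
Coordinates are in ROI pixels, x right / y down, with the color area
occupying ``[0, 200) x [0, 200)``.  The four markers sit just outside
the ROI corners on the white board margin; their positions per id are
fixed by :class:`CheckerboardLayout` and shared with the synthetic-scene
renderer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from skimage.transform import ProjectiveTransform, estimate_transform, warp

from . import fiducials
from .errors import ExtractionError, LocalizationError
from .fiducials import MarkerDetection, detect_markers  # re-exported

__all__ = [
    "REFERENCE_COLORS_RGB",
    "CheckerboardLayout",
    "Homography",
    "MarkerDetection",
    "detect_markers",
    "estimate_roi_homography",
    "extract_block_colors",
    "render_board",
]

#: The 24 reference colors of the checkerboard, row-major reading order.
REFERENCE_COLORS_RGB = np.array(
    [
        [111, 77, 71], [189, 149, 132], [93, 116, 151], [86, 106, 67],
        [118, 123, 164], [92, 181, 170], [206, 121, 37], [50, 85, 164],
        [172, 75, 85], [88, 62, 103], [164, 201, 100], [212, 149, 55],
        [20, 46, 123], [67, 140, 76], [162, 46, 55], [205, 185, 0],
        [194, 83, 145], [47, 144, 170], [229, 225, 230], [201, 201, 200],
        [158, 161, 162], [118, 119, 123], [83, 86, 90], [55, 58, 54],
    ],
    dtype=float,
)


@dataclass
class Homography:
    """A 3x3 projective transform mapping image -> canonical ROI coordinates."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if not np.all(np.isfinite(self.matrix)) or abs(np.linalg.det(self.matrix)) < 1e-12:
            raise LocalizationError("homography is singular or non-finite")

    def normalized(self) -> np.ndarray:
        """Matrix scaled so the bottom-right entry is 1."""
        return self.matrix / self.matrix[2, 2]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Apply to (n, 2) points in (x, y) order."""
        pts = np.asarray(points, dtype=float)
        homog = np.hstack([pts, np.ones((len(pts), 1))]) @ self.matrix.T
        return homog[:, :2] / homog[:, 2:3]


@dataclass
class CheckerboardLayout:
    """Geometry and reference colors of the board, in the canonical frame."""

    rows: int = 4
    cols: int = 6
    roi_size: int = 200
    marker_ids: tuple = (0, 1, 2, 3)  # top-left, top-right, bottom-right, bottom-left
    marker_side: int = 42
    marker_gap: int = 8
    reference_colors: np.ndarray = field(
        default_factory=lambda: REFERENCE_COLORS_RGB.copy()
    )

    def __post_init__(self):
        self.reference_colors = np.asarray(self.reference_colors, dtype=float)
        if self.reference_colors.shape != (self.rows * self.cols, 3):
            raise ValueError(
                f"expected {self.rows * self.cols} reference colors, "
                f"got {self.reference_colors.shape}"
            )
        if len(self.marker_ids) != 4:
            raise ValueError("layout needs exactly 4 marker ids")

    @property
    def n_blocks(self) -> int:
        return self.rows * self.cols

    def cell_rect(self, index: int) -> tuple:
        """Canonical (x0, y0, x1, y1) bounds of cell ``index`` (row-major)."""
        r, c = divmod(index, self.cols)
        cw = self.roi_size / self.cols
        ch = self.roi_size / self.rows
        return (c * cw, r * ch, (c + 1) * cw, (r + 1) * ch)

    def marker_corner_points(self, marker_id: int) -> np.ndarray:
        """Canonical (4, 2) corner points (TL, TR, BR, BL) of one marker."""
        idx = self.marker_ids.index(marker_id)
        s, g, n = self.marker_side, self.marker_gap, self.roi_size
        anchors = {
            0: (-g - s, -g - s),  # top-left marker's top-left corner
            1: (n + g, -g - s),
            2: (n + g, n + g),
            3: (-g - s, n + g),
        }
        x0, y0 = anchors[idx]
        return np.array(
            [[x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s]], dtype=float
        )

    @property
    def board_extent(self) -> tuple:
        """Canonical (x0, y0, x1, y1) of the full white board."""
        m = self.marker_gap + self.marker_side + self.marker_gap
        return (-m, -m, self.roi_size + m, self.roi_size + m)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "roi_size": self.roi_size,
            "marker_ids": list(self.marker_ids),
            "marker_side": self.marker_side,
            "marker_gap": self.marker_gap,
            "reference_colors": self.reference_colors.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CheckerboardLayout":
        d = dict(d)
        if "marker_ids" in d:
            d["marker_ids"] = tuple(d["marker_ids"])
        if "reference_colors" in d:
            d["reference_colors"] = np.asarray(d["reference_colors"], dtype=float)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "CheckerboardLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def estimate_roi_homography(
    markers: list, layout: CheckerboardLayout
) -> Homography:
    """Least-squares projective homography from marker corners to the ROI frame.

    All corners of every detected marker whose id belongs to the layout are
    used as correspondences (16 points when all four markers are visible;
    a minimum of 4 non-degenerate points is required).
    """
    src, dst = [], []
    for det in markers:
        if det.marker_id in layout.marker_ids:
            src.append(det.corners)
            dst.append(layout.marker_corner_points(det.marker_id))
    if not src:
        raise LocalizationError("no layout markers among the detections")
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    if len(src) < 4:
        raise LocalizationError(f"need >= 4 correspondences, got {len(src)}")
    tform = estimate_transform("projective", src, dst)
    params = np.asarray(tform.params)
    if not np.all(np.isfinite(params)) or abs(np.linalg.det(params)) < 1e-12:
        raise LocalizationError("degenerate marker configuration (collinear points?)")
    # guard against garbage fits: reprojection must be tight
    resid = np.linalg.norm(tform(src) - dst, axis=1)
    if np.max(resid) > 0.1 * layout.roi_size:
        raise LocalizationError(
            f"homography reprojection error too large (max {np.max(resid):.1f} px)"
        )
    return Homography(params)


def extract_block_colors(
    image: np.ndarray, h: Homography, layout: CheckerboardLayout
) -> np.ndarray:
    """Warp the ROI to canonical size and return the 24 cell mean colors.

    Each cell is sampled on its central 50% x 50% window to avoid bleed at
    cell borders.  Returns an ``(n_blocks, 3)`` float array of mean RGB in
    the layout's row-major reading order.
    """
    image = np.asarray(image, dtype=float)
    inv = ProjectiveTransform(matrix=np.linalg.inv(h.normalized()))
    roi = warp(
        image,
        inverse_map=inv,
        output_shape=(layout.roi_size, layout.roi_size),
        order=1,
        mode="edge",
        preserve_range=True,
    )
    means = np.empty((layout.n_blocks, 3), dtype=float)
    for i in range(layout.n_blocks):
        x0, y0, x1, y1 = layout.cell_rect(i)
        # central 50% window
        cx0 = int(round(x0 + 0.25 * (x1 - x0)))
        cx1 = int(round(x1 - 0.25 * (x1 - x0)))
        cy0 = int(round(y0 + 0.25 * (y1 - y0)))
        cy1 = int(round(y1 - 0.25 * (y1 - y0)))
        window = roi[cy0:cy1, cx0:cx1]
        if window.size == 0:
            raise ExtractionError(f"empty sampling window for cell {i}")
        means[i] = window.reshape(-1, 3).mean(axis=0)
    return means


def render_board(
    layout: CheckerboardLayout | None = None,
    dictionary: fiducials.FiducialDictionary | None = None,
) -> tuple:
    """Rasterize the canonical board.

    Returns ``(raster, origin)`` where ``raster`` is an (S, S, 3) uint8
    image and ``origin`` is the canonical (x, y) of its top-left pixel, so
    canonical point (x, y) maps to raster pixel (y - origin[1], x - origin[0]).
    """
    layout = layout or CheckerboardLayout()
    dictionary = dictionary or fiducials.default_dictionary()
    x0, y0, x1, y1 = layout.board_extent
    size = int(round(x1 - x0))
    raster = np.full((size, size, 3), 255, dtype=np.uint8)

    def paint(rect, colors):
        rx0, ry0, rx1, ry1 = rect
        raster[
            int(round(ry0 - y0)) : int(round(ry1 - y0)),
            int(round(rx0 - x0)) : int(round(rx1 - x0)),
        ] = colors

    for i in range(layout.n_blocks):
        paint(layout.cell_rect(i), layout.reference_colors[i].astype(np.uint8))
    if layout.marker_side % fiducials.MODULES != 0:
        raise ValueError("marker_side must be divisible by the module count")
    scale = layout.marker_side // fiducials.MODULES
    for mid in layout.marker_ids:
        bitmap = fiducials.render_marker(mid, dictionary)
        tile = np.kron(bitmap, np.ones((scale, scale), dtype=np.uint8))
        corners = layout.marker_corner_points(mid)
        mx, my = corners[0]
        r0, c0 = int(round(my - y0)), int(round(mx - x0))
        raster[r0 : r0 + tile.shape[0], c0 : c0 + tile.shape[1]] = tile[..., None]
    return raster, (x0, y0)
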