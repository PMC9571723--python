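"""Square binary fiducial markers for checkerboard localization.

The board corners carry ArUco-style markers: a 6x6-module square whose
border modules are black and whose inner 4x4 modules encode the marker
id.  The dictionary holds 50 ids and is generated deterministically so
that every code is at Hamming distance >= 4 from every rotation of every
other code, and >= 4 from its own non-trivial rotations (orientation is
therefore unambiguous).

Detection is contour-based: dark regions of plausible size are fitted
with a quadrilateral, the 36 module centers are sampled through a
projective transform, the border is checked, and the inner bits are
matched against the dictionary in all four rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.transform import ProjectiveTransform

__all__ = [
    "GRID_BITS",
    "MODULES",
    "FiducialDictionary",
    "MarkerDetection",
    "default_dictionary",
    "render_marker",
    "decode_marker",
    "detect_markers",
]

#: Inner payload grid (bits per side).
GRID_BITS = 4
#: Full marker side in modules (payload + one-module black border).
MODULES = GRID_BITS + 2

_DICTIONARY_SEED = 20220920
_MIN_HAMMING = 4
_DICTIONARY_SIZE = 50


def _rotations(bits: np.ndarray):
    return [np.rot90(bits, r) for r in range(4)]


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


@dataclass(frozen=True)
class FiducialDictionary:
    """A fixed set of rotation-distinct 4x4 marker codes."""

    codes: tuple  # tuple of (4, 4) bool ndarrays, index == marker id

    def __len__(self) -> int:
        return len(self.codes)

    def match(self, bits: np.ndarray, max_hamming: int = 0):
        """Match observed payload bits against the dictionary.

        Returns ``(marker_id, rotation)`` where ``rotation`` is the number
        of counter-clockwise quarter turns bringing the observed bits onto
        the canonical code, or ``None`` if nothing matches within
        ``max_hamming``.
        """
        best = None
        for marker_id, code in enumerate(self.codes):
            for r in range(4):
                d = _hamming(np.rot90(bits, r), code)
                if d <= max_hamming and (best is None or d < best[2]):
                    best = (marker_id, r, d)
        if best is None:
            return None
        return best[0], best[1]


def _generate_codes(n: int, seed: int, min_hamming: int) -> tuple:
    rng = np.random.default_rng(seed)
    codes: list[np.ndarray] = []
    while len(codes) < n:
        cand = rng.integers(0, 2, size=(GRID_BITS, GRID_BITS)).astype(bool)
        # orientation must be unambiguous
        if any(_hamming(cand, np.rot90(cand, r)) < min_hamming for r in (1, 2, 3)):
            continue
        ok = True
        for code in codes:
            if min(_hamming(rot, code) for rot in _rotations(cand)) < min_hamming:
                ok = False
                break
        if ok:
            codes.append(cand)
    return tuple(codes)


_DEFAULT_DICT: FiducialDictionary | None = None


def default_dictionary() -> FiducialDictionary:
    """The package's standard 4x4, 50-id dictionary (deterministic)."""
    global _DEFAULT_DICT
    if _DEFAULT_DICT is None:
        _DEFAULT_DICT = FiducialDictionary(
            _generate_codes(_DICTIONARY_SIZE, _DICTIONARY_SEED, _MIN_HAMMING)
        )
    return _DEFAULT_DICT


def render_marker(marker_id: int, dictionary: FiducialDictionary | None = None) -> np.ndarray:
    """Render a marker as a (MODULES, MODULES) uint8 bitmap (0 black, 255 white)."""
    dictionary = dictionary or default_dictionary()
    bitmap = np.zeros((MODULES, MODULES), dtype=np.uint8)
    bitmap[1:-1, 1:-1] = dictionary.codes[marker_id].astype(np.uint8) * 255
    return bitmap


@dataclass
class MarkerDetection:
    """One detected fiducial marker.

    ``corners`` are image coordinates (x right, y down), ordered to match
    the canonical bitmap: top-left, top-right, bottom-right, bottom-left
    of the *unrotated* marker.
    """

    marker_id: int
    corners: np.ndarray = field(repr=False)  # (4, 2) float

    def __post_init__(self):
        self.corners = np.asarray(self.corners, dtype=float)
        if self.corners.shape != (4, 2):
            raise ValueError("corners must have shape (4, 2)")
        # non-collinearity: the quad must span a non-degenerate area
        x, y = self.corners[:, 0], self.corners[:, 1]
        area = 0.5 * abs(
            np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
        )
        if area < 1e-9:
            raise ValueError("marker corners are collinear")

    @property
    def center(self) -> np.ndarray:
        return self.corners.mean(axis=0)


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image @ np.array([0.299, 0.587, 0.114])
    return image


def _refine_quad(contour_xy: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Refine quad corners by fitting a line to each contour edge and
    intersecting adjacent lines (subpixel; robust to rounded corners)."""
    lines = []
    for k in range(4):
        a, b = quad[k], quad[(k + 1) % 4]
        ab = b - a
        length = np.linalg.norm(ab)
        if length < 4:
            return quad
        u = ab / length
        t = (contour_xy - a) @ u
        proj = a + t[:, None] * u
        d = np.linalg.norm(contour_xy - proj, axis=1)
        sel = (t > 0.15 * length) & (t < 0.85 * length) & (d < 2.5)
        pts = contour_xy[sel]
        if len(pts) < 4:
            return quad
        mean = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
        lines.append((mean, vt[0]))
    refined = np.empty((4, 2))
    for k in range(4):
        (p1, d1), (p2, d2) = lines[(k - 1) % 4], lines[k]
        A = np.stack([d1, -d2], axis=1)
        if abs(np.linalg.det(A)) < 1e-9:
            return quad
        t = np.linalg.solve(A, p2 - p1)
        refined[k] = p1 + t[0] * d1
    if np.max(np.linalg.norm(refined - quad, axis=1)) > 3:
        return quad  # refinement diverged; keep the coarse corners
    return refined


def _quad_from_region(region_mask: np.ndarray, origin: tuple) -> np.ndarray | None:
    """Fit a convex quadrilateral to a binary region; None if not quad-like."""
    padded = np.pad(region_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    if not np.allclose(contour[0], contour[-1]):
        return None
    perimeter = np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1))
    quad = None
    for rel_tol in (0.02, 0.04, 0.08):
        poly = measure.approximate_polygon(contour, tolerance=rel_tol * perimeter)
        if not np.allclose(poly[0], poly[-1]):
            continue
        verts = poly[:-1]
        # the arbitrary contour start point is always retained by the
        # simplifier; strip near-collinear vertices it leaves behind
        while len(verts) > 4:
            devs = []
            for k in range(len(verts)):
                a, b, c = verts[k - 1], verts[k], verts[(k + 1) % len(verts)]
                ab = c - a
                norm = np.linalg.norm(ab)
                cross = ab[0] * (b - a)[1] - ab[1] * (b - a)[0]
                devs.append(abs(cross) / norm if norm > 1e-9 else 0.0)
            k = int(np.argmin(devs))
            if devs[k] > max(2.0, rel_tol * perimeter):
                break
            verts = np.delete(verts, k, axis=0)
        if len(verts) == 4:
            quad = verts
            break
    if quad is None:
        return None
    # (row, col) in padded crop -> (x, y) in image
    def to_xy(rc):
        return np.stack(
            [rc[:, 1] - 1 + origin[1], rc[:, 0] - 1 + origin[0]], axis=1
        )

    xy = _refine_quad(to_xy(contour[:-1]), to_xy(quad))
    # convexity: all cross products of consecutive edges share a sign
    edges = np.roll(xy, -1, axis=0) - xy
    nxt = np.roll(edges, -1, axis=0)
    cross = edges[:, 0] * nxt[:, 1] - edges[:, 1] * nxt[:, 0]
    if not (np.all(cross > 0) or np.all(cross < 0)):
        return None
    # canonical winding: positive shoelace (clockwise on screen, y down)
    x, y = xy[:, 0], xy[:, 1]
    if np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y) < 0:
        xy = xy[::-1]
    return xy


def decode_marker(
    gray: np.ndarray,
    quad: np.ndarray,
    dictionary: FiducialDictionary,
    max_hamming: int = 1,
) -> MarkerDetection | None:
    """Sample a candidate quad's module grid and match it to the dictionary."""
    src = np.array([[0, 0], [MODULES, 0], [MODULES, MODULES], [0, MODULES]], dtype=float)
    from skimage.transform import estimate_transform

    tform = estimate_transform("projective", src, np.asarray(quad, dtype=float))
    if not np.all(np.isfinite(np.asarray(tform.params))):
        return None
    # oversample the whole marker, then majority-vote each module's center;
    # a small grid-offset search absorbs sub-module quad inaccuracy at low
    # marker resolutions
    sub = 10
    n = MODULES * sub
    u = (np.arange(n) + 0.5) / sub  # module coordinates of subpixel centers
    border_mask = np.zeros((MODULES, MODULES), dtype=bool)
    border_mask[[0, -1]] = True
    border_mask[:, [0, -1]] = True
    best = None
    for dy in (-0.2, 0.0, 0.2):
        for dx in (-0.2, 0.0, 0.2):
            rows, cols = np.meshgrid(u + dy, u + dx, indexing="ij")
            centers = np.stack([rows, cols], axis=-1).reshape(-1, 2)
            pts = tform(centers[:, ::-1])  # transform expects (x, y)
            patch = ndimage.map_coordinates(
                gray, [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
            ).reshape(n, n)
            lo, hi = patch.min(), patch.max()
            if hi - lo < 30:  # not enough contrast to be a marker
                continue
            fine = patch > (lo + hi) / 2.0
            frac = fine.reshape(MODULES, sub, MODULES, sub)[
                :, 2:-2, :, 2:-2
            ].mean(axis=(1, 3))
            border_dark = 1.0 - frac[border_mask].mean()
            if best is None or border_dark > best[0]:
                best = (border_dark, frac)
    if best is None:
        return None
    frac = best[1]
    bits = frac > 0.5
    border = bits[border_mask]
    if np.count_nonzero(border) > 2:  # tolerate slight edge undersampling
        return None
    matched = dictionary.match(bits[1:-1, 1:-1], max_hamming=max_hamming)
    if matched is None:
        return None
    marker_id, rotation = matched
    # observed bitmap == canonical rotated clockwise by `rotation` quarter
    # turns, so canonical corner j sits at observed position (j + rotation) % 4
    corners = np.asarray(quad, dtype=float)[(np.arange(4) + rotation) % 4]
    return MarkerDetection(marker_id=marker_id, corners=corners)


def detect_markers(
    image: np.ndarray,
    dictionary: FiducialDictionary | None = None,
    max_hamming: int = 1,
    min_area: int = 64,
    max_area: int = 40000,
) -> list[MarkerDetection]:
    """Detect fiducial markers in an 8-bit RGB (or grayscale) image.

    Returns detections sorted by marker id; an empty list is a valid
    result (e.g. a blank image).
    """
    dictionary = dictionary or default_dictionary()
    gray = _to_gray(image)
    if gray.max() - gray.min() < 1e-9:
        return []
    from skimage.filters import threshold_otsu

    dark = gray < threshold_otsu(gray)
    if not dark.any():
        return []
    labels, n = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
    detections = []
    for region in ndimage.find_objects(labels):
        if region is None:
            continue
        h = region[0].stop - region[0].start
        w = region[1].stop - region[1].start
        if min(h, w) < 8 or h * w < min_area or h * w > 4 * max_area:
            continue
        region_mask = labels[region] == labels[region][h // 2, w // 2]
        # the centre pixel may be a hole; use any label present instead
        vals = labels[region][dark[region]]
        lab = np.bincount(vals).argmax()
        region_mask = labels[region] == lab
        area = int(region_mask.sum())
        if area < min_area or area > max_area:
            continue
        quad = _quad_from_region(region_mask, (region[0].start, region[1].start))
        if quad is None:
            continue
        det = decode_marker(gray, quad, dictionary, max_hamming=max_hamming)
        if det is not None:
            detections.append(det)
    # deduplicate by id keeping the largest quad (nested contours etc.)
    by_id: dict[int, MarkerDetection] = {}
    for det in detections:
        prev = by_id.get(det.marker_id)
        if prev is None:
            by_id[det.marker_id] = det
    return [by_id[k] for k in sorted(by_id)]
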