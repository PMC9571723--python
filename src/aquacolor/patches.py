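"""Random sampling and fuzzy scoring of water-only candidate patches.

Square w x w patches are drawn uniformly in the lower two-thirds of the
(color-corrected) frame — the upper third is skipped because distant
water is routinely contaminated by reflection.  Each patch is scored by
the fuzzy system on two features: its minimum Euclidean distance to any
foam contour (p1) and the standard deviation of its gray levels (p2).
Patches whose crisp degree exceeds the threshold are collected until N
candidates exist; the N1 highest-degree candidates go on to color
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import CandidateExhaustedError, DomainError
from .fuzzy import FISConfig, RuleBase, fis_degree
from .segmentation import LABEL_FOAM, LABEL_WATER, ClassMask, foam_components

__all__ = [
    "ExtractionConfig",
    "CandidatePatch",
    "rgb_to_gray",
    "patch_stats",
    "min_foam_distance",
    "band_diagonal",
    "extract_candidates",
    "rank_candidates",
]

#: ITU-R BT.601 luma weights used for the intensity feature.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ExtractionConfig:
    """Sampling parameters of the candidate-extraction loop.

    ``n_candidates`` (N) patches are collected, of which the top
    ``n_selected`` (N1) by degree are kept; a patch is accepted when its
    degree exceeds ``threshold`` (T).  The patch side w defaults to one
    twentieth of the image width.  ``max_attempts`` caps the sampling loop
    (the acceptance loop alone would not terminate on hopeless scenes).
    """

    n_candidates: int = 11
    n_selected: int = 5
    threshold: float = 0.5
    patch_side: int | None = None  # None -> image width // 20
    seed: int | None = None
    max_attempts: int | None = None  # None -> 1000 * n_candidates

    def __post_init__(self):
        if not (0 < self.n_selected <= self.n_candidates):
            raise DomainError("need 0 < n_selected <= n_candidates")
        if not (0 < self.threshold < 1):
            raise DomainError("threshold must be inside (0, 1)")
        if self.patch_side is not None and self.patch_side < 4:
            raise DomainError("patch side must be at least 4 pixels")

    def resolved_patch_side(self, image_width: int) -> int:
        w = self.patch_side if self.patch_side is not None else image_width // 20
        if w < 4:
            raise DomainError(f"patch side {w} too small (image width {image_width})")
        return w


@dataclass
class CandidatePatch:
    """A sampled w x w crop with its antecedents and crisp degree."""

    rect: tuple  # (x1, y1, x2, y2), 0-based half-open
    side: int
    p1: float  # min distance to foam contours, pixels
    p2: float  # intensity standard deviation, gray levels
    q: float  # crisp FIS degree in [0, 1]
    order: int = 0  # sampling order, used for deterministic tie-breaks

    def to_dict(self) -> dict:
        return {
            "rect": [int(v) for v in self.rect],
            "side": int(self.side),
            "p1": float(self.p1),
            "p2": float(self.p2),
            "q": float(self.q),
            "order": int(self.order),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CandidatePatch":
        return cls(
            rect=tuple(d["rect"]), side=d["side"], p1=d["p1"], p2=d["p2"],
            q=d["q"], order=d.get("order", 0),
        )


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """BT.601 luma, rounded to integer gray levels."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return np.rint(image)
    return np.rint(image @ _LUMA)


def patch_stats(gray_patch: np.ndarray) -> tuple:
    """Mean and population standard deviation of a gray patch's intensities."""
    gray_patch = np.asarray(gray_patch, dtype=float)
    if gray_patch.size == 0:
        raise DomainError("patch is empty")
    mu = float(gray_patch.mean())
    sigma = float(np.sqrt(np.mean(gray_patch**2) - mu**2))
    return mu, sigma


def band_diagonal(width: int, height: int) -> float:
    """L1: diagonal length of the lower two-thirds band of the image."""
    return float(np.hypot(width, height - height // 3))


def _border_pixels(rect: tuple) -> tuple:
    """(rows, cols) index arrays of the boundary pixels of a half-open rect."""
    x1, y1, x2, y2 = rect
    xs = np.arange(x1, x2)
    ys = np.arange(y1, y2)
    top = np.stack([np.full_like(xs, y1), xs], axis=1)
    bottom = np.stack([np.full_like(xs, y2 - 1), xs], axis=1)
    left = np.stack([ys[1:-1], np.full_like(ys[1:-1], x1)], axis=1)
    right = np.stack([ys[1:-1], np.full_like(ys[1:-1], x2 - 1)], axis=1)
    border = np.concatenate([top, bottom, left, right])
    return border[:, 0], border[:, 1]


def min_foam_distance(
    rect: tuple,
    foam: list | np.ndarray,
    l1: float,
    distance_map: np.ndarray | None = None,
) -> float:
    """Minimum Euclidean distance from a patch to any foam contour.

    ``foam`` is either the list of :class:`FoamComponent` or a boolean foam
    mask.  The distance is measured from the patch boundary pixels to the
    foam contour pixels (a set-to-set distance); a patch overlapping foam
    is at distance 0, and a scene with no foam yields the maximal value
    ``l1``.  ``distance_map`` may carry a precomputed Euclidean distance
    transform of the foam mask to avoid recomputation in sampling loops.
    """
    x1, y1, x2, y2 = (int(v) for v in rect)
    if distance_map is None:
        if isinstance(foam, np.ndarray):
            foam_mask = foam.astype(bool)
        else:
            if not foam:
                return float(l1)
            shape_r = max(int(c.pixels[:, 0].max()) for c in foam) + 1
            shape_c = max(int(c.pixels[:, 1].max()) for c in foam) + 1
            shape_r = max(shape_r, y2)
            shape_c = max(shape_c, x2)
            foam_mask = np.zeros((shape_r, shape_c), dtype=bool)
            for comp in foam:
                foam_mask[comp.pixels[:, 0], comp.pixels[:, 1]] = True
        if not foam_mask.any():
            return float(l1)
        distance_map = ndimage.distance_transform_edt(~foam_mask)
    if np.any(distance_map[y1:y2, x1:x2] == 0):
        return 0.0
    rows, cols = _border_pixels((x1, y1, x2, y2))
    d = float(distance_map[rows, cols].min())
    return float(np.clip(d, 0.0, l1))


def extract_candidates(
    image: np.ndarray,
    mask: ClassMask,
    cfg: ExtractionConfig | None = None,
    fis_cfg: FISConfig | None = None,
    rules: RuleBase | None = None,
    rng: np.random.Generator | None = None,
) -> list:
    """Collect N water-only candidate patches from the lower two-thirds.

    Patch centers are drawn uniformly with w/2 margins inside the lower
    two-thirds band.  A draw is rejected outright if the crop contains any
    non-water label (foam, waterwheel, checkerboard or background), and
    otherwise accepted when its fuzzy degree exceeds the threshold.

    Raises
    ------
    CandidateExhaustedError
        If ``max_attempts`` draws fail to produce N candidates.
    """
    cfg = cfg or ExtractionConfig()
    fis_cfg = fis_cfg or FISConfig()
    rules = rules or RuleBase()
    image = np.asarray(image)
    if image.shape[:2] != mask.shape:
        raise DomainError("image and mask shapes differ")
    height, width = mask.shape
    w = cfg.resolved_patch_side(width)
    half = w // 2
    l1 = band_diagonal(width, height)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    gray = rgb_to_gray(image)
    foam_mask = mask.labels == LABEL_FOAM
    distance_map = (
        ndimage.distance_transform_edt(~foam_mask) if foam_mask.any() else None
    )
    water = mask.labels == LABEL_WATER

    x_lo, x_hi = half, width - half  # inclusive bounds for the center
    y_lo, y_hi = height // 3 + half, height - half
    if x_lo > x_hi or y_lo > y_hi:
        raise DomainError("image too small for the requested patch side")

    max_attempts = cfg.max_attempts or 1000 * cfg.n_candidates
    candidates: list[CandidatePatch] = []
    best_q = 0.0
    attempts = 0
    while len(candidates) < cfg.n_candidates:
        if attempts >= max_attempts:
            raise CandidateExhaustedError(
                f"collected {len(candidates)}/{cfg.n_candidates} candidates "
                f"after {attempts} attempts (best degree {best_q:.3f})",
                attempts=attempts,
                best_q=best_q,
            )
        attempts += 1
        x = int(rng.integers(x_lo, x_hi + 1))
        y = int(rng.integers(y_lo, y_hi + 1))
        x1, y1 = x - half, y - half
        x2, y2 = x1 + w, y1 + w
        if not np.all(water[y1:y2, x1:x2]):
            continue
        if distance_map is None:
            p1 = l1
        else:
            p1 = min_foam_distance((x1, y1, x2, y2), foam_mask, l1, distance_map)
        _, p2 = patch_stats(gray[y1:y2, x1:x2])
        q = fis_degree(p1, p2, fis_cfg, rules)
        best_q = max(best_q, q)
        if q > cfg.threshold:
            candidates.append(
                CandidatePatch(
                    rect=(x1, y1, x2, y2), side=w, p1=p1, p2=p2, q=q,
                    order=len(candidates),
                )
            )
    return candidates


def rank_candidates(candidates: list, n_selected: int) -> list:
    """Top ``n_selected`` candidates by degree.

    Sorted by descending q; ties broken by larger p1, then by sampling
    order (first-sampled wins).
    """
    if len(candidates) < n_selected:
        raise DomainError(
            f"need at least {n_selected} candidates, got {len(candidates)}"
        )
    ranked = sorted(candidates, key=lambda c: (-c.q, -c.p1, c.order))
    return ranked[:n_selected]
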