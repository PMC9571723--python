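"""Patch statistics, foam distances and the candidate-sampling loop."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from aquacolor import patches as pat
from aquacolor import segmentation as seg
from aquacolor.errors import CandidateExhaustedError, DomainError


def test_constant_patch_has_zero_deviation():
    mu, sigma = pat.patch_stats(np.full((8, 8), 77.0))
    assert mu == 77.0
    assert sigma == 0.0


def test_two_by_two_patch_closed_form():
    mu, sigma = pat.patch_stats(np.array([[0.0, 0.0], [255.0, 255.0]]))
    assert mu == 127.5
    assert sigma == 127.5


def test_population_deviation_matches_two_pass_oracle():
    rng = np.random.default_rng(0)
    patch = rng.uniform(0, 255, (13, 13))
    mu, sigma = pat.patch_stats(patch)
    mu_o = patch.sum() / patch.size
    sigma_o = np.sqrt(((patch - mu_o) ** 2).sum() / patch.size)  # divisor n
    assert mu == pytest.approx(mu_o, abs=1e-9)
    assert sigma == pytest.approx(sigma_o, abs=1e-9)


def test_empty_patch_rejected():
    with pytest.raises(DomainError):
        pat.patch_stats(np.empty((0, 0)))


class TestFoamDistance:
    def _mask(self, shape, foam_pixels):
        labels = np.full(shape, seg.LABEL_WATER, dtype=np.uint8)
        for r, c in foam_pixels:
            labels[r, c] = seg.LABEL_FOAM
        return seg.ClassMask(labels)

    def test_no_foam_returns_band_diagonal(self):
        assert pat.min_foam_distance((10, 10, 20, 20), [], l1=500.0) == 500.0

    def test_overlapping_patch_is_at_distance_zero(self):
        mask = self._mask((64, 64), [(30, 30)])
        foam = mask.labels == seg.LABEL_FOAM
        assert pat.min_foam_distance((25, 25, 35, 35), foam, 500.0) == 0.0

    def test_single_pixel_foam_diagonal_distance(self):
        """Foam pixel at (100, 100), nearest patch corner at (90, 90):
        the distance is sqrt(200)."""
        mask = self._mask((128, 128), [(100, 100)])
        d = pat.min_foam_distance(
            (80, 80, 91, 91), mask.labels == seg.LABEL_FOAM, 500.0
        )
        assert d == pytest.approx(np.sqrt(200.0), abs=1e-9)

    def test_distance_clamped_to_band_diagonal(self):
        mask = self._mask((128, 128), [(100, 100)])
        d = pat.min_foam_distance((0, 0, 10, 10), mask.labels == seg.LABEL_FOAM, 50.0)
        assert d == 50.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        """Distance-transform path equals brute-force min over all
        (border pixel, contour pixel) pairs."""
        rng = np.random.default_rng(seed)
        labels = np.where(
            rng.random((64, 64)) < 0.03, seg.LABEL_FOAM, seg.LABEL_WATER
        ).astype(np.uint8)
        mask = seg.ClassMask(labels)
        comps = seg.foam_components(mask)
        if not comps:
            pytest.skip("random draw produced no foam")
        rect = (5, 40, 17, 52)
        d = pat.min_foam_distance(rect, mask.labels == seg.LABEL_FOAM, 500.0)
        rows, cols = pat._border_pixels(rect)
        border = np.stack([rows, cols], axis=1)
        contour = np.concatenate([c.contour for c in comps])
        overlap = np.any(labels[rect[1]:rect[3], rect[0]:rect[2]] == seg.LABEL_FOAM)
        oracle = 0.0 if overlap else cdist(border, contour).min()
        assert d == pytest.approx(min(oracle, 500.0), abs=1e-9)


def _water_scene(h=240, w=320, foam_rects=()):
    rng = np.random.default_rng(99)
    image = np.clip(
        rng.normal(120, 4, (h, w, 3)), 0, 255
    ).astype(np.uint8)
    labels = np.full((h, w), seg.LABEL_WATER, dtype=np.uint8)
    for (r0, c0, r1, c1) in foam_rects:
        labels[r0:r1, c0:c1] = seg.LABEL_FOAM
        image[r0:r1, c0:c1] = 240
    return image, seg.ClassMask(labels)


class TestExtraction:
    def test_collects_default_n_candidates(self):
        image, mask = _water_scene()
        cands = pat.extract_candidates(image, mask, rng=np.random.default_rng(0))
        assert len(cands) == 11
        assert all(0 <= c.q <= 1 for c in cands)
        assert all(c.q > 0.5 for c in cands)

    def test_rects_confined_to_lower_two_thirds(self):
        image, mask = _water_scene()
        h, w = mask.shape
        cfg = pat.ExtractionConfig(seed=3)
        cands = pat.extract_candidates(image, mask, cfg)
        side = cfg.resolved_patch_side(w)
        for c in cands:
            x1, y1, x2, y2 = c.rect
            assert x2 - x1 == side and y2 - y1 == side
            assert 0 <= x1 and x2 <= w
            assert y1 >= h // 3 and y2 <= h

    def test_all_foam_scene_exhausts(self):
        image, mask = _water_scene(foam_rects=[(0, 0, 240, 320)])
        with pytest.raises(CandidateExhaustedError) as err:
            pat.extract_candidates(
                image, mask, pat.ExtractionConfig(max_attempts=200),
                rng=np.random.default_rng(0),
            )
        assert err.value.attempts == 200

    def test_candidates_avoid_non_water_regions(self):
        image, mask = _water_scene(foam_rects=[(120, 100, 170, 160)])
        cands = pat.extract_candidates(image, mask, rng=np.random.default_rng(1))
        foam = mask.labels == seg.LABEL_FOAM
        for c in cands:
            x1, y1, x2, y2 = c.rect
            assert not foam[y1:y2, x1:x2].any()
            assert c.p1 > 0

    def test_deterministic_under_seed(self):
        image, mask = _water_scene()
        a = pat.extract_candidates(image, mask, pat.ExtractionConfig(seed=5))
        b = pat.extract_candidates(image, mask, pat.ExtractionConfig(seed=5))
        assert [c.to_dict() for c in a] == [c.to_dict() for c in b]


class TestRanking:
    def _cand(self, q, p1=10.0, order=0):
        return pat.CandidatePatch(
            rect=(0, 0, 4, 4), side=4, p1=p1, p2=1.0, q=q, order=order
        )

    def test_returns_top_five_of_eleven(self):
        cands = [self._cand(q=i / 11, order=i) for i in range(11)]
        top = pat.rank_candidates(cands, 5)
        assert [c.q for c in top] == sorted(
            (c.q for c in cands), reverse=True
        )[:5]

    def test_equal_degrees_preserve_sampling_order(self):
        cands = [self._cand(q=0.7, order=i) for i in range(6)]
        top = pat.rank_candidates(cands, 3)
        assert [c.order for c in top] == [0, 1, 2]

    def test_degree_ties_break_on_larger_foam_distance(self):
        cands = [
            self._cand(q=0.7, p1=5.0, order=0),
            self._cand(q=0.7, p1=50.0, order=1),
        ]
        assert pat.rank_candidates(cands, 1)[0].p1 == 50.0

    def test_too_few_candidates_rejected(self):
        with pytest.raises(DomainError):
            pat.rank_candidates([self._cand(0.9)], 2)
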