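"""Color-code scheme, nearest-centroid classification and voting."""

import numpy as np
import pytest

from aquacolor import classifier as clf
from aquacolor import color_spaces as cs
from aquacolor.errors import DomainError


def _patch_from_lab(lab, side=8):
    rgb = cs.lab_to_rgb(np.asarray(lab, dtype=float))
    return np.tile(rgb.astype(np.uint8), (side, side, 1))


def test_scheme_has_19_codes_in_six_major_colors():
    assert len(clf.WATER_COLOR_CODES) == 19
    majors = {c.major_code for c in clf.WATER_COLOR_CODES}
    assert majors == {"001", "002", "003", "004", "005", "006"}
    assert clf.code_from_string("001-002").name == "Dark green"
    with pytest.raises(DomainError):
        clf.code_from_string("009-001")


def test_default_palette_centroids_well_separated(palette):
    assert len(palette.centroids) == 19
    assert palette.min_pairwise_distance() > 5.0


def test_palette_yaml_round_trip(tmp_path, palette):
    path = tmp_path / "palette.yaml"
    palette.to_yaml(path)
    loaded = clf.PaletteConfig.from_yaml(path)
    for code, lab in palette.centroids.items():
        assert np.allclose(loaded.centroids[code], lab)


def test_centroid_colored_patch_classified_as_its_code(palette):
    for code in ("001-003", "004-001", "005-002"):
        out = clf.classify_nearest(_patch_from_lab(palette.centroids[code]), palette)
        assert out.predicted.full_code == code
        assert out.confidence == out.probabilities.max()


def test_probabilities_sum_to_one_and_match_softmax(palette):
    out = clf.classify_nearest(_patch_from_lab([60, 10, 10]), palette)
    assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(out.probabilities >= 0)


def test_equidistant_patch_splits_probability(palette):
    """A sample midway between two centroids gets equal probabilities."""
    c = palette.centroid_matrix()
    mid = (c[0] + c[1]) / 2
    model = clf.NearestCentroidWaterColorClassifier(palette).fit()
    lab = mid
    dist = np.linalg.norm(model.centroids_ - lab, axis=1)
    probs = np.exp(-dist + dist.min())
    probs /= probs.sum()
    assert probs[0] == pytest.approx(probs[1], abs=1e-9)


def test_far_from_every_centroid_is_unknown(palette):
    out = clf.classify_nearest(_patch_from_lab([99.0, 120.0, -120.0]), palette)
    assert out.predicted is clf.UNKNOWN


def test_perfect_separability_on_noise_free_patches(palette):
    model = clf.NearestCentroidWaterColorClassifier(palette).fit()
    patches = [
        _patch_from_lab(palette.centroids[c.full_code])
        for c in clf.WATER_COLOR_CODES
    ]
    labels = [c.full_code for c in clf.WATER_COLOR_CODES]
    assert model.score(patches, labels) == 1.0


def test_fit_on_labeled_patches_recovers_shifted_centroids(palette):
    """Training data systematically shifted from the palette moves the
    fitted centroids to the data."""
    rng = np.random.default_rng(0)
    X, y = [], []
    shift = np.array([3.0, -2.0, 1.0])
    for c in clf.WATER_COLOR_CODES:
        for _ in range(5):
            lab = palette.centroids[c.full_code] + shift + rng.normal(0, 0.1, 3)
            X.append(_patch_from_lab(lab))
            y.append(c.full_code)
    model = clf.NearestCentroidWaterColorClassifier(palette).fit(X, y)
    moved = model.centroids_ - palette.centroid_matrix()
    assert np.allclose(moved, shift, atol=1.0)
    assert model.score(X, y) == 1.0


def test_fit_rejects_labels_outside_scheme():
    with pytest.raises(DomainError):
        clf.NearestCentroidWaterColorClassifier().fit(
            [np.zeros((4, 4, 3))], ["007-001"]
        )


class TestRepresentativeColor:
    def _out(self, code, confidence=0.9):
        probs = np.full(19, (1 - confidence) / 18)
        idx = [c.full_code for c in clf.WATER_COLOR_CODES].index(code)
        probs[idx] = confidence
        return clf.ClassifierOutput(
            probabilities=probs,
            predicted=clf.WATER_COLOR_CODES[idx],
            confidence=confidence,
        )

    def test_strict_majority_wins(self):
        outs = [self._out(c) for c in
                ("001-002", "001-002", "001-002", "002-001", "003-001")]
        assert clf.representative_color(outs).full_code == "001-002"

    def test_unanimous_vote(self):
        outs = [self._out("004-004")] * 5
        assert clf.representative_color(outs).full_code == "004-004"

    def test_tied_mode_falls_back_to_confidence(self):
        outs = [
            self._out("001-001", 0.6),
            self._out("001-001", 0.7),
            self._out("002-002", 0.95),
            self._out("002-002", 0.5),
            self._out("003-003", 0.8),
        ]
        assert clf.representative_color(outs).full_code == "002-002"

    def test_unique_mode_wins_without_majority(self):
        outs = [
            self._out("001-001", 0.5),
            self._out("001-001", 0.5),
            self._out("002-002", 0.99),
            self._out("003-003", 0.99),
            self._out("004-004", 0.99),
        ]
        assert clf.representative_color(outs).full_code == "001-001"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        outs = [
            self._out("001-001", 0.6),
            self._out("002-002", 0.7),
            self._out("002-002", 0.65),
            self._out("005-001", 0.9),
            self._out("006-001", 0.8),
        ]
        winner = clf.representative_color(outs)
        for _ in range(10):
            perm = list(rng.permutation(len(outs)))
            assert clf.representative_color([outs[i] for i in perm]) == winner

    def test_strict_majority_is_always_modal(self):
        """Consistency of the voting cascade: any strict-majority code is
        necessarily the unique mode, so rule order cannot disagree."""
        rng = np.random.default_rng(2)
        codes = [c.full_code for c in clf.WATER_COLOR_CODES[:4]]
        for _ in range(100):
            votes = [rng.choice(codes) for _ in range(5)]
            counts = {c: votes.count(c) for c in set(votes)}
            top_code, top = max(counts.items(), key=lambda kv: kv[1])
            if top > len(votes) / 2:
                modal = [c for c, k in counts.items() if k == top]
                assert modal == [top_code]

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            clf.representative_color([])


class TestCNNSpec:
    def test_defaults_follow_published_architecture(self):
        spec = clf.CNNSpec()
        assert spec.input_size == 224
        assert spec.block_repeats == (3, 4, 6, 3)
        assert spec.head_widths == (2048, 1000, 100, 19)
        assert spec.batch_size == 32 and spec.max_epochs == 200
        assert spec.dropout == 0.5 and spec.learning_rate == 1e-4

    def test_head_must_end_in_class_count(self):
        with pytest.raises(DomainError):
            clf.CNNSpec(head_widths=(2048, 1000, 100, 20))

    def test_depth_scaling_keeps_at_least_one_block_per_group(self):
        spec = clf.CNNSpec(depth_scale=4)
        assert spec.scaled_repeats() == (1, 1, 1, 1)
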