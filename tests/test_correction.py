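"""Lab-space correction-matrix estimation and application."""

import numpy as np
import pytest

from aquacolor import color_spaces as cs
from aquacolor import correction as corr
from aquacolor.checkerboard import REFERENCE_COLORS_RGB
from aquacolor.errors import DomainError, EstimationError, LocalizationError
from aquacolor.synthetic import SceneSpec, render_scene

REF_LAB = cs.rgb_to_lab(REFERENCE_COLORS_RGB)


def _random_invertible(rng, spread=0.3):
    while True:
        T = np.eye(3) + rng.uniform(-spread, spread, (3, 3))
        if abs(np.linalg.det(T)) > 1e-3:
            return T


def test_lsq_system_dimensions_and_structure():
    system = corr.build_lsq_system(corr.BlockCorrespondence(REF_LAB, REF_LAB))
    A, d = system
    assert A.shape == (72, 9)
    assert d.shape == (72,)
    # first row places block 1's measured Lab on the first diagonal slot
    assert np.array_equal(A[0], np.r_[REF_LAB[0], np.zeros(6)])
    assert np.array_equal(A[1], np.r_[np.zeros(3), REF_LAB[0], np.zeros(3)])
    # d stacks the reference triples
    assert np.array_equal(d[:3], REF_LAB[0])


def test_lsq_system_rejects_wrong_block_count():
    with pytest.raises(DomainError):
        corr.build_lsq_system(corr.BlockCorrespondence(REF_LAB[:10], REF_LAB[:10]))


def test_identity_when_measured_equals_reference():
    model = corr.estimate_correction(corr.BlockCorrespondence(REF_LAB, REF_LAB))
    assert np.allclose(model.matrix, np.eye(3), atol=1e-8)
    assert model.residual == pytest.approx(0.0, abs=1e-8)


def test_exact_recovery_of_noise_free_linear_distortions():
    """24 consistent equations in 9 unknowns: least squares inverts any
    invertible Lab distortion to machine precision."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        T = _random_invertible(rng, spread=0.8)
        measured = REF_LAB @ T.T
        model = corr.estimate_correction(
            corr.BlockCorrespondence(measured, REF_LAB)
        )
        assert np.max(np.abs(model.matrix - np.linalg.inv(T))) < 1e-6


def test_recovery_under_measurement_noise():
    """Monte-Carlo: sigma = 0.5 Lab noise perturbs each matrix entry by
    less than 0.05."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        T = _random_invertible(rng)
        measured = REF_LAB @ T.T + rng.normal(0, 0.5, REF_LAB.shape)
        model = corr.estimate_correction(
            corr.BlockCorrespondence(measured, REF_LAB)
        )
        assert np.max(np.abs(model.matrix - np.linalg.inv(T))) < 0.05


def test_rank_deficient_measurements_raise():
    measured = np.tile(REF_LAB[0], (24, 1))  # all blocks identical
    with pytest.raises(EstimationError):
        corr.estimate_correction(corr.BlockCorrespondence(measured, REF_LAB))


def test_apply_identity_correction_is_near_identity():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
    out = corr.apply_correction(img, corr.CorrectionModel.identity())
    assert np.max(np.abs(out.astype(int) - img.astype(int))) <= 1


def test_least_squares_never_increases_block_residual():
    rng = np.random.default_rng(3)
    for _ in range(20):
        measured = REF_LAB + rng.normal(0, 5.0, REF_LAB.shape)
        model = corr.estimate_correction(
            corr.BlockCorrespondence(measured, REF_LAB)
        )
        before = np.sqrt(np.mean(np.sum((measured - REF_LAB) ** 2, axis=1)))
        assert model.residual <= before + 1e-9


def test_model_json_round_trip(tmp_path):
    model = corr.CorrectionModel(np.arange(9).reshape(3, 3) / 7.0, 1.25)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = corr.CorrectionModel.from_json(path)
    assert np.array_equal(loaded.matrix, model.matrix)
    assert loaded.residual == model.residual


class TestEndToEnd:
    def test_corrected_blocks_return_to_reference(self, layout):
        """Distort a scene with a known Lab matrix, estimate the correction
        from the embedded board, and check block colors come back."""
        from aquacolor.checkerboard import (
            detect_markers,
            estimate_roi_homography,
            extract_block_colors,
        )

        # chosen so the distorted board colors stay inside the RGB gamut
        T = np.array([[0.96, 0.02, 0.0], [0.01, 0.95, 0.02], [0.0, -0.02, 0.95]])
        bundle = render_scene(SceneSpec(seed=21, distortion=T, noise_sigma=0))
        corrected, model = corr.correct_image(bundle.image, layout)
        dets = detect_markers(corrected)
        h = estimate_roi_homography(dets, layout)
        blocks = extract_block_colors(corrected, h, layout)
        assert np.max(np.abs(blocks - REFERENCE_COLORS_RGB)) <= 3

    def test_correction_shrinks_chromaticity_error(self, layout):
        """Corrected block colors are closer to the ideal values in the
        a-b plane than the uncorrected ones."""
        T = np.array([[1.1, 0.05, 0.0], [0.0, 0.85, 0.05], [0.02, 0.0, 1.1]])
        bundle = render_scene(SceneSpec(seed=22, distortion=T, noise_sigma=1.0))
        corrector = corr.LabColorCorrector(layout).fit(bundle.image)
        measured_lab = cs.rgb_to_lab(corrector.measured_rgb_)
        corrected_lab = corrector.transform(measured_lab)
        before = np.linalg.norm(measured_lab[:, 1:] - REF_LAB[:, 1:], axis=1).mean()
        after = np.linalg.norm(corrected_lab[:, 1:] - REF_LAB[:, 1:], axis=1).mean()
        assert after < before

    def test_identity_distortion_gives_near_identity_model(self, clean_scene_bundle):
        _, model = corr.correct_image(clean_scene_bundle.image)
        assert np.max(np.abs(model.matrix - np.eye(3))) < 0.02

    def test_scene_without_board_raises_localization_error(self):
        bundle = render_scene(
            SceneSpec(seed=23, include_checkerboard=False, n_foam=0,
                      waterwheel_rect=None)
        )
        with pytest.raises(LocalizationError):
            corr.correct_image(bundle.image)

    def test_sklearn_style_params_round_trip(self, layout):
        est = corr.LabColorCorrector()
        assert est.get_params()["layout"] is None
        est.set_params(layout=layout)
        assert est.get_params()["layout"] is layout
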