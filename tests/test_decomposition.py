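"""The decomposition model: alpha, bone image, recomposition, baselines."""

import numpy as np
import pytest

from btd import (
    DegeneratePixelError,
    NoBoneSignalError,
    compute_alpha,
    compute_bone,
    contrast_report,
    decompose,
    evaluate_recovery,
    generate_phantom,
    linear_tissue,
    recompose,
    tissue_from_bone,
    PhantomSpec,
)


def flat_pair(shape=(10, 10), t_value=0.5):
    t = np.full(shape, t_value)
    f = t.copy()
    return f, t


class TestComputeAlpha:
    def test_ratio_one_gives_alpha_one(self):
        f, t = flat_pair()
        f[3, 3] = 1.0  # r = (1 - 0.5) / (1 - 0.5) = 1
        assert compute_alpha(f, t) == pytest.approx(1.0)

    def test_reciprocal_of_max_ratio(self):
        f, t = flat_pair(t_value=0.5)
        f[2, 2] = 0.75  # r = 0.25 / 0.5 = 0.5
        assert compute_alpha(f, t) == pytest.approx(2.0)

    def test_no_bone_signal(self):
        f, t = flat_pair()
        with pytest.raises(NoBoneSignalError):
            compute_alpha(f, t)

    def test_alpha_at_least_one_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.uniform(0.0, 0.9, (8, 8))
            f = np.clip(t + rng.uniform(0.0, 1.0, (8, 8)) * (1 - t), 0, 1)
            assert compute_alpha(f, t) >= 1.0


class TestComputeBone:
    def test_zero_where_f_equals_t(self):
        f, t = flat_pair()
        f[1, 1] = 0.9
        b = compute_bone(f, t, compute_alpha(f, t))
        assert b[5, 5] == 0.0 and b[1, 1] > 0

    def test_direct_arithmetic(self):
        b = compute_bone(np.full((3, 3), 0.8), np.full((3, 3), 0.6), 1.5)
        assert b[0, 0] == pytest.approx(1.5 * 0.2 / 0.4)

    def test_max_is_one_with_closed_form_alpha(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0.0, 0.8, (12, 12))
        f = np.clip(t + rng.uniform(0.0, 0.5, (12, 12)), 0, 1)
        alpha = compute_alpha(f, t)
        assert compute_bone(f, t, alpha).max() == pytest.approx(1.0, abs=1e-12)


class TestRecompose:
    def test_zero_bone_returns_tissue(self):
        t = np.random.default_rng(2).uniform(0, 0.9, (6, 6))
        assert np.array_equal(recompose(np.zeros((6, 6)), t, 1.3), t)

    def test_zero_tissue_returns_scaled_bone(self):
        b = np.random.default_rng(3).uniform(0, 1, (6, 6))
        assert np.allclose(recompose(b, np.zeros((6, 6)), 2.0), b / 2.0)

    def test_algebraic_inverse_of_compute_bone(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0.0, 0.8, (15, 15))
        f = np.clip(t + rng.uniform(0.0, 0.3, (15, 15)), 0, 1)
        alpha = compute_alpha(f, t)
        f_hat = recompose(compute_bone(f, t, alpha), t, alpha)
        assert np.abs(f_hat - f).max() <= 1e-12


class TestTissueFromBone:
    def test_zero_bone_is_identity(self):
        f = np.random.default_rng(5).uniform(0, 0.9, (6, 6))
        assert np.allclose(tissue_from_bone(f, np.zeros((6, 6)), 1.5), f)

    def test_direct_arithmetic(self):
        out = tissue_from_bone(np.full((3, 3), 0.8), np.full((3, 3), 0.75), 1.5)
        assert out[0, 0] == pytest.approx(0.6)

    def test_degenerate_denominator_lists_positions(self):
        f = np.full((4, 4), 0.5)
        b = np.zeros((4, 4))
        b[2, 3] = 1.0
        with pytest.raises(DegeneratePixelError) as err:
            tissue_from_bone(f, b, 1.0)
        assert [2, 3] in err.value.positions.tolist()

    def test_dominates_linear_model_on_grid(self):
        """(f - b)/(1 - b) >= f - b for all f <= 1, 0 <= b < 1: the
        nonlinear suppression never darkens tissue below the linear
        subtraction.  The only slack allowed is the denominator-guard
        clip to 1 - eps, which can shave the f = 1 equality cases by at
        most eps."""
        eps = 1e-6
        fv, bv = np.meshgrid(
            np.linspace(0, 1, 101), np.linspace(0, 1 - eps, 101), indexing="ij"
        )
        nonlinear = tissue_from_bone(fv, bv, 1.0, epsilon=eps / 2)
        linear = linear_tissue(fv, bv)
        assert np.all(nonlinear >= linear - eps)
        # away from the clipped equality edge the dominance is strict
        interior = fv <= 1 - 2 * eps
        assert np.all(nonlinear[interior] >= linear[interior] - 1e-12)


class TestLinearTissue:
    @pytest.mark.parametrize(
        "f,fb,expected", [(0.8, 0.3, 0.5), (0.8, 0.0, 0.8), (0.8, 0.8, 0.0)]
    )
    def test_pixelwise_difference(self, f, fb, expected):
        out = linear_tissue(np.full((3, 3), f), np.full((3, 3), fb))
        assert out[1, 1] == pytest.approx(expected)


class TestContrastReport:
    def test_constant_tissue_enhances_everywhere(self):
        """With T constant the composition is a pure affine rescale of
        B, so the bone gradient dominates at every evaluated pixel."""
        sample = generate_phantom(PhantomSpec(seed=9, n_bones=2))
        t = np.full_like(sample.T_true, 0.3)
        f = recompose(sample.B_true, t, sample.alpha_true)
        report = contrast_report(f, sample.B_true, t, sample.M_true)
        assert report.grad_t.max() == 0.0
        assert report.n_evaluated == int(sample.M_true.sum())
        assert report.fraction_enhanced == 1.0

    def test_pure_bone_image_scales_gradient(self):
        sample = generate_phantom(PhantomSpec(seed=10, n_bones=1, tissue_max=0.0))
        alpha = 1.8
        f = sample.B_true / alpha
        report = contrast_report(f, sample.B_true, np.zeros_like(f), sample.M_true)
        assert report.fraction_enhanced == 1.0

    def test_constant_image_is_all_ties(self):
        f = np.full((8, 8), 0.4)
        mask = np.zeros((8, 8), dtype=bool)
        mask[3:5, 3:5] = True
        report = contrast_report(f, np.zeros_like(f), f, mask)
        assert report.fraction_enhanced == 1.0

    def test_empty_evaluation_set_reports_not_raises(self):
        rows, cols = np.mgrid[0:8, 0:8]
        t = (rows + cols) / 14 * 0.9  # steep everywhere except far edges
        mask = np.zeros((8, 8), dtype=bool)
        mask[:7, :7] = True  # far edges carry zero-padded gradients
        report = contrast_report(t, np.zeros_like(t), t, mask, flat_threshold=1e-12)
        assert report.n_evaluated == 0
        assert 0.0 <= report.fraction_enhanced <= 1.0


class TestDecompose:
    def test_harmonic_phantom_recovery(self, harmonic_sample):
        result = decompose(harmonic_sample.f, harmonic_sample.M_true)
        rec = evaluate_recovery(harmonic_sample, result)
        assert rec["max_abs_T"] <= 1e-6
        assert rec["alpha_rel_error"] <= 1e-6
        assert rec["max_abs_B"] <= 1e-5

    def test_round_trip_reproduces_clamped_input(self, smooth_sample):
        result = decompose(smooth_sample.f, smooth_sample.M_true)
        f_hat = recompose(result.bone, result.tissue, result.alpha)
        f_clamped = np.maximum(smooth_sample.f, result.tissue)
        assert np.abs(f_hat - f_clamped).max() <= 1e-10

    def test_bone_free_image_raises(self):
        """A bone-free radiograph is one whose intensity equals its own
        tissue estimate; an affine field is discrete-harmonic, so the
        solve reproduces it and the bone ratio vanishes."""
        rows, cols = np.mgrid[0:64, 0:64]
        f = 0.1 + 0.004 * rows + 0.006 * cols
        mask = np.zeros_like(f, dtype=bool)
        mask[20:40, 20:40] = True
        with pytest.raises(NoBoneSignalError):
            decompose(f, mask)

    def test_alpha_and_max_bone_guarantees(self, smooth_sample):
        result = decompose(smooth_sample.f, smooth_sample.M_true)
        assert result.alpha >= 1.0
        assert result.bone.max() == pytest.approx(1.0, abs=1e-9)

    def test_bone_zero_outside_mask(self, smooth_sample):
        result = decompose(smooth_sample.f, smooth_sample.M_true)
        assert np.all(result.bone[~result.mask] == 0.0)

    def test_diagnostics_populated(self, smooth_sample):
        result = decompose(smooth_sample.f, smooth_sample.M_true)
        d = result.diagnostics
        assert d["max_residual"] <= 1e-8
        assert d["clamped_pixels"] >= 0
        assert 0.0 <= d["fraction_enhanced"] <= 1.0

    def test_estimated_mask_end_to_end(self, smooth_sample):
        """The full pipeline also works from an automatically estimated
        mask, not only from the phantom's true mask."""
        from btd import estimate_mask

        mask = estimate_mask(smooth_sample.f)
        result = decompose(smooth_sample.f, mask)
        assert result.alpha >= 1.0
        assert result.bone.max() == pytest.approx(1.0, abs=1e-9)
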