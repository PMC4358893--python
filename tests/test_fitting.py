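"""Normalization, single-spectrum fits, model selection, and map fitting."""

import numpy as np
import pytest

from zapped import (
    FitConfig,
    Lineshape,
    PoolParams,
    ZSpectrum,
    fit_roi_mean,
    fit_voxelwise,
    fit_zspectrum,
    forward_zspectrum,
    make_phantom,
    normalize_stack,
    nrmsd,
    select_lineshapes,
    subsample_schedule,
)
from zapped.phantom import TissueSpec

SEED = 20150313


class TestNrmsd:
    def test_perfect_fit_is_zero(self):
        y = [1.0, 0.5, 0.1]
        assert nrmsd(y, y) == 0.0

    def test_two_point_hand_value(self):
        assert nrmsd([1.0, 0.0], [1.0, 0.1]) == pytest.approx(
            np.sqrt(0.005), rel=1e-12
        )

    def test_scale_invariance(self, rng):
        y = rng.random(20)
        f = y + rng.normal(0, 0.01, 20)
        assert nrmsd(3.7 * y, 3.7 * f) == pytest.approx(nrmsd(y, f), rel=1e-12)

    def test_constant_measurement_rejected(self):
        with pytest.raises(ValueError):
            nrmsd([0.5, 0.5], [0.4, 0.6])


class TestNormalizeStack:
    def test_no_saturation_gives_zero(self, schedule):
        stack = np.full((2, 2, len(schedule)), 100.0)
        y, valid, qc = normalize_stack(stack, schedule)
        assert np.all(valid)
        np.testing.assert_allclose(y, 0.0, atol=1e-14)

    def test_full_on_resonance_saturation(self, schedule):
        n = len(schedule)
        stack = np.full((1, n), 50.0)
        stack[0, n // 2] = 0.0  # x = 0 volume
        y, _, _ = normalize_stack(stack, schedule)
        assert y[0, 0] == 0.0 and y[0, -1] == 0.0
        assert y[0, n // 2] == 1.0

    def test_separate_reference_round_trip(self, schedule, gm_params):
        y_model = forward_zspectrum(gm_params, schedule).values
        s0 = 1234.5
        stack = (s0 * (1 - y_model))[None, :]
        y, valid, qc = normalize_stack(stack, schedule, reference=np.array([s0]))
        np.testing.assert_allclose(y[0], y_model, rtol=1e-12)
        assert qc["n_clipped"] == 0

    def test_nonpositive_reference_excluded(self, schedule):
        stack = np.zeros((3, len(schedule)))
        stack[0] = 10.0
        y, valid, qc = normalize_stack(stack, schedule)
        assert list(valid) == [True, False, False]
        assert qc["n_invalid_reference"] == 2
        assert np.all(np.isnan(y[1]))

    def test_shape_mismatch_rejected(self, schedule):
        with pytest.raises(ValueError):
            normalize_stack(np.zeros((2, 10)), schedule)


@pytest.mark.parametrize("f_r", [0.05, 0.25, 0.45])
@pytest.mark.parametrize("t2f_us", [400.0, 1200.0])
@pytest.mark.parametrize("t2r_us", [10.0, 40.0])
def test_noiseless_recovery_across_parameter_grid(schedule, f_r, t2f_us, t2r_us):
    """All three free parameters recovered to <=1e-6 relative, noiseless."""
    gen = PoolParams.from_t2(f_r, t2f_us, t2r_us)
    fit = fit_zspectrum(forward_zspectrum(gen, schedule))
    assert fit.converged
    np.testing.assert_allclose(fit.params.as_array(), gen.as_array(), rtol=1e-6)


class TestFitZspectrum:
    def test_wm_means_recovered_exactly(self, schedule, wm_params):
        fit = fit_zspectrum(forward_zspectrum(wm_params, schedule))
        np.testing.assert_allclose(
            fit.params.as_array(), wm_params.as_array(), rtol=1e-6
        )
        assert fit.nrmsd < 1e-8

    def test_single_pool_input_pins_fraction_at_bound(self, schedule):
        gen = PoolParams(f_restricted=0.0, lw_free=400.0, lw_restricted=16000.0)
        fit = fit_zspectrum(forward_zspectrum(gen, schedule))
        # the narrow component carries everything; fitted F_r collapses
        assert fit.params.f_restricted < 1e-6
        assert fit.params.lw_free == pytest.approx(400.0, rel=1e-3)

    def test_noise_replicates_unbiased_mean(self, schedule, gm_params, rng):
        """Mean recovered F_r over 100 sigma=0.005 replicates within 0.01."""
        y0 = forward_zspectrum(gm_params, schedule).values
        frs = [
            fit_zspectrum(
                ZSpectrum(schedule.offsets, y0 + rng.normal(0, 0.005, len(schedule)))
            ).params.f_restricted
            for _ in range(100)
        ]
        assert abs(np.mean(frs) - gm_params.f_restricted) < 0.01

    def test_labeling_stable_under_swapped_initialization(self, schedule, gm_params):
        """The broader component is always reported as restricted."""
        z = forward_zspectrum(gm_params, schedule)
        # adversarial start inside the overlap region of the two width boxes,
        # with the broad component in the "free" slot
        fit = fit_zspectrum(z, init=np.array([0.5, 4900.0, 2100.0]))
        assert fit.params.lw_restricted >= fit.params.lw_free
        np.testing.assert_allclose(
            fit.params.as_array(), gm_params.as_array(), rtol=1e-4
        )

    def test_too_few_points_rejected(self, gm_params):
        x = np.array([-30000.0, -10000.0, 0.0, 10000.0, 30000.0])
        z = forward_zspectrum(gm_params, x)
        with pytest.raises(ValueError):
            fit_zspectrum(z)

    def test_noise_consistency_spread_shrinks_with_sigma(
        self, schedule, gm_params, rng
    ):
        y0 = forward_zspectrum(gm_params, schedule).values
        spreads = []
        for sigma in (0.02, 0.01, 0.005):
            frs = [
                fit_zspectrum(
                    ZSpectrum(
                        schedule.offsets, y0 + rng.normal(0, sigma, len(schedule))
                    )
                ).params.f_restricted
                for _ in range(100)
            ]
            spreads.append(np.std(frs))
        assert spreads[0] > spreads[1] > spreads[2]


class TestSelectLineshapes:
    def test_generative_pair_wins_noiseless(self, schedule, gm_params):
        LL = (Lineshape.LORENTZIAN, Lineshape.LORENTZIAN)
        GG = (Lineshape.GAUSSIAN, Lineshape.GAUSSIAN)
        for pair in (LL, GG):
            z = forward_zspectrum(gm_params, schedule, *pair)
            ranked = select_lineshapes(z)
            assert ranked[0][0] == pair
            assert ranked[0][1] < 1e-12
            assert [r[1] for r in ranked] == sorted(r[1] for r in ranked)

    def test_lorentzian_pair_wins_under_noise(self, schedule, gm_params, rng):
        """LL wins in >=90% of 50 replicates at sigma=0.01 (frozen seed)."""
        y0 = forward_zspectrum(gm_params, schedule).values
        LL = (Lineshape.LORENTZIAN, Lineshape.LORENTZIAN)
        wins = sum(
            select_lineshapes(
                ZSpectrum(schedule.offsets, y0 + rng.normal(0, 0.01, len(schedule)))
            )[0][0]
            == LL
            for _ in range(50)
        )
        assert wins >= 45


def _two_region_phantom(schedule, gm_params, wm_params, sigma=0.0, matrix=16):
    return make_phantom(
        "two-disc",
        [TissueSpec("GM", gm_params), TissueSpec("WM", wm_params)],
        schedule,
        noise_sigma=sigma,
        seed=SEED,
        matrix=matrix,
    )


class TestFitVoxelwise:
    def test_two_region_round_trip(self, schedule, gm_params, wm_params):
        stack, labels, truth = _two_region_phantom(schedule, gm_params, wm_params)
        maps = fit_voxelwise(stack, schedule, mask=labels, reference=truth["s0"])
        m = maps.mask
        np.testing.assert_allclose(
            maps.f_restricted_map[m], truth["f_restricted"][m], atol=1e-4
        )
        assert maps.f_restricted_map[labels == 1].mean() == pytest.approx(0.17, abs=1e-4)
        assert maps.f_restricted_map[labels == 2].mean() == pytest.approx(0.28, abs=1e-4)
        # fractions sum to 1 on the mask, T2 maps positive
        np.testing.assert_allclose(
            maps.f_free_map[m] + maps.f_restricted_map[m], 1.0, atol=1e-12
        )
        assert np.all(maps.t2_free_map[m] > 0) and np.all(maps.t2_restricted_map[m] > 0)
        assert np.all(np.isnan(maps.f_restricted_map[~m]))

    def test_all_background_stack_raises(self, schedule):
        stack = np.zeros((4, 4, len(schedule)))
        with pytest.raises(ValueError, match="mask"):
            fit_voxelwise(stack, schedule)

    def test_reduced_schedule_maps_match_full(self, schedule, gm_params, wm_params):
        """31-point maps agree with 53-point maps within 1% (noiseless)."""
        stack, labels, truth = _two_region_phantom(schedule, gm_params, wm_params)
        sub = subsample_schedule(schedule, 31)
        keep = np.isin(schedule.offsets, sub.offsets)
        full = fit_voxelwise(stack, schedule, mask=labels, reference=truth["s0"])
        red = fit_voxelwise(stack[..., keep], sub, mask=labels, reference=truth["s0"])
        m = full.mask
        for a, b in (
            (full.f_restricted_map, red.f_restricted_map),
            (full.t2_free_map, red.t2_free_map),
            (full.t2_restricted_map, red.t2_restricted_map),
        ):
            np.testing.assert_allclose(b[m], a[m], rtol=0.01)


class TestFitRoiMean:
    def test_homogeneous_region_matches_member_voxel(
        self, schedule, gm_params, wm_params
    ):
        stack, labels, truth = _two_region_phantom(schedule, gm_params, wm_params)
        roi = fit_roi_mean(stack, schedule, labels, 2, reference=truth["s0"])
        vox = tuple(np.argwhere(labels == 2)[0])
        y, _, _ = normalize_stack(stack, schedule, reference=truth["s0"])
        single = fit_zspectrum(ZSpectrum(schedule.offsets, y[vox]))
        np.testing.assert_allclose(
            roi.params.as_array(), single.params.as_array(), rtol=1e-8
        )
        assert roi.nrmsd < 1e-6

    def test_mixed_region_fraction_between_components(self, schedule):
        """50/50 mix: fitted F_r falls between the two generating values."""
        a = PoolParams.from_t2(0.10, 800.0, 18.0)
        b = PoolParams.from_t2(0.30, 600.0, 25.0)
        ya = forward_zspectrum(a, schedule).values
        yb = forward_zspectrum(b, schedule).values
        stack = np.stack([1000 * (1 - ya), 1000 * (1 - yb)])[None]
        labels = np.ones((1, 2), dtype=int)
        s0 = np.full((1, 2), 1000.0)
        roi = fit_roi_mean(stack, schedule, labels, 1, reference=s0)
        # oracle: fit of the analytically averaged spectrum
        oracle = fit_zspectrum(ZSpectrum(schedule.offsets, (ya + yb) / 2))
        assert 0.10 < roi.params.f_restricted < 0.30
        np.testing.assert_allclose(
            roi.params.as_array(), oracle.params.as_array(), rtol=1e-8
        )

    def test_absent_class_rejected(self, schedule, gm_params, wm_params):
        stack, labels, truth = _two_region_phantom(schedule, gm_params, wm_params)
        with pytest.raises(ValueError, match="absent"):
            fit_roi_mean(stack, schedule, labels, 9)
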