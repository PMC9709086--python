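"""Reconstruction chain: matching, binning, retrieval, unwrapping, thickness."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acoustoholo.config import RunConfig
from acoustoholo.pipeline import simulate_stack
from acoustoholo.reconstruct import (
    UnwrapError,
    WrappedPhaseMap,
    anchor_background,
    bin_frames,
    denoise_frame,
    match_step_offsets,
    phase_to_thickness,
    reference_subtract,
    retrieve_phase,
    unwrap_phase,
    wrap,
)


def itoh_unwrap(psi_w):
    """Row/column path-integration oracle for residue-free wrapped fields."""
    out = np.zeros_like(psi_w)
    out[:, 0] = np.concatenate([[psi_w[0, 0]],
                                psi_w[0, 0] + np.cumsum(wrap(np.diff(psi_w[:, 0])))])
    for i in range(psi_w.shape[0]):
        out[i, 1:] = out[i, 0] + np.cumsum(wrap(np.diff(psi_w[i])))
    return out


def _fast_offset_config(seed, offsets="random", snr_db=None):
    """Small acquisition (8 steps of π/4, 16 frames) for matcher tests."""
    return RunConfig(
        scene={"kind": "bead", "diameter": 5.0, "material": "PAA",
               "medium": "DI_water"},
        grid_shape=(32, 32), pixel_pitch=0.4, pressure=500.0,
        n_steps=8, step_phase=np.pi / 4, frames_per_step=16,
        step_offsets=offsets, seed=seed, snr_db=snr_db,
    )


class TestMatching:
    def test_recovers_injected_offsets_exactly_noise_free(self):
        for seed in (0, 1, 2):
            scene, stack = simulate_stack(_fast_offset_config(seed))
            result = match_step_offsets(stack)
            np.testing.assert_array_equal(result.shifts, stack.expected_shifts)

    def test_identical_start_phases_give_zero_shifts(self):
        scene, stack = simulate_stack(_fast_offset_config(3, offsets=None))
        result = match_step_offsets(stack)
        np.testing.assert_array_equal(result.shifts, np.zeros(8, dtype=int))

    def test_invariant_to_global_intensity_scale(self):
        scene, stack = simulate_stack(_fast_offset_config(4))
        ref = match_step_offsets(stack).shifts
        stack.frames = stack.frames * 1.7
        np.testing.assert_array_equal(match_step_offsets(stack).shifts, ref)

    def test_vibration_free_sequence_flagged_ambiguous(self):
        cfg = _fast_offset_config(5, offsets=None)
        cfg.pressure = 0.0
        scene, stack = simulate_stack(cfg)
        with pytest.warns(RuntimeWarning, match="ambiguous"):
            result = match_step_offsets(stack)
        assert result.ambiguous
        np.testing.assert_array_equal(result.shifts, np.zeros(8, dtype=int))


class TestBinning:
    def test_default_plan_yields_50_bins_of_20(self, small_bead_config):
        scene, stack = simulate_stack(small_bead_config)
        bins = bin_frames(stack, np.zeros(20, dtype=int))
        assert bins.n_bins == 50
        assert bins.frames.shape[:2] == (50, 20)
        assert bins.psi[0] == 0 and bins.psi[-1] < 2 * np.pi
        np.testing.assert_allclose(np.diff(bins.psi), 2 * np.pi / 50)

    def test_unbinning_restores_frame_multiset(self):
        scene, stack = simulate_stack(_fast_offset_config(6))
        shifts = match_step_offsets(stack).shifts
        bins = bin_frames(stack, shifts)
        # invert the permutation: frame (j+s_k)%F of step k sits in bin j
        F = stack.plan.frames_per_step
        restored = np.empty_like(stack.frames)
        for k in range(stack.plan.n_steps):
            for j in range(F):
                restored[k, (j + shifts[k]) % F] = bins.frames[j, k]
        np.testing.assert_array_equal(restored, stack.frames)

    def test_shift_count_validated(self, small_bead_config):
        scene, stack = simulate_stack(small_bead_config)
        with pytest.raises(ValueError, match="one shift per step"):
            bin_frames(stack, np.zeros(7, dtype=int))


class TestDenoise:
    def test_zero_sigma_is_identity(self, rng):
        frame = rng.uniform(0, 4000, (32, 32))
        out = denoise_frame(frame, 0.0)
        np.testing.assert_array_equal(out, frame)

    @pytest.mark.parametrize("method", ["nl_means", "wavelet"])
    def test_noisy_fringes_rmse_reduced(self, method, rng):
        yy, xx = np.mgrid[:64, :64]
        clean = 1000.0 * (1 + 0.9 * np.cos(0.2 * xx + 0.1 * yy + 0.002 * xx * yy))
        noisy = clean + rng.normal(0, 10.0, clean.shape)
        out = denoise_frame(noisy, 10.0, method=method, full_scale=4095.0)
        assert np.sqrt(np.mean((out - clean) ** 2)) < np.sqrt(
            np.mean((noisy - clean) ** 2)
        )

    def test_flat_image_variance_reduced(self, rng):
        noisy = 500.0 + rng.normal(0, 8.0, (48, 48))
        out = denoise_frame(noisy, 8.0, full_scale=4095.0)
        assert out.var() < noisy.var()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            denoise_frame(np.zeros((4, 4)), 1.0, method="median")


class TestRetrievePhase:
    def _frames(self, phi, theta, I0=100.0, V=0.8):
        return np.stack([I0 * (1 + V * np.cos(phi + t)) for t in theta])

    def test_exact_recovery_with_20_steps(self, rng):
        phi = rng.uniform(-3, 3, (32, 32))
        theta = np.arange(20) * np.pi / 10
        wrapped = retrieve_phase(self._frames(phi, theta), theta)
        np.testing.assert_allclose(wrapped.phase, wrap(phi), atol=1e-9)
        np.testing.assert_allclose(wrapped.visibility, 0.8, atol=1e-9)

    def test_known_constant_phase(self):
        theta = np.arange(20) * np.pi / 10
        wrapped = retrieve_phase(self._frames(np.full((8, 8), 1.0), theta), theta)
        np.testing.assert_allclose(wrapped.phase, 1.0, atol=1e-9)

    def test_zero_phase_gives_pure_cosine_quadrature(self):
        theta = np.arange(20) * np.pi / 10
        wrapped = retrieve_phase(self._frames(np.zeros((8, 8)), theta), theta)
        np.testing.assert_allclose(wrapped.phase, 0.0, atol=1e-9)

    def test_invariance_to_intensity_offset_and_scale(self, rng):
        phi = rng.uniform(-3, 3, (16, 16))
        theta = np.arange(20) * np.pi / 10
        frames = self._frames(phi, theta)
        ref = retrieve_phase(frames, theta).phase
        shifted = retrieve_phase(3.0 * frames + 40.0, theta).phase
        np.testing.assert_allclose(shifted, ref, atol=1e-9)

    def test_rank_deficient_design_rejected(self):
        frames = np.zeros((3, 4, 4))
        with pytest.raises(ValueError, match="rank-deficient|distinct"):
            retrieve_phase(frames, np.array([0.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="at least 3"):
            retrieve_phase(frames[:2], np.array([0.0, 1.0]))

    def test_low_visibility_pixels_get_zero_quality(self, rng):
        phi = rng.uniform(-3, 3, (8, 8))
        theta = np.arange(20) * np.pi / 10
        frames = self._frames(phi, theta, V=0.01)
        wrapped = retrieve_phase(frames, theta, visibility_floor=0.05)
        assert np.all(wrapped.quality == 0)


class TestUnwrap:
    def _quadratic(self, n=64, span=15.0):
        yy, xx = np.mgrid[:n, :n] / (n - 1)
        return span * ((xx - 0.3) ** 2 + (yy - 0.6) ** 2)

    def test_matches_path_integration_oracle(self):
        phi = self._quadratic()
        psi_w = wrap(phi)
        res = unwrap_phase(psi_w)
        oracle = itoh_unwrap(psi_w)
        diff = res.phase - oracle
        assert np.ptp(diff - diff.mean()) <= 1e-6

    def test_wrap_consistency_everywhere(self):
        phi = self._quadratic()
        res = unwrap_phase(wrap(phi))
        np.testing.assert_allclose(wrap(res.phase), wrap(phi), atol=1e-9)

    def test_in_range_smooth_phase_preserved_up_to_constant(self):
        phi = 0.4 * self._quadratic(span=5.0) - 1.0  # stays within (−π, π]
        res = unwrap_phase(phi)
        diff = res.phase - phi
        assert np.ptp(diff) <= 1e-9

    def test_zero_field_maps_to_zero(self):
        res = unwrap_phase(np.zeros((32, 32)))
        np.testing.assert_allclose(res.phase, 0.0, atol=1e-12)

    def test_weighted_pcg_ignores_bad_region(self, rng):
        phi = self._quadratic(48)
        psi_w = wrap(phi)
        bad = np.zeros_like(phi, dtype=bool)
        bad[20:28, 20:28] = True
        corrupted = psi_w.copy()
        corrupted[bad] = rng.uniform(-np.pi, np.pi, bad.sum())
        weights = np.where(bad, 0.0, 1.0)
        res = unwrap_phase(corrupted, weights=weights)
        good = ~bad
        diff = (res.phase - phi)[good]
        assert np.std(diff) < 1e-3

    def test_weighted_quality_map_triggers_pcg(self, rng):
        phi = self._quadratic(32, span=4.0)
        quality = np.ones_like(phi)
        quality[10:14, 10:14] = 0.0
        wrapped = WrappedPhaseMap(phase=wrap(phi), amplitude=np.ones_like(phi),
                                  visibility=np.ones_like(phi), quality=quality)
        res = unwrap_phase(wrapped)
        assert res.n_iterations > 0

    def test_nonfinite_phase_rejected(self):
        bad = np.zeros((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            unwrap_phase(bad)

    def test_iteration_cap_raises_with_residual(self, rng):
        phi = self._quadratic(48)
        weights = rng.uniform(0.05, 1.0, phi.shape)
        with pytest.raises(UnwrapError) as err:
            unwrap_phase(wrap(phi), weights=weights, tol=1e-16, max_iterations=2)
        assert err.value.residual > 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), span=st.floats(2.0, 25.0))
    def test_wrap_consistency_property_on_smooth_fields(self, seed, span):
        g = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter

        phi = gaussian_filter(g.standard_normal((32, 32)), 4.0)
        phi = span * phi / max(np.ptp(phi), 1e-9)
        # keep the field residue-free: neighbour steps below π
        if max(np.abs(np.diff(phi, axis=0)).max(),
               np.abs(np.diff(phi, axis=1)).max()) >= np.pi:
            return
        res = unwrap_phase(wrap(phi))
        np.testing.assert_allclose(wrap(res.phase), wrap(phi), atol=1e-9)


class TestReferenceAndThickness:
    def test_subtracting_self_gives_zero(self):
        phi = np.random.default_rng(0).uniform(0, 5, (16, 16))
        out = reference_subtract(phi, phi)
        np.testing.assert_allclose(out.phase, 0.0, atol=1e-12)

    def test_zero_blank_is_identity_up_to_anchor(self):
        phi = self._smooth()
        out = reference_subtract(phi, np.zeros_like(phi))
        diff = phi - out.phase
        assert np.ptp(diff) <= 1e-12

    def _smooth(self):
        yy, xx = np.mgrid[:24, :24] / 23.0
        return 3.0 * xx * yy

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            reference_subtract(np.zeros((8, 8)), np.zeros((9, 9)))

    def test_background_aberration_removed_via_blank(self):
        # simulate sample + blank with the same low-order background phase
        yy, xx = np.mgrid[:32, :32] / 31.0
        bg = 0.8 * (xx - 0.5) + 0.5 * (yy - 0.5) ** 2
        cfg = RunConfig(
            scene={"kind": "bead", "diameter": 5.0, "material": "PAA",
                   "medium": "DI_water"},
            grid_shape=(32, 32), pixel_pitch=0.4, pressure=0.0, seed=0,
            n_steps=8, step_phase=np.pi / 4, frames_per_step=4,
        )
        optics = cfg.build_optics()
        optics.background_phase = bg
        from acoustoholo.simulate import acquire_stack, render_interferogram

        scene = cfg.build_scene()
        theta = np.arange(8) * np.pi / 4
        sample = np.stack([
            render_interferogram(scene.h0, t, optics, scene.delta_n)
            for t in theta
        ])
        blank = np.stack([
            render_interferogram(np.zeros_like(scene.h0), t, optics, scene.delta_n)
            for t in theta
        ])
        phi_s = unwrap_phase(retrieve_phase(sample, theta)).phase
        phi_b = unwrap_phase(retrieve_phase(blank, theta)).phase
        cleaned = reference_subtract(phi_s, phi_b)
        expected = 2 * np.pi * scene.delta_n * scene.h0 / optics.wavelength
        np.testing.assert_allclose(
            cleaned.phase, anchor_background(expected), atol=1e-6
        )

    def test_thickness_formula_hand_value(self):
        # 2π rad of phase, PS in water at 532 nm: h = λ/Δn = 0.532/0.2575
        h = phase_to_thickness(np.full((4, 4), 2 * np.pi), 0.532, 1.5915, 1.334)
        np.testing.assert_allclose(h, 2.066019417475728, atol=1e-4)

    def test_zero_phase_zero_thickness_and_scaling(self):
        assert phase_to_thickness(np.zeros((2, 2)), 0.532, 1.5, 1.3).max() == 0
        h1 = phase_to_thickness(np.full((2, 2), 1.0), 0.532, 1.40, 1.30)
        h2 = phase_to_thickness(np.full((2, 2), 1.0), 0.532, 1.50, 1.30)
        np.testing.assert_allclose(h1, 2 * h2, rtol=1e-12)

    def test_zero_contrast_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            phase_to_thickness(np.zeros((2, 2)), 0.532, 1.4, 1.4)


class TestEndToEndFidelity:
    def test_noise_free_bead_thickness_error_below_5nm(self, small_bead_config):
        from acoustoholo.pipeline import reconstruct_series
        from acoustoholo.stiffness import ElasticModelParams, elastic_forward

        scene, stack = simulate_stack(small_bead_config)
        series, _ = reconstruct_series(stack)
        w = elastic_forward(scene.E_true, scene.h0,
                            ElasticModelParams(pressure=500.0), scene.pixel_pitch)
        for j in range(0, 50, 7):
            truth = scene.h0 - w * (1 + np.sin(stack.psi[0, j])) / 2
            assert np.abs(series.maps[j] - truth).max() <= 0.005

    def test_noise_free_phase_rmse_below_1e6(self, small_bead_config):
        from acoustoholo.pipeline import simulate_stack

        scene, stack = simulate_stack(small_bead_config)
        bins = bin_frames(stack, np.zeros(20, dtype=int))
        wrapped = retrieve_phase(bins.frames[0], bins.theta)
        phase = anchor_background(unwrap_phase(wrapped).phase)
        expected = 2 * np.pi * scene.delta_n * scene.h0 / 0.527
        # bin 0 is the undeformed instant only up to the deformation phase;
        # use the actual deformed truth
        from acoustoholo.stiffness import ElasticModelParams, elastic_forward

        w = elastic_forward(scene.E_true, scene.h0,
                            ElasticModelParams(pressure=500.0), scene.pixel_pitch)
        h_true = scene.h0 - w * (1 + np.sin(stack.psi[0, 0])) / 2
        expected = 2 * np.pi * scene.delta_n * h_true / stack.optics.wavelength
        rmse = np.sqrt(np.mean((phase - expected) ** 2))
        assert rmse <= 1e-6
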