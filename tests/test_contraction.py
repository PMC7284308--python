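"""Optical flow, binning, beat kinematics and the pacing classifier."""

import numpy as np
import pytest

from mtphen import contraction as con
from mtphen.contraction import (
    BeatSeries,
    ContractionProfile,
    FlowParams,
    PacingRule,
    beats_from_profile,
    bin_and_select,
    classify_pacing,
    contraction_direction,
    flow_movie,
    horn_schunck,
    normalized_contraction_duration,
    profile_parameters,
)
from mtphen.synthgen import BeatRecipe, MovieRecipe, generate_beat_series, generate_movie


def analytic_profile(
    fps=100.0, period_s=1.0, n_beats=6, peak=30.0, relax_peak=18.0,
    width_s=0.2,
):
    """Speed trace of a sin²-pulse beat train (contraction + relaxation)."""
    t = np.arange(int(n_beats * period_s * fps)) / fps
    tau = np.mod(t, period_s)
    w = width_s
    w_r = w * peak / relax_peak
    s = np.zeros_like(t)
    c = tau < w
    s[c] = peak * np.sin(np.pi * tau[c] / w) ** 2
    r = (tau >= w) & (tau < w + w_r)
    s[r] = relax_peak * np.sin(np.pi * (tau[r] - w) / w_r) ** 2
    return ContractionProfile(
        time_s=t, speed_um_s=s, sd_um_s=np.zeros_like(s), fps=fps,
        bin_index=(0, 0),
    )


class TestHornSchunck:
    def test_identical_frames_give_exact_zero(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 255, (64, 64))
        u, v = horn_schunck(f, f)
        assert np.all(u == 0) and np.all(v == 0)

    def test_translation_recovered_within_10pct(self):
        mv = generate_movie(MovieRecipe(
            motion="translation", velocity_px_per_frame=(0.0, 0.5),
            n_frames=4, noise_sd=1.0, seed=3,
        ))
        params = FlowParams(n_iter=400, um_per_px=1.0, fps=100.0)
        fields = flow_movie(mv.frames, params)
        interior = fields[:, 1, 20:-20, 20:-20]
        assert interior.mean() == pytest.approx(0.5, rel=0.10)

    def test_approximately_linear_in_small_displacements(self):
        params = FlowParams(um_per_px=1.0, fps=100.0)
        means = []
        for vel in (0.25, 0.5):
            mv = generate_movie(MovieRecipe(
                motion="translation", velocity_px_per_frame=(0.0, vel),
                n_frames=3, noise_sd=0.5, seed=3,
            ))
            fields = flow_movie(mv.frames, params)
            means.append(np.abs(fields[:, 1, 20:-20, 20:-20]).mean())
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.15)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        from scipy import ndimage as ndi

        base = ndi.gaussian_filter(rng.uniform(0, 255, (80, 80)), 3)
        shifted = np.roll(base, 1, axis=1)  # move +x by 1 px
        u, v = horn_schunck(base, shifted, alpha=20.0)
        # rotate both frames 90° CCW: motion along +x becomes motion along
        # -y (in array row terms).  The 2x2 derivative stencils are not
        # perfectly rotation-symmetric, so agreement is statistical.
        u2, v2 = horn_schunck(np.rot90(base), np.rot90(shifted), alpha=20.0)
        inner = slice(10, -10)
        a = np.rot90(u)[inner, inner]
        b = -v2[inner, inner]
        assert a.mean() == pytest.approx(b.mean(), rel=0.05)
        assert np.corrcoef(a.ravel(), b.ravel())[0, 1] > 0.95
        assert np.abs(np.rot90(v)[inner, inner]).mean() < 0.2 * np.abs(a).mean() + 1e-6
        assert np.abs(u2[inner, inner]).mean() < 0.2 * np.abs(a).mean() + 1e-6

    def test_size_mismatch_fails(self):
        with pytest.raises(ValueError):
            horn_schunck(np.zeros((10, 10)), np.zeros((12, 10)))


class TestBinning:
    def test_uniform_translation_calibrated_to_50_um_s(self):
        mv = generate_movie(MovieRecipe(
            motion="translation", velocity_px_per_frame=(0.0, 0.5),
            n_frames=6, noise_sd=1.0, seed=3,
        ))
        params = FlowParams(um_per_px=1.0, fps=100.0)
        profile = bin_and_select(flow_movie(mv.frames, params), params)
        assert profile.speed_um_s.mean() == pytest.approx(50.0, rel=0.10)

    def test_zero_motion_flat_zero_profile(self):
        mv = generate_movie(MovieRecipe(motion="none", n_frames=4, noise_sd=0.0))
        params = FlowParams(um_per_px=1.0, fps=100.0)
        profile = bin_and_select(flow_movie(mv.frames, params), params)
        assert np.all(profile.speed_um_s == 0.0)

    def test_auto_bin_inside_active_patch(self):
        mv = generate_movie(MovieRecipe(
            motion="pulse", n_frames=30, region=(40.0, 88.0, 30.0),
            shape=(128, 128), noise_sd=0.5, seed=2,
        ))
        params = FlowParams(um_per_px=1.0, fps=100.0, selection_um=128.0)
        profile = bin_and_select(flow_movie(mv.frames, params), params)
        bi, bj = profile.bin_index
        bin_px = int(round(params.bin_um))
        cy = (128 - 8 * bin_px) // 2 + (bi + 0.5) * bin_px
        cx = (128 - 8 * bin_px) // 2 + (bj + 0.5) * bin_px
        assert np.hypot(cy - 40.0, cx - 88.0) < 30.0

    def test_manual_selection_outside_frame_fails(self):
        fields = np.zeros((3, 2, 64, 64))
        params = FlowParams(
            um_per_px=1.0, fps=100.0, selection_um=60.0,
            selection_origin=(30, 30),
        )
        with pytest.raises(ValueError, match="outside"):
            bin_and_select(fields, params)

    def test_speed_calibration_is_exact(self):
        fields = np.zeros((2, 2, 60, 60))
        fields[:, 1] = 0.3  # px/frame along x
        params = FlowParams(um_per_px=0.65, fps=100.0)
        profile = bin_and_select(fields, params)
        assert np.allclose(profile.speed_um_s, 0.3 * 0.65 * 100.0)


class TestProfileParameters:
    def test_recovers_pulse_peaks_and_symmetry(self):
        prof = analytic_profile(peak=30.0, relax_peak=30.0)
        kin = profile_parameters(prof)
        assert kin.n_beats == 6
        assert kin.upstroke_velocity_um_s == pytest.approx(30.0, rel=0.05)
        assert kin.relaxation_velocity_um_s == pytest.approx(
            kin.upstroke_velocity_um_s, rel=0.05
        )

    def test_asymmetric_pulse_separates_phases(self):
        prof = analytic_profile(peak=30.0, relax_peak=18.0)
        kin = profile_parameters(prof)
        assert kin.upstroke_velocity_um_s == pytest.approx(30.0, rel=0.05)
        assert kin.relaxation_velocity_um_s == pytest.approx(18.0, rel=0.05)

    def test_beat_duration_of_200ms_pulse_within_one_frame(self):
        # single-phase 200 ms sin² pulse: 10% threshold crossings at
        # (w/pi)*asin(sqrt(0.1)) from each end
        fps = 100.0
        t = np.arange(600) / fps
        tau = np.mod(t, 1.0)
        s = np.where(tau < 0.2, 30.0 * np.sin(np.pi * tau / 0.2) ** 2, 0.0)
        prof = ContractionProfile(t, s, np.zeros_like(s), fps, (0, 0))
        kin = profile_parameters(prof)
        margin = 0.2 / np.pi * np.arcsin(np.sqrt(0.1))
        expected = 0.2 - 2 * margin
        assert kin.beat_duration_s == pytest.approx(expected, abs=0.01)

    def test_too_few_beats_fails_with_count(self):
        prof = analytic_profile(n_beats=3)
        with pytest.raises(ValueError, match="3 beats"):
            profile_parameters(prof)

    def test_upstroke_acceleration_matches_analytic_derivative(self):
        prof = analytic_profile(peak=30.0, relax_peak=30.0, fps=1000.0)
        kin = profile_parameters(prof)
        # d/dt [P sin²(πt/w)] has maximum P*π/w at t = w/4
        expected = 30.0 * np.pi / 0.2
        assert kin.upstroke_acceleration_um_s2 == pytest.approx(expected, rel=0.05)


class TestDirectionsAndDurations:
    @pytest.mark.parametrize(
        "u, v, angle",
        [(1.0, 0.0, 0.0), (0.0, 1.0, np.pi / 2), (-1.0, 0.0, np.pi)],
    )
    def test_cardinal_directions(self, u, v, angle):
        assert contraction_direction(np.array([u]), np.array([v]))[0] == pytest.approx(angle)

    def test_zero_vector_masked(self):
        out = contraction_direction(np.array([0.0]), np.array([0.0]))
        assert np.isnan(out[0])

    @pytest.mark.parametrize(
        "cd, ibi, expected",
        [(0.4, 1.0, 0.4), (0.4, 0.25, 0.8), (0.3, 2.25, 0.2)],
    )
    def test_normalized_contraction_duration(self, cd, ibi, expected):
        assert normalized_contraction_duration(cd, ibi) == pytest.approx(expected)

    def test_nonpositive_inputs_fail(self):
        with pytest.raises(ValueError):
            normalized_contraction_duration(0.0, 1.0)
        with pytest.raises(ValueError):
            normalized_contraction_duration(0.4, -1.0)


class TestPacingClassifier:
    @pytest.mark.parametrize("dev_pct", [0, 14, 16, 20])
    @pytest.mark.parametrize("cv", [0.10, 0.27, 0.29])
    def test_truth_table_on_generated_beats(self, dev_pct, cv):
        pacing = 2.0
        rate = pacing * (1 + dev_pct / 100)
        beats = generate_beat_series(
            BeatRecipe(rate_hz=rate, amplitude_cv=cv, n_beats=12, seed=8)
        )
        expected = (dev_pct <= 15) and (cv < 0.28)
        assert classify_pacing(beats, pacing) is expected

    def test_rate_estimator_is_interval_based(self):
        beats = BeatSeries(
            times=np.array([0.0, 0.5, 1.0, 1.5, 2.0]),
            amplitudes=np.ones(5),
        )
        assert beats.rate_hz == pytest.approx(2.0)

    def test_fewer_than_three_beats_fails(self):
        beats = BeatSeries(times=np.array([0.0, 1.0]), amplitudes=np.ones(2))
        with pytest.raises(ValueError):
            classify_pacing(beats, 1.0)

    def test_rule_bounds_validated(self):
        with pytest.raises(ValueError):
            PacingRule(rate_tolerance=1.5)


class TestEndToEndMovie:
    def test_pulse_movie_kinematics_and_beats(self):
        mv = generate_movie(MovieRecipe(
            motion="pulse", n_frames=500, fps=100.0, period_s=1.0,
            peak_um_s=30.0, shape=(96, 96), noise_sd=1.0, seed=4,
        ))
        params = FlowParams(um_per_px=1.0, fps=100.0)
        profile = bin_and_select(flow_movie(mv.frames, params), params)
        kin = profile_parameters(profile)
        assert kin.n_beats == 5
        assert kin.upstroke_velocity_um_s == pytest.approx(30.0, rel=0.10)
        beats = beats_from_profile(profile)
        assert beats.rate_hz == pytest.approx(1.0, rel=0.02)
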