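"""Two-point cross-correlogram velocimetry: oracles and parameter recovery."""

import numpy as np
import pytest

import microcirc as mc
from microcirc.velocimetry import _disc_offsets

from conftest import capillary_center_row


def brute_force_correlogram(z1, z2, max_lag):
    """Direct double-loop definition of the unbiased cross-correlogram."""
    n = len(z1)
    out = {}
    for tau in range(-max_lag, max_lag + 1):
        s = 0.0
        for t in range(n):
            if 0 <= t + tau < n:
                s += z1[t] * z2[t + tau]
        out[tau] = s / (n - abs(tau))
    return out


def shifted_pair_stack(shift=3, n=256, period=12.0, dx_px=40, pixel_size=0.5,
                       frame_interval=0.005):
    """Stack whose two sample points carry identical periodic traces offset
    by an exact integer number of frames."""
    t = np.arange(n + shift)
    f = 50.0 + 20.0 * np.sin(2 * np.pi * t / period)
    frames = np.zeros((n, 3, dx_px + 20))
    frames[:, :, :] = 30.0
    frames[:, 1, 5] = f[shift:]            # p1 leads
    frames[:, 1, 5 + dx_px] = f[:n]        # p2 lags by `shift` frames
    return mc.ImageStack(frames, frame_interval=frame_interval, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# extract_point_trace
# ---------------------------------------------------------------------------

def test_radius_zero_returns_raw_pixel_series():
    rng = np.random.default_rng(0)
    frames = rng.random((20, 6, 6))
    stack = mc.ImageStack(frames)
    trace = mc.extract_point_trace(stack, (2, 3), radius=0)
    assert np.array_equal(trace.values, frames[:, 3, 2])


def test_constant_movie_gives_constant_trace():
    stack = mc.ImageStack(np.full((20, 6, 6), 4.0))
    trace = mc.extract_point_trace(stack, (3, 3), radius=1)
    assert np.all(trace.values == 4.0)


def test_disc_mean_matches_pixel_enumeration():
    rng = np.random.default_rng(1)
    frames = rng.random((16, 12, 12))
    stack = mc.ImageStack(frames)
    radius = 2.5
    trace = mc.extract_point_trace(stack, (6, 5), radius=radius)
    # oracle: enumerate disc pixels explicitly
    acc = []
    for t in range(16):
        vals = [frames[t, y, x]
                for y in range(12) for x in range(12)
                if (x - 6) ** 2 + (y - 5) ** 2 <= radius**2]
        acc.append(np.mean(vals))
    assert np.allclose(trace.values, acc)
    dy, dx = _disc_offsets(radius)
    assert len(dy) == len([1 for y in range(-3, 4) for x in range(-3, 4)
                           if x * x + y * y <= radius**2])


def test_out_of_bounds_sampling_is_rejected():
    stack = mc.ImageStack(np.zeros((16, 6, 6)))
    with pytest.raises(ValueError, match="outside"):
        mc.extract_point_trace(stack, (5, 5), radius=2)


# ---------------------------------------------------------------------------
# zscore_trace
# ---------------------------------------------------------------------------

def test_zscore_uses_population_sd():
    assert np.allclose(mc.zscore_trace(np.array([0.0, 2.0])), [-1.0, 1.0])


def test_zscore_output_is_standardized_and_affine_invariant():
    rng = np.random.default_rng(2)
    x = rng.random(100)
    z = mc.zscore_trace(x)
    assert abs(z.mean()) < 1e-12 and abs(z.std() - 1) < 1e-12
    assert np.allclose(mc.zscore_trace(3.5 * x + 11.0), z)


def test_zscore_rejects_flat_trace():
    with pytest.raises(ValueError, match="flat trace"):
        mc.zscore_trace(np.full(32, 5.0))


# ---------------------------------------------------------------------------
# unbiased_crosscorrelogram
# ---------------------------------------------------------------------------

def test_identical_traces_peak_at_zero_with_unit_correlation():
    z = mc.zscore_trace(np.sin(np.arange(64) / 3.0))
    corr = mc.unbiased_crosscorrelogram(z, z, max_lag=10)
    mid = np.flatnonzero(corr.lags == 0)[0]
    assert corr.values[mid] == pytest.approx(1.0)
    assert np.argmax(corr.values) == mid


def test_shifted_trace_peaks_at_the_shift():
    z = mc.zscore_trace(np.sin(2 * np.pi * np.arange(128) / 32.0))
    z2 = np.roll(z, 3)  # z2 lags z by 3 frames
    corr = mc.unbiased_crosscorrelogram(z, z2, max_lag=8)
    assert corr.lags[np.argmax(corr.values)] == 3


def test_six_sample_hand_vectors_match_double_loop_at_every_lag():
    z1 = mc.zscore_trace(np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0]))
    z2 = np.roll(z1, 1)
    corr = mc.unbiased_crosscorrelogram(z1, z2, max_lag=3)
    oracle = brute_force_correlogram(z1, z2, 3)
    for lag, value in zip(corr.lags, corr.values):
        assert value == pytest.approx(oracle[lag], abs=1e-12)


def test_fast_correlogram_equals_direct_sum_on_random_traces():
    rng = np.random.default_rng(3)
    for _ in range(10):
        z1 = mc.zscore_trace(rng.random(50))
        z2 = mc.zscore_trace(rng.random(50))
        corr = mc.unbiased_crosscorrelogram(z1, z2, max_lag=12)
        oracle = brute_force_correlogram(z1, z2, 12)
        assert max(abs(v - oracle[l]) for l, v in zip(corr.lags, corr.values)) < 1e-9


def test_correlogram_input_validation():
    z = np.zeros(20)
    with pytest.raises(ValueError, match="equal length"):
        mc.unbiased_crosscorrelogram(z, np.zeros(10), 4)
    with pytest.raises(ValueError, match="max_lag"):
        mc.unbiased_crosscorrelogram(z, z, 15)


# ---------------------------------------------------------------------------
# estimate_velocity
# ---------------------------------------------------------------------------

def test_exact_three_frame_shift_gives_textbook_speed():
    # Δx = 40 px · 0.5 μm = 20 μm, τ = 3 frames · 5 ms  →  20 μm / 15 ms
    stack = shifted_pair_stack(shift=3)
    est = mc.estimate_velocity(stack, (5, 1), (45, 1), radius=0, max_lag=5)
    assert est.lag == pytest.approx(3.0, abs=0.02)
    assert est.speed == pytest.approx(20.0 / 15.0, rel=0.02)
    assert est.direction == "p1->p2"


def test_swapping_points_negates_lag_and_preserves_speed(kymo_slow):
    stack, truth = kymo_slow
    cy = capillary_center_row(truth)
    a = mc.estimate_velocity(stack, (30, cy), (70, cy), radius=1, max_lag=25)
    b = mc.estimate_velocity(stack, (70, cy), (30, cy), radius=1, max_lag=25)
    assert a.lag == pytest.approx(-b.lag, abs=0.05)
    assert a.speed == pytest.approx(b.speed, rel=0.02)
    assert {a.direction, b.direction} == {"p1->p2", "p2->p1"}


def test_speed_is_invariant_to_affine_intensity_rescaling(kymo_slow):
    stack, truth = kymo_slow
    cy = capillary_center_row(truth)
    a = mc.estimate_velocity(stack, (30, cy), (70, cy), radius=1, max_lag=25)
    rescaled = mc.ImageStack(2.7 * stack.frames + 13.0,
                             frame_interval=stack.frame_interval,
                             pixel_size=stack.pixel_size)
    b = mc.estimate_velocity(rescaled, (30, cy), (70, cy), radius=1, max_lag=25)
    assert a.speed == pytest.approx(b.speed, rel=1e-6)
    assert a.lag == pytest.approx(b.lag, abs=1e-6)


def test_end_to_end_recovery_at_two_mm_per_s():
    cfg = mc.KymographSimConfig(n_frames=2000, frame_rate=200.0, pixel_size=0.5,
                                rbc_speed=2.0, seed=1)
    stack, truth = mc.make_kymograph_movie(cfg)
    cy = capillary_center_row(truth)
    est = mc.estimate_velocity(stack, (30, cy), (70, cy), radius=1, max_lag=25)
    assert est.speed == pytest.approx(2.0, rel=0.05)


def test_recovery_error_is_small_in_the_median_across_speeds_and_seeds():
    """Median |relative error| < 5% over 24 (speed, seed) conditions spanning
    0.5-8 mm/s at 200 Hz; individual errors blow up as the transit time per
    frame approaches the frame interval (the documented resolution limit)."""
    rng = np.random.default_rng(12345)
    errs = []
    for speed in (0.5, 1.0, 2.0, 4.0, 6.0, 8.0):
        for seed in range(4):
            dt = 1 / 200.0
            dx_um = rng.uniform(5.5, 6.5) * speed * 1000 * dt
            dx_px = max(4, round(dx_um / 0.5))
            cfg = mc.KymographSimConfig(
                n_frames=2000, frame_rate=200.0, pixel_size=0.5, rbc_speed=speed,
                capillary_length=dx_px * 0.5 + 30.0, noise_sd=8.0, seed=100 + seed)
            stack, truth = mc.make_kymograph_movie(cfg)
            cy = capillary_center_row(truth)
            est = mc.estimate_velocity(stack, (20, cy), (20 + dx_px, cy),
                                       radius=1, max_lag=60)
            errs.append(abs(est.speed - speed) / speed)
    assert np.median(errs) < 0.05


def test_velocity_error_cases():
    stack = shifted_pair_stack(shift=0)
    with pytest.raises(ValueError, match="unresolvable lag"):
        mc.estimate_velocity(stack, (5, 1), (45, 1), radius=0, max_lag=5)
    with pytest.raises(ValueError, match="distinct"):
        mc.estimate_velocity(stack, (5, 1), (5, 1))
    flat = mc.ImageStack(np.full((64, 4, 50), 9.0), frame_interval=0.005, pixel_size=0.5)
    with pytest.raises(ValueError, match="flat trace"):
        mc.estimate_velocity(flat, (5, 1), (45, 1), radius=0)
    nometa = mc.ImageStack(np.zeros((64, 4, 50)), frame_interval=0.005)
    with pytest.raises(ValueError, match="pixel_size"):
        mc.estimate_velocity(nometa, (5, 1), (45, 1))


# ---------------------------------------------------------------------------
# extract_kymograph
# ---------------------------------------------------------------------------

def test_kymograph_of_constant_movie_is_constant():
    stack = mc.ImageStack(np.full((10, 8, 30), 6.0))
    k = mc.extract_kymograph(stack, ((2, 4), (25, 4)))
    assert np.all(k == 6.0)
    assert k.shape[1] == 10


def test_kymograph_without_rbcs_has_no_dark_stripes():
    cfg = mc.KymographSimConfig(n_frames=64, hematocrit=0.0, noise_sd=1.0, seed=0)
    stack, truth = mc.make_kymograph_movie(cfg)
    cy = capillary_center_row(truth)
    k = mc.extract_kymograph(stack, ((5, cy), (100, cy)))
    assert k.min() > 90.0   # everything near plasma level


def test_kymograph_stripe_slope_matches_configured_speed():
    """Radon-transform orientation oracle on the kymograph recovers the
    configured speed within 10%."""
    from skimage.transform import radon

    speed = 0.4  # mm/s → 2 px/frame at 200 Hz and 0.5 μm/px
    cfg = mc.KymographSimConfig(n_frames=240, frame_rate=200.0, pixel_size=0.5,
                                capillary_length=60.0, rbc_speed=speed,
                                noise_sd=2.0, seed=7)
    stack, truth = mc.make_kymograph_movie(cfg)
    cy = capillary_center_row(truth)
    k = mc.extract_kymograph(stack, ((0, cy), (119, cy)))
    k = k[:, :120] - k[:, :120].mean()
    theta = np.linspace(5.0, 85.0, 321)
    sinogram = radon(k, theta=theta, circle=False)
    slope = 1.0 / np.tan(np.deg2rad(theta[np.argmax(sinogram.var(axis=0))]))
    speed_oracle = slope * cfg.pixel_size * cfg.frame_rate / 1000.0  # mm/s
    assert speed_oracle == pytest.approx(speed, rel=0.10)


def test_kymograph_rejects_zero_length_line():
    stack = mc.ImageStack(np.zeros((10, 8, 8)))
    with pytest.raises(ValueError, match="zero-length"):
        mc.extract_kymograph(stack, ((2, 2), (2, 2)))
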