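"""Arena simulator: determinism, confinement, event generation, rendering,
song synthesis."""

import numpy as np
import pytest

import flycourt as fc
from flycourt.errors import InvalidParameterError, OverlapError
from flycourt.sim import PulseBoutSpec, SineSpec


def test_identical_seeds_reproduce_and_different_seeds_differ():
    p7a = fc.SimParams(seed=7, epoch_schedule=[("low", 20, 0.4)])
    p7b = fc.SimParams(seed=7, epoch_schedule=[("low", 20, 0.4)])
    p8 = fc.SimParams(seed=8, epoch_schedule=[("low", 20, 0.4)])
    ta, _ = fc.simulate_arena(p7a)
    tb, _ = fc.simulate_arena(p7b)
    tc, _ = fc.simulate_arena(p8)
    assert np.array_equal(ta.positions, tb.positions)
    assert not np.array_equal(ta.positions, tc.positions)


@pytest.mark.parametrize("seed", [0, 3, 11])
def test_positions_confined_to_arena_disc(seed):
    params = fc.SimParams(seed=seed, epoch_schedule=[("high", 60, 18.0)])
    traj, _ = fc.simulate_arena(params)
    r = np.linalg.norm(traj.positions, axis=2)
    assert r.max() <= params.arena_radius_mm + 1e-9
    assert traj.n_frames == int(60 * params.frame_rate)
    assert traj.valid.all()


def test_zero_chase_rate_generates_no_events():
    params = fc.SimParams(seed=2, chase_rate=lambda i: 0.0,
                          epoch_schedule=[("high", 60, 18.0)])
    _, gt = fc.simulate_arena(params)
    assert gt.chase_events == []
    assert gt.chain_events == []


def test_ground_truth_event_invariants(default_sim):
    params, traj, gt = default_sim
    T = traj.n_frames
    assert len(gt.chase_events) > 0
    for e in gt.chase_events:
        assert 0 <= e.start < e.end <= T
        assert e.chaser != e.target
        assert 1 <= e.chaser <= params.n_flies
    for c in gt.chain_events:
        assert 0 <= c.start <= c.end <= T
        assert len(c.members) >= 3
        assert len(set(c.members)) == len(c.members)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_flies": 0},
        {"arena_radius_mm": -1.0},
        {"epoch_schedule": [("low", -5, 0.4)]},
        {"frame_rate": 0.0},
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(InvalidParameterError):
        fc.SimParams(**kwargs)


def test_chase_rate_curve_is_monotone_in_intensity():
    grid = [0.1, 0.4, 1.0, 2.0, 3.5, 6.0, 10.0, 18.0, 30.0]
    rates = [fc.default_chase_rate(i) for i in grid]
    assert all(b >= a for a, b in zip(rates, rates[1:]))
    # the curve separates the protocol's low and high settings decisively
    assert fc.default_chase_rate(18.0) > 50 * fc.default_chase_rate(0.4)


def test_mean_chase_count_increases_with_intensity():
    """More light, more chases: ground-truth counts over 20 seed pairs."""
    lo, hi = [], []
    for seed in range(20):
        _, gt_lo = fc.simulate_arena(
            fc.SimParams(seed=seed, epoch_schedule=[("low", 60, 0.4)]))
        _, gt_hi = fc.simulate_arena(
            fc.SimParams(seed=seed, epoch_schedule=[("high", 60, 18.0)]))
        lo.append(len(gt_lo.chase_events))
        hi.append(len(gt_hi.chase_events))
    assert np.mean(hi) > np.mean(lo)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def _static_trajectory(points_mm, n_frames=5, frame_rate=15.0):
    pos = np.repeat(np.asarray(points_mm, float)[:, None, :], n_frames, axis=1)
    return fc.TrajectorySet(positions=pos,
                            valid=np.ones((len(points_mm), n_frames), bool),
                            frame_rate=frame_rate)


def test_rendered_blob_centroid_matches_projection():
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    traj = _static_trajectory([[0.0, 0.0]])
    frame = next(fc.sim.iter_rendered_frames(traj, arena, noise_sigma=0.0))
    ys, xs = np.nonzero(frame < 128)
    cx, cy = arena.roi_centres[0]
    assert abs(xs.mean() - cx) <= 1.0
    assert abs(ys.mean() - cy) <= 1.0


def test_render_without_flies_leaves_background_clean():
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    traj = fc.TrajectorySet(positions=np.empty((0, 4, 2)),
                            valid=np.empty((0, 4), bool), frame_rate=15.0)
    frame = next(fc.sim.iter_rendered_frames(traj, arena, noise_sigma=0.0,
                                             draw_boundary=False))
    assert not (frame < 128).any()


def test_well_separated_flies_render_as_distinct_components():
    from scipy import ndimage

    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    pts = np.column_stack((8 * np.cos(ang), 8 * np.sin(ang)))
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    traj = _static_trajectory(pts)
    frame = next(fc.sim.iter_rendered_frames(traj, arena, noise_sigma=0.0,
                                             draw_boundary=False))
    _, n = ndimage.label(frame < 128)
    assert n == 8


def test_render_rejects_bad_scale():
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    arena.mm_per_px = -0.1
    traj = _static_trajectory([[0.0, 0.0]])
    with pytest.raises(InvalidParameterError):
        next(fc.sim.iter_rendered_frames(traj, arena))


# ----------------------------------------------------------------------
# song synthesis
# ----------------------------------------------------------------------

def test_empty_song_is_silence_unless_noise_requested():
    wave, gt = fc.synthesize_song([], sample_rate=10_000, duration_s=1.0)
    assert np.all(wave == 0)
    assert gt.song_elements == []
    noisy, _ = fc.synthesize_song([], sample_rate=10_000, duration_s=1.0,
                                  noise_snr_db=20, seed=0)
    assert noisy.std() > 0


def test_pulse_peak_spacing_matches_requested_ipi():
    fs = 10_000
    wave, _ = fc.synthesize_song(
        [PulseBoutSpec(start_s=0.2, n_pulses=10, ipi_s=0.035)],
        sample_rate=fs, duration_s=1.0)
    from scipy.signal import find_peaks

    env = np.abs(wave)
    peaks, _ = find_peaks(env, height=0.5 * env.max(), distance=int(0.02 * fs))
    assert len(peaks) == 10
    spacing = np.diff(peaks) / fs
    assert np.all(np.abs(spacing - 0.035) <= 1.0 / fs + 1e-12)


def test_sine_element_has_dominant_peak_at_requested_frequency():
    from scipy.signal import periodogram

    fs = 10_000
    wave, _ = fc.synthesize_song(
        [SineSpec(start_s=0.1, duration_s=0.5, freq_hz=150.0)],
        sample_rate=fs, duration_s=1.0)
    seg = wave[int(0.1 * fs): int(0.6 * fs)]
    freqs, pxx = periodogram(seg, fs=fs)
    assert abs(freqs[np.argmax(pxx)] - 150.0) <= freqs[1] - freqs[0]


def test_overlapping_song_elements_rejected():
    with pytest.raises(OverlapError):
        fc.synthesize_song(
            [SineSpec(start_s=0.0, duration_s=0.5, freq_hz=150.0),
             PulseBoutSpec(start_s=0.3, n_pulses=5, ipi_s=0.03)],
            sample_rate=10_000, duration_s=1.0)
    with pytest.raises(InvalidParameterError):
        fc.synthesize_song([SineSpec(start_s=0.8, duration_s=0.5, freq_hz=150.0)],
                           sample_rate=10_000, duration_s=1.0)
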