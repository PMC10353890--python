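"""Detection, identity linking and calibration."""

import numpy as np
import pytest

import flycourt as fc
from flycourt.errors import EmptyInputError, GeometryError, InvalidParameterError
from flycourt.tracking import DetectionSet, detect_flies, detect_sequence, link_identities

from conftest import identity_agreement, well_separated_mask


def _static_traj(points_mm, n_frames=5):
    pos = np.repeat(np.asarray(points_mm, float)[:, None, :], n_frames, axis=1)
    return fc.TrajectorySet(positions=pos,
                            valid=np.ones((len(points_mm), n_frames), bool),
                            frame_rate=15.0)


def test_detect_recovers_well_separated_centroids_within_one_pixel():
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    pts = np.column_stack((8 * np.cos(ang), 8 * np.sin(ang)))
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    traj = _static_traj(pts)
    frame = next(fc.sim.iter_rendered_frames(traj, arena, noise_sigma=0.0))
    found = detect_flies(frame, arena, expected_n=8)
    cents = np.array([b.centroid for b in found.rois[0]])
    assert len(cents) == 8
    cx, cy = arena.roi_centres[0]
    expected = np.column_stack((cx + pts[:, 0] / 0.1, cy - pts[:, 1] / 0.1))
    d = np.linalg.norm(expected[:, None, :] - cents[None, :, :], axis=2)
    assert d.min(axis=1).max() <= 1.0


def test_blank_frame_yields_no_detections_without_error():
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    h, w = arena.frame_shape
    frame = np.full((h, w), 220, dtype=np.uint8)
    found = detect_flies(frame, arena, expected_n=8)
    assert found.rois[0] == []


def test_close_pair_is_flagged_as_merged():
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    traj = _static_traj([[0.0, 0.0], [1.0, 0.0]])
    frame = next(fc.sim.iter_rendered_frames(traj, arena, noise_sigma=0.0))
    found = detect_flies(frame, arena, expected_n=2)
    assert len(found.rois[0]) == 1
    assert found.rois[0][0].merged


def test_frame_smaller_than_roi_raises_geometry_error():
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    with pytest.raises(GeometryError):
        detect_flies(np.full((50, 50), 220, np.uint8), arena, expected_n=8)


def test_arena_scale_consistency_enforced():
    with pytest.raises(InvalidParameterError):
        fc.ArenaConfig(roi_centres=[(100, 100)], roi_radius_px=100,
                       mm_per_px=0.2)  # implies 40 mm diameter, not 26


def test_single_fly_track_equals_detections_in_mm():
    rng = np.random.default_rng(0)
    steps = rng.normal(0, 0.2, size=(60, 2))
    pos = np.cumsum(steps, axis=0)[None, :, :]
    traj = fc.TrajectorySet(positions=pos, valid=np.ones((1, 60), bool),
                            frame_rate=15.0)
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    frames = fc.sim.iter_rendered_frames(traj, arena, noise_sigma=0.0)
    tracked = fc.track_frames(frames, arena, expected_n=1)
    err = np.linalg.norm(tracked.positions - traj.positions, axis=2)
    assert err.max() < 0.15  # within ~1.5 px of the rendered truth
    assert tracked.valid.all()


def test_parallel_non_crossing_tracks_keep_identities():
    T = 100
    t = np.arange(T) / 15.0
    pos = np.zeros((2, T, 2))
    pos[0, :, 0] = -8 + 3 * t
    pos[0, :, 1] = 4.0
    pos[1, :, 0] = -8 + 3 * t
    pos[1, :, 1] = -4.0
    traj = fc.TrajectorySet(positions=pos, valid=np.ones((2, T), bool), frame_rate=15.0)
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    tracked = fc.track_frames(fc.sim.iter_rendered_frames(traj, arena, noise_sigma=0.0),
                              arena, expected_n=2)
    agree, err, _ = identity_agreement(traj, tracked)
    assert agree == 1.0


def test_linking_is_invariant_to_detection_order_within_frames(short_low_sim):
    _, traj, _ = short_low_sim
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    frames = list(fc.sim.iter_rendered_frames(traj, arena, seed=1))[:200]
    dets = detect_sequence(frames, arena, expected_n=8)
    shuffled = DetectionSet()
    rng = np.random.default_rng(0)
    for fd in dets:
        rois = []
        for blobs in fd.rois:
            blobs = list(blobs)
            rng.shuffle(blobs)
            rois.append(blobs)
        shuffled.append(type(fd)(rois=rois))
    a = link_identities(dets, arena, expected_n=8)
    b = link_identities(shuffled, arena, expected_n=8)
    assert np.allclose(a.positions, b.positions)
    assert np.array_equal(a.valid, b.valid)


def test_linking_requires_frames():
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    with pytest.raises(EmptyInputError):
        link_identities(DetectionSet(), arena, expected_n=8)


def test_round_trip_tracks_default_arena(short_low_sim):
    """simulate -> render -> detect -> link recovers identities and positions."""
    _, traj, _ = short_low_sim
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    frames = fc.sim.iter_rendered_frames(traj, arena, seed=99)
    tracked = fc.track_frames(frames, arena, expected_n=8)
    assert tracked.n_flies == 8  # conservation of tracks
    agree, err, perm = identity_agreement(traj, tracked)
    assert agree >= 0.95
    sep = well_separated_mask(traj, perm)
    ok = sep & tracked.valid
    rms_px = np.sqrt(np.mean(err[ok] ** 2)) / arena.mm_per_px
    assert rms_px <= 1.0


def test_calibrate_scale_from_drawn_circle():
    img = np.full((300, 300), 220.0)
    yy, xx = np.mgrid[0:300, 0:300]
    rr = np.hypot(xx - 150, yy - 150)
    img[np.abs(rr - 130) < 1.5] = 80
    scale = fc.calibrate_scale(img, known_diameter_mm=26.0)
    assert scale == pytest.approx(0.1, rel=0.02)


def test_calibrate_scale_round_trip_through_renderer(short_low_sim):
    _, traj, _ = short_low_sim
    arena = fc.ArenaConfig.single_roi(mm_per_px=0.1)
    frame = next(fc.sim.iter_rendered_frames(traj, arena, seed=0))
    scale = fc.calibrate_scale(frame, known_diameter_mm=26.0)
    assert scale == pytest.approx(arena.mm_per_px, rel=0.02)
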