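"""Interactograms, chase and chain detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flycourt as fc
from flycourt.errors import AlignmentError, InvalidParameterError
from flycourt.social import interactogram_segments

from conftest import (
    brute_force_interactogram,
    make_follow_line,
    make_stationary_cluster,
)


def _pair_at(distance_mm, n_frames=30):
    pos = np.zeros((2, n_frames, 2))
    pos[1, :, 0] = distance_mm
    return fc.TrajectorySet(positions=pos, valid=np.ones((2, n_frames), bool),
                            frame_rate=15.0)


def test_coincident_flies_always_interact():
    ig = fc.compute_interactogram(_pair_at(0.0))
    assert ig.tensor[0, 1].all() and ig.tensor[1, 0].all()
    assert not ig.tensor[0, 0].any()


def test_proximity_criterion_is_strict_at_the_boundary():
    """Centroids exactly at the criterion distance do not count as interacting."""
    ig = fc.compute_interactogram(_pair_at(3.75))
    assert not ig.tensor.any()
    ig = fc.compute_interactogram(_pair_at(3.75 - 1e-6))
    assert ig.tensor[0, 1].all()


def test_interactogram_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    params = fc.InteractionParams()
    for _ in range(10):
        pos = rng.uniform(-13, 13, size=(8, 50, 2))
        valid = rng.random((8, 50)) > 0.05
        traj = fc.TrajectorySet(positions=pos, valid=valid, frame_rate=15.0)
        ig = fc.compute_interactogram(traj, params)
        assert np.array_equal(ig.tensor, brute_force_interactogram(traj, params.proximity_mm))


def test_invalid_frames_are_never_interactions():
    traj = _pair_at(1.0)
    traj.valid[0, 10:20] = False
    ig = fc.compute_interactogram(traj)
    assert not ig.tensor[:, :, 10:20].any()
    assert ig.tensor[0, 1, :10].all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_interactogram_symmetric_irreflexive_and_monotone(seed):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-13, 13, size=(4, 20, 2))
    traj = fc.TrajectorySet(positions=pos, valid=np.ones((4, 20), bool), frame_rate=15.0)
    small = fc.compute_interactogram(traj, fc.InteractionParams(proximity_mm=3.75))
    large = fc.compute_interactogram(traj, fc.InteractionParams(proximity_mm=6.0))
    assert np.array_equal(small.tensor, np.swapaxes(small.tensor, 0, 1))
    assert not np.einsum("iif->if", small.tensor).any()
    # enlarging the criterion never removes an interaction
    assert not (small.tensor & ~large.tensor).any()


def test_mismatched_axes_raise_alignment_error():
    a = _pair_at(1.0, n_frames=30)
    b = _pair_at(1.0, n_frames=20)
    ig = fc.compute_interactogram(b)
    with pytest.raises(AlignmentError):
        fc.detect_chases(a, ig)


def test_chain_min_size_must_be_sensible():
    with pytest.raises(InvalidParameterError):
        fc.InteractionParams(chain_min_size=1)


# ----------------------------------------------------------------------
# chase detection
# ----------------------------------------------------------------------

def test_sustained_pursuit_yields_one_chase_with_correct_roles():
    traj = make_follow_line(2, duration_s=3.0, spacing_mm=2.0)
    ig = fc.compute_interactogram(traj)
    chases = fc.detect_chases(traj, ig)
    assert len(chases) == 1
    ev = chases[0]
    # fly 2 trails fly 1 in the constructed line
    assert (ev.chaser, ev.target) == (2, 1)
    assert ev.duration_s(traj.frame_rate) >= 2.5


def test_stationary_proximity_is_not_chasing():
    traj = _pair_at(1.0, n_frames=60)
    ig = fc.compute_interactogram(traj)
    assert fc.detect_chases(traj, ig) == []


def test_brief_pursuit_below_minimum_duration_is_ignored():
    traj = make_follow_line(2, duration_s=0.5, spacing_mm=2.0)
    ig = fc.compute_interactogram(traj)
    assert fc.detect_chases(traj, ig) == []


def test_masked_frames_break_chase_runs():
    traj = make_follow_line(2, duration_s=2.0, spacing_mm=2.0)
    traj.valid[0, 14:16] = False  # 0.93 s on either side of the gap
    ig = fc.compute_interactogram(traj)
    assert fc.detect_chases(traj, ig) == []


# ----------------------------------------------------------------------
# chain detection
# ----------------------------------------------------------------------

def test_four_fly_follow_line_is_one_chain():
    traj = make_follow_line(4, duration_s=2.0)
    ig = fc.compute_interactogram(traj)
    chains = fc.detect_chains(traj, ig)
    assert len(chains) == 1
    assert set(chains[0].members) == {1, 2, 3, 4}
    assert chains[0].mean_speed_mm_s >= 2.0


def test_three_fly_follow_line_is_below_the_chain_minimum():
    traj = make_follow_line(3, duration_s=2.0)
    ig = fc.compute_interactogram(traj)
    assert fc.detect_chains(traj, ig) == []


def test_stationary_cluster_is_not_a_mobile_chain():
    traj = make_stationary_cluster(5)
    ig = fc.compute_interactogram(traj)
    assert fc.detect_chains(traj, ig) == []


def test_two_concurrent_follow_lines_are_separate_chains():
    a = make_follow_line(4, duration_s=2.0)
    b = make_follow_line(4, duration_s=2.0)
    pos = np.concatenate([a.positions, b.positions + [0.0, 30.0]], axis=0)
    traj = fc.TrajectorySet(positions=pos, valid=np.ones((8, a.n_frames), bool),
                            frame_rate=15.0)
    ig = fc.compute_interactogram(traj)
    chains = fc.detect_chains(traj, ig)
    assert len(chains) == 2
    assert {frozenset(c.members) for c in chains} == {
        frozenset({1, 2, 3, 4}), frozenset({5, 6, 7, 8})}


# ----------------------------------------------------------------------
# interactogram rendering
# ----------------------------------------------------------------------

def test_interactogram_figure_and_segments():
    import matplotlib

    matplotlib.use("Agg")
    n, T = 3, 60
    tensor = np.zeros((n, n, T), bool)
    tensor[0, 1, 10:21] = True
    tensor[1, 0, 10:21] = True
    ig = fc.Interactogram(tensor=tensor, fly_ids=np.arange(1, n + 1), frame_rate=15.0)
    segs = interactogram_segments(ig)
    assert segs[(1, 2)] == [(10 / 15.0, 21 / 15.0)]
    assert segs[(2, 1)] == segs[(1, 2)]  # reciprocal bands mirror each other
    assert segs[(1, 3)] == []
    fig = fc.render_interactogram(ig)
    assert fig is not None
    # an all-false interactogram renders bands with no segments
    empty = fc.Interactogram(tensor=np.zeros_like(tensor), fly_ids=ig.fly_ids,
                             frame_rate=15.0)
    assert all(v == [] for v in interactogram_segments(empty).values())


# ----------------------------------------------------------------------
# detector performance against the simulator's ground truth
# ----------------------------------------------------------------------

def test_detectors_recover_simulated_events(default_sim):
    from conftest import chase_recall_precision, chain_recall_precision

    params, traj, gt = default_sim
    ip = fc.InteractionParams()
    ig = fc.compute_interactogram(traj, ip)
    chases = fc.detect_chases(traj, ig, ip)
    chains = fc.detect_chains(traj, ig, ip)
    rec, prec = chase_recall_precision(gt, chases, traj.frame_rate)
    assert rec >= 0.9 and prec >= 0.8
    crec, cprec = chain_recall_precision(gt, chains, traj.frame_rate)
    assert crec is None or crec >= 0.8
    assert cprec is None or cprec >= 0.8
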