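"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import flycourt as fc
from flycourt.events import interval_overlap


# ----------------------------------------------------------------------
# constructed trajectory fixtures
# ----------------------------------------------------------------------

def make_follow_line(
    n_flies: int,
    duration_s: float = 3.0,
    spacing_mm: float = 3.0,
    speed_mm_s: float = 4.0,
    frame_rate: float = 15.0,
    extra_stationary: int = 0,
) -> fc.TrajectorySet:
    """Noiseless single-file line moving along +x, leader first (fly 1)."""
    T = int(round(duration_s * frame_rate))
    total = n_flies + extra_stationary
    pos = np.zeros((total, T, 2))
    t = np.arange(T) / frame_rate
    for m in range(n_flies):
        pos[m, :, 0] = speed_mm_s * t - m * spacing_mm
    for k in range(extra_stationary):
        pos[n_flies + k, :, 0] = 50.0 + 10 * k  # far away, parked
    return fc.TrajectorySet(
        positions=pos,
        valid=np.ones((total, T), dtype=bool),
        frame_rate=frame_rate,
    )


def make_stationary_cluster(n_flies: int, radius_mm: float = 1.5,
                            duration_s: float = 3.0, frame_rate: float = 15.0) -> fc.TrajectorySet:
    """Motionless flies packed inside the proximity criterion."""
    T = int(round(duration_s * frame_rate))
    ang = np.linspace(0, 2 * np.pi, n_flies, endpoint=False)
    base = np.column_stack((radius_mm * np.cos(ang), radius_mm * np.sin(ang)))
    pos = np.repeat(base[:, None, :], T, axis=1)
    return fc.TrajectorySet(positions=pos, valid=np.ones((n_flies, T), bool),
                            frame_rate=frame_rate)


# ----------------------------------------------------------------------
# oracle helpers
# ----------------------------------------------------------------------

def brute_force_interactogram(traj: fc.TrajectorySet, proximity_mm: float) -> np.ndarray:
    """Straightforward double loop over pairs and frames (independent oracle)."""
    n, T = traj.n_flies, traj.n_frames
    out = np.zeros((n, n, T), dtype=bool)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            for f in range(T):
                if not (traj.valid[a, f] and traj.valid[b, f]):
                    continue
                dx = traj.positions[a, f, 0] - traj.positions[b, f, 0]
                dy = traj.positions[a, f, 1] - traj.positions[b, f, 1]
                if (dx * dx + dy * dy) ** 0.5 < proximity_mm:
                    out[a, b, f] = True
    return out


def union_coverage(start: int, end: int, intervals) -> int:
    """Frames of [start, end) covered by the union of the given intervals."""
    cov, t = 0, start
    for s, e in sorted(intervals):
        s, e = max(s, start), min(e, end)
        if e > max(s, t):
            cov += e - max(s, t)
            t = e
    return cov


def chase_recall_precision(gt, detected, frame_rate, min_duration_s=1.0):
    """Event-level recall/precision of chase detections vs ground truth.

    A ground-truth chase counts as recovered when a detection of the same
    (chaser, target) pair overlaps at least half of it; a detection is a true
    positive when same-pair ground-truth events cover at least half of it.
    Ground-truth events shorter than the detector's minimum duration are not
    scored for recall (they are unresolvable by definition).
    """
    gtc = [e for e in gt.chase_events if e.duration_s(frame_rate) >= min_duration_s]
    hits = 0
    for g in gtc:
        for d in detected:
            if (d.chaser, d.target) != (g.chaser, g.target):
                continue
            if interval_overlap(g.start, g.end, d.start, d.end) >= 0.5 * (g.end - g.start):
                hits += 1
                break
    recall = hits / len(gtc) if gtc else None
    tp = 0
    for d in detected:
        cov = sum(
            interval_overlap(g.start, g.end, d.start, d.end)
            for g in gt.chase_events
            if (d.chaser, d.target) == (g.chaser, g.target)
        )
        if cov >= 0.5 * (d.end - d.start):
            tp += 1
    precision = tp / len(detected) if detected else None
    return recall, precision


def chain_recall_precision(gt, detected, frame_rate, min_size=4, min_duration_s=1.0):
    """Event-level recall/precision of chain detections vs ground truth.

    Recall is against logged chain events of the detector-relevant size.  For
    precision, a detected chain is credited when ground-truth courtship
    activity (chase or chain events) among its members covers at least half
    of its interval: the generator logs chains per pursuit, so two pursuits
    falling into one file — genuinely a chain on video — carry chase-event
    ground truth rather than a chain record.
    """
    gtch = [
        c for c in gt.chain_events
        if len(c.members) >= min_size and c.duration_s(frame_rate) >= min_duration_s
    ]
    hits = sum(
        1
        for g in gtch
        if any(
            interval_overlap(g.start, g.end, d.start, d.end) >= 0.5 * (g.end - g.start)
            for d in detected
        )
    )
    recall = hits / len(gtch) if gtch else None
    tp = 0
    for d in detected:
        mem = set(d.members)
        ivals = [(g.start, g.end) for g in gt.chain_events]
        ivals += [
            (g.start, g.end)
            for g in gt.chase_events
            if g.chaser in mem and g.target in mem
        ]
        if union_coverage(d.start, d.end, ivals) >= 0.5 * (d.end - d.start):
            tp += 1
    precision = tp / len(detected) if detected else None
    return recall, precision


def identity_agreement(truth: fc.TrajectorySet, tracked: fc.TrajectorySet,
                       tol_mm: float = 2.0):
    """Fraction of fly-frames where tracked identities follow the true flies.

    Identities are paired by first-frame positions (the labelling is
    arbitrary); agreement is the fraction of fly-frames within ``tol_mm`` of
    the paired true fly.  Also returns the per-fly-frame error matrix and
    the permutation used.
    """
    d0 = np.linalg.norm(
        tracked.positions[:, None, 0, :] - truth.positions[None, :, 0, :], axis=2
    )
    r, c = linear_sum_assignment(d0)
    perm = c[np.argsort(r)]
    err = np.linalg.norm(tracked.positions - truth.positions[perm], axis=2)
    return float((err < tol_mm).mean()), err, perm


def well_separated_mask(truth: fc.TrajectorySet, perm, min_sep_mm: float = 3.0):
    """Fly-frames whose nearest neighbour (in truth) is at least min_sep away."""
    dd = np.linalg.norm(
        truth.positions[:, None, :, :] - truth.positions[None, :, :, :], axis=3
    )
    idx = np.arange(truth.n_flies)
    dd[idx, idx, :] = np.inf
    return dd.min(axis=1)[perm] > min_sep_mm


@pytest.fixture(scope="session")
def short_low_sim():
    """One 60-s low-light arena (900 frames), shared across tests."""
    params = fc.SimParams(seed=5, epoch_schedule=[("low", 60.0, 0.4)])
    traj, gt = fc.simulate_arena(params)
    return params, traj, gt


@pytest.fixture(scope="session")
def default_sim():
    """One full low/high/low protocol arena, shared across tests."""
    params = fc.SimParams(seed=1)
    traj, gt = fc.simulate_arena(params)
    return params, traj, gt
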