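"""Pairwise proximity structure and social-event detection.

The *interactogram* marks, for every ordered fly pair and frame, whether the
two centroids are closer than the interaction proximity criterion
(3.75 mm — the separation that best captures chasing between fly centroids
in a 26-mm arena; the comparison is strict ``<``).  Chases and mobile
follow-line chains are detected from the interactogram plus kinematic
criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, InvalidParameterError
from .events import ChainEvent, ChaseEvent
from .trajectories import TrajectorySet

__all__ = [
    "InteractionParams",
    "Interactogram",
    "compute_interactogram",
    "detect_chases",
    "detect_chains",
    "render_interactogram",
]


@dataclass
class InteractionParams:
    """Thresholds for proximity, chase and chain detection.

    ``proximity_mm`` is the interaction criterion between centroids (strict
    ``<``).  A chase requires sustained proximity, both flies moving at
    ``chain_min_speed_mm_s`` or more, and the chaser's displacement heading
    within ``heading_alignment_deg`` of the bearing to its target, for at
    least ``min_chase_duration_s``.  A chain is a mobile single-file line of
    at least ``chain_min_size`` flies.
    """

    proximity_mm: float = 3.75
    min_chase_duration_s: float = 1.0
    heading_alignment_deg: float = 60.0
    chain_min_size: int = 4
    chain_min_speed_mm_s: float = 2.0
    chain_min_duration_s: float = 1.0
    speed_smooth_frames: int = 3
    require_nearest_target: bool = True
    nearest_tolerance_mm: float = 0.5
    max_gap_s: float = 0.3

    def __post_init__(self):
        if self.proximity_mm <= 0:
            raise InvalidParameterError("proximity_mm must be positive")
        if self.chain_min_size < 2:
            raise InvalidParameterError("chain_min_size must be >= 2")
        for name in ("min_chase_duration_s", "chain_min_duration_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass
class Interactogram:
    """Boolean proximity tensor indexed (fly A, fly B, frame).

    Symmetric in (A, B) with a False diagonal; entries at frames where either
    fly's position is invalid are False.
    """

    tensor: np.ndarray  # bool, (n, n, T)
    fly_ids: np.ndarray
    frame_rate: float
    proximity_mm: float = 3.75

    @property
    def n_flies(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_frames(self) -> int:
        return self.tensor.shape[2]


def compute_interactogram(
    traj: TrajectorySet, params: InteractionParams | None = None
) -> Interactogram:
    """Mark every ordered pair and frame with sub-threshold centroid proximity.

    Entry (A, B, f) is True iff the Euclidean centroid distance at frame f is
    strictly less than ``params.proximity_mm`` and both positions are valid.
    """
    params = params or InteractionParams()
    if traj.n_flies < 2:
        raise InvalidParameterError("interactogram needs at least 2 flies")
    p = traj.positions  # (n, T, 2)
    diff = p[:, None, :, :] - p[None, :, :, :]
    dist = np.linalg.norm(diff, axis=3)  # (n, n, T)
    tensor = dist < params.proximity_mm
    both_valid = traj.valid[:, None, :] & traj.valid[None, :, :]
    tensor &= both_valid
    idx = np.arange(traj.n_flies)
    tensor[idx, idx, :] = False
    return Interactogram(
        tensor=tensor,
        fly_ids=traj.fly_ids.copy(),
        frame_rate=traj.frame_rate,
        proximity_mm=params.proximity_mm,
    )


def _check_aligned(traj: TrajectorySet, ig: Interactogram) -> None:
    if ig.n_frames != traj.n_frames or ig.n_flies != traj.n_flies:
        raise AlignmentError(
            "interactogram frame/fly axes do not match the trajectory set"
        )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts, ends))


def _close_gaps(mask: np.ndarray, max_gap: int, hard_break: np.ndarray | None = None) -> np.ndarray:
    """Fill False gaps of up to ``max_gap`` frames between True runs.

    Brief dropouts of a per-frame criterion (one fly clipping another's
    heading cone, a single sub-threshold speed sample) should not fragment a
    behavioural event.  Frames marked in ``hard_break`` (e.g. tracking gaps)
    are never filled.
    """
    if max_gap <= 0 or not mask.any():
        return mask
    out = mask.copy()
    runs = _runs(mask)
    for (s0, e0), (s1, e1) in zip(runs, runs[1:]):
        if s1 - e0 <= max_gap:
            if hard_break is not None and hard_break[e0:s1].any():
                continue
            out[e0:s1] = True
    return out


def detect_chases(
    traj: TrajectorySet,
    ig: Interactogram,
    params: InteractionParams | None = None,
) -> list[ChaseEvent]:
    """Find sustained directed pursuits between fly pairs.

    For an ordered pair (chaser, target), a frame qualifies when the pair is
    in proximity, both flies move at or above the mobility criterion, and the
    chaser's displacement heading points within the alignment tolerance of
    the bearing to the target.  With ``require_nearest_target`` (the default)
    the target must additionally be the chaser's nearest fly *within its
    heading cone*, to within ``nearest_tolerance_mm`` — a chaser pursues the
    closest fly ahead of it, which suppresses spurious pairings inside dense
    groups and between non-consecutive members of a follow-line (a chaser's
    own follower sits behind it and so never competes).  Maximal qualifying
    runs of at least ``min_chase_duration_s`` become :class:`ChaseEvent`
    records.  Invalid (masked) frames break runs.
    """
    params = params or InteractionParams()
    _check_aligned(traj, ig)
    n = traj.n_flies
    pursuit = _pursuit_mask(traj, ig, params)  # (n, n, T)
    min_frames = max(1, int(round(params.min_chase_duration_s * traj.frame_rate)))
    gap = int(round(params.max_gap_s * traj.frame_rate))

    events: list[ChaseEvent] = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            invalid = ~(traj.valid[i] & traj.valid[j])
            ok = _close_gaps(pursuit[i, j], gap, hard_break=invalid)
            for s, e in _runs(ok):
                if e - s >= min_frames:
                    events.append(
                        ChaseEvent(
                            chaser=int(traj.fly_ids[i]),
                            target=int(traj.fly_ids[j]),
                            start=int(s),
                            end=int(e),
                        )
                    )
    events.sort(key=lambda ev: (ev.start, ev.chaser, ev.target))
    return events


def _pursuit_mask(
    traj: TrajectorySet, ig: Interactogram, params: InteractionParams
) -> np.ndarray:
    """Per-frame directed pursuit predicate: (chaser i, target j, frame).

    True where the pair is in proximity, both flies meet the mobility
    criterion, i's displacement heading points within the alignment tolerance
    of the bearing to j and (optionally) j is i's nearest fly inside that
    heading cone.  Shared by the chase and chain detectors: a chain is a
    directed path of pursuit links, each fly courting the one ahead.
    """
    n = traj.n_flies
    vel = traj.velocities(smooth_frames=params.speed_smooth_frames)
    speed = np.linalg.norm(vel, axis=2)
    moving = np.where(np.isfinite(speed), speed, 0.0) >= params.chain_min_speed_mm_s
    cos_tol = math.cos(math.radians(params.heading_alignment_deg))

    diff = traj.positions[None, :, :, :] - traj.positions[:, None, :, :]  # i -> j
    dist = np.linalg.norm(diff, axis=3)  # (n, n, T)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("itk,ijtk->ijt", vel, diff) / (dist * speed[:, None, :])
    cosang = np.where(np.isfinite(cosang), cosang, -1.0)
    aligned = cosang >= cos_tol

    ok = ig.tensor & aligned
    ok &= moving[:, None, :] & moving[None, :, :]
    ok &= traj.valid[:, None, :] & traj.valid[None, :, :]
    if params.require_nearest_target:
        cone_dist = np.where(aligned, dist, np.inf)
        idx = np.arange(n)
        cone_dist[idx, idx, :] = np.inf
        nearest_in_cone = cone_dist.min(axis=1)  # (n, T)
        ok &= dist <= nearest_in_cone[:, None, :] + params.nearest_tolerance_mm
    idx = np.arange(n)
    ok[idx, idx, :] = False
    return ok


def _longest_directed_path(succ: dict[int, list[int]], nodes: list[int]) -> list[int]:
    """Longest simple directed path in a small graph, by exhaustive DFS.

    Graphs here have at most 8 nodes (one fly each), so exhaustive search is
    exact and cheap.  Ties break on the lexicographically smallest sequence.
    Cycles ('wheels' of mutually courting flies) are handled because the
    path must be simple.
    """
    best: list[int] = []

    def extend(path: list[int], seen: set[int]) -> None:
        nonlocal best
        last = path[-1]
        extended = False
        for nb in succ.get(last, ()):
            if nb not in seen:
                extended = True
                path.append(nb)
                seen.add(nb)
                extend(path, seen)
                seen.remove(nb)
                path.pop()
        if not extended and (
            len(path) > len(best) or (len(path) == len(best) and path < best)
        ):
            best = list(path)

    for start in sorted(nodes):
        extend([start], {start})
    return best


def detect_chains(
    traj: TrajectorySet,
    ig: Interactogram,
    params: InteractionParams | None = None,
) -> list[ChainEvent]:
    """Find mobile single-file follow-lines of ``chain_min_size`` or more flies.

    A chain is a single-file line in which each fly courts the fly ahead, so
    per frame the detector builds the *directed pursuit graph* (the same
    per-frame predicate the chase detector uses: proximity + mutual motion +
    heading-to-bearing alignment) and searches it for a simple directed path
    of at least ``chain_min_size`` flies — follower to leader.  Candidate
    frames are stitched into an event while the member set overlaps by at
    least 50% frame-to-frame; an event must last ``chain_min_duration_s``
    and be *mobile*: every member's mean speed over the event must meet
    ``chain_min_speed_mm_s``.
    """
    params = params or InteractionParams()
    _check_aligned(traj, ig)
    n, T = traj.n_flies, traj.n_frames
    speed = traj.speeds(smooth_frames=params.speed_smooth_frames)
    pursuit = _pursuit_mask(traj, ig, params)
    gap = int(round(params.max_gap_s * traj.frame_rate))
    # stabilize each directed link over brief dropouts, as for chases
    stable = np.empty_like(pursuit)
    for i in range(n):
        for j in range(n):
            invalid = ~(traj.valid[i] & traj.valid[j])
            stable[i, j] = _close_gaps(pursuit[i, j], gap, hard_break=invalid)

    # disjoint directed follow-paths per frame (several chains can coexist)
    cands: list[list[list[int]]] = []
    for f in range(T):
        adj = stable[:, :, f]
        found: list[list[int]] = []
        if adj.sum() >= params.chain_min_size - 1:
            remaining = adj.copy()
            while True:
                succ = {
                    i: list(np.nonzero(remaining[i])[0])
                    for i in range(n)
                    if remaining[i].any()
                }
                if not succ:
                    break
                nodes = sorted(set(succ) | {j for js in succ.values() for j in js})
                p = _longest_directed_path(succ, nodes)
                if len(p) < params.chain_min_size:
                    break
                found.append([int(x) for x in p[::-1]])  # leader first
                remaining[p, :] = False
                remaining[:, p] = False
        cands.append(found)

    min_frames = max(1, int(round(params.chain_min_duration_s * traj.frame_rate)))
    max_gap = int(round(params.max_gap_s * traj.frame_rate))
    events: list[ChainEvent] = []
    active: list[dict] = []

    def finalize(run: dict) -> None:
        start, end = run["start"], run["frames"][-1] + 1
        if end - start < min_frames:
            return
        rep = max(run["members_by_frame"], key=len)  # longest observed line
        # mobility: each member must move, on average, while it is part of
        # the line (not over frames before it joined or after it left)
        frames_of: dict[int, list[int]] = {m: [] for m in rep}
        for fr, p in zip(run["frames"], run["members_by_frame"]):
            for m in p:
                if m in frames_of:
                    frames_of[m].append(fr)
        member_means = np.array(
            [np.nanmean(speed[m, frames_of[m]]) if frames_of[m] else 0.0 for m in rep]
        )
        mean_speed = float(np.nanmean(speed[np.ix_(rep, np.arange(start, end))]))
        if member_means.min() >= params.chain_min_speed_mm_s:
            events.append(
                ChainEvent(
                    members=tuple(int(traj.fly_ids[m]) for m in rep),
                    start=int(start),
                    end=int(end),
                    mean_speed_mm_s=mean_speed,
                )
            )

    for f in range(T):
        unmatched = set(range(len(active)))
        new_runs: list[dict] = []
        for path in cands[f]:
            cur = set(path)
            best, best_ov = None, 0.0
            for k in unmatched:
                prev = set(active[k]["members_by_frame"][-1])
                ov = len(prev & cur) / max(len(prev), len(cur))
                if ov > best_ov:
                    best_ov, best = ov, k
            if best is not None and best_ov >= 0.5:
                run = active[best]
                run["members_by_frame"].append(path)
                run["frames"].append(f)
                run["gap"] = 0
                unmatched.discard(best)
            else:
                new_runs.append(
                    {"start": f, "frames": [f], "members_by_frame": [path], "gap": 0}
                )
        survivors = []
        for k, run in enumerate(active):
            if k not in unmatched:
                survivors.append(run)
                continue
            run["gap"] += 1
            if run["gap"] > max_gap:
                finalize(run)
            else:
                survivors.append(run)
        active = survivors + new_runs
    for run in active:
        finalize(run)
    events.sort(key=lambda ev: ev.start)
    return events


# ----------------------------------------------------------------------
# interactogram figure
# ----------------------------------------------------------------------

def render_interactogram(ig: Interactogram, ax=None):
    """Draw the interactogram: one horizontal band per fly, darker segments
    for intervals when a given partner is within the proximity criterion.

    Colours are assigned deterministically by fly id (matplotlib tab10/tab20
    cycle).  Returns the matplotlib Figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    n, T = ig.n_flies, ig.n_frames
    cmap = plt.get_cmap("tab10" if n <= 10 else "tab20")
    colours = {i: cmap(i % cmap.N) for i in range(n)}

    if ax is None:
        fig, ax = plt.subplots(figsize=(10, 0.6 * n + 1))
    else:
        fig = ax.figure
    fr = ig.frame_rate
    band_h = 1.0
    sub_h = band_h / max(n - 1, 1)
    for a in range(n):
        y0 = a * (band_h + 0.25)
        ax.add_patch(
            Rectangle((0, y0), T / fr, band_h, color=colours[a], alpha=0.2, lw=0)
        )
        row = 0
        for b in range(n):
            if b == a:
                continue
            for s, e in _runs(ig.tensor[a, b]):
                ax.add_patch(
                    Rectangle(
                        (s / fr, y0 + row * sub_h),
                        (e - s) / fr,
                        sub_h,
                        color=colours[b],
                        lw=0,
                    )
                )
            row += 1
    ax.set_xlim(0, T / fr)
    ax.set_ylim(-0.25, n * (band_h + 0.25))
    ax.set_yticks([a * (band_h + 0.25) + band_h / 2 for a in range(n)])
    ax.set_yticklabels([f"fly {int(ig.fly_ids[a])}" for a in range(n)])
    ax.set_xlabel("time (s)")
    return fig


def interactogram_segments(ig: Interactogram) -> dict[tuple[int, int], list[tuple[float, float]]]:
    """Per ordered pair, the (start_s, end_s) proximity segments (plot data)."""
    out: dict[tuple[int, int], list[tuple[float, float]]] = {}
    fr = ig.frame_rate
    for a in range(ig.n_flies):
        for b in range(ig.n_flies):
            if a == b:
                continue
            segs = [(s / fr, e / fr) for s, e in _runs(ig.tensor[a, b])]
            out[(int(ig.fly_ids[a]), int(ig.fly_ids[b]))] = segs
    return out
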