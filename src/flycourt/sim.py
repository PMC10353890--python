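"""Agent-based synthetic arena: trajectories, video frames and song audio.

The simulator emulates the standard light-protocol experiment: eight male
flies in a 26-mm circular arena, filmed at 15 frames/s, exposed to a
2-min low / 2-min high / 2-min low illuminance schedule.  Flies perform a
correlated random walk; with a light-intensity-dependent rate a fly starts
pursuing its nearest neighbour (a chase), and an ongoing chase can recruit
further flies into a single-file follow-line (a chain).  Every generated
event is logged in a :class:`SimGroundTruth`, which downstream detectors are
tested against.

The locomotion model is deliberately minimal — constant-speed agents with
heading noise, pursuit steering with a capped turn rate, and a reflecting
arena boundary — because the quantities the analysis pipeline measures
(proximity structure, event intervals, interval scores) depend on the
interaction bookkeeping, not on fine kinematic realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import InvalidParameterError, OverlapError
from .events import ChainEvent, ChaseEvent
from .trajectories import TrajectorySet

__all__ = [
    "SimParams",
    "SimGroundTruth",
    "PulseBoutSpec",
    "SineSpec",
    "default_chase_rate",
    "simulate_arena",
    "render_frames",
    "iter_rendered_frames",
    "synthesize_song",
]

#: The standard illuminance protocol: low / high / low, 2 minutes each.
DEFAULT_EPOCH_SCHEDULE: tuple[tuple[str, float, float], ...] = (
    ("low", 120.0, 0.4),
    ("high", 120.0, 18.0),
    ("low", 120.0, 0.4),
)


def default_chase_rate(intensity_klx: float) -> float:
    """Per-fly, per-second chase-initiation probability as a function of light.

    A logistic curve in log-illuminance, centred near 3.5 klx with its steepest
    rise between roughly 2 and 6 klx, saturating a little above 0.25 s^-1.
    At the protocol's 0.4 klx (room light) the rate is ~0.002 s^-1; at 18 klx
    it is ~0.25 s^-1.
    """
    if intensity_klx <= 0:
        return 0.0
    return 0.002 + 0.25 * float(expit(4.0 * math.log(intensity_klx / 3.5)))


def _as_rate_function(rate) -> Callable[[float], float]:
    if callable(rate):
        return rate
    if isinstance(rate, Mapping):
        # piecewise-linear interpolation in log-intensity
        pts = sorted((float(k), float(v)) for k, v in rate.items())
        xs = np.log([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])

        def lookup(intensity: float) -> float:
            return float(np.interp(math.log(max(intensity, 1e-12)), xs, ys))

        return lookup
    raise InvalidParameterError("chase_rate must be callable or a {klx: rate} mapping")


@dataclass
class SimParams:
    """Configuration of the arena simulator.

    Rates are per second; the per-frame initiation probability is
    ``rate / frame_rate``.  ``chase_rate`` maps illuminance (klx) to the
    per-fly chase-initiation rate and must be non-decreasing in intensity.
    """

    n_flies: int = 8
    arena_radius_mm: float = 13.0
    frame_rate: float = 15.0
    epoch_schedule: Sequence[tuple[str, float, float]] = DEFAULT_EPOCH_SCHEDULE
    chase_rate: Callable[[float], float] | Mapping[float, float] = default_chase_rate
    chain_rate: float = 0.25
    base_speed_mm_s: float = 4.0
    chase_speed_mm_s: float = 8.0
    turn_noise_rad_sqrt_s: float = 1.5
    follow_spacing_mm: float = 3.0
    contact_dist_mm: float = 3.5
    recruit_radius_mm: float = 10.0
    pause_rate_per_s: float = 0.5
    resume_rate_per_s: float = 1.0
    avoid_radius_mm: float = 3.5
    body_min_sep_mm: float = 2.2
    chase_duration_min_s: float = 1.0
    chase_duration_mean_s: float = 2.0
    recruit_extension_s: float = 2.0
    pursuit_timeout_s: float = 4.0
    max_turn_rate_rad_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_flies < 1:
            raise InvalidParameterError("n_flies must be >= 1")
        if self.arena_radius_mm <= 0:
            raise InvalidParameterError("arena_radius_mm must be positive")
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if not self.epoch_schedule:
            raise InvalidParameterError("epoch_schedule must contain at least one epoch")
        for label, dur, intensity in self.epoch_schedule:
            if dur <= 0:
                raise InvalidParameterError(f"epoch {label!r} has non-positive duration")
            if intensity < 0:
                raise InvalidParameterError(f"epoch {label!r} has negative intensity")
        if self.chase_duration_mean_s < self.chase_duration_min_s:
            raise InvalidParameterError("chase_duration_mean_s must be >= chase_duration_min_s")
        self._rate_fn = _as_rate_function(self.chase_rate)

    # total schedule duration in seconds
    @property
    def duration_s(self) -> float:
        return float(sum(e[1] for e in self.epoch_schedule))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    def intensity_at(self, t_s: float) -> float:
        acc = 0.0
        for _, dur, intensity in self.epoch_schedule:
            acc += dur
            if t_s < acc:
                return intensity
        return self.epoch_schedule[-1][2]


@dataclass
class SongElementRecord:
    """Ground-truth record of one synthesized song element."""

    kind: str  # "pulse_bout" or "sine"
    start_s: float
    end_s: float
    params: dict = field(default_factory=dict)


@dataclass
class SimGroundTruth:
    """Event log emitted by the simulator; the oracle for the detectors."""

    chase_events: list[ChaseEvent] = field(default_factory=list)
    chain_events: list[ChainEvent] = field(default_factory=list)
    song_elements: list[SongElementRecord] = field(default_factory=list)

    def chains_of_size(self, min_size: int) -> list[ChainEvent]:
        return [c for c in self.chain_events if len(c.members) >= min_size]


# ----------------------------------------------------------------------
# arena simulation
# ----------------------------------------------------------------------

_FREE, _LEADER, _FOLLOWER, _JOINING = 0, 1, 2, 3


class _Pursuit:
    __slots__ = (
        "line", "start_frame", "contact_frame", "end_frame",
        "member_contact", "joiner", "joiner_start", "segment_start",
    )

    def __init__(self, leader: int, chaser: int, frame: int):
        self.line = [leader, chaser]  # follow order, leader first
        self.start_frame = frame
        self.contact_frame: int | None = None
        self.end_frame: int | None = None
        self.member_contact = {}  # follower id -> frame of first contact
        self.joiner: int | None = None
        self.joiner_start: int | None = None
        self.segment_start: int | None = None  # open chain segment (size >= 3)


def simulate_arena(params: SimParams) -> tuple[TrajectorySet, SimGroundTruth]:
    """Run the agent-based arena model.

    Returns one trajectory per fly covering every frame of the light
    schedule, plus the ground-truth log of every chase and chain generated.
    Identical ``params`` (including ``seed``) give bit-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_flies
    T = params.n_frames
    fps = params.frame_rate
    dt = 1.0 / fps
    R = params.arena_radius_mm

    pos = _initial_positions(rng, n, R)
    heading = rng.uniform(0, 2 * math.pi, size=n)
    speed = np.full(n, params.base_speed_mm_s)
    walking = rng.random(n) < 0.67  # stationary fraction at equilibrium
    mode = np.full(n, _FREE, dtype=int)
    follow_pred = np.full(n, -1, dtype=int)  # fly immediately ahead, if any

    traj = np.empty((n, T, 2))
    traj[:, 0] = pos
    gt = SimGroundTruth()
    pursuits: list[_Pursuit] = []

    def release(p: _Pursuit, frame: int, log: bool) -> None:
        if log and p.contact_frame is not None:
            for k in range(1, len(p.line)):
                f = p.line[k]
                start = p.member_contact.get(f)
                if start is not None and frame > start:
                    gt.chase_events.append(
                        ChaseEvent(chaser=f, target=p.line[k - 1], start=start, end=frame)
                    )
            if p.segment_start is not None and frame > p.segment_start:
                gt.chain_events.append(
                    ChainEvent(members=tuple(p.line), start=p.segment_start, end=frame)
                )
        for f in p.line[0:]:
            mode[f] = _FREE
            follow_pred[f] = -1
            walking[f] = True
        if p.joiner is not None:
            mode[p.joiner] = _FREE
            follow_pred[p.joiner] = -1
            walking[p.joiner] = True
        pursuits.remove(p)

    timeout_frames = int(round(params.pursuit_timeout_s * fps))

    for t in range(1, T):
        t_s = t * dt
        intensity = params.intensity_at(t_s)
        rate = params._rate_fn(intensity)

        # --- chase initiation --------------------------------------------
        if rate > 0:
            p_init = rate * dt
            draws = rng.random(n)
            for i in range(n):
                if mode[i] != _FREE or draws[i] >= p_init:
                    continue
                target = _nearest_free(pos, mode, i, params.recruit_radius_mm)
                if target is None:
                    continue
                pur = _Pursuit(target, i, t)
                mode[target] = _LEADER
                mode[i] = _FOLLOWER
                follow_pred[i] = target
                pursuits.append(pur)

        # --- chain recruitment -------------------------------------------
        if params.chain_rate > 0 and pursuits:
            for pur in list(pursuits):
                if pur.contact_frame is None or pur.joiner is not None:
                    continue
                if len(pur.line) >= n:
                    continue
                if rng.random() >= params.chain_rate * dt:
                    continue
                tail = pur.line[-1]
                recruit = _nearest_free(pos, mode, tail, params.recruit_radius_mm)
                if recruit is None:
                    continue
                pur.joiner = recruit
                pur.joiner_start = t
                mode[recruit] = _JOINING
                follow_pred[recruit] = tail

        # --- movement -----------------------------------------------------
        new_heading = heading.copy()
        new_speed = speed.copy()
        noise = rng.standard_normal(n)
        pause_draw = rng.random(n)
        for i in range(n):
            if mode[i] == _FREE:
                # intermittent locomotion: walk bouts alternate with pauses
                if walking[i] and pause_draw[i] < params.pause_rate_per_s * dt:
                    walking[i] = False
                elif not walking[i] and pause_draw[i] < params.resume_rate_per_s * dt:
                    walking[i] = True
                    new_heading[i] = rng.uniform(0, 2 * math.pi)
            if mode[i] in (_FREE, _LEADER):
                if mode[i] == _FREE and not walking[i]:
                    new_speed[i] = 0.0
                    continue
                # a pursued fly runs straighter (escape-like) than a free walker
                tn = params.turn_noise_rad_sqrt_s * (0.3 if mode[i] == _LEADER else 1.0)
                h = heading[i] + tn * math.sqrt(dt) * noise[i]
                # non-courting flies veer away from close conspecifics ahead
                if mode[i] == _FREE and params.avoid_radius_mm > 0:
                    nb, nb_d = _nearest_any(pos, i)
                    if nb is not None and nb_d < params.avoid_radius_mm:
                        bearing = math.atan2(pos[nb, 1] - pos[i, 1], pos[nb, 0] - pos[i, 0])
                        rel = (bearing - h + math.pi) % (2 * math.pi) - math.pi
                        if abs(rel) < math.pi / 2:  # only if the other fly is ahead
                            h = _turn_toward(h, bearing + math.pi,
                                             params.max_turn_rate_rad_s * dt)
                # near the rim, flies wall-follow: steer toward the tangent
                # (a shallow, followable arc rather than a hairpin turn)
                r = math.hypot(pos[i, 0], pos[i, 1])
                if r > R - 2.5:
                    phi = math.atan2(pos[i, 1], pos[i, 0])
                    t1, t2 = phi + math.pi / 2, phi - math.pi / 2
                    d1 = abs((t1 - h + math.pi) % (2 * math.pi) - math.pi)
                    d2 = abs((t2 - h + math.pi) % (2 * math.pi) - math.pi)
                    tangent = t1 if d1 <= d2 else t2
                    # bias slightly inward so the arc stays off the wall.
                    # A pursued fly turns on a wider radius (comparable to
                    # the follow spacing) so its chaser can hold the arc;
                    # overshoot is handled by the reflecting boundary.
                    inward = math.atan2(-pos[i, 1], -pos[i, 0])
                    target = tangent + 0.25 * ((inward - tangent + math.pi) % (2 * math.pi) - math.pi)
                    cap = 1.5 if mode[i] == _LEADER else 3.0
                    h = _turn_toward(h, target, cap * dt)
                new_heading[i] = h
                new_speed[i] = params.base_speed_mm_s
            else:  # FOLLOWER or JOINING: trail the fly ahead
                # station-keeping on the trailing slot one follow-spacing
                # behind the predecessor: a lateral catch-up swings in behind
                # it instead of colliding with its flank, and a settled
                # follower copies the predecessor's heading (no jitter)
                pred = follow_pred[i]
                dx = pos[pred, 0] - pos[i, 0]
                dy = pos[pred, 1] - pos[i, 1]
                gap = math.hypot(dx, dy)
                if gap > 1.5 * params.follow_spacing_mm:
                    # far approach: steer for the trailing slot behind the
                    # predecessor so a lateral catch-up swings in behind it
                    sx = pos[pred, 0] - params.follow_spacing_mm * math.cos(heading[pred])
                    sy = pos[pred, 1] - params.follow_spacing_mm * math.sin(heading[pred])
                    bearing = math.atan2(sy - pos[i, 1], sx - pos[i, 0])
                else:
                    bearing = math.atan2(dy, dx)
                    # inside the follow spacing, veer tangentially (a chaser
                    # circles a slowing target rather than running it over)
                    encroach = (0.95 * params.follow_spacing_mm - gap) / (
                        0.35 * params.follow_spacing_mm
                    )
                    if encroach > 0:
                        # capped at 45 degrees: the deflection stays inside a
                        # courtship-typical heading cone while shedding most
                        # of the closing speed
                        off = min(1.0, encroach) * (math.pi / 4)
                        d1 = abs((bearing + off - heading[i] + math.pi) % (2 * math.pi) - math.pi)
                        d2 = abs((bearing - off - heading[i] + math.pi) % (2 * math.pi) - math.pi)
                        bearing = bearing + off if d1 <= d2 else bearing - off
                new_heading[i] = _turn_toward(
                    heading[i], bearing, params.max_turn_rate_rad_s * dt
                )
                # speed control settles the gap at follow_spacing; reference
                # is the predecessor's velocity along the line of sight (its
                # scalar speed would overshoot on a lateral approach)
                los = math.atan2(dy, dx)
                pred_recede = speed[pred] * math.cos(heading[pred] - los)
                target_speed = pred_recede + 2.0 * (gap - params.follow_spacing_mm)
                # a courting pursuer keeps pace even through the target's
                # turns; the floor sits just above the mobility criterion
                floor = 0.55 * params.base_speed_mm_s
                new_speed[i] = min(max(target_speed, floor), params.chase_speed_mm_s)

        heading = new_heading
        speed = new_speed
        pos = pos + (speed * dt)[:, None] * np.column_stack(
            (np.cos(heading), np.sin(heading))
        )
        # hard body constraints: flies are solid.  A pursuer may crowd its
        # predecessor but not pass through it, and no two flies overlap
        # beyond a body-core separation (total overlap would also make
        # video identities physically unresolvable).
        min_sep = 0.6 * params.follow_spacing_mm
        follow_pairs = set()
        for pur in pursuits:
            members = pur.line[1:] + ([pur.joiner] if pur.joiner is not None else [])
            for fidx in members:
                pred = follow_pred[fidx]
                follow_pairs.add((min(fidx, pred), max(fidx, pred)))
                vec = pos[fidx] - pos[pred]
                d = math.hypot(vec[0], vec[1])
                if 1e-9 < d < min_sep:
                    # push back out and swing the contact toward the
                    # predecessor's tail, restoring tail-chase geometry
                    vx, vy = vec[0] / d, vec[1] / d
                    bx = -math.cos(heading[pred])
                    by = -math.sin(heading[pred])
                    sx, sy = vx + 0.3 * (bx - vx), vy + 0.3 * (by - vy)
                    nrm = math.hypot(sx, sy)
                    pos[fidx, 0] = pos[pred, 0] + sx / nrm * min_sep
                    pos[fidx, 1] = pos[pred, 1] + sy / nrm * min_sep
        if params.body_min_sep_mm > 0:
            core = params.body_min_sep_mm
            for i in range(n):
                for j in range(i + 1, n):
                    if (i, j) in follow_pairs:
                        continue
                    vec = pos[j] - pos[i]
                    d = math.hypot(vec[0], vec[1])
                    if 1e-9 < d < core:
                        push = 0.5 * (core - d) / d
                        pos[i] -= vec * push
                        pos[j] += vec * push
        _reflect_boundary(pos, heading, R)
        traj[:, t] = pos

        # --- contact checks and termination ------------------------------
        for pur in list(pursuits):
            leader, chaser = pur.line[0], pur.line[1]
            if pur.contact_frame is None:
                gap = np.linalg.norm(pos[chaser] - pos[leader])
                if gap <= params.contact_dist_mm:
                    pur.contact_frame = t
                    pur.member_contact[chaser] = t
                    dur = params.chase_duration_min_s + rng.exponential(
                        params.chase_duration_mean_s - params.chase_duration_min_s
                    )
                    pur.end_frame = t + max(1, int(round(dur * fps)))
                elif t - pur.start_frame > timeout_frames:
                    release(pur, t, log=False)
                continue

            if pur.joiner is not None:
                tail = pur.line[-1]
                gap = np.linalg.norm(pos[pur.joiner] - pos[tail])
                if gap <= params.contact_dist_mm:
                    if pur.segment_start is not None:
                        gt.chain_events.append(
                            ChainEvent(members=tuple(pur.line),
                                       start=pur.segment_start, end=t)
                        )
                    pur.line.append(pur.joiner)
                    pur.member_contact[pur.joiner] = t
                    mode[pur.joiner] = _FOLLOWER
                    pur.joiner = None
                    pur.segment_start = t  # line now has >= 3 members
                    pur.end_frame += int(round(params.recruit_extension_s * fps))
                elif t - pur.joiner_start > timeout_frames:
                    mode[pur.joiner] = _FREE
                    follow_pred[pur.joiner] = -1
                    pur.joiner = None

            if t >= pur.end_frame:
                release(pur, t, log=True)

    for pur in list(pursuits):
        release(pur, T - 1, log=True)

    ts = TrajectorySet(
        positions=traj,
        valid=np.ones((n, T), dtype=bool),
        frame_rate=fps,
        fly_ids=np.arange(1, n + 1),
    )
    # ground-truth ids are 1-based to match TrajectorySet fly_ids
    gt.chase_events = [
        ChaseEvent(e.chaser + 1, e.target + 1, e.start, e.end) for e in gt.chase_events
    ]
    gt.chain_events = [
        ChainEvent(tuple(m + 1 for m in c.members), c.start, c.end)
        for c in gt.chain_events
    ]
    return ts, gt


def _initial_positions(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform positions in the disc, rejection-sampled to >=3 mm separation."""
    pts: list[np.ndarray] = []
    margin = min(2.0, 0.2 * radius)
    for _ in range(10000):
        r = (radius - margin) * math.sqrt(rng.random())
        a = rng.uniform(0, 2 * math.pi)
        p = np.array([r * math.cos(a), r * math.sin(a)])
        if all(np.linalg.norm(p - q) >= 3.0 for q in pts):
            pts.append(p)
        if len(pts) == n:
            return np.array(pts)
    # dense arenas: accept whatever spacing is achievable
    while len(pts) < n:
        r = (radius - margin) * math.sqrt(rng.random())
        a = rng.uniform(0, 2 * math.pi)
        pts.append(np.array([r * math.cos(a), r * math.sin(a)]))
    return np.array(pts)


def _nearest_free(pos: np.ndarray, mode: np.ndarray, i: int, radius: float) -> int | None:
    best, best_d = None, radius
    for j in range(len(pos)):
        if j == i or mode[j] != _FREE:
            continue
        d = math.hypot(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1])
        if d < best_d:
            best, best_d = j, d
    return best


def _nearest_any(pos: np.ndarray, i: int) -> tuple[int | None, float]:
    best, best_d = None, math.inf
    for j in range(len(pos)):
        if j == i:
            continue
        d = math.hypot(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1])
        if d < best_d:
            best, best_d = j, d
    return best, best_d


def _turn_toward(current: float, desired: float, max_step: float) -> float:
    delta = (desired - current + math.pi) % (2 * math.pi) - math.pi
    if abs(delta) <= max_step:
        return desired
    return current + math.copysign(max_step, delta)


def _reflect_boundary(pos: np.ndarray, heading: np.ndarray, radius: float) -> None:
    """Reflect positions (and headings) that crossed the arena wall, in place."""
    r = np.linalg.norm(pos, axis=1)
    out = r > radius
    for i in np.nonzero(out)[0]:
        phi = math.atan2(pos[i, 1], pos[i, 0])
        pos[i] *= (2 * radius - r[i]) / r[i]
        heading[i] = 2 * phi + math.pi - heading[i]


# ----------------------------------------------------------------------
# frame rendering
# ----------------------------------------------------------------------

def iter_rendered_frames(
    traj: TrajectorySet,
    arena,
    roi_index: int = 0,
    fly_length_mm: float = 2.5,
    fly_width_mm: float = 1.2,
    background: int = 220,
    fly_value: int = 40,
    ring_value: int = 120,
    noise_sigma: float = 2.0,
    seed: int = 0,
    draw_boundary: bool = True,
) -> Iterator[np.ndarray]:
    """Yield grayscale uint8 frames, one dark ellipse per fly.

    The ellipse major axis is ~2.5 mm at the arena scale, oriented along the
    fly's displacement heading.  A dark ring marks the ROI wall; optional
    Gaussian pixel noise emulates sensor noise.
    """
    if arena.mm_per_px <= 0:
        raise InvalidParameterError("mm_per_px must be positive")
    rng = np.random.default_rng(seed)
    h, w = arena.frame_shape
    cx, cy = arena.roi_centres[roi_index]
    s = arena.mm_per_px

    base = np.full((h, w), float(background))
    if draw_boundary:
        yy, xx = np.mgrid[0:h, 0:w]
        rr = np.hypot(xx - cx, yy - cy)
        ring = np.abs(rr - arena.roi_radius_px) < 1.5
        base[ring] = ring_value

    a = (fly_length_mm / 2) / s  # semi-major axis, px
    b = (fly_width_mm / 2) / s
    half = int(math.ceil(a)) + 2
    vel = traj.velocities()

    for f in range(traj.n_frames):
        frame = base.copy()
        for i in range(traj.n_flies):
            if not traj.valid[i, f]:
                continue
            x_mm, y_mm = traj.positions[i, f]
            px = cx + x_mm / s
            py = cy - y_mm / s
            vx, vy = vel[i, f]
            if np.isfinite(vx) and (vx != 0 or vy != 0):
                theta = math.atan2(-vy, vx)  # y axis flips in pixel space
            else:
                theta = 0.0
            _stamp_ellipse(frame, px, py, a, b, theta, half, background, fly_value)
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
        yield np.clip(frame, 0, 255).astype(np.uint8)


def render_frames(traj: TrajectorySet, arena, **kwargs) -> np.ndarray:
    """Materialize all rendered frames as a (n_frames, H, W) uint8 stack.

    Convenience wrapper over :func:`iter_rendered_frames`; for long
    recordings prefer the iterator to bound memory.
    """
    return np.stack(list(iter_rendered_frames(traj, arena, **kwargs)))


def _stamp_ellipse(frame, px, py, a, b, theta, half, background, fly_value):
    h, w = frame.shape
    x0, x1 = int(px) - half, int(px) + half + 1
    y0, y1 = int(py) - half, int(py) + half + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    ys, xs = np.mgrid[y0c:y1c, x0c:x1c]
    u = (xs - px) * math.cos(theta) + (ys - py) * math.sin(theta)
    v = -(xs - px) * math.sin(theta) + (ys - py) * math.cos(theta)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    alpha = np.clip((1.0 - rho) * b, 0.0, 1.0)  # ~1-px anti-aliased edge
    patch = frame[y0c:y1c, x0c:x1c]
    np.minimum(patch, background - alpha * (background - fly_value), out=patch)


# ----------------------------------------------------------------------
# song synthesis
# ----------------------------------------------------------------------

@dataclass
class PulseBoutSpec:
    """A train of damped-oscillation pulses at a fixed inter-pulse interval."""

    start_s: float
    n_pulses: int
    ipi_s: float
    carrier_hz: float = 220.0
    decay_s: float = 0.005
    amplitude: float = 1.0

    @property
    def end_s(self) -> float:
        return self.start_s + (self.n_pulses - 1) * self.ipi_s + 8 * self.decay_s


@dataclass
class SineSpec:
    """A sustained pure-tone hum segment."""

    start_s: float
    duration_s: float
    freq_hz: float
    amplitude: float = 1.0

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


def synthesize_song(
    elements: Iterable[PulseBoutSpec | SineSpec],
    sample_rate: float,
    duration_s: float,
    noise_snr_db: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, SimGroundTruth]:
    """Render a courtship-song waveform from element specifications.

    Pulses are exponentially damped sinusoids (carrier ~220 Hz, ~5 ms decay);
    sine elements are pure tones with short cosine ramps.  If ``noise_snr_db``
    is given, white Gaussian noise is added with RMS set relative to a
    unit-amplitude tone (RMS 1/sqrt(2)), i.e. ``noise_rms =
    10**(-snr/20) / sqrt(2)``.  Ground truth records every element.
    """
    elements = list(elements)
    n_samples = int(round(duration_s * sample_rate))
    wave = np.zeros(n_samples)
    gt = SimGroundTruth()

    spans = sorted((e.start_s, e.end_s) for e in elements)
    for (s0, e0), (s1, _) in zip(spans, spans[1:]):
        if s1 < e0:
            raise OverlapError(f"song elements overlap near t={s1:.3f} s")
    for e in elements:
        if e.start_s < 0 or e.end_s > duration_s:
            raise InvalidParameterError("song element lies outside the recording span")

    for e in elements:
        if isinstance(e, PulseBoutSpec):
            _add_pulse_bout(wave, e, sample_rate)
            gt.song_elements.append(
                SongElementRecord(
                    "pulse_bout", e.start_s, e.end_s,
                    {"n_pulses": e.n_pulses, "ipi_s": e.ipi_s,
                     "carrier_hz": e.carrier_hz, "decay_s": e.decay_s},
                )
            )
        elif isinstance(e, SineSpec):
            _add_sine(wave, e, sample_rate)
            gt.song_elements.append(
                SongElementRecord(
                    "sine", e.start_s, e.end_s,
                    {"freq_hz": e.freq_hz, "duration_s": e.duration_s},
                )
            )
        else:
            raise InvalidParameterError(f"unknown song element type: {type(e)!r}")

    if noise_snr_db is not None:
        rng = np.random.default_rng(seed)
        noise_rms = 10 ** (-noise_snr_db / 20) / math.sqrt(2)
        wave = wave + rng.normal(0.0, noise_rms, size=n_samples)
    return wave, gt


def _add_pulse_bout(wave: np.ndarray, e: PulseBoutSpec, fs: float) -> None:
    pulse_len = int(round(8 * e.decay_s * fs))
    t = np.arange(pulse_len) / fs
    pulse = e.amplitude * np.sin(2 * math.pi * e.carrier_hz * t) * np.exp(-t / e.decay_s)
    for k in range(e.n_pulses):
        i0 = int(round((e.start_s + k * e.ipi_s) * fs))
        i1 = min(i0 + pulse_len, len(wave))
        wave[i0:i1] += pulse[: i1 - i0]


def _add_sine(wave: np.ndarray, e: SineSpec, fs: float) -> None:
    i0 = int(round(e.start_s * fs))
    n = int(round(e.duration_s * fs))
    t = np.arange(n) / fs
    seg = e.amplitude * np.sin(2 * math.pi * e.freq_hz * t)
    ramp_n = min(int(0.005 * fs), n // 2)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.linspace(0, math.pi, ramp_n)))
        seg[:ramp_n] *= ramp
        seg[-ramp_n:] *= ramp[::-1]
    i1 = min(i0 + n, len(wave))
    wave[i0:i1] += seg[: i1 - i0]
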