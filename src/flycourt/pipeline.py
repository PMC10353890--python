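"""End-to-end runs of the light-protocol experiment.

``run_roi`` takes one arena through simulate (or track) -> interactogram ->
chase/chain detection -> kinematics -> interval scoring; ``run_experiment``
repeats it over ROIs and compares epochs.  These are the same entry points
the command-line interface drives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import sim, social, tracking
from .events import events_to_intervals
from .kinematics import KinematicsSummary, compute_kinematics
from .scoring import (
    BehaviorScoreSheet,
    EpochComparison,
    LightProtocol,
    compare_epochs,
    score_intervals,
)
from .trajectories import TrajectorySet

__all__ = ["RoiResult", "run_roi", "run_experiment", "protocol_from_params"]


def protocol_from_params(params: sim.SimParams, bin_s: float = 10.0) -> LightProtocol:
    """Derive the scoring protocol from the simulator's epoch schedule."""
    return LightProtocol(epochs=list(params.epoch_schedule), bin_s=bin_s)


@dataclass
class RoiResult:
    """Everything the pipeline derives for one arena."""

    traj: TrajectorySet
    interactogram: social.Interactogram
    chases: list
    chains: list
    kinematics: KinematicsSummary
    sheet: BehaviorScoreSheet
    ground_truth: sim.SimGroundTruth | None = None


def run_roi(
    traj: TrajectorySet,
    protocol: LightProtocol,
    interaction: social.InteractionParams | None = None,
    roi_id: int = 0,
    ground_truth: sim.SimGroundTruth | None = None,
) -> RoiResult:
    """Social + kinematics + scoring stages for one tracked arena."""
    interaction = interaction or social.InteractionParams()
    ig = social.compute_interactogram(traj, interaction)
    chases = social.detect_chases(traj, ig, interaction)
    chains = social.detect_chains(traj, ig, interaction)
    kin = compute_kinematics(traj)
    events = {
        "chase": events_to_intervals(chases, traj.frame_rate),
        "chain": events_to_intervals(chains, traj.frame_rate),
    }
    # clip detector events to the protocol span (the last frame's interval
    # may end a fraction of a frame past it)
    span = protocol.total_duration_s
    events = {k: [(s, min(e, span)) for s, e in v] for k, v in events.items()}
    sheet = score_intervals(events, protocol, roi_id=roi_id)
    return RoiResult(
        traj=traj,
        interactogram=ig,
        chases=chases,
        chains=chains,
        kinematics=kin,
        sheet=sheet,
        ground_truth=ground_truth,
    )


def run_experiment(
    params: sim.SimParams,
    n_rois: int = 4,
    seed: int | None = None,
    through_video: bool = False,
    mm_per_px: float = 0.15,
    interaction: social.InteractionParams | None = None,
) -> tuple[list[RoiResult], EpochComparison]:
    """Simulate ``n_rois`` arenas under one light protocol and compare epochs.

    With ``through_video`` the simulated trajectories are first rendered to
    frames and re-tracked (detection + identity linking), exercising the full
    video pipeline; otherwise the simulator's trajectories feed the social
    stage directly.
    """
    import dataclasses

    base_seed = params.seed if seed is None else seed
    protocol = protocol_from_params(params)
    results = []
    for r in range(n_rois):
        p = dataclasses.replace(params, seed=int(base_seed) + 1000 * r)
        traj, gt = sim.simulate_arena(p)
        if through_video:
            arena = tracking.ArenaConfig.single_roi(
                mm_per_px=mm_per_px, frame_rate=p.frame_rate
            )
            frames = sim.iter_rendered_frames(traj, arena, seed=p.seed + 1)
            traj = tracking.track_frames(frames, arena, expected_n=p.n_flies)
        results.append(
            run_roi(traj, protocol, interaction=interaction, roi_id=r, ground_truth=gt)
        )
    comparison = compare_epochs([r.sheet for r in results], design="paired")
    return results, comparison
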