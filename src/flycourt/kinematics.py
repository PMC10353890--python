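"""Per-fly locomotor summaries: distance travelled, speed, % time moving."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .trajectories import TrajectorySet

__all__ = ["KinematicsSummary", "compute_kinematics"]


@dataclass
class KinematicsSummary:
    """Locomotor statistics per fly plus across-fly aggregates for the ROI.

    ``per_fly`` has one row per fly with columns ``fly_id``, ``distance_mm``,
    ``mean_speed_mm_s`` and ``pct_time_moving``; ``aggregate`` holds the mean
    and SEM of each column across flies.
    """

    per_fly: pd.DataFrame
    aggregate: pd.DataFrame
    roi_id: int = 0

    def to_csv(self, path) -> None:
        self.per_fly.to_csv(path, index=False)


def compute_kinematics(
    traj: TrajectorySet,
    moving_threshold_mm_s: float = 1.0,
    window_s: float = 0.2,
) -> KinematicsSummary:
    """Distance travelled, mean speed and percent time moving per fly.

    Distance sums frame-to-frame displacements over steps with both endpoints
    valid; steps across tracking gaps contribute to neither numerator nor
    denominator.  Instantaneous speed is the step displacement times the
    frame rate, smoothed with a centred boxcar of ``window_s``; a step counts
    as *moving* when the smoothed speed is at or above the threshold.  Mean
    speed is distance divided by the elapsed time of valid steps.  Flies with
    fewer than two valid frames are excluded with a warning.
    """
    if moving_threshold_mm_s < 0 or window_s <= 0:
        raise InvalidParameterError("threshold must be >= 0 and window_s > 0")
    fps = traj.frame_rate
    steps = traj.step_displacements()  # (n, T-1), NaN across gaps
    k = max(1, int(round(window_s * fps)))
    kernel = np.ones(k) / k

    rows = []
    for i in range(traj.n_flies):
        d = steps[i]
        ok = np.isfinite(d)
        n_valid = int(ok.sum())
        if traj.valid[i].sum() < 2 or n_valid == 0:
            warnings.warn(
                f"fly {int(traj.fly_ids[i])} has <2 valid frames; excluded from kinematics",
                stacklevel=2,
            )
            continue
        distance = float(d[ok].sum())
        elapsed = n_valid / fps
        speed_inst = np.where(ok, d, 0.0) * fps
        num = np.convolve(speed_inst, kernel, mode="same")
        den = np.convolve(ok.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            speed_smooth = num / den
        moving = ok & (speed_smooth >= moving_threshold_mm_s)
        rows.append(
            {
                "fly_id": int(traj.fly_ids[i]),
                "distance_mm": distance,
                "mean_speed_mm_s": distance / elapsed,
                "pct_time_moving": 100.0 * moving.sum() / n_valid,
            }
        )
    per_fly = pd.DataFrame(rows, columns=["fly_id", "distance_mm", "mean_speed_mm_s", "pct_time_moving"])
    if len(per_fly):
        cols = ["distance_mm", "mean_speed_mm_s", "pct_time_moving"]
        agg = pd.DataFrame(
            {
                "mean": per_fly[cols].mean(),
                "sem": per_fly[cols].sem(ddof=1) if len(per_fly) > 1 else np.nan,
            }
        )
    else:
        agg = pd.DataFrame(columns=["mean", "sem"])
    return KinematicsSummary(per_fly=per_fly, aggregate=agg, roi_id=traj.roi_id)
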