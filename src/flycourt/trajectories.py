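"""Identity-resolved fly trajectories.

The :class:`TrajectorySet` is the backbone of the pipeline: every stage
downstream of tracking (interactograms, chase/chain detection, kinematics,
interval scoring) consumes one.  Positions are stored in millimetres relative
to the centre of the circular arena (ROI), x to the right, y up, one row of
frames per fly, all flies sharing the frame axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = ["TrajectorySet"]


@dataclass
class TrajectorySet:
    """Per-fly, per-frame centroid positions with validity flags.

    Parameters
    ----------
    positions : ndarray, shape (n_flies, n_frames, 2)
        Centroid coordinates in mm relative to the ROI centre.  Entries at
        invalid frames may be NaN or interpolated values; the ``valid`` mask
        is authoritative.
    valid : ndarray of bool, shape (n_flies, n_frames)
        False wherever a position is missing or interpolated.
    frame_rate : float
        Frames per second of the recording (nominally 15).
    fly_ids : ndarray of int, shape (n_flies,)
        Stable identity labels (1..n by convention).
    roi_id : int
        Which circular arena this set belongs to.
    """

    positions: np.ndarray
    valid: np.ndarray
    frame_rate: float
    fly_ids: np.ndarray | None = None
    roi_id: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise InvalidParameterError(
                f"positions must have shape (n_flies, n_frames, 2), got {self.positions.shape}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.positions).all(axis=2)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.positions.shape[:2]:
            raise InvalidParameterError("valid mask shape must match (n_flies, n_frames)")
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if self.fly_ids is None:
            self.fly_ids = np.arange(1, self.positions.shape[0] + 1)
        self.fly_ids = np.asarray(self.fly_ids, dtype=int)
        if self.fly_ids.shape != (self.positions.shape[0],):
            raise InvalidParameterError("fly_ids length must equal n_flies")

    @property
    def n_flies(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in seconds (frame / frame_rate, frames from 0)."""
        return np.arange(self.n_frames) / self.frame_rate

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    def step_displacements(self) -> np.ndarray:
        """Per-fly frame-to-frame displacement magnitudes (mm).

        Shape (n_flies, n_frames - 1); NaN where either endpoint is invalid.
        """
        d = np.linalg.norm(np.diff(self.positions, axis=1), axis=2)
        ok = self.valid[:, :-1] & self.valid[:, 1:]
        d = np.where(ok, d, np.nan)
        return d

    def velocities(self, smooth_frames: int = 1) -> np.ndarray:
        """Per-frame velocity vectors in mm/s, shape (n_flies, n_frames, 2).

        Central differences in the interior, one-sided at the ends; optionally
        smoothed with a centred boxcar of ``smooth_frames`` frames.  Entries
        touching invalid frames are NaN.
        """
        p = np.where(self.valid[..., None], self.positions, np.nan)
        v = np.gradient(p, axis=1) * self.frame_rate
        if smooth_frames > 1:
            k = int(smooth_frames)
            kernel = np.ones(k) / k
            # NaN-tolerant smoothing: leave NaN runs NaN, average over the rest
            for axis in (0, 1):
                comp = v[:, :, axis]
                mask = np.isfinite(comp)
                filled = np.where(mask, comp, 0.0)
                num = np.apply_along_axis(np.convolve, 1, filled, kernel, "same")
                den = np.apply_along_axis(np.convolve, 1, mask.astype(float), kernel, "same")
                with np.errstate(invalid="ignore", divide="ignore"):
                    sm = num / den
                v[:, :, axis] = np.where(mask, sm, np.nan)
        return v

    def speeds(self, smooth_frames: int = 1) -> np.ndarray:
        """Per-frame speeds in mm/s, shape (n_flies, n_frames)."""
        return np.linalg.norm(self.velocities(smooth_frames=smooth_frames), axis=2)

    # ------------------------------------------------------------------
    # conversion
    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns frame, time_s, fly_id, x_mm, y_mm, valid."""
        n, t = self.n_flies, self.n_frames
        frames = np.tile(np.arange(t), n)
        ids = np.repeat(self.fly_ids, t)
        return pd.DataFrame(
            {
                "frame": frames,
                "time_s": frames / self.frame_rate,
                "fly_id": ids,
                "x_mm": self.positions[:, :, 0].ravel(),
                "y_mm": self.positions[:, :, 1].ravel(),
                "valid": self.valid.ravel().astype(int),
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, frame_rate: float, roi_id: int = 0
    ) -> "TrajectorySet":
        ids = np.sort(df["fly_id"].unique())
        frames = np.sort(df["frame"].unique())
        n, t = len(ids), len(frames)
        pos = np.full((n, t, 2), np.nan)
        val = np.zeros((n, t), dtype=bool)
        id_index = {f: i for i, f in enumerate(ids)}
        frame_index = {f: i for i, f in enumerate(frames)}
        fi = df["fly_id"].map(id_index).to_numpy()
        fr = df["frame"].map(frame_index).to_numpy()
        pos[fi, fr, 0] = df["x_mm"].to_numpy()
        pos[fi, fr, 1] = df["y_mm"].to_numpy()
        if "valid" in df.columns:
            val[fi, fr] = df["valid"].to_numpy().astype(bool)
        else:
            val[fi, fr] = True
        return cls(positions=pos, valid=val, frame_rate=frame_rate,
                   fly_ids=ids, roi_id=roi_id)

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, TrajectorySet):
            return NotImplemented
        return (
            self.positions.shape == other.positions.shape
            and np.allclose(self.positions, other.positions, equal_nan=True)
            and np.array_equal(self.valid, other.valid)
            and np.isclose(self.frame_rate, other.frame_rate)
            and np.array_equal(self.fly_ids, other.fly_ids)
            and self.roi_id == other.roi_id
        )
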