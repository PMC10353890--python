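"""Interval-based behaviour scoring across the light protocol, epoch
statistics, dose-response summaries and spectral normalization.

The experiment's scoring scheme: each 2-min illuminance epoch is divided
into 10-s bins; per bin and behaviour (chase, wing extension, chain) the
presence or absence of the behaviour is marked 1 or 0, and the per-epoch sum
is the *total score*, 0-12 for a 2-min epoch.  In the manual two-operator
protocol each 10-s interval is split into two 5-s scoring windows and paired
ROIs are scored alternately; that alternating mode is available for parity
with manual scores, while the automated pipeline scores the full bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InsufficientLevelsError,
    InsufficientReplicatesError,
    InvalidParameterError,
    RangeError,
)

__all__ = [
    "LightProtocol",
    "BehaviorScoreSheet",
    "SpectrumRecord",
    "score_intervals",
    "compare_epochs",
    "dose_response",
    "normalize_spectrum",
    "paired_t",
]

BEHAVIOURS = ("chase", "wing_extension", "chain")


@dataclass
class LightProtocol:
    """Ordered illuminance epochs: (label, duration_s, intensity_klx).

    The default is the standard low/high/low protocol: 120 s at 0.4 klx,
    120 s at 18 klx, 120 s at 0.4 klx.  The 10-s scoring grid must divide
    each epoch evenly.
    """

    epochs: Sequence[tuple[str, float, float]] = (
        ("low", 120.0, 0.4),
        ("high", 120.0, 18.0),
        ("low", 120.0, 0.4),
    )
    bin_s: float = 10.0

    def __post_init__(self):
        self.epochs = [(str(l), float(d), float(i)) for l, d, i in self.epochs]
        if self.bin_s <= 0:
            raise InvalidParameterError("bin_s must be positive")
        for label, dur, _ in self.epochs:
            if dur <= 0:
                raise InvalidParameterError(f"epoch {label!r} has non-positive duration")
            n = dur / self.bin_s
            if abs(n - round(n)) > 1e-9:
                raise InvalidParameterError(
                    f"epoch {label!r} duration {dur} s is not a multiple of the "
                    f"{self.bin_s}-s bin"
                )

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d, _ in self.epochs)

    @property
    def n_bins(self) -> int:
        return int(round(self.total_duration_s / self.bin_s))

    def bins_per_epoch(self) -> list[int]:
        return [int(round(d / self.bin_s)) for _, d, _ in self.epochs]

    def epoch_labels(self) -> list[str]:
        """Unique labels: repeated labels get a positional suffix (low1, low2)."""
        counts: dict[str, int] = {}
        for l, _, _ in self.epochs:
            counts[l] = counts.get(l, 0) + 1
        seen: dict[str, int] = {}
        out = []
        for l, _, _ in self.epochs:
            if counts[l] > 1:
                seen[l] = seen.get(l, 0) + 1
                out.append(f"{l}{seen[l]}")
            else:
                out.append(l)
        return out

    def epoch_of_bin(self, b: int) -> int:
        acc = 0
        for e, nb in enumerate(self.bins_per_epoch()):
            acc += nb
            if b < acc:
                return e
        raise IndexError(b)


@dataclass
class BehaviorScoreSheet:
    """Per-ROI 0/1 marks per behaviour and 10-s bin, with epoch totals."""

    protocol: LightProtocol
    marks: dict[str, np.ndarray]  # behaviour -> (n_bins,) of 0/1
    roi_id: int = 0
    alternating: bool = False
    window_slot: int = 0  # which 5-s half-window this ROI was scored in

    def __post_init__(self):
        nb = self.protocol.n_bins
        for b, m in self.marks.items():
            m = np.asarray(m, dtype=int)
            if m.shape != (nb,):
                raise InvalidParameterError(
                    f"marks for {b!r} must have {nb} bins, got {m.shape}"
                )
            if not np.isin(m, (0, 1)).all():
                raise InvalidParameterError("marks must be 0 or 1")
            self.marks[b] = m

    def epoch_totals(self, behaviour: str) -> np.ndarray:
        """Total score per epoch (0-12 for a 2-min epoch on the 10-s grid)."""
        m = self.marks[behaviour]
        out, acc = [], 0
        for nb in self.protocol.bins_per_epoch():
            out.append(int(m[acc : acc + nb].sum()))
            acc += nb
        return np.array(out)

    @property
    def behaviours(self) -> list[str]:
        return list(self.marks)

    def to_dataframe(self) -> pd.DataFrame:
        labels = self.protocol.epoch_labels()
        rows = []
        for b, m in self.marks.items():
            for k, mark in enumerate(m):
                rows.append(
                    {
                        "roi": self.roi_id,
                        "epoch": labels[self.protocol.epoch_of_bin(k)],
                        "behaviour": b,
                        "bin": k,
                        "mark": int(mark),
                    }
                )
        return pd.DataFrame(rows)


def score_intervals(
    events: Mapping[str, Sequence[tuple[float, float]]],
    protocol: LightProtocol,
    roi_id: int = 0,
    alternating: bool = False,
    window_slot: int = 0,
) -> BehaviorScoreSheet:
    """Score behaviour presence/absence per 10-s bin of the light protocol.

    ``events`` maps behaviour name to (start_s, end_s) intervals.  A bin is
    marked 1 iff any event of that behaviour overlaps the bin's scoring
    window, however briefly.  In ``alternating`` mode only the ROI's
    assigned 5-s half-window of each 10-s interval is consulted
    (``window_slot`` 0 = first half, 1 = second), mirroring the two-operator
    live protocol.  Events outside the protocol span raise ``RangeError``.
    """
    span = protocol.total_duration_s
    nb = protocol.n_bins
    bin_s = protocol.bin_s
    if window_slot not in (0, 1):
        raise InvalidParameterError("window_slot must be 0 or 1")
    marks: dict[str, np.ndarray] = {}
    for behaviour, intervals in events.items():
        m = np.zeros(nb, dtype=int)
        for (s, e) in intervals:
            if e < s:
                raise InvalidParameterError("event end precedes start")
            if s < 0 or e > span + 1e-9:
                raise RangeError(
                    f"event ({s:.3f}, {e:.3f}) s outside the 0-{span:.0f} s recording span"
                )
            for k in range(nb):
                if alternating:
                    w0 = k * bin_s + window_slot * (bin_s / 2)
                    w1 = w0 + bin_s / 2
                else:
                    w0, w1 = k * bin_s, (k + 1) * bin_s
                if s < w1 and e > w0 or (s == e and w0 <= s < w1):
                    m[k] = 1
        marks[behaviour] = m
    return BehaviorScoreSheet(
        protocol=protocol, marks=marks, roi_id=roi_id,
        alternating=alternating, window_slot=window_slot,
    )


# ----------------------------------------------------------------------
# epoch statistics
# ----------------------------------------------------------------------

def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test, with explicit degenerate conventions.

    All differences zero -> (0, 1); constant non-zero differences -> the
    statistic diverges, reported as signed infinity with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("paired samples must be 1-D and equal length")
    if len(x) < 2:
        raise InsufficientReplicatesError("paired t needs at least 2 pairs")
    d = x - y
    if np.allclose(d, 0):
        return 0.0, 1.0
    if np.isclose(d.std(ddof=1), 0):
        return math.copysign(math.inf, d.mean()), 0.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class EpochComparison:
    """Statistics report from :func:`compare_epochs`."""

    design: str
    summary: pd.DataFrame       # behaviour x epoch: mean, sem, n
    tests: pd.DataFrame         # pairwise tests (and ANOVA rows in multi-group)
    n_rois: int

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "design": self.design,
                "n_rois": self.n_rois,
                "summary": self.summary.to_dict(orient="records"),
                "tests": self.tests.replace({np.inf: "inf", -np.inf: "-inf"})
                .to_dict(orient="records"),
            },
            indent=2,
        )

    def text(self) -> str:
        lines = [f"Epoch comparison ({self.design}, n = {self.n_rois} ROIs)", ""]
        lines.append(self.summary.to_string(index=False))
        lines.append("")
        lines.append(self.tests.to_string(index=False))
        return "\n".join(lines)


def compare_epochs(
    sheets: Sequence[BehaviorScoreSheet],
    design: str = "paired",
) -> EpochComparison:
    """Compare per-epoch total scores across ROIs.

    ``design='paired'``: per behaviour, mean +/- SEM per epoch and two-sided
    paired t-tests between consecutive epochs (low1 vs high, high vs low2 in
    the standard three-epoch protocol); the replicate unit is the ROI.

    ``design='multi-group'``: per behaviour, a one-way ANOVA across epochs
    followed by Bonferroni-corrected pairwise t-tests (the correction factor
    is the number of pairwise comparisons).  Significance tiers are reported
    at 0.05 / 0.01 / 0.001.
    """
    if len(sheets) < 2:
        raise InsufficientReplicatesError("need score sheets from >= 2 ROIs")
    proto = sheets[0].protocol
    labels = proto.epoch_labels()
    for s in sheets[1:]:
        if s.protocol.epoch_labels() != labels or s.protocol.bins_per_epoch() != proto.bins_per_epoch():
            raise InvalidParameterError("all score sheets must share the epoch structure")
    behaviours = [b for b in sheets[0].behaviours]

    sum_rows, test_rows = [], []
    for b in behaviours:
        totals = np.array([s.epoch_totals(b) for s in sheets], dtype=float)  # (n_roi, n_epoch)
        for e, lab in enumerate(labels):
            col = totals[:, e]
            sum_rows.append(
                {
                    "behaviour": b,
                    "epoch": lab,
                    "mean": col.mean(),
                    "sem": col.std(ddof=1) / math.sqrt(len(col)),
                    "n": len(col),
                }
            )
        pairs = list(zip(range(len(labels) - 1), range(1, len(labels))))
        if design == "paired":
            for i, j in pairs:
                t, p = paired_t(totals[:, j], totals[:, i])
                test_rows.append(
                    {
                        "behaviour": b,
                        "test": "paired t",
                        "comparison": f"{labels[i]} vs {labels[j]}",
                        "statistic": t,
                        "p": p,
                        "significance": _stars(p),
                    }
                )
        elif design == "multi-group":
            groups = [totals[:, e] for e in range(len(labels))]
            if all(np.allclose(g, groups[0]) for g in groups[1:]) and all(
                np.isclose(g.std(ddof=1), 0) for g in groups
            ):
                f_stat, p_anova = 0.0, 1.0
            else:
                f_stat, p_anova = stats.f_oneway(*groups)
            test_rows.append(
                {
                    "behaviour": b,
                    "test": "one-way ANOVA",
                    "comparison": " vs ".join(labels),
                    "statistic": float(f_stat),
                    "p": float(p_anova),
                    "significance": _stars(float(p_anova)),
                }
            )
            m = len(pairs)
            for i, j in pairs:
                t, p = paired_t(totals[:, j], totals[:, i])
                p_adj = min(1.0, p * m)
                test_rows.append(
                    {
                        "behaviour": b,
                        "test": f"Bonferroni t ({m} comparisons)",
                        "comparison": f"{labels[i]} vs {labels[j]}",
                        "statistic": t,
                        "p": p_adj,
                        "significance": _stars(p_adj),
                    }
                )
        else:
            raise InvalidParameterError("design must be 'paired' or 'multi-group'")
    return EpochComparison(
        design=design,
        summary=pd.DataFrame(sum_rows),
        tests=pd.DataFrame(test_rows),
        n_rois=len(sheets),
    )


# ----------------------------------------------------------------------
# dose-response
# ----------------------------------------------------------------------

@dataclass
class DoseResponse:
    """Per-intensity score summary and the steepest proportional-rise interval."""

    summary: pd.DataFrame  # intensity_klx, mean, sem, n (sorted by intensity)
    steepest_interval: tuple[float, float] | None
    monotone_nondecreasing: bool


def dose_response(scores_by_intensity) -> DoseResponse:
    """Summarize total scores across light intensities.

    Input is an iterable of (intensity_klx, total_score) pairs or a DataFrame
    with those two columns.  Reports the mean +/- SEM per intensity and the
    adjacent-level interval of maximal proportional increase
    ``(mean[i+1] - mean[i]) / mean[i]`` (a rise from zero dominates any
    finite ratio).  Constant scores yield no steepest interval.
    """
    if isinstance(scores_by_intensity, pd.DataFrame):
        df = scores_by_intensity.iloc[:, :2].copy()
        df.columns = ["intensity_klx", "score"]
    else:
        df = pd.DataFrame(list(scores_by_intensity), columns=["intensity_klx", "score"])
    levels = np.sort(df["intensity_klx"].unique())
    if len(levels) < 3:
        raise InsufficientLevelsError("dose-response needs >= 3 intensity levels")
    rows = []
    for lv in levels:
        col = df.loc[df["intensity_klx"] == lv, "score"].to_numpy(dtype=float)
        rows.append(
            {
                "intensity_klx": float(lv),
                "mean": col.mean(),
                "sem": col.std(ddof=1) / math.sqrt(len(col)) if len(col) > 1 else np.nan,
                "n": len(col),
            }
        )
    summary = pd.DataFrame(rows)
    means = summary["mean"].to_numpy()
    best, best_rise = None, 0.0
    for i in range(len(levels) - 1):
        delta = means[i + 1] - means[i]
        if delta <= 0:
            continue
        rise = math.inf if means[i] == 0 else delta / means[i]
        if rise > best_rise:
            best_rise = rise
            best = (float(levels[i]), float(levels[i + 1]))
    monotone = bool(np.all(np.diff(means) >= -1e-12))
    return DoseResponse(summary=summary, steepest_interval=best,
                        monotone_nondecreasing=monotone)


# ----------------------------------------------------------------------
# spectral normalization
# ----------------------------------------------------------------------

@dataclass
class SpectrumRecord:
    """Emission spectrum E(lambda) over wavelengths (nm)."""

    wavelengths_nm: np.ndarray
    emission: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if self.wavelengths_nm.shape != self.emission.shape:
            raise InvalidParameterError("wavelengths and emission must align")


def normalize_spectrum(spec: SpectrumRecord) -> SpectrumRecord:
    """Normalize an emission spectrum to its peak: E(lambda) / E(peak).

    The output maximum is exactly 1, attained at the peak wavelength;
    an all-zero (or non-positive) spectrum is a degenerate input.
    """
    peak = spec.emission.max(initial=-math.inf)
    if not np.isfinite(peak) or peak <= 0:
        raise DegenerateInputError("spectrum has no positive emission value")
    return SpectrumRecord(
        wavelengths_nm=spec.wavelengths_nm.copy(),
        emission=spec.emission / peak,
        normalized=True,
    )
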