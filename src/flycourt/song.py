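"""Courtship-song segmentation: pulse trains and sine song.

Drosophila courtship song has two modes: *pulse song* — trains of brief
(~millisecond) sound pulses whose inter-pulse interval (IPI) is a classic
species-specific parameter — and *sine song*, a sustained low-frequency
(~100-200 Hz) hum.  The segmenter band-passes the recording, detects pulses
as envelope peaks above a noise-relative threshold, groups them into bouts,
and finds sine segments as sustained sine-band power whose spectral peak
lies inside the sine band.

All thresholds are expressed relative to the recording's noise level
(median absolute deviation of the envelope), so the segmentation is
invariant to overall amplitude scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import InvalidParameterError, SampleRateError

__all__ = [
    "SongParams",
    "PulseBout",
    "SineSegment",
    "SongSegmentation",
    "segment_song",
    "compare_song_stats",
]


@dataclass
class SongParams:
    """Analysis bands and thresholds for song segmentation."""

    sample_rate: float = 10_000.0
    pulse_band_hz: tuple[float, float] = (100.0, 500.0)
    sine_band_hz: tuple[float, float] = (100.0, 200.0)
    pulse_threshold_mads: float = 6.0
    refractory_s: float = 0.005
    bout_break_s: float = 0.1
    min_pulses_per_bout: int = 3
    min_sine_duration_s: float = 0.2
    sine_threshold_mads: float = 6.0
    envelope_cutoff_hz: float = 60.0

    def __post_init__(self):
        for band in (self.pulse_band_hz, self.sine_band_hz):
            if band[0] <= 0 or band[1] <= band[0]:
                raise InvalidParameterError("frequency bands must be positive and ordered")
        if self.pulse_threshold_mads <= 0 or self.sine_threshold_mads <= 0:
            raise InvalidParameterError("thresholds must be positive")
        if self.sample_rate < 2 * max(self.pulse_band_hz[1], self.sine_band_hz[1]):
            raise SampleRateError(
                "sample rate must be at least twice the upper analysis band edge"
            )


@dataclass
class PulseBout:
    """A group of pulses separated by gaps no longer than the bout break."""

    start_s: float
    end_s: float
    n_pulses: int
    ipis_s: list[float]

    @property
    def mean_ipi_s(self) -> float:
        return float(np.mean(self.ipis_s)) if self.ipis_s else math.nan


@dataclass
class SineSegment:
    start_s: float
    end_s: float
    dominant_freq_hz: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SongSegmentation:
    """Pulse times, pulse bouts and sine segments of one recording."""

    pulse_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    bouts: list[PulseBout] = field(default_factory=list)
    sine_segments: list[SineSegment] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.pulse_times_s) == 0 and not self.sine_segments

    def ipis_s(self) -> np.ndarray:
        """All within-bout inter-pulse intervals pooled across bouts."""
        vals = [ipi for b in self.bouts for ipi in b.ipis_s]
        return np.asarray(vals)


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _envelope(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    # rectification + zero-phase low-pass
    sos = signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    return np.maximum(signal.sosfiltfilt(sos, np.abs(x)), 0.0)


def segment_song(audio: np.ndarray, params: SongParams | None = None) -> SongSegmentation:
    """Segment a mono waveform into pulse and sine song components.

    Pulses are local maxima of the band-passed envelope that exceed
    ``pulse_threshold_mads`` times the envelope's MAD-based noise scale,
    separated by at least the refractory interval.  Pulses with gaps no
    longer than ``bout_break_s`` form a bout (kept if it has at least
    ``min_pulses_per_bout`` pulses).  Sine segments are maximal runs of
    sustained sine-band envelope whose periodogram peak lies inside the sine
    band and that last at least ``min_sine_duration_s``; the dominant
    frequency comes from the segment's own periodogram.
    """
    params = params or SongParams()
    fs = params.sample_rate
    x = np.asarray(audio, dtype=float)
    if x.ndim != 1:
        raise InvalidParameterError("audio must be a 1-D waveform")
    if len(x) < int(0.05 * fs):
        return SongSegmentation()

    # ---- pulses -------------------------------------------------------
    xp = _bandpass(x, params.pulse_band_hz, fs)
    env = _envelope(xp, fs, params.envelope_cutoff_hz)
    baseline = float(np.median(env))
    noise = 1.4826 * np.median(np.abs(env - baseline))
    thr = baseline + params.pulse_threshold_mads * noise + 1e-3 * env.max(initial=0.0) + 1e-30
    # prominence keeps sustained-hum ripple (sine song falls inside the
    # pulse band) from masquerading as pulses: a real pulse rises from a
    # near-silent envelope, ripple rides on a high sustained baseline
    peaks, _ = signal.find_peaks(
        env,
        height=thr,
        distance=max(1, int(params.refractory_s * fs)),
        prominence=thr - baseline,
    )
    pulse_times = peaks / fs

    bouts: list[PulseBout] = []
    if len(pulse_times):
        splits = np.nonzero(np.diff(pulse_times) > params.bout_break_s)[0]
        groups = np.split(pulse_times, splits + 1)
        for g in groups:
            if len(g) >= params.min_pulses_per_bout:
                bouts.append(
                    PulseBout(
                        start_s=float(g[0]),
                        end_s=float(g[-1]),
                        n_pulses=len(g),
                        ipis_s=list(np.diff(g)),
                    )
                )

    # ---- sine song ----------------------------------------------------
    xs = _bandpass(x, params.sine_band_hz, fs)
    env_s = _envelope(xs, fs, params.envelope_cutoff_hz / 2)
    baseline_s = float(np.median(env_s))
    noise_s = 1.4826 * np.median(np.abs(env_s - baseline_s))
    thr_s = baseline_s + params.sine_threshold_mads * noise_s + 1e-3 * env_s.max(initial=0.0) + 1e-30
    active = env_s > thr_s
    sine_segments: list[SineSegment] = []
    min_len = int(params.min_sine_duration_s * fs)
    for s, e in _bool_runs(active):
        if e - s < min_len:
            continue
        seg = x[s:e]
        freqs, pxx = signal.periodogram(seg, fs=fs)
        # restrict the peak search to below the pulse band's upper edge
        sel = freqs <= params.pulse_band_hz[1]
        fpeak = float(freqs[sel][np.argmax(pxx[sel])])
        if params.sine_band_hz[0] <= fpeak <= params.sine_band_hz[1]:
            sine_segments.append(
                SineSegment(start_s=s / fs, end_s=e / fs, dominant_freq_hz=fpeak)
            )

    return SongSegmentation(
        pulse_times_s=pulse_times, bouts=bouts, sine_segments=sine_segments
    )


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    return list(zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]))


# ----------------------------------------------------------------------
# comparison of two segmentations
# ----------------------------------------------------------------------

def _range_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap of the two value ranges (1 for identical, 0 disjoint)."""
    lo_a, hi_a = float(np.min(a)), float(np.max(a))
    lo_b, hi_b = float(np.min(b)), float(np.max(b))
    inter = max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
    union = max(hi_a, hi_b) - min(lo_a, lo_b)
    if union == 0:  # both ranges are single points
        return 1.0 if lo_a == lo_b else 0.0
    return inter / union


def compare_song_stats(a: SongSegmentation, b: SongSegmentation) -> dict:
    """Compare song parameters between two segmentations.

    For each parameter (IPI, pulses per bout, sine frequency, sine duration)
    the report gives summary statistics, the overlap fraction of the two
    value ranges, and a two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.
    Parameters absent from either segmentation are flagged not comparable.
    """
    from scipy.stats import mannwhitneyu

    params = {
        "ipi_s": (a.ipis_s(), b.ipis_s()),
        "pulses_per_bout": (
            np.array([x.n_pulses for x in a.bouts], dtype=float),
            np.array([x.n_pulses for x in b.bouts], dtype=float),
        ),
        "sine_freq_hz": (
            np.array([x.dominant_freq_hz for x in a.sine_segments]),
            np.array([x.dominant_freq_hz for x in b.sine_segments]),
        ),
        "sine_duration_s": (
            np.array([x.duration_s for x in a.sine_segments]),
            np.array([x.duration_s for x in b.sine_segments]),
        ),
    }
    report: dict[str, dict] = {}
    for name, (va, vb) in params.items():
        if len(va) == 0 or len(vb) == 0:
            report[name] = {"comparable": False}
            continue
        if np.array_equal(va, vb):
            p = 1.0  # identical samples: no evidence of a shift, ties convention
        else:
            _, p = mannwhitneyu(va, vb, alternative="two-sided")
        report[name] = {
            "comparable": True,
            "n_a": int(len(va)),
            "n_b": int(len(vb)),
            "mean_a": float(np.mean(va)),
            "mean_b": float(np.mean(vb)),
            "range_a": (float(np.min(va)), float(np.max(va))),
            "range_b": (float(np.min(vb)), float(np.max(vb))),
            "range_overlap": _range_overlap(va, vb),
            "rank_sum_p": float(p),
        }
    return report
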