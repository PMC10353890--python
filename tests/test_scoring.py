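"""Interval scoring, epoch statistics, dose-response and spectra."""

import numpy as np
import pytest

import flycourt as fc
from flycourt.errors import (
    DegenerateInputError,
    InsufficientLevelsError,
    InsufficientReplicatesError,
    InvalidParameterError,
    RangeError,
)
from flycourt.scoring import paired_t


def test_protocol_bins_must_divide_epochs():
    with pytest.raises(InvalidParameterError):
        fc.LightProtocol(epochs=[("low", 125.0, 0.4)])
    proto = fc.LightProtocol()
    assert proto.n_bins == 36
    assert proto.bins_per_epoch() == [12, 12, 12]
    assert proto.epoch_labels() == ["low1", "high", "low2"]


def test_saturated_epoch_reaches_the_twelve_point_ceiling():
    proto = fc.LightProtocol()
    sheet = fc.score_intervals({"chase": [(0.0, 360.0)]}, proto)
    assert list(sheet.epoch_totals("chase")) == [12, 12, 12]


def test_no_events_scores_zero_everywhere():
    sheet = fc.score_intervals({"chase": [], "chain": []}, fc.LightProtocol())
    assert not sheet.marks["chase"].any()
    assert not sheet.marks["chain"].any()


def test_events_mark_exactly_their_bins():
    proto = fc.LightProtocol()
    # bins 1 and 5 of the high epoch = bins 13 and 17 overall
    events = [(120.0 + 10.0 + 2.0, 120.0 + 10.0 + 3.0),
              (120.0 + 50.0 + 1.0, 120.0 + 50.0 + 2.5)]
    sheet = fc.score_intervals({"chase": events}, proto)
    assert sheet.epoch_totals("chase")[1] == 2
    assert np.flatnonzero(sheet.marks["chase"]).tolist() == [13, 17]


def test_alternating_mode_consults_only_the_assigned_half_window():
    proto = fc.LightProtocol()
    event = [(6.0, 7.0)]  # second half of the first 10-s interval
    first = fc.score_intervals({"chase": event}, proto, alternating=True, window_slot=0)
    second = fc.score_intervals({"chase": event}, proto, alternating=True, window_slot=1)
    assert first.epoch_totals("chase")[0] == 0
    assert second.epoch_totals("chase")[0] == 1


def test_event_outside_protocol_span_raises_range_error():
    with pytest.raises(RangeError):
        fc.score_intervals({"chase": [(350.0, 380.0)]}, fc.LightProtocol())


def test_adding_events_never_decreases_totals():
    proto = fc.LightProtocol()
    rng = np.random.default_rng(1)
    starts = np.sort(rng.uniform(0, 355, size=12))
    events = [(s, s + 2.0) for s in starts]
    prev = np.zeros(3, int)
    for k in range(1, len(events) + 1):
        totals = fc.score_intervals({"chase": events[:k]}, proto).epoch_totals("chase")
        assert np.all(totals >= prev)
        assert np.all(totals <= 12)
        prev = totals


# ----------------------------------------------------------------------
# epoch statistics
# ----------------------------------------------------------------------

def _sheets_from_totals(low1, high, low2):
    """Build score sheets whose epoch totals equal the given vectors."""
    proto = fc.LightProtocol()
    sheets = []
    for r, (a, b, c) in enumerate(zip(low1, high, low2)):
        marks = np.zeros(36, int)
        marks[:a] = 1
        marks[12 : 12 + b] = 1
        marks[24 : 24 + c] = 1
        sheets.append(
            fc.BehaviorScoreSheet(protocol=proto, marks={"chase": marks}, roi_id=r)
        )
    return sheets


def test_identical_epochs_give_t_zero_p_one():
    totals = [3, 5, 2, 7, 4, 6, 3, 5, 2, 7, 4, 6]
    sheets = _sheets_from_totals(totals, totals, totals)
    report = fc.compare_epochs(sheets, design="paired")
    assert np.allclose(report.tests["statistic"], 0.0)
    assert np.allclose(report.tests["p"], 1.0)


def test_paired_t_matches_hand_computed_textbook_value():
    """low (1,2,1,0,2) vs high (9,10,12,8,11): t = 15.0918755, p = 1.1235e-4."""
    t, p = paired_t(np.array([9, 10, 12, 8, 11]), np.array([1, 2, 1, 0, 2]))
    assert t == pytest.approx(15.091875492540778, abs=1e-6)
    assert p == pytest.approx(0.00011234981625991717, abs=1e-9)


def test_constant_nonzero_shift_reports_divergent_statistic():
    t, p = paired_t(np.array([5.0, 6.0, 7.0]), np.array([1.0, 2.0, 3.0]))
    assert np.isinf(t) and t > 0
    assert p == 0.0


def test_compare_epochs_requires_replicates():
    sheets = _sheets_from_totals([1], [5], [1])
    with pytest.raises(InsufficientReplicatesError):
        fc.compare_epochs(sheets)


def test_multi_group_anova_with_bonferroni_posthoc():
    rng = np.random.default_rng(0)
    low = rng.integers(0, 4, size=10)
    high = rng.integers(8, 13, size=10)
    low2 = rng.integers(0, 4, size=10)
    report = fc.compare_epochs(_sheets_from_totals(low, high, low2),
                               design="multi-group")
    anova = report.tests[report.tests.test == "one-way ANOVA"].iloc[0]
    assert anova.p < 0.001
    posthoc = report.tests[report.tests.test.str.startswith("Bonferroni")]
    assert len(posthoc) == 2
    assert (posthoc.p <= 1.0).all()


def test_anova_type_one_error_calibrated_under_the_null():
    """Three groups from one distribution: rejection rate ~ alpha = 0.05."""
    rng = np.random.default_rng(2024)
    rejections = 0
    for _ in range(100):
        groups = rng.normal(5, 2, size=(3, 12))
        sheets = _sheets_from_totals(*np.clip(np.round(groups), 0, 12).astype(int))
        report = fc.compare_epochs(sheets, design="multi-group")
        p = report.tests[report.tests.test == "one-way ANOVA"].iloc[0].p
        rejections += p < 0.05
    # Binomial(100, 0.05): central 99.9% interval is about [0, 12]
    assert rejections <= 12


# ----------------------------------------------------------------------
# dose-response
# ----------------------------------------------------------------------

def test_steepest_proportional_rise_interval():
    table = [(0.4, 1.0), (2.0, 2.0), (6.0, 10.0), (18.0, 11.0)]
    dr = fc.dose_response(table)
    assert dr.steepest_interval == (2.0, 6.0)
    assert dr.monotone_nondecreasing


def test_constant_scores_have_no_rise():
    dr = fc.dose_response([(0.4, 5.0), (2.0, 5.0), (6.0, 5.0)])
    assert dr.steepest_interval is None


def test_dose_response_needs_three_levels():
    with pytest.raises(InsufficientLevelsError):
        fc.dose_response([(0.4, 1.0), (18.0, 11.0)])


def test_simulated_intensity_sweep_is_monotone():
    """Detected chase scores increase with illuminance across the sweep."""
    rows = []
    ip = fc.InteractionParams()
    for intensity in (0.4, 2.0, 6.0, 18.0):
        for seed in range(3):
            params = fc.SimParams(
                seed=seed, epoch_schedule=[("sweep", 120.0, intensity)])
            traj, _ = fc.simulate_arena(params)
            ig = fc.compute_interactogram(traj, ip)
            chases = fc.detect_chases(traj, ig, ip)
            proto = fc.LightProtocol(epochs=[("sweep", 120.0, intensity)])
            events = [(s, min(e, 120.0)) for s, e in
                      fc.events_to_intervals(chases, traj.frame_rate)]
            sheet = fc.score_intervals({"chase": events}, proto)
            rows.append((intensity, int(sheet.epoch_totals("chase")[0])))
    dr = fc.dose_response(rows)
    means = dr.summary["mean"].to_numpy()
    assert np.all(np.diff(means) >= -1.0)  # sampling tolerance of one interval
    assert means[-1] > means[0] + 5


# ----------------------------------------------------------------------
# spectra
# ----------------------------------------------------------------------

def test_normalize_spectrum_examples_and_properties():
    spec = fc.SpectrumRecord(wavelengths_nm=[400, 500, 600], emission=[2.0, 4.0, 8.0])
    out = fc.normalize_spectrum(spec)
    assert np.allclose(out.emission, [0.25, 0.5, 1.0])
    # idempotence and scale invariance
    again = fc.normalize_spectrum(out)
    assert np.allclose(again.emission, out.emission)
    scaled = fc.normalize_spectrum(
        fc.SpectrumRecord(spec.wavelengths_nm, spec.emission * 37.5))
    assert np.allclose(scaled.emission, out.emission)


def test_normalize_spectrum_random_vector_peak_is_one():
    rng = np.random.default_rng(7)
    e = rng.uniform(0.1, 5.0, size=100)
    out = fc.normalize_spectrum(fc.SpectrumRecord(np.arange(100), e))
    assert out.emission.max() == 1.0
    assert np.argmax(out.emission) == np.argmax(e)


def test_all_zero_spectrum_is_degenerate():
    with pytest.raises(DegenerateInputError):
        fc.normalize_spectrum(fc.SpectrumRecord(np.arange(5), np.zeros(5)))
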