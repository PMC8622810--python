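"""Fixation detection, outlier exclusion and analysis-window extraction."""

import numpy as np
import pytest

import gazehmm as gz
from gazehmm.errors import WindowError
from gazehmm.preprocessing import ExclusionReport


def _samples(positions, dt_ms=10.0, t0=0.0):
    return [gz.GazeSample(t=t0 + i * dt_ms, x=p[0], y=p[1])
            for i, p in enumerate(positions)]


# --------------------------------------------------------------------- #
#  detect_fixations
# --------------------------------------------------------------------- #

def test_constant_position_is_one_fixation():
    samples = _samples([(1.0, 1.0)] * 30)  # 290 ms span at 100 Hz
    seq = gz.detect_fixations(samples)
    assert len(seq) == 1
    assert seq.duration[0] == pytest.approx(290.0)
    assert np.allclose(seq.xy[0], [1.0, 1.0])


def test_constant_fast_motion_yields_no_fixations():
    # 120 deg/s at 100 Hz: 1.2 deg between samples
    samples = _samples([(i * 1.2, 0.0) for i in range(50)])
    assert len(gz.detect_fixations(samples)) == 0


def test_short_dwell_rejected():
    """A 200-ms dwell passes the 60-ms rule; a 50-ms dwell does not."""
    pos = [(0.0, 0.0)] * 21            # 200-ms dwell (21 samples at 100 Hz)
    pos += [(5.0, 0.0), (10.0, 0.0)]   # fast transit, 500 deg/s
    pos += [(15.0, 0.0)] * 6           # 50-ms dwell (span 230..280 ms)
    seq = gz.detect_fixations(_samples(pos))
    assert len(seq) == 1
    assert np.allclose(seq.xy[0], [0.0, 0.0])


def test_too_few_samples_gives_empty_sequence():
    assert len(gz.detect_fixations(_samples([(0, 0)]))) == 0


def test_invalid_samples_split_runs():
    pos = [(0.0, 0.0)] * 40
    samples = _samples(pos)
    # two consecutive tracking losses: the 30-ms hole exceeds 2 sample
    # intervals, so the dwell is split; a single loss (20 ms) would not split
    for i in (20, 21):
        samples[i] = gz.GazeSample(t=samples[i].t, x=0.0, y=0.0, valid=False)
    seq = gz.detect_fixations(samples)
    assert len(seq) == 2
    single = list(samples)
    single[21] = gz.GazeSample(t=samples[21].t, x=0.0, y=0.0)
    assert len(gz.detect_fixations(single)) == 1


# --------------------------------------------------------------------- #
#  exclude_outlier_fixations
# --------------------------------------------------------------------- #

def _seq_with_durations(durations):
    n = len(durations)
    onsets = np.cumsum([0.0] + [d + 50 for d in durations[:-1]])
    return gz.FixationSequence(xy=np.zeros((n, 2)), onset=onsets,
                               duration=np.array(durations, float))


def test_equal_durations_keep_everything():
    seqs = [_seq_with_durations([250.0] * 100)]
    kept, report = gz.exclude_outlier_fixations(seqs)
    assert report.n_removed == 0
    assert len(kept[0]) == 100


def test_single_extreme_duration_removed():
    """Direct mean/SD arithmetic: only the 5000-ms fixation exceeds
    mean + 3 SD of 99 x 200 ms + 1 x 5000 ms."""
    durations = [200.0] * 99 + [5000.0]
    mean = np.mean(durations)
    sd = np.std(durations, ddof=1)
    assert 5000.0 > mean + 3 * sd > 200.0  # oracle arithmetic
    kept, report = gz.exclude_outlier_fixations([_seq_with_durations(durations)])
    assert report.n_removed == 1
    assert len(kept[0]) == 99
    assert np.all(kept[0].duration == 200.0)


def test_no_removal_is_identity():
    seq = _seq_with_durations([200.0, 220.0, 260.0])
    kept, _ = gz.exclude_outlier_fixations([seq])
    assert kept[0] is seq


def test_exclusion_fraction_exact():
    durations = [100.0] * 49 + [9000.0]
    _, report = gz.exclude_outlier_fixations([_seq_with_durations(durations)])
    assert report.fraction_removed == 1 - (report.n_total - report.n_removed) / report.n_total


def test_report_handles_empty_input():
    kept, report = gz.exclude_outlier_fixations([])
    assert kept == [] and isinstance(report, ExclusionReport)
    assert report.fraction_removed == 0.0


# --------------------------------------------------------------------- #
#  extract_window
# --------------------------------------------------------------------- #

def _seq_at(onsets):
    n = len(onsets)
    return gz.FixationSequence(xy=np.zeros((n, 2)),
                               onset=np.array(onsets, float),
                               duration=np.full(n, 100.0))


def test_window_membership_half_open():
    seq = _seq_at([4000.0, 6000.0, 14500.0, 15200.0])
    event = gz.AnalysisEvent(kind="no_go_target", block=0, onset=15000.0)
    win = gz.extract_window(seq, event)
    assert list(win.onset) == [6000.0, 14500.0]
    assert win.window_type == "pre_target"
    assert not win.truncated


def test_early_event_truncates_window():
    seq = _seq_at([1000.0, 3500.0])
    event = gz.AnalysisEvent(kind="probe", block=2, onset=4000.0)
    win = gz.extract_window(seq, event)
    assert win.truncated
    assert win.window_type == "pre_probe"
    assert list(win.onset) == [1000.0, 3500.0]


def test_empty_input_gives_empty_window():
    seq = _seq_at([])
    event = gz.AnalysisEvent(kind="probe", block=0, onset=1000.0)
    assert len(gz.extract_window(seq, event)) == 0


def test_event_outside_recording_rejected():
    seq = _seq_at([0.0, 500.0])
    with pytest.raises(WindowError):
        gz.extract_window(seq, gz.AnalysisEvent(kind="probe", block=0,
                                                onset=-5.0))
    with pytest.raises(WindowError):
        gz.extract_window(seq, gz.AnalysisEvent(kind="probe", block=0,
                                                onset=99_000.0))


def test_window_never_alters_fixation_fields(rng):
    spec = gz.make_archetype("centralized", 2)
    seq = gz.sample_fixation_sequence(spec, 25, rng)
    event = gz.AnalysisEvent(kind="no_go_target", block=1,
                             onset=float(seq.onset[-1]))
    win = gz.extract_window(seq, event)
    for i, onset in enumerate(win.onset):
        j = int(np.flatnonzero(seq.onset == onset)[0])
        assert np.array_equal(win.xy[i], seq.xy[j])
        assert win.duration[i] == seq.duration[j]
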