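"""SDT scoring, probe labeling, the D-C scale, G² and group statistics."""

import csv
import math
from pathlib import Path
from statistics import NormalDist

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazehmm as gz
from gazehmm.analysis import EXCLUDED, FA, MW
from gazehmm.errors import AnalysisError

DATA = Path(__file__).parent / "data"


def _record(participant="p", block=0, trial=1, letter="A", is_target=False,
            responded=True, rt=300.0):
    return gz.SartRecord(participant=participant, block=block,
                         trial_index=trial, letter=letter, is_target=is_target,
                         responded=responded, rt_ms=rt if responded else None)


def _target(responded, block=0, trial=10):
    return _record(block=block, trial=trial, letter="C", is_target=True,
                   responded=responded)


# --------------------------------------------------------------------- #
#  SDT
# --------------------------------------------------------------------- #

def test_score_sdt_perfect_performance():
    records = [_target(False, block=b) for b in range(40)]
    records += [_record(block=b % 40, trial=2 + b % 20) for b in range(960)]
    counts = gz.score_sdt(records)
    assert (counts.hits, counts.misses, counts.false_alarms,
            counts.correct_rejections) == (40, 0, 0, 960)


def test_score_sdt_all_commissions():
    counts = gz.score_sdt([_target(True, block=b) for b in range(40)])
    assert counts.hits == 0 and counts.misses == 40


def test_score_sdt_toy_log_hand_count():
    """10-trial toy log: 1 target withheld, 2 Go lapses -> (1, 0, 2, 7)."""
    records = [_target(False, trial=6)]
    records += [_record(trial=t, responded=False, rt=None) for t in (2, 9)]
    records += [_record(trial=t) for t in (1, 3, 4, 5, 7, 8, 10)]
    counts = gz.score_sdt(records)
    assert (counts.hits, counts.misses, counts.false_alarms,
            counts.correct_rejections) == (1, 0, 2, 7)


def test_dprime_zero_at_equal_corrected_rates():
    counts = gz.SdtCounts(hits=20, misses=20, false_alarms=480,
                          correct_rejections=480)
    assert gz.dprime(counts) == pytest.approx(0.0, abs=1e-9)


def test_dprime_against_independent_quantile_oracle():
    """Log-linear corrected d' versus the stdlib inverse-normal CDF."""
    counts = gz.SdtCounts(hits=32, misses=8, false_alarms=48,
                          correct_rejections=912)
    inv = NormalDist().inv_cdf
    expected = inv((32 + 0.5) / 41) - inv((48 + 0.5) / 961)
    assert gz.dprime(counts) == pytest.approx(expected, abs=1e-9)


def test_dprime_monotone_in_hits():
    values = [gz.dprime(gz.SdtCounts(h, 40 - h, 48, 912)) for h in range(41)]
    assert np.all(np.diff(values) > 0)


def test_dprime_finite_at_extremes():
    assert math.isfinite(gz.dprime(gz.SdtCounts(40, 0, 0, 960)))
    assert math.isfinite(gz.dprime(gz.SdtCounts(0, 40, 960, 0)))


def test_dprime_requires_both_classes():
    with pytest.raises(AnalysisError):
        gz.dprime(gz.SdtCounts(0, 0, 10, 10))


def test_windowed_records_keep_five_go_trials_per_block():
    records = [_record(trial=t, block=0) for t in range(1, 26) if t != 12]
    records.append(_target(False, block=0, trial=12))
    windowed = gz.windowed_records(records)
    gos = [r.trial_index for r in windowed if not r.is_target]
    assert sorted(gos) == [7, 8, 9, 10, 11]
    assert sum(r.is_target for r in windowed) == 1


# --------------------------------------------------------------------- #
#  labels
# --------------------------------------------------------------------- #

def test_label_objective():
    assert gz.label_objective(_target(False)) == FA
    assert gz.label_objective(_target(True)) == MW
    with pytest.raises(AnalysisError):
        gz.label_objective(_record())


def test_label_subjective_matches_truth_table():
    """Exhaustive 35-pair enumeration versus the hand-written table."""
    with open(DATA / "probe_label_truth.csv") as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == 35
    for row in rows:
        probe = gz.ProbeResponse("p", 0, int(row["option"]), int(row["rating"]))
        assert gz.label_subjective(probe) == row["label"], row


def test_probe_out_of_range_rejected():
    with pytest.raises(AnalysisError):
        gz.ProbeResponse("p", 0, option=6, rating=3)
    with pytest.raises(AnalysisError):
        gz.ProbeResponse("p", 0, option=1, rating=8)


def test_proportion_fa_denominator_includes_excluded():
    labels = [FA] * 20 + [MW] * 10 + [EXCLUDED] * 10
    assert gz.proportion_fa(labels) == 0.5
    assert gz.proportion_fa([FA] * 40) == 1.0
    assert gz.proportion_fa([MW, EXCLUDED]) == 0.0
    with pytest.raises(AnalysisError):
        gz.proportion_fa([])


# --------------------------------------------------------------------- #
#  D-C scale and trial classification
# --------------------------------------------------------------------- #

def _dc(d_mll, c_mll):
    denom = abs(d_mll) + abs(c_mll)
    return (d_mll - c_mll) / denom


def test_dc_score_arithmetic(two_state_model, rng):
    """dc is computed from the two mean log-likelihoods exactly as the
    normalized difference; (-8, -12) gives +0.2."""
    assert _dc(-8.0, -12.0) == pytest.approx(0.2)
    spec = gz.ArchetypeSpec("distributed", two_state_model)
    seqs = [gz.sample_fixation_sequence(spec, 15, rng) for _ in range(5)]
    other = two_state_model.permute([1, 0])
    score = gz.dc_score(seqs, two_state_model, other)
    assert score.dc == pytest.approx(_dc(score.d_mll, score.c_mll))
    swapped = gz.dc_score(seqs, other, two_state_model)
    assert swapped.dc == pytest.approx(-score.dc, abs=1e-12)


def test_dc_zero_for_identical_representatives(two_state_model, rng):
    spec = gz.ArchetypeSpec("distributed", two_state_model)
    seqs = [gz.sample_fixation_sequence(spec, 10, rng)]
    score = gz.dc_score(seqs, two_state_model, two_state_model)
    assert score.dc == pytest.approx(0.0)


@settings(max_examples=200, derandomize=True)
@given(st.floats(-1e6, -1e-3), st.floats(-1e6, -1e-3))
def test_dc_always_in_unit_interval(d_mll, c_mll):
    assert -1.0 <= _dc(d_mll, c_mll) <= 1.0


def test_classify_trial_tie_and_invariance(two_state_model, rng):
    seq = gz.FixationSequence(xy=[[0.0, 0.0]], onset=[0.0], duration=[200.0])
    assert gz.classify_trial(seq, two_state_model, two_state_model) == "centralized"
    c = gz.make_archetype("centralized", 0).hmm
    d = gz.make_archetype("distributed", 0).hmm
    spec = gz.ArchetypeSpec("centralized", c)
    sample = gz.sample_fixation_sequence(spec, 20, rng)
    label = gz.classify_trial(sample, d, c)
    assert label == gz.classify_trial(sample, d.permute([2, 0, 1]),
                                      c.permute([1, 2, 0]))


def test_classify_trial_recovers_generator(rng):
    """Sequences drawn from the centralized representative classify as
    centralized in the large majority of draws."""
    c = gz.make_archetype("centralized", 0).hmm
    d = gz.make_archetype("distributed", 0).hmm
    spec = gz.ArchetypeSpec("centralized", c)
    hits = sum(
        gz.classify_trial(gz.sample_fixation_sequence(spec, 20, rng), d, c)
        == "centralized"
        for _ in range(200)
    )
    assert hits >= 160


# --------------------------------------------------------------------- #
#  G² and group statistics
# --------------------------------------------------------------------- #

def test_g2_uniform_table():
    g2, p, odds = gz.g2_test(gz.ContingencyTable(10, 10, 10, 10))
    assert g2 == pytest.approx(0.0, abs=1e-12)
    assert odds == pytest.approx(1.0)
    assert p == pytest.approx(1.0)


def test_g2_against_direct_formula():
    """G²([[30,10],[10,30]]) = 2(2*30 ln 1.5 + 2*10 ln 0.5); OR = 9."""
    expected = 2 * (2 * 30 * math.log(1.5) + 2 * 10 * math.log(0.5))
    g2, p, odds = gz.g2_test(gz.ContingencyTable(30, 10, 10, 30))
    assert g2 == pytest.approx(expected, abs=1e-9)
    assert odds == pytest.approx(9.0)
    assert 0 < p < 1e-3


def test_g2_transpose_invariance():
    a = gz.g2_test(gz.ContingencyTable(12, 5, 7, 20))[0]
    b = gz.g2_test(gz.ContingencyTable(12, 7, 5, 20))[0]
    assert a == pytest.approx(b, abs=1e-12)


def test_g2_zero_margin_rejected_and_haldane_correction():
    with pytest.raises(AnalysisError):
        gz.g2_test(gz.ContingencyTable(0, 0, 10, 10))
    _, _, odds = gz.g2_test(gz.ContingencyTable(10, 0, 5, 10))
    assert odds == pytest.approx((10.5 * 10.5) / (0.5 * 5.5))


@settings(max_examples=100, derandomize=True)
@given(st.tuples(*[st.integers(1, 500)] * 4))
def test_g2_symmetry_properties(cells):
    """G² is invariant to transposition and the OR inverts when the outcome
    columns are swapped, for any positive 2x2 table."""
    a, b, c, d = cells
    g2, _, odds = gz.g2_test(gz.ContingencyTable(a, b, c, d))
    g2_t, _, _ = gz.g2_test(gz.ContingencyTable(a, c, b, d))
    g2_s, _, odds_s = gz.g2_test(gz.ContingencyTable(b, a, d, c))
    assert g2 >= -1e-12
    assert g2_t == pytest.approx(g2, abs=1e-9)
    assert g2_s == pytest.approx(g2, abs=1e-9)
    assert odds_s == pytest.approx(1.0 / odds, rel=1e-9)


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 40), st.integers(0, 960))
def test_dprime_finite_everywhere(hits, fas):
    """The log-linear correction keeps d' finite over the whole count grid."""
    val = gz.dprime(gz.SdtCounts(hits, 40 - hits, fas, 960 - fas))
    assert math.isfinite(val)


def test_group_stats_identical_groups():
    stats = gz.group_stats(group_a=[1.0, 2.0, 3.0], group_b=[1.0, 2.0, 3.0])
    assert stats.t_ind == pytest.approx(0.0)
    assert stats.cohen_d == pytest.approx(0.0)


def test_group_stats_perfect_negative_line():
    xy = [(x, 5.0 - 2.0 * x) for x in (0.0, 1.0, 2.0, 3.0)]
    stats = gz.group_stats(xy_pairs=xy)
    assert stats.pearson_r == pytest.approx(-1.0)


def test_group_stats_textbook_oracle():
    """Five-point hand dataset versus the classical formulas."""
    a = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
    b = np.array([2.0, 3.0, 5.0, 6.0, 4.0])
    # hand-computed pooled t statistic
    sp2 = ((a.var(ddof=1) * 4) + (b.var(ddof=1) * 4)) / 8
    t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (2 / 5))
    # hand-computed Pearson r
    r_hand = float(np.sum((a - a.mean()) * (b - b.mean()))
                   / math.sqrt(np.sum((a - a.mean()) ** 2)
                               * np.sum((b - b.mean()) ** 2)))
    stats = gz.group_stats(group_a=a, group_b=b, xy_pairs=list(zip(a, b)))
    assert stats.t_ind == pytest.approx(t_hand, abs=1e-12)
    assert stats.pearson_r == pytest.approx(r_hand, abs=1e-12)


def test_group_stats_degenerate_rejected():
    with pytest.raises(AnalysisError):
        gz.group_stats(group_a=[1.0, 1.0], group_b=[1.0, 1.0])
    with pytest.raises(AnalysisError):
        gz.group_stats(xy_pairs=[(1, 2), (1, 3), (1, 4)])


def test_paired_t_direction():
    pairs = [(3.0, 1.0), (4.0, 2.5), (5.0, 3.0), (6.0, 5.5)]
    stats = gz.group_stats(paired_pairs=pairs)
    assert stats.t_paired > 0
    assert stats.df_paired == 3
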