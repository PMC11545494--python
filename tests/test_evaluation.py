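"""Frame truth construction, confusion-cell metrics, stream evaluation."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egdloc.evaluation import (
    ConfusionCell,
    FrameTruth,
    IntervalLabel,
    build_frame_truth,
    evaluate_stream,
    metric_formulas,
    read_intervals,
    window_sweep,
    write_intervals,
)
from egdloc.taxonomy import FINE_ORDER, FineLabel


# --- interval I/O ----------------------------------------------------------


def test_interval_csv_roundtrip(tmp_path):
    ivs = [IntervalLabel(0, 10, "ES"), IntervalLabel(10, 25.5, "GE")]
    path = tmp_path / "gt.csv"
    write_intervals(ivs, path)
    assert read_intervals(path) == ivs
    with pytest.raises(ValueError, match="header"):
        read_intervals(io.StringIO("a,b,c\n0,1,ES\n"))


def test_interval_validation():
    with pytest.raises(ValueError, match="invalid interval"):
        IntervalLabel(5, 5, "ES")
    with pytest.raises(ValueError):
        IntervalLabel(-1, 5, "ES")


# --- frame truth -----------------------------------------------------------


def test_ambiguity_window_spans_180_frames_at_60fps():
    """3 s ambiguity at 60 fps covers exactly 180 frames around a boundary."""
    ivs = [IntervalLabel(0, 10, "ES"), IntervalLabel(10, 20, "GE")]
    truth = build_frame_truth(ivs, fps=60, n_frames=1200, ambiguity_seconds=3.0)
    both = [ft.frame_index for ft in truth if len(ft.allowed) == 2]
    assert len(both) == 180
    assert both[0] == 510 and both[-1] == 689
    assert truth[500].allowed == frozenset({FineLabel.ES})
    assert truth[700].allowed == frozenset({FineLabel.GE})


def test_single_interval_all_singletons():
    ivs = [IntervalLabel(0, 5, "AT")]
    truth = build_frame_truth(ivs, fps=60, n_frames=300)
    assert all(ft.allowed == frozenset({FineLabel.AT}) for ft in truth)


def test_gap_and_overlap_rejected():
    with pytest.raises(ValueError, match="gap"):
        build_frame_truth(
            [IntervalLabel(0, 5, "ES"), IntervalLabel(6, 10, "GE")], 60, 600
        )
    with pytest.raises(ValueError, match="overlap"):
        build_frame_truth(
            [IntervalLabel(0, 5, "ES"), IntervalLabel(4, 10, "GE")], 60, 600
        )
    with pytest.raises(ValueError, match="before duration"):
        build_frame_truth([IntervalLabel(0, 5, "ES")], 60, 600)


def test_close_boundaries_never_give_three_labels():
    # 1 s middle segment, 3 s windows: nearest-boundary rule caps at 2
    ivs = [
        IntervalLabel(0, 5, "ES"),
        IntervalLabel(5, 6, "NO"),
        IntervalLabel(6, 12, "GE"),
    ]
    truth = build_frame_truth(ivs, fps=60, n_frames=720)
    assert max(len(ft.allowed) for ft in truth) == 2
    # frames nearer the first boundary pair with ES, nearer the second with GE
    assert truth[310].allowed == frozenset({FineLabel.ES, FineLabel.NO})
    assert truth[350].allowed == frozenset({FineLabel.NO, FineLabel.GE})


# --- metric formulas -------------------------------------------------------


def test_metric_formulas_balanced_cell():
    m = metric_formulas(ConfusionCell(TP=9, FP=1, FN=1, TN=9))
    assert m.accuracy == 0.9
    assert m.precision == 0.9
    assert m.recall == 0.9
    assert m.specificity == 0.9
    assert math.isclose(m.f1, 0.9)


def test_metric_formulas_undefined_ratios_are_nan():
    m = metric_formulas(ConfusionCell(TP=1))
    assert m.precision == 1.0 and m.recall == 1.0 and m.f1 == 1.0
    assert math.isnan(m.specificity)
    m2 = metric_formulas(ConfusionCell(FN=5, TN=5))
    assert m2.recall == 0.0
    assert math.isnan(m2.precision)
    with pytest.raises(ValueError, match="all-zero"):
        metric_formulas(ConfusionCell())


# --- stream evaluation -----------------------------------------------------


def singleton_truth(labels):
    return [
        FrameTruth(i, frozenset({l})) for i, l in enumerate(labels)
    ]


def test_perfect_predictions_perfect_metrics():
    labels = [FineLabel.ES] * 5 + [FineLabel.AT] * 5
    truth = singleton_truth(labels)
    report = evaluate_stream(list(enumerate(labels)), truth)
    assert report.accuracy == 1.0
    for code in ("ES", "AT"):
        m = report.class_metrics(code)
        assert m.recall == 1.0 and m.specificity == 1.0


def test_no_votes_excluded_and_counts():
    """10 frames: 3 NO votes excluded, 2 wrong among the rest -> 5/7 accuracy."""
    truth = singleton_truth([FineLabel.AT] * 10)
    voted = [FineLabel.AT] * 5 + [FineLabel.AG] * 2 + [FineLabel.NO] * 3
    report = evaluate_stream(list(enumerate(voted)), truth)
    assert report.evaluated_frames == 7
    assert report.excluded_frames == 3
    assert report.accuracy == pytest.approx(5 / 7)


def test_no_vote_correct_when_truth_allows_no():
    truth = singleton_truth([FineLabel.NO] * 4)
    report = evaluate_stream(list(enumerate([FineLabel.NO] * 4)), truth)
    assert report.excluded_frames == 0
    assert report.evaluated_frames == 4
    assert report.per_class["NO"].TP == 4


def test_ambiguous_frame_either_label_correct():
    truth = [FrameTruth(0, frozenset({FineLabel.ES, FineLabel.GE}))]
    for label in (FineLabel.ES, FineLabel.GE):
        report = evaluate_stream([(0, label)], truth)
        assert report.accuracy == 1.0
        assert report.per_class[label.code].TP == 1
    report = evaluate_stream([(0, FineLabel.CR)], truth)
    assert report.per_class["CR"].FP == 1
    assert report.per_class["ES"].FN == 1 and report.per_class["GE"].FN == 1


def test_cell_conservation_invariant(default_stream):
    preds, truth = default_stream
    report = evaluate_stream([(p.frame_index, p.fine) for p in preds], truth)
    for code, cell in report.per_class.items():
        assert cell.total == report.evaluated_frames, code


def test_exclusion_monotonicity():
    """Appending NO-voted frames (truth not allowing NO) changes no cells."""
    truth = singleton_truth([FineLabel.AT] * 6)
    base = [(0, FineLabel.AT), (1, FineLabel.AG)]
    extended = base + [(2, FineLabel.NO), (3, FineLabel.NO)]
    r1 = evaluate_stream(base, truth)
    r2 = evaluate_stream(extended, truth)
    assert r1.per_class == r2.per_class
    assert r2.excluded_frames == 2


def test_missing_truth_errors():
    truth = singleton_truth([FineLabel.AT])
    with pytest.raises(ValueError, match="no ground truth"):
        evaluate_stream([(5, FineLabel.AT)], truth)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.sampled_from([l for l in FINE_ORDER]),  # truth
            st.sampled_from([l for l in FINE_ORDER]),  # vote
        ),
        min_size=1,
        max_size=50,
    )
)
def test_evaluate_matches_brute_force_tally(data):
    """Cell counts agree with a direct per-frame enumeration."""
    truth = singleton_truth([t for t, _ in data])
    voted = [(i, v) for i, (_, v) in enumerate(data)]
    report = evaluate_stream(voted, truth)
    # independent tally
    evaluated = [
        (t, v) for t, v in data if not (v is FineLabel.NO and t is not FineLabel.NO)
    ]
    assert report.evaluated_frames == len(evaluated)
    assert report.excluded_frames == len(data) - len(evaluated)
    for c in FINE_ORDER:
        tp = sum(1 for t, v in evaluated if v is c and v is t)
        fp = sum(1 for t, v in evaluated if v is c and v is not t)
        fn = sum(1 for t, v in evaluated if v is not c and t is c and v is not t)
        tn = len(evaluated) - tp - fp - fn
        assert report.per_class[c.code] == ConfusionCell(TP=tp, TN=tn, FP=fp, FN=fn)
    correct = sum(1 for t, v in evaluated if t is v)
    if evaluated:
        assert report.accuracy == pytest.approx(correct / len(evaluated))


# --- window sweep ----------------------------------------------------------


def test_window_sweep_noiseless_stream_all_perfect(default_procedure):
    from egdloc import EmissionSpec, SamplingPlan, emit_predictions

    spec, intervals, frames = default_procedure
    preds = emit_predictions(
        frames, SamplingPlan(fps=spec.fps), EmissionSpec(np.eye(11), seed=0)
    )
    truth = build_frame_truth(intervals, spec.fps, len(frames))
    table = window_sweep(preds, truth, sizes=[1, 4, 7])
    # noiseless raw stream: k=1 is perfect; larger windows only lag at
    # transitions, which the ambiguity windows absorb
    assert table.loc[table["window"] == 1, "accuracy"].item() == 1.0


def test_window_sweep_smoothing_beats_raw_under_noise(default_stream):
    preds, truth = default_stream
    table = window_sweep(preds, truth, sizes=[1, 7]).set_index("window")
    assert table.loc[7, "macro_f1"] >= table.loc[1, "macro_f1"]
    assert table.loc[7, "accuracy"] > table.loc[1, "accuracy"]


def test_window_sweep_size1_equals_unsmoothed(default_stream):
    preds, truth = default_stream
    table = window_sweep(preds, truth, sizes=[1])
    direct = evaluate_stream([(p.frame_index, p.fine) for p in preds], truth)
    assert table.loc[0, "accuracy"] == pytest.approx(direct.accuracy)
    assert table.loc[0, "evaluated_frames"] == direct.evaluated_frames
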