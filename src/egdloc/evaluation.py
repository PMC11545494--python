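"""Frame-level evaluation against interval ground truth.

Video ground truth is labeled in whole seconds because anatomical
boundaries are visually ambiguous; per-frame truth is derived from the
intervals, and every frame inside an ambiguity window around a transition
(3 s ≙ 180 frames at 60 fps, centered on the boundary) accepts either
adjacent label.  Evaluation is frame-by-frame, one-vs-rest per class, with
one deliberate exclusion: a frame whose *predicted* label is non-clear
(NO) is dropped from scoring — the model has declared the view
uninterpretable — unless the ground truth itself allows NO, in which case
the NO vote is simply correct.

Metrics are the standard confusion-cell ratios: accuracy, precision,
recall (sensitivity), specificity, F1.  Undefined ratios (0/0) are
reported as NaN, never coerced to 0.  Summary rows are macro averages over
the classes with at least one positive frame.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

from .classifier import FinePrediction
from .taxonomy import FINE_ORDER, FineLabel, as_fine
from .video import smooth_stream

__all__ = [
    "IntervalLabel",
    "FrameTruth",
    "ConfusionCell",
    "Metrics",
    "MetricsReport",
    "read_intervals",
    "write_intervals",
    "build_frame_truth",
    "evaluate_stream",
    "metric_formulas",
    "window_sweep",
]

_TOL = 1e-9


@dataclass(frozen=True)
class IntervalLabel:
    """One ground-truth segment: [start_second, end_second) → fine label."""

    start_second: float
    end_second: float
    label: FineLabel

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", as_fine(self.label))
        if self.start_second < 0 or self.end_second <= self.start_second:
            raise ValueError(
                f"invalid interval [{self.start_second}, {self.end_second})"
            )


@dataclass(frozen=True)
class FrameTruth:
    """Acceptable fine labels for one frame (two inside ambiguity windows)."""

    frame_index: int
    allowed: frozenset[FineLabel]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "allowed", frozenset(as_fine(l) for l in self.allowed)
        )
        if not 1 <= len(self.allowed) <= 2:
            raise ValueError("allowed set must have 1 or 2 labels")


class ConfusionCell(NamedTuple):
    """One-vs-rest confusion counts for a single class."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


class Metrics(NamedTuple):
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def metric_formulas(cell: ConfusionCell) -> Metrics:
    """Accuracy, precision, recall, specificity and F1 from one cell.

    accuracy = (TP+TN)/(TP+FP+FN+TN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); specificity = TN/(TN+FP);
    F1 = 2·precision·recall/(precision+recall).  0/0 → NaN.
    """
    if cell.total == 0:
        raise ValueError("all-zero confusion cell")
    precision = _ratio(cell.TP, cell.TP + cell.FP)
    recall = _ratio(cell.TP, cell.TP + cell.FN)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(
        accuracy=_ratio(cell.TP + cell.TN, cell.total),
        precision=precision,
        recall=recall,
        specificity=_ratio(cell.TN, cell.TN + cell.FP),
        f1=f1,
    )


def read_intervals(source: Union[str, Path, IO[str]]) -> list[IntervalLabel]:
    """Read interval ground truth CSV (header ``start_second,end_second,label``)."""
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_intervals(fh)
    reader = csv.DictReader(source)
    required = {"start_second", "end_second", "label"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValueError(
            "interval CSV must have header 'start_second,end_second,label'"
        )
    return [
        IntervalLabel(float(r["start_second"]), float(r["end_second"]), r["label"])
        for r in reader
    ]


def write_intervals(
    intervals: Sequence[IntervalLabel], dest: Union[str, Path, IO[str]]
) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            write_intervals(intervals, fh)
        return
    writer = csv.writer(dest)
    writer.writerow(["start_second", "end_second", "label"])
    for iv in intervals:
        writer.writerow([iv.start_second, iv.end_second, iv.label.code])


def _check_tiling(
    intervals: Sequence[IntervalLabel], duration: float
) -> list[IntervalLabel]:
    ivs = sorted(intervals, key=lambda iv: iv.start_second)
    if not ivs:
        raise ValueError("no intervals given")
    if ivs[0].start_second > _TOL:
        raise ValueError(f"gap before first interval at second {ivs[0].start_second}")
    for a, b in zip(ivs, ivs[1:]):
        if b.start_second > a.end_second + _TOL:
            raise ValueError(
                f"gap between second {a.end_second} and {b.start_second}"
            )
        if b.start_second < a.end_second - _TOL:
            raise ValueError(
                f"overlap between second {b.start_second} and {a.end_second}"
            )
    if ivs[-1].end_second < duration - _TOL:
        raise ValueError(
            f"intervals end at second {ivs[-1].end_second}, before duration "
            f"{duration}"
        )
    return ivs


def build_frame_truth(
    intervals: Sequence[IntervalLabel],
    fps: float,
    n_frames: int,
    ambiguity_seconds: float = 3.0,
) -> list[FrameTruth]:
    """Expand second-resolution intervals to per-frame acceptable labels.

    The intervals must tile ``[0, n_frames/fps]`` without gaps or overlaps.
    Each frame's base label comes from the interval covering its timestamp;
    frames within the ambiguity window — ``round(ambiguity_seconds·fps)``
    frames centered on each transition boundary — additionally accept the
    adjacent interval's label (180 frames at 60 fps with the default 3 s).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if n_frames < 0:
        raise ValueError("n_frames must be nonnegative")
    ivs = _check_tiling(intervals, n_frames / fps)
    # Base per-frame labels.
    allowed: list[set[FineLabel]] = []
    j = 0
    for f in range(n_frames):
        t = f / fps
        while j + 1 < len(ivs) and t >= ivs[j].end_second - _TOL:
            j += 1
        allowed.append({ivs[j].label})
    # Ambiguity windows, centered on each internal boundary.  When two
    # boundaries sit closer than the window width (short segments, e.g.
    # brief non-clear bursts), a frame belongs to the window of its
    # *nearest* boundary only, so the allowed set never exceeds 2 labels.
    width = int(round(ambiguity_seconds * fps))
    half = width // 2
    owner: list[tuple[int, int] | None] = [None] * n_frames  # (distance, k)
    for k, (a, b) in enumerate(zip(ivs, ivs[1:])):
        boundary = int(round(a.end_second * fps))
        lo = max(0, boundary - half)
        hi = min(n_frames, boundary - half + width)
        for f in range(lo, hi):
            dist = abs(f - boundary)
            if owner[f] is None or (dist, k) < owner[f]:
                owner[f] = (dist, k)
    for f, own in enumerate(owner):
        if own is not None:
            _, k = own
            allowed[f].update((ivs[k].label, ivs[k + 1].label))
    return [FrameTruth(f, frozenset(s)) for f, s in enumerate(allowed)]


@dataclass
class MetricsReport:
    """Per-class one-vs-rest cells and metrics plus macro aggregates."""

    per_class: dict[str, ConfusionCell]
    evaluated_frames: int
    excluded_frames: int
    correct_frames: int

    @property
    def accuracy(self) -> float:
        """Micro accuracy: correct frames / evaluated frames."""
        return _ratio(self.correct_frames, self.evaluated_frames)

    def class_metrics(self, code: str) -> Metrics:
        return metric_formulas(self.per_class[code])

    def _present_classes(self) -> list[str]:
        return [
            c for c, cell in self.per_class.items() if cell.TP + cell.FN > 0
        ]

    def _macro(self, attr: str) -> float:
        vals = [
            getattr(self.class_metrics(c), attr) for c in self._present_classes()
        ]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    @property
    def macro_precision(self) -> float:
        return self._macro("precision")

    @property
    def macro_recall(self) -> float:
        return self._macro("recall")

    @property
    def macro_f1(self) -> float:
        return self._macro("f1")

    def to_frame(self) -> pd.DataFrame:
        """Per-class cells and metrics as a DataFrame (canonical order)."""
        rows = []
        for code, cell in self.per_class.items():
            if cell.total == 0:
                continue
            m = metric_formulas(cell)
            rows.append(
                {
                    "label": code,
                    "TP": cell.TP,
                    "TN": cell.TN,
                    "FP": cell.FP,
                    "FN": cell.FN,
                    "sensitivity": m.recall,
                    "specificity": m.specificity,
                    "precision": m.precision,
                    "f1": m.f1,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def clean(x: float) -> float | None:
            return None if math.isnan(x) else x

        out = {
            "evaluated_frames": self.evaluated_frames,
            "excluded_frames": self.excluded_frames,
            "accuracy": clean(self.accuracy),
            "macro_precision": clean(self.macro_precision),
            "macro_recall": clean(self.macro_recall),
            "macro_f1": clean(self.macro_f1),
            "per_class": {},
        }
        for code, cell in self.per_class.items():
            if cell.total == 0:
                continue
            m = metric_formulas(cell)
            out["per_class"][code] = {
                "TP": cell.TP,
                "TN": cell.TN,
                "FP": cell.FP,
                "FN": cell.FN,
                "sensitivity": clean(m.recall),
                "specificity": clean(m.specificity),
                "precision": clean(m.precision),
                "f1": clean(m.f1),
            }
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"evaluated frames: {self.evaluated_frames}  "
            f"(excluded as non-clear: {self.excluded_frames})",
            f"accuracy: {100 * self.accuracy:.2f}%",
            f"macro precision/recall/F1: "
            f"{100 * self.macro_precision:.2f}% / "
            f"{100 * self.macro_recall:.2f}% / {100 * self.macro_f1:.2f}%",
            "",
            df.to_string(index=False, float_format=lambda v: f"{100 * v:.2f}"),
        ]
        return "\n".join(lines)


def _voted_pairs(voted) -> list[tuple[int, FineLabel]]:
    pairs = []
    for item in voted:
        if isinstance(item, tuple):
            idx, label = item
        elif isinstance(item, FinePrediction):
            idx, label = item.frame_index, item.fine
        else:
            raise TypeError(
                "voted stream items must be (frame_index, label) pairs or "
                "FinePrediction objects"
            )
        pairs.append((int(idx), as_fine(label)))
    return pairs


def evaluate_stream(
    voted, truth: Sequence[FrameTruth]
) -> MetricsReport:
    """Score a voted label stream frame-by-frame against per-frame truth.

    ``voted`` is an iterable of ``(frame_index, fine_label)`` pairs (or
    FinePrediction objects, whose ``fine`` field is used).  Frames voted NO
    are excluded from scoring unless the truth allows NO there.  A
    prediction is correct iff it is in the frame's allowed set; one-vs-rest
    cells assign the TP to the voted class, an FN to each allowed class of
    an incorrectly predicted frame, and TNs elsewhere.
    """
    truth_by_index = {ft.frame_index: ft for ft in truth}
    pairs = _voted_pairs(voted)
    no = FineLabel.NO
    cells = {f.code: [0, 0, 0, 0] for f in FINE_ORDER}  # TP, TN, FP, FN
    evaluated = excluded = correct_frames = 0
    for idx, label in pairs:
        ft = truth_by_index.get(idx)
        if ft is None:
            raise ValueError(f"no ground truth for frame {idx}")
        if label is no and no not in ft.allowed:
            excluded += 1
            continue
        evaluated += 1
        correct = label in ft.allowed
        if correct:
            correct_frames += 1
        for f in FINE_ORDER:
            cell = cells[f.code]
            if f is label:
                if correct:
                    cell[0] += 1  # TP
                else:
                    cell[2] += 1  # FP
            elif f in ft.allowed and not correct:
                cell[3] += 1  # FN
            else:
                cell[1] += 1  # TN
    per_class = {
        code: ConfusionCell(TP=c[0], TN=c[1], FP=c[2], FN=c[3])
        for code, c in cells.items()
    }
    return MetricsReport(
        per_class=per_class,
        evaluated_frames=evaluated,
        excluded_frames=excluded,
        correct_frames=correct_frames,
    )


def window_sweep(
    raw: Sequence[FinePrediction],
    truth: Sequence[FrameTruth],
    sizes: Sequence[int] = (4, 7, 10, 13),
) -> pd.DataFrame:
    """Compare vote-window sizes on one prediction stream.

    Smooths the same raw stream with each window size, evaluates each
    result, and returns one summary row per size (macro F1 / precision /
    recall, micro accuracy, frame counts).
    """
    rows = []
    indices = [p.frame_index for p in raw]
    for k in sizes:
        voted = smooth_stream(raw, k=k)
        report = evaluate_stream(list(zip(indices, voted)), truth)
        rows.append(
            {
                "window": k,
                "macro_f1": report.macro_f1,
                "macro_precision": report.macro_precision,
                "macro_recall": report.macro_recall,
                "accuracy": report.accuracy,
                "evaluated_frames": report.evaluated_frames,
                "excluded_frames": report.excluded_frames,
            }
        )
    return pd.DataFrame(rows)
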