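"""Synthetic EGD procedures, manifests and prediction streams.

No public EGD image or video corpus backs this pipeline, so everything the
tool chain consumes can be generated here instead:

* a manifest whose per-class counts equal the reference still-image corpus
  (31,403 images over the 11 fine classes) for split arithmetic;
* labeled endoscope trajectories — an ordered insertion pass through the
  anatomy (ES → GE → CR → UB → MB → LB → AG → AT → BB → SD), a withdrawal
  pass back out, and short interspersed non-clear bursts (lens against the
  wall, fluid, rapid motion) — with interval ground truth and per-frame
  true labels that are mutually consistent by construction;
* confusion-corrupted prediction streams that stand in for a trained CNN's
  per-frame output, with errors concentrated on anatomically adjacent
  classes (the gastric body subsections are the classic confusable trio);
* procedurally textured class frames (distinct hue and texture frequency
  per label; non-clear is rendered blurred and low-contrast) so small
  trainable backends have something separable to fit.

Defaults describe a realistic procedure: ~177 s total at 60 fps (matching
the reported average video length of 2 min 57 s), two non-clear bursts per
minute of 1.5 s each, and a 0.8-diagonal confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .classifier import FinePrediction, ScoreVector
from .dataset import ManifestRecord
from .evaluation import IntervalLabel
from .taxonomy import FINE_ORDER, FineLabel, as_fine, fine_index, primary_of
from .video import SamplingPlan, sample_indices

__all__ = [
    "TrajectorySpec",
    "EmissionSpec",
    "default_trajectory_spec",
    "default_confusion",
    "simulate_trajectory",
    "emit_predictions",
    "render_frame",
    "table1_fixture",
    "TABLE1_COUNTS",
]

#: Per-fine-class image counts of the reference still-image corpus.
TABLE1_COUNTS: dict[FineLabel, int] = {
    FineLabel.ES: 4707,
    FineLabel.GE: 2203,
    FineLabel.CR: 2126,
    FineLabel.UB: 3046,
    FineLabel.MB: 3521,
    FineLabel.LB: 2248,
    FineLabel.AG: 2226,
    FineLabel.AT: 4161,
    FineLabel.BB: 1036,
    FineLabel.SD: 1595,
    FineLabel.NO: 4534,
}

#: Anatomical traversal order of an insertion pass.
INSERTION_ORDER: tuple[FineLabel, ...] = (
    FineLabel.ES,
    FineLabel.GE,
    FineLabel.CR,
    FineLabel.UB,
    FineLabel.MB,
    FineLabel.LB,
    FineLabel.AG,
    FineLabel.AT,
    FineLabel.BB,
    FineLabel.SD,
)


@dataclass
class TrajectorySpec:
    """A stated endoscope path: ordered (label, duration-seconds) segments.

    Non-clear bursts are overlaid on the segments at a Poisson rate of
    ``no_burst_rate`` per minute, each lasting ``no_burst_duration``
    seconds; they replace (never extend) the underlying anatomy.
    """

    segments: list[tuple[FineLabel, float]]
    fps: float = 60.0
    no_burst_rate: float = 2.0
    no_burst_duration: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.segments = [(as_fine(l), float(d)) for l, d in self.segments]
        if not self.segments:
            raise ValueError("trajectory needs at least one segment")
        if any(d <= 0 for _, d in self.segments):
            raise ValueError("segment durations must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.no_burst_rate < 0 or self.no_burst_duration < 0:
            raise ValueError("burst parameters must be nonnegative")

    @property
    def total_seconds(self) -> float:
        return sum(d for _, d in self.segments)


def default_trajectory_spec(
    seed: int = 0, total_seconds: float = 177.0, fps: float = 60.0
) -> TrajectorySpec:
    """Insertion + withdrawal trajectory scaled to ~3 minutes.

    Segment durations are drawn uniformly in [0.5, 1.5] × base (seeded)
    and rescaled so the total matches ``total_seconds``; the withdrawal
    pass revisits the anatomy in reverse, exercising label re-entry.
    """
    labels = list(INSERTION_ORDER) + list(reversed(INSERTION_ORDER[:-1]))
    rng = np.random.default_rng(seed)
    weights = rng.uniform(0.5, 1.5, size=len(labels))
    durations = weights / weights.sum() * total_seconds
    return TrajectorySpec(
        segments=list(zip(labels, durations)),
        fps=fps,
        seed=seed,
    )


@dataclass
class EmissionSpec:
    """Row-stochastic 11×11 fine-label confusion matrix plus a seed."""

    confusion: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.confusion, dtype=float)
        if m.shape != (len(FINE_ORDER), len(FINE_ORDER)):
            raise ValueError(f"confusion must be 11×11, got {m.shape}")
        if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must be nonnegative and sum to 1")
        self.confusion = m


def default_confusion(diagonal: float = 0.8) -> np.ndarray:
    """Confusion with anatomically adjacent errors.

    Each anatomical class keeps ``diagonal`` mass on itself; the remainder
    is split equally between its neighbors along the traversal chain
    (UB↔MB↔LB etc.) and the non-clear class — mimicking a CNN that mixes
    up visually contiguous regions.  The non-clear row spreads its
    off-diagonal mass uniformly over the anatomical classes.
    """
    if not 0 <= diagonal <= 1:
        raise ValueError("diagonal must be in [0, 1]")
    n = len(FINE_ORDER)
    m = np.zeros((n, n))
    chain = list(INSERTION_ORDER)
    off = 1.0 - diagonal
    for label in FINE_ORDER:
        i = fine_index(label)
        m[i, i] = diagonal
        if label is FineLabel.NO:
            for other in chain:
                m[i, fine_index(other)] = off / len(chain)
            continue
        pos = chain.index(label)
        neighbors = [
            chain[j] for j in (pos - 1, pos + 1) if 0 <= j < len(chain)
        ]
        targets = neighbors + [FineLabel.NO]
        for t in targets:
            m[i, fine_index(t)] += off / len(targets)
    return m


def simulate_trajectory(
    spec: TrajectorySpec,
) -> tuple[list[IntervalLabel], list[FineLabel]]:
    """Generate interval ground truth and per-frame true labels.

    Frames are laid down from the segment list, non-clear bursts are
    overlaid at seeded Poisson times, and the intervals are re-derived from
    the final frame sequence — so the intervals tile ``[0, total]`` and
    agree with the per-frame labels by construction.
    """
    n_frames = int(round(spec.total_seconds * spec.fps))
    frames: list[FineLabel] = []
    for label, duration in spec.segments:
        count = int(round(duration * spec.fps))
        frames.extend([label] * count)
    # rounding drift: pad/trim against the target frame count
    if len(frames) < n_frames:
        frames.extend([frames[-1]] * (n_frames - len(frames)))
    frames = frames[:n_frames]

    rng = np.random.default_rng(spec.seed)
    if spec.no_burst_rate > 0 and spec.no_burst_duration > 0:
        expected = spec.no_burst_rate * spec.total_seconds / 60.0
        n_bursts = rng.poisson(expected)
        starts = np.sort(rng.uniform(0, spec.total_seconds, size=n_bursts))
        burst_frames = int(round(spec.no_burst_duration * spec.fps))
        for start in starts:
            lo = int(round(start * spec.fps))
            hi = min(n_frames, lo + burst_frames)
            for f in range(lo, hi):
                frames[f] = FineLabel.NO

    intervals: list[IntervalLabel] = []
    run_start = 0
    for f in range(1, n_frames + 1):
        if f == n_frames or frames[f] is not frames[run_start]:
            intervals.append(
                IntervalLabel(
                    start_second=run_start / spec.fps,
                    end_second=f / spec.fps,
                    label=frames[run_start],
                )
            )
            run_start = f
    return intervals, frames


def emit_predictions(
    true_labels: Sequence[FineLabel],
    plan: SamplingPlan,
    emission: EmissionSpec,
) -> list[FinePrediction]:
    """Sample frames and corrupt their true labels through the confusion.

    For each sampled frame index the predicted fine label is drawn from
    the confusion row of the frame's true label; the cascade fields are
    filled consistently (primary = part of the fine label, point-mass
    scores), emulating a raw per-frame CNN prediction stream.
    """
    rng = np.random.default_rng(emission.seed)
    n = len(FINE_ORDER)
    preds: list[FinePrediction] = []
    for idx in sample_indices(len(true_labels), plan):
        true = as_fine(true_labels[idx])
        row = emission.confusion[fine_index(true)]
        fine = FINE_ORDER[rng.choice(n, p=row)]
        primary = primary_of(fine)
        secondary = (
            ScoreVector.point_mass(fine.code, primary.code)
            if primary.is_merged
            else None
        )
        preds.append(
            FinePrediction(
                frame_index=idx,
                primary=primary,
                fine=fine,
                primary_scores=ScoreVector.point_mass(primary.code, "primary"),
                secondary_scores=secondary,
            )
        )
    return preds


# Base hue (RGB weights) and texture frequency per label; NO is rendered
# separately as blurred low-contrast noise.
_LABEL_STYLE: dict[FineLabel, tuple[tuple[float, float, float], float]] = {
    FineLabel.ES: ((0.9, 0.5, 0.5), 2.0),
    FineLabel.GE: ((0.9, 0.4, 0.6), 3.0),
    FineLabel.CR: ((0.8, 0.3, 0.3), 4.0),
    FineLabel.UB: ((0.9, 0.6, 0.4), 5.0),
    FineLabel.MB: ((0.85, 0.55, 0.35), 6.5),
    FineLabel.LB: ((0.8, 0.5, 0.3), 8.0),
    FineLabel.AG: ((0.95, 0.7, 0.5), 10.0),
    FineLabel.AT: ((0.9, 0.65, 0.55), 12.0),
    FineLabel.BB: ((0.7, 0.45, 0.4), 14.0),
    FineLabel.SD: ((0.65, 0.4, 0.35), 16.0),
}


def render_frame(label: FineLabel, edge: int, seed: int = 0) -> np.ndarray:
    """Procedurally textured ``edge×edge×3`` uint8 frame for one class.

    Deterministic per (label, seed).  Anatomical classes get a distinct
    base hue and sinusoidal texture frequency; the non-clear class is
    blurred, low-contrast noise, echoing unidentifiable video frames.
    """
    if edge <= 0:
        raise ValueError("edge must be positive")
    label = as_fine(label)
    rng = np.random.default_rng([seed, fine_index(label)])
    yy, xx = np.mgrid[0:edge, 0:edge] / edge
    if label is FineLabel.NO:
        noise = rng.normal(0.5, 0.05, size=(edge, edge))
        base = ndimage.gaussian_filter(noise, sigma=max(edge / 16, 1.0))
        img = np.stack([base * 0.9, base * 0.75, base * 0.7], axis=-1)
    else:
        hue, freq = _LABEL_STYLE[label]
        phase = rng.uniform(0, 2 * np.pi)
        texture = 0.5 + 0.35 * np.sin(
            2 * np.pi * freq * xx + phase
        ) * np.cos(2 * np.pi * freq * yy)
        texture += rng.normal(0, 0.03, size=(edge, edge))
        img = np.stack([texture * c for c in hue], axis=-1)
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def table1_fixture() -> list[ManifestRecord]:
    """Synthetic manifest matching the reference corpus class counts.

    31,403 records with opaque image references; per-fine-class counts
    equal the published distribution exactly, so split arithmetic can be
    checked without any image data.
    """
    records: list[ManifestRecord] = []
    for label in FINE_ORDER:
        for i in range(TABLE1_COUNTS[label]):
            records.append(
                ManifestRecord(f"synthetic/{label.code}_{i:05d}.png", label)
            )
    return records
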