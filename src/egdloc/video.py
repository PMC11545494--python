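"""Fixed-interval frame sampling and sliding-window hard-vote smoothing.

Per-frame classifiers trained on still images flicker when run on video:
consecutive frames are nearly identical yet each is judged independently.
Two cheap temporal mechanisms stabilize the stream.  First, frames are
sampled at a fixed interval (every 20th frame of a 60 fps video, i.e. 3
inferences per second) rather than classifying every frame.  Second, each
sampled prediction is pooled with the previous k−1 predictions (k = 7 by
default) and the modal label of the window — a hard vote — is emitted as
the final location.

Ties in the vote break toward the tied label seen most recently, which
favors the newer anatomical region while the endoscope is transiting a
boundary.  During warm-up (fewer than k predictions so far) the vote runs
over whatever is available, so every sampled frame produces an output —
required for real-time use.  The non-clear label votes like any other;
excluding non-clear outcomes is the evaluator's job, not the smoother's.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Sequence, Union

from .classifier import FinePrediction
from .taxonomy import FineLabel, as_fine

__all__ = [
    "SamplingPlan",
    "VoteWindow",
    "sample_indices",
    "hard_vote",
    "smooth_stream",
]


@dataclass(frozen=True)
class SamplingPlan:
    """Fixed-interval sampling of a frame stream.

    ``interval`` counts frames between consecutive samples; the effective
    inference rate is ``fps / interval`` samples per second (3/s for the
    default 60 fps, interval-20 plan).
    """

    fps: float = 60.0
    interval: int = 20

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.interval < 1:
            raise ValueError("interval must be >= 1")

    @property
    def samples_per_second(self) -> float:
        return self.fps / self.interval


def sample_indices(n_frames: int, plan: SamplingPlan) -> list[int]:
    """0-based indices of the sampled frames: 0, interval, 2·interval, …"""
    if n_frames < 0:
        raise ValueError("n_frames must be nonnegative")
    return list(range(0, n_frames, plan.interval))


@dataclass
class VoteWindow:
    """Bounded buffer of the k most recent fine labels, oldest first."""

    size: int = 7
    buffer: deque = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("window size must be >= 1")
        existing = list(self.buffer) if self.buffer else []
        self.buffer = deque(
            (as_fine(l) for l in existing), maxlen=self.size
        )

    def push(self, label: Union[FineLabel, str]) -> None:
        self.buffer.append(as_fine(label))


def hard_vote(window: VoteWindow) -> FineLabel:
    """Modal label of the window; ties go to the most recently seen label."""
    buf = list(window.buffer)
    if not buf:
        raise ValueError("cannot vote on an empty window")
    counts = Counter(buf)
    top = max(counts.values())
    tied = {label for label, c in counts.items() if c == top}
    if len(tied) == 1:
        return next(iter(tied))
    for label in reversed(buf):
        if label in tied:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def _label_of(item) -> FineLabel:
    if isinstance(item, FinePrediction):
        return item.fine
    return as_fine(item)


def smooth_stream(
    raw: Sequence, k: int = 7
) -> list[FineLabel]:
    """Hard-vote smooth an ordered prediction stream.

    ``raw`` is a sequence of :class:`~egdloc.classifier.FinePrediction`
    objects (must be in ascending frame_index order) or plain fine labels.
    Output ``i`` is the vote over entries ``max(0, i−k+1) … i``; the first
    k−1 outputs vote over the shorter warm-up window.  ``k=1`` is the
    identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    prev_index = -1
    has_indices = any(isinstance(item, FinePrediction) for item in raw)
    window = VoteWindow(size=k)
    voted: list[FineLabel] = []
    for item in raw:
        if has_indices and isinstance(item, FinePrediction):
            if item.frame_index <= prev_index:
                raise ValueError(
                    f"prediction stream out of order at frame_index "
                    f"{item.frame_index} (previous {prev_index})"
                )
            prev_index = item.frame_index
        window.push(_label_of(item))
        voted.append(hard_vote(window))
    return voted
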