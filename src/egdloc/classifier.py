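"""Pluggable per-frame classifiers and the coarse-to-fine cascade.

A backend is any callable mapping a frame to a :class:`ScoreVector` over a
label space.  The cascade runs a 7-way primary backend first; when the
argmax is a merged part (esophagus part, gastric bodies part, duodenum
part) the part's secondary backend refines it to a fine label, otherwise
the singleton member passes through.  Combination is by sequential argmax,
not by multiplying stage probabilities, and argmax ties break toward the
lowest index in the canonical label order so inference is deterministic.

Two backend families ship with the package:

* :func:`mock_classifier` — a confusion-matrix test double.  It expects
  frames that carry their true label (synthetic frames do) and samples the
  predicted label from the true label's confusion row; this stands in for
  the error structure of a trained CNN without any weights or image data.
* :func:`train_backend` — small scikit-learn models (logistic regression
  or an MLP) fitted on downsampled pixels.  This is a functional, CPU-only
  stand-in for the heavyweight CNN backends (ResNet101 / InceptionV3 /
  InceptionResNetV2 with ImageNet transfer), which would slot behind the
  same interface but need GPU training and are out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .taxonomy import (
    FINE_ORDER,
    MERGED_PARTS,
    PRIMARY_ORDER,
    FineLabel,
    PrimaryLabel,
    as_fine,
    as_primary,
    primary_of,
    secondary_members,
)

__all__ = [
    "ScoreVector",
    "BackendConfig",
    "CascadeModel",
    "FinePrediction",
    "cascade_predict",
    "mock_classifier",
    "MockClassifier",
    "build_mock_cascade",
    "train_backend",
    "train_single_backend",
    "label_space_codes",
]

Frame = object  # a preprocessed raster, or any tagged object a backend accepts
Backend = Callable[[Frame], "ScoreVector"]

_SUM_TOL = 1e-6


def label_space_codes(label_space: str) -> tuple[str, ...]:
    """Codes of a label space: ``"primary"``, ``"fine"`` or a merged part."""
    if label_space == "primary":
        return tuple(p.code for p in PRIMARY_ORDER)
    if label_space == "fine":
        return tuple(f.code for f in FINE_ORDER)
    part = as_primary(label_space)
    if not part.is_merged:
        raise ValueError(f"{part.code} is not a merged part")
    return tuple(m.code for m in part.members)


@dataclass(frozen=True)
class ScoreVector:
    """Normalized class scores over one label space.

    ``scores`` maps every code of the space to a nonnegative weight; the
    weights must sum to 1 within 1e-6 (softmax output contract).
    """

    scores: Mapping[str, float]
    label_space: str

    def __post_init__(self) -> None:
        expected = label_space_codes(self.label_space)
        if set(self.scores) != set(expected):
            raise ValueError(
                f"scores keys {sorted(self.scores)} do not match label space "
                f"{self.label_space!r} codes {sorted(expected)}"
            )
        if any(v < 0 for v in self.scores.values()):
            raise ValueError("scores must be nonnegative")
        total = sum(self.scores.values())
        if not math.isclose(total, 1.0, abs_tol=_SUM_TOL):
            raise ValueError(f"scores sum to {total}, expected 1 within {_SUM_TOL}")

    def argmax(self) -> str:
        """Highest-scoring code; ties break toward the canonical order."""
        best = None
        best_score = -1.0
        for code in label_space_codes(self.label_space):
            s = self.scores[code]
            if s > best_score:
                best, best_score = code, s
        return best  # type: ignore[return-value]

    @classmethod
    def point_mass(cls, code: str, label_space: str) -> "ScoreVector":
        codes = label_space_codes(label_space)
        return cls({c: (1.0 if c == code else 0.0) for c in codes}, label_space)

    @classmethod
    def from_array(
        cls, values: Sequence[float], label_space: str
    ) -> "ScoreVector":
        codes = label_space_codes(label_space)
        if len(values) != len(codes):
            raise ValueError(
                f"expected {len(codes)} scores for {label_space!r}, got {len(values)}"
            )
        return cls(dict(zip(codes, map(float, values))), label_space)


@dataclass
class BackendConfig:
    """Training hyperparameters recorded with a cascade.

    Defaults mirror a transfer-learning CNN recipe: 300 epochs, batch 32,
    SGD at 1e-5 with reduce-on-plateau (factor 0.1, patience 10).  The
    scikit-learn stand-in backends honor ``epochs`` and ``learning_rate``;
    the remaining fields are kept for provenance and for real CNN backends
    plugged in by users.
    """

    epochs: int = 300
    batch_size: int = 32
    optimizer: str = "sgd"
    learning_rate: float = 1e-5
    lr_schedule: str = "reduce_on_plateau"
    lr_factor: float = 0.1
    lr_patience: int = 10
    target_edge: int = 299
    feature_edge: int = 16  # frames are downsampled to this before sklearn fits


@dataclass
class CascadeModel:
    """A primary backend plus one secondary backend per merged part."""

    primary_model: Backend
    secondary_models: Mapping[str, Backend]
    config: BackendConfig = field(default_factory=BackendConfig)

    def __post_init__(self) -> None:
        expected = {p.code for p in MERGED_PARTS}
        if set(self.secondary_models) != expected:
            raise ValueError(
                f"secondary_models keys {sorted(self.secondary_models)} must be "
                f"exactly the merged parts {sorted(expected)}"
            )


@dataclass(frozen=True)
class FinePrediction:
    """One sampled frame's cascade output."""

    frame_index: int
    primary: PrimaryLabel
    fine: FineLabel
    primary_scores: ScoreVector | None = None
    secondary_scores: ScoreVector | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "primary", as_primary(self.primary))
        object.__setattr__(self, "fine", as_fine(self.fine))
        if self.frame_index < 0:
            raise ValueError("frame_index must be nonnegative")
        if self.fine not in secondary_members(self.primary):
            raise ValueError(
                f"fine label {self.fine.code} is not a member of {self.primary.code}"
            )


def cascade_predict(
    frame: Frame, model: CascadeModel, frame_index: int = 0
) -> FinePrediction:
    """Run the two-stage cascade on one preprocessed frame.

    The primary backend's argmax picks the coarse part; merged parts are
    refined by that part's secondary backend, singletons pass through.
    """
    try:
        primary_scores = model.primary_model(frame)
    except Exception as exc:
        raise RuntimeError(f"primary backend failed at frame {frame_index}") from exc
    primary = as_primary(primary_scores.argmax())
    secondary_scores = None
    if primary.is_merged:
        try:
            secondary_scores = model.secondary_models[primary.code](frame)
        except Exception as exc:
            raise RuntimeError(
                f"secondary backend for {primary.code} failed at frame {frame_index}"
            ) from exc
        fine = as_fine(secondary_scores.argmax())
    else:
        fine = primary.members[0]
    return FinePrediction(
        frame_index=frame_index,
        primary=primary,
        fine=fine,
        primary_scores=primary_scores,
        secondary_scores=secondary_scores,
    )


def _validate_row_stochastic(matrix: np.ndarray, n: int, tol: float = 1e-9) -> None:
    if matrix.shape != (n, n):
        raise ValueError(f"confusion matrix must be {n}×{n}, got {matrix.shape}")
    if np.any(matrix < 0):
        raise ValueError("confusion matrix entries must be nonnegative")
    sums = matrix.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=tol):
        raise ValueError(f"confusion rows must sum to 1 within {tol}; got {sums}")


class MockClassifier:
    """Confusion-matrix test double for a trained backend.

    Frames must expose their true label, either as a plain label code /
    enum or via a ``true_label`` attribute.  Conditioned on true label
    ``t``, the sampled prediction equals label ``j`` with probability
    ``confusion[t, j]`` (rows/columns in the label space's canonical
    order).  The emitted score vector places mass 1 on the sampled label.

    A true label outside the label space (possible when a secondary mock
    is consulted after a primary mock erred into the wrong part) falls
    back to a uniform row.
    """

    def __init__(
        self, confusion: np.ndarray, label_space: str, seed: int | None = 0
    ) -> None:
        self.codes = label_space_codes(label_space)
        self.label_space = label_space
        matrix = np.asarray(confusion, dtype=float)
        _validate_row_stochastic(matrix, len(self.codes))
        self.confusion = matrix
        self._index = {c: i for i, c in enumerate(self.codes)}
        self._rng = np.random.default_rng(seed)

    @staticmethod
    def _true_code(frame: Frame) -> str:
        label = getattr(frame, "true_label", frame)
        return label.value if hasattr(label, "value") else str(label)

    def __call__(self, frame: Frame) -> ScoreVector:
        code = self._true_code(frame)
        if code in self._index:
            row = self.confusion[self._index[code]]
        else:
            row = np.full(len(self.codes), 1.0 / len(self.codes))
        j = self._rng.choice(len(self.codes), p=row)
        return ScoreVector.point_mass(self.codes[j], self.label_space)


def mock_classifier(
    confusion: np.ndarray, label_space: str = "primary", seed: int | None = 0
) -> MockClassifier:
    """Build a seeded confusion-matrix backend (see :class:`MockClassifier`)."""
    return MockClassifier(confusion, label_space, seed)


class _TruePrimaryView:
    """Adapts a fine-true-labeled frame for a primary-space mock."""

    __slots__ = ("true_label",)

    def __init__(self, frame: Frame) -> None:
        self.true_label = primary_of(MockClassifier._true_code(frame)).code


def build_mock_cascade(
    primary_confusion: np.ndarray,
    secondary_confusions: Mapping[str, np.ndarray] | None = None,
    seed: int = 0,
    config: BackendConfig | None = None,
) -> CascadeModel:
    """Assemble a full mock cascade from confusion matrices.

    ``primary_confusion`` is 7×7 over the coarse parts; each entry of
    ``secondary_confusions`` (keyed by merged-part code) is square over
    that part's members.  Missing secondary matrices default to identity.
    Frames fed to the cascade must carry a true *fine* label.
    """
    primary = mock_classifier(primary_confusion, "primary", seed)
    primary_backend: Backend = lambda frame: primary(_TruePrimaryView(frame))
    secondaries: dict[str, Backend] = {}
    for i, part in enumerate(MERGED_PARTS):
        n = len(part.members)
        conf = (
            np.eye(n)
            if secondary_confusions is None or part.code not in secondary_confusions
            else secondary_confusions[part.code]
        )
        secondaries[part.code] = mock_classifier(conf, part.code, seed + 1 + i)
    return CascadeModel(
        primary_model=primary_backend,
        secondary_models=secondaries,
        config=config or BackendConfig(),
    )


# ---------------------------------------------------------------------------
# Trainable scikit-learn backends (CPU stand-ins for the CNN architectures).

_ARCHS = ("logreg", "mlp")


def _features(frame: np.ndarray, feature_edge: int) -> np.ndarray:
    from .dataset import preprocess_frame

    small = preprocess_frame(np.asarray(frame), feature_edge)
    return small.reshape(-1)


def train_single_backend(
    records,
    loader: Callable[[str], np.ndarray],
    label_space: str,
    arch: str = "logreg",
    config: BackendConfig | None = None,
) -> Backend:
    """Fit one backend over a label space from manifest records.

    ``loader`` maps an image reference to a raster.  Labels are taken from
    each record's fine label, mapped to the coarse part when the space is
    ``"primary"``.  ``epochs=0`` returns an untrained backend emitting a
    uniform score vector (still a valid classifier interface).
    """
    if arch not in _ARCHS:
        raise ValueError(f"unknown arch {arch!r}; available: {_ARCHS}")
    cfg = config or BackendConfig()
    codes = label_space_codes(label_space)
    n = len(codes)

    if cfg.epochs == 0:
        uniform = ScoreVector.from_array(np.full(n, 1.0 / n), label_space)
        return lambda frame: uniform

    X, y = [], []
    for rec in records:
        fine = rec.fine_label
        code = primary_of(fine).code if label_space == "primary" else fine.code
        if code not in codes:
            continue
        X.append(_features(loader(rec.image_ref), cfg.feature_edge))
        y.append(code)
    if not X:
        raise ValueError(f"no training records fall in label space {label_space!r}")
    X = np.asarray(X)

    try:
        from sklearn.linear_model import LogisticRegression
        from sklearn.neural_network import MLPClassifier
    except ImportError as exc:  # pragma: no cover - sklearn is a hard dep here
        raise ImportError(
            "scikit-learn is required for trainable backends; install it or "
            "use the mock classifier"
        ) from exc

    if arch == "logreg":
        est = LogisticRegression(max_iter=max(cfg.epochs, 100))
    else:
        est = MLPClassifier(
            hidden_layer_sizes=(32,),
            max_iter=max(cfg.epochs, 200),
            learning_rate_init=max(cfg.learning_rate, 1e-3),
            random_state=0,
        )
    est.fit(X, y)
    class_pos = {c: i for i, c in enumerate(est.classes_)}

    def backend(frame: Frame) -> ScoreVector:
        proba = est.predict_proba(
            _features(np.asarray(frame), cfg.feature_edge)[None, :]
        )[0]
        full = np.zeros(n)
        for code, i in class_pos.items():
            full[codes.index(code)] = proba[i]
        total = full.sum()
        full = full / total if total > 0 else np.full(n, 1.0 / n)
        return ScoreVector.from_array(full, label_space)

    return backend


def train_backend(
    split,
    loader: Callable[[str], np.ndarray],
    arch: str = "logreg",
    config: BackendConfig | None = None,
) -> CascadeModel:
    """Fit a full cascade (primary + three secondaries) from a split.

    Secondary backends are trained only on the training records of their
    own part.  CPU-friendly; intended for small synthetic fixtures, not
    for clinical-scale image corpora.
    """
    cfg = config or BackendConfig()
    primary = train_single_backend(split.train, loader, "primary", arch, cfg)
    secondaries = {
        part.code: train_single_backend(split.train, loader, part.code, arch, cfg)
        for part in MERGED_PARTS
    }
    return CascadeModel(primary, secondaries, cfg)
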