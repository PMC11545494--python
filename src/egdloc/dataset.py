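"""Image manifests, stratified splitting and frame preprocessing.

A manifest is a flat list of (image reference, fine label) records, read
from a two-column CSV (``image,label``).  Splitting follows a two-step
procedure designed to avoid class imbalance in the test set: a fixed
per-class quota of records is undersampled into the test pool first, and
the per-class remainder is then divided train:validation = 8:1.  The
primary task stratifies on the 7 coarse parts; a secondary task restricts
the manifest to one merged part and stratifies on its fine members.

Splits are deterministic: per class (canonical label order) the records
are shuffled with a seeded generator and partitioned, so the same
(manifest, seed, quota) always yields a byte-identical split.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, Decimal
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .taxonomy import (
    FINE_ORDER,
    PRIMARY_ORDER,
    FineLabel,
    PrimaryLabel,
    as_fine,
    as_primary,
    fine_index,
    primary_of,
    secondary_members,
)

__all__ = [
    "ManifestRecord",
    "SplitResult",
    "read_manifest",
    "write_manifest",
    "split_primary",
    "split_secondary",
    "class_distribution",
    "preprocess_frame",
]


@dataclass(frozen=True)
class ManifestRecord:
    """One labeled still image: an opaque reference plus its fine label."""

    image_ref: str
    fine_label: FineLabel

    def __post_init__(self) -> None:
        if not self.image_ref:
            raise ValueError("image_ref must be nonempty")
        object.__setattr__(self, "fine_label", as_fine(self.fine_label))


@dataclass
class SplitResult:
    """Outcome of a stratified quota split.

    ``train``/``validation``/``test`` partition the input manifest; the
    test pool holds exactly ``quota`` records for every class of the task
    (classes are coarse parts for the primary task, fine members for a
    secondary task).
    """

    train: list[ManifestRecord]
    validation: list[ManifestRecord]
    test: list[ManifestRecord]
    seed: int
    quota: int
    ratio: tuple[int, int, int] = (8, 1, 1)
    task: str = "primary"

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "train": len(self.train),
            "validation": len(self.validation),
            "test": len(self.test),
        }

    def save(self, out_dir: Union[str, Path]) -> None:
        """Write three manifest CSVs plus JSON metadata."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("train", "validation", "test"):
            write_manifest(getattr(self, name), out / f"{name}.csv")
        meta = {
            "task": self.task,
            "seed": self.seed,
            "quota": self.quota,
            "ratio": list(self.ratio),
            "sizes": self.sizes,
        }
        (out / "split.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_manifest(source: Union[str, Path, IO[str]]) -> list[ManifestRecord]:
    """Read a manifest CSV with header ``image,label``.

    Unknown label codes raise a ValueError naming the offending row;
    duplicate image references are kept with a warning.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_manifest(fh)
    reader = csv.DictReader(source)
    if reader.fieldnames is None or not {"image", "label"} <= set(reader.fieldnames):
        raise ValueError("manifest CSV must have header columns 'image,label'")
    records: list[ManifestRecord] = []
    seen: set[str] = set()
    for row_no, row in enumerate(reader, start=2):  # header is line 1
        try:
            label = as_fine(row["label"])
        except ValueError as exc:
            raise ValueError(f"manifest row {row_no}: {exc}") from None
        ref = row["image"]
        if not ref:
            raise ValueError(f"manifest row {row_no}: empty image reference")
        if ref in seen:
            warnings.warn(f"duplicate image reference {ref!r} (kept)", stacklevel=2)
        seen.add(ref)
        records.append(ManifestRecord(ref, label))
    return records


def write_manifest(
    records: Iterable[ManifestRecord], dest: Union[str, Path, IO[str]]
) -> None:
    """Write records as a manifest CSV (header ``image,label``, UTF-8)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            write_manifest(records, fh)
        return
    writer = csv.writer(dest)
    writer.writerow(["image", "label"])
    for rec in records:
        writer.writerow([rec.image_ref, rec.fine_label.code])


def _split_stratified(
    manifest: Sequence[ManifestRecord],
    key,
    classes: Sequence,
    quota: int,
    ratio: tuple[int, int, int],
    seed: int,
    task: str,
) -> SplitResult:
    """Quota-then-ratio split, one class at a time in canonical order."""
    if quota < 0:
        raise ValueError("quota must be nonnegative")
    if len(ratio) != 3 or any(r < 0 for r in ratio) or ratio[0] + ratio[1] == 0:
        raise ValueError(f"invalid ratio {ratio!r}")
    by_class: dict = {c: [] for c in classes}
    for rec in manifest:
        k = key(rec)
        if k in by_class:
            by_class[k].append(rec)
    rng = np.random.default_rng(seed)
    train: list[ManifestRecord] = []
    validation: list[ManifestRecord] = []
    test: list[ManifestRecord] = []
    train_w, val_w = ratio[0], ratio[1]
    for cls in classes:
        pool = by_class[cls]
        if len(pool) < quota:
            raise ValueError(
                f"class {getattr(cls, 'code', cls)} has {len(pool)} records, "
                f"fewer than the test quota {quota}"
            )
        order = rng.permutation(len(pool))
        shuffled = [pool[i] for i in order]
        test.extend(shuffled[:quota])
        remainder = shuffled[quota:]
        n_train = int(round(len(remainder) * train_w / (train_w + val_w)))
        train.extend(remainder[:n_train])
        validation.extend(remainder[n_train:])
    return SplitResult(
        train=train,
        validation=validation,
        test=test,
        seed=seed,
        quota=quota,
        ratio=tuple(ratio),
        task=task,
    )


def split_primary(
    manifest: Sequence[ManifestRecord],
    quota: int = 180,
    ratio: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
) -> SplitResult:
    """Split for the 7-way coarse task.

    Per coarse part: exactly ``quota`` records are undersampled (seeded,
    without replacement) into the test pool; the part's remainder is split
    train:validation = 8:1.  With the full still-image corpus and the
    default quota of 180 this yields a balanced 1260-image test set.
    """
    return _split_stratified(
        manifest,
        key=lambda rec: primary_of(rec.fine_label),
        classes=PRIMARY_ORDER,
        quota=quota,
        ratio=ratio,
        seed=seed,
        task="primary",
    )


def split_secondary(
    manifest: Sequence[ManifestRecord],
    part: PrimaryLabel,
    quota: int,
    ratio: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
) -> SplitResult:
    """Split for one merged part's fine refinement task.

    Restricts the manifest to records whose fine label belongs to *part*
    and applies the same per-class quota/ratio logic over the fine members
    (e.g. duodenum part with quota 88 → a 176-image test set).
    """
    part = as_primary(part)
    if not part.is_merged:
        raise ValueError(f"{part.code} is not a merged part")
    members = secondary_members(part)
    restricted = [rec for rec in manifest if rec.fine_label in members]
    return _split_stratified(
        restricted,
        key=lambda rec: rec.fine_label,
        classes=members,
        quota=quota,
        ratio=ratio,
        seed=seed,
        task=part.code.lower(),
    )


def _pct_floor(numer: int, denom: int) -> float:
    # One-decimal truncation reproduces the corpus' printed distribution
    # table exactly (e.g. 2203/6910 -> 31.8, 8815/31403 -> 28.0), which
    # round-half-up does not.
    q = Decimal(numer * 100) / Decimal(denom)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_DOWN))


def class_distribution(
    manifest: Sequence[ManifestRecord], level: str = "primary"
) -> pd.DataFrame:
    """Per-class counts and one-decimal percentages.

    ``level="primary"`` tallies coarse parts with percentages of the whole
    manifest; ``level="secondary"`` tallies fine labels with percentages
    relative to their part's count.  Percentages are truncated (not
    rounded) to one decimal, matching conventional distribution tables.
    """
    if not manifest:
        raise ValueError("empty manifest")
    if level not in ("primary", "secondary"):
        raise ValueError(f"level must be 'primary' or 'secondary', got {level!r}")
    fine_counts = {f: 0 for f in FINE_ORDER}
    for rec in manifest:
        fine_counts[rec.fine_label] += 1
    total = len(manifest)
    if level == "primary":
        rows = []
        for p in PRIMARY_ORDER:
            count = sum(fine_counts[m] for m in p.members)
            rows.append((p.code, count, _pct_floor(count, total)))
        return pd.DataFrame(rows, columns=["label", "count", "percent"])
    rows = []
    for p in PRIMARY_ORDER:
        part_count = sum(fine_counts[m] for m in p.members)
        for m in p.members:
            pct = _pct_floor(fine_counts[m], part_count) if part_count else float("nan")
            rows.append((p.code, m.code, fine_counts[m], pct))
    return pd.DataFrame(rows, columns=["part", "label", "count", "percent"])


def preprocess_frame(
    image: np.ndarray,
    target_edge: int,
    crop: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Crop, square-resize and rescale one frame.

    Parameters
    ----------
    image
        H×W or H×W×C array, integer or float.
    target_edge
        Output side length (224 for ResNet-style backends, 299 for
        Inception-style ones).
    crop
        Optional ``(top, left, height, width)`` rectangle applied before
        the resize; used to strip patient/device overlays from the frame
        border.  Must lie inside the image.

    Returns
    -------
    ``target_edge × target_edge`` (×C) float64 array with values in [0, 1]
    (bilinear interpolation; uint8 inputs are divided by 255).
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    arr = np.asarray(image)
    if arr.ndim not in (2, 3):
        raise ValueError("image must be 2-D (grayscale) or 3-D (color)")
    if crop is not None:
        top, left, height, width = crop
        if (
            top < 0
            or left < 0
            or height <= 0
            or width <= 0
            or top + height > arr.shape[0]
            or left + width > arr.shape[1]
        ):
            raise ValueError(
                f"crop {crop!r} outside image bounds {arr.shape[:2]}"
            )
        arr = arr[top : top + height, left : left + width]
    if arr.dtype == np.uint8:
        scaled = arr.astype(np.float64) / 255.0
    else:
        scaled = arr.astype(np.float64)
    if scaled.shape[:2] != (target_edge, target_edge):
        # PIL's bilinear resample, channel-plane by channel-plane so float
        # inputs keep full precision.
        planes = scaled[..., None] if scaled.ndim == 2 else scaled
        out = np.empty(
            (target_edge, target_edge, planes.shape[2]), dtype=np.float64
        )
        for c in range(planes.shape[2]):
            im = Image.fromarray(planes[:, :, c], mode="F")
            out[:, :, c] = np.asarray(
                im.resize((target_edge, target_edge), Image.BILINEAR)
            )
        scaled = out[:, :, 0] if scaled.ndim == 2 else out
    return np.clip(scaled, 0.0, 1.0)
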