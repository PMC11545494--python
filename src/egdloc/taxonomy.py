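"""Anatomical label taxonomy for upper-GI endoscopy (EGD).

Eleven fine anatomical classes cover the path of the endoscope from the
esophagus to the second part of the duodenum, plus a non-clear class for
frames in which no landmark is identifiable (blur, wall contact, fluid):

    ES esophagus, GE gastroesophageal junction, CR cardia,
    UB/MB/LB upper/middle/lower gastric body, AG angular notch (angle),
    AT antrum, BB duodenal bulb, SD second part of the duodenum,
    NO non-clear.

Visually contiguous fine classes are merged into coarse "parts" for the
primary (7-way) classification stage: {ES, GE} → esophagus part,
{UB, MB, LB} → gastric bodies part, {BB, SD} → duodenum part; cardia,
angle, antrum and non-clear stand alone.  The secondary stage refines a
merged part back into its fine members.

The taxonomy is fixed: label codes are the field's standard two-letter
abbreviations and the canonical ordering below is used everywhere labels
are serialized or score vectors are laid out.
"""

from __future__ import annotations

import enum
import json
from typing import Union

__all__ = [
    "FineLabel",
    "PrimaryLabel",
    "FINE_ORDER",
    "PRIMARY_ORDER",
    "MERGED_PARTS",
    "primary_of",
    "secondary_members",
    "as_fine",
    "as_primary",
    "fine_index",
    "primary_index",
    "taxonomy_to_json",
]


class FineLabel(str, enum.Enum):
    """One of the 11 fine anatomical classes."""

    ES = "ES"
    GE = "GE"
    CR = "CR"
    UB = "UB"
    MB = "MB"
    LB = "LB"
    AG = "AG"
    AT = "AT"
    BB = "BB"
    SD = "SD"
    NO = "NO"

    @property
    def code(self) -> str:
        return self.value

    @property
    def display_name(self) -> str:
        return _FINE_DISPLAY[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class PrimaryLabel(str, enum.Enum):
    """One of the 7 coarse classes of the primary stage."""

    ESOPHAGUS_PART = "ESOPHAGUS_PART"
    CR = "CR"
    GASTRIC_BODIES_PART = "GASTRIC_BODIES_PART"
    AG = "AG"
    AT = "AT"
    DUODENUM_PART = "DUODENUM_PART"
    NO = "NO"

    @property
    def code(self) -> str:
        return self.value

    @property
    def display_name(self) -> str:
        return _PRIMARY_DISPLAY[self]

    @property
    def members(self) -> tuple[FineLabel, ...]:
        return _MEMBERS[self]

    @property
    def is_merged(self) -> bool:
        return len(_MEMBERS[self]) > 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_FINE_DISPLAY = {
    FineLabel.ES: "Esophagus",
    FineLabel.GE: "Gastroesophageal junction",
    FineLabel.CR: "Cardia",
    FineLabel.UB: "Upper body",
    FineLabel.MB: "Middle body",
    FineLabel.LB: "Lower body",
    FineLabel.AG: "Angle",
    FineLabel.AT: "Antrum",
    FineLabel.BB: "Duodenal bulb",
    FineLabel.SD: "Duodenum second portion",
    FineLabel.NO: "Non-clear",
}

_PRIMARY_DISPLAY = {
    PrimaryLabel.ESOPHAGUS_PART: "Esophagus part",
    PrimaryLabel.CR: "Cardia",
    PrimaryLabel.GASTRIC_BODIES_PART: "Gastric bodies part",
    PrimaryLabel.AG: "Angle",
    PrimaryLabel.AT: "Antrum",
    PrimaryLabel.DUODENUM_PART: "Duodenum part",
    PrimaryLabel.NO: "Non-clear",
}

# Coarse -> fine mapping; merged parts group visually contiguous regions.
_MEMBERS: dict[PrimaryLabel, tuple[FineLabel, ...]] = {
    PrimaryLabel.ESOPHAGUS_PART: (FineLabel.ES, FineLabel.GE),
    PrimaryLabel.CR: (FineLabel.CR,),
    PrimaryLabel.GASTRIC_BODIES_PART: (FineLabel.UB, FineLabel.MB, FineLabel.LB),
    PrimaryLabel.AG: (FineLabel.AG,),
    PrimaryLabel.AT: (FineLabel.AT,),
    PrimaryLabel.DUODENUM_PART: (FineLabel.BB, FineLabel.SD),
    PrimaryLabel.NO: (FineLabel.NO,),
}

#: Canonical orderings used for serialization, score vectors and reports.
FINE_ORDER: tuple[FineLabel, ...] = tuple(FineLabel)
PRIMARY_ORDER: tuple[PrimaryLabel, ...] = tuple(PrimaryLabel)

#: The three merged parts, in canonical order.
MERGED_PARTS: tuple[PrimaryLabel, ...] = tuple(
    p for p in PRIMARY_ORDER if p.is_merged
)

_PRIMARY_OF: dict[FineLabel, PrimaryLabel] = {
    fine: primary for primary, fines in _MEMBERS.items() for fine in fines
}

_FINE_INDEX = {label: i for i, label in enumerate(FINE_ORDER)}
_PRIMARY_INDEX = {label: i for i, label in enumerate(PRIMARY_ORDER)}

FineLike = Union[FineLabel, str]
PrimaryLike = Union[PrimaryLabel, str]


def as_fine(label: FineLike) -> FineLabel:
    """Coerce a code string or FineLabel to a FineLabel.

    Raises ValueError for unknown codes.
    """
    if isinstance(label, FineLabel):
        return label
    try:
        return FineLabel(label)
    except ValueError:
        raise ValueError(
            f"unknown fine label code {label!r}; expected one of "
            f"{[l.code for l in FINE_ORDER]}"
        ) from None


def as_primary(label: PrimaryLike) -> PrimaryLabel:
    """Coerce a code string or PrimaryLabel to a PrimaryLabel."""
    if isinstance(label, PrimaryLabel):
        return label
    try:
        return PrimaryLabel(label)
    except ValueError:
        raise ValueError(
            f"unknown primary label code {label!r}; expected one of "
            f"{[l.code for l in PRIMARY_ORDER]}"
        ) from None


def primary_of(label: FineLike) -> PrimaryLabel:
    """Return the unique coarse part that contains *label*."""
    return _PRIMARY_OF[as_fine(label)]


def secondary_members(primary: PrimaryLike) -> tuple[FineLabel, ...]:
    """Fine members of a coarse part, in canonical order.

    Length 1 for the singleton parts (CR, AG, AT, NO) and 2 or 3 for the
    merged parts.
    """
    return as_primary(primary).members


def fine_index(label: FineLike) -> int:
    """Position of a fine label in the canonical ordering."""
    return _FINE_INDEX[as_fine(label)]


def primary_index(label: PrimaryLike) -> int:
    """Position of a primary label in the canonical ordering."""
    return _PRIMARY_INDEX[as_primary(label)]


def taxonomy_to_json(indent: int | None = 2) -> str:
    """Serialize the fixed taxonomy (for documentation / provenance)."""
    payload = {
        "fine_labels": [
            {
                "code": f.code,
                "display_name": f.display_name,
                "primary": primary_of(f).code,
            }
            for f in FINE_ORDER
        ],
        "primary_labels": [
            {
                "code": p.code,
                "display_name": p.display_name,
                "members": [m.code for m in p.members],
            }
            for p in PRIMARY_ORDER
        ],
    }
    return json.dumps(payload, indent=indent)
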