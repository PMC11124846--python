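"""Behavior vocabulary and label-grouping schemes.

The ethogram for extensively grazed cattle distinguishes five behaviors:
grazing (head-down foraging), walking, resting, ruminating, and grooming.
Coarser groupings collapse these into activity levels (active = grazing or
walking) or into a grazing / non-grazing dichotomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

BEHAVIORS: tuple[str, ...] = ("grazing", "walking", "resting", "ruminating", "grooming")

SOURCES: tuple[str, ...] = ("in_pasture", "collar_video")


class VocabularyError(ValueError):
    """Raised when a behavior label is not in the closed vocabulary."""


def normalize_label(label: str) -> str:
    """Case-normalize and strip a behavior label; reject unknown labels."""
    norm = str(label).strip().lower()
    if norm not in BEHAVIORS:
        raise VocabularyError(
            f"unknown behavior label {label!r}; expected one of {BEHAVIORS}"
        )
    return norm


@dataclass(frozen=True)
class GroupingScheme:
    """A deterministic relabeling of the full ethogram.

    ``mapping`` sends each behavior to its group name; a value of ``None``
    drops epochs with that behavior from the analysis.
    """

    name: str
    mapping: Mapping[str, Optional[str]]

    def apply(self, label: str) -> Optional[str]:
        if label not in self.mapping:
            raise KeyError(f"label {label!r} missing from grouping scheme {self.name!r}")
        return self.mapping[label]

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for v in self.mapping.values():
            if v is not None and v not in seen:
                seen.append(v)
        return tuple(seen)


FULL = GroupingScheme("full", {b: b for b in BEHAVIORS})

#: Four-behavior accounting (grooming excluded from the analysis).
FULL4 = GroupingScheme(
    "full4", {**{b: b for b in BEHAVIORS}, "grooming": None}
)

ACTIVITY = GroupingScheme(
    "activity",
    {
        "grazing": "active",
        "walking": "active",
        "resting": "inactive",
        "ruminating": "inactive",
        "grooming": "inactive",
    },
)

GRAZING_BINARY = GroupingScheme(
    "grazing_binary",
    {b: ("grazing" if b == "grazing" else "non_grazing") for b in BEHAVIORS},
)

SCHEMES: Mapping[str, GroupingScheme] = {
    s.name: s for s in (FULL, FULL4, ACTIVITY, GRAZING_BINARY)
}
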