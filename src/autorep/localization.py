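"""Cellular-localization breakdown of group-defining reactivities.

Antigens carry one or more localization categories from a fixed
five-label vocabulary; the breakdown reports, for a group's overlap set,
the percentage of antigens carrying each category.  Multi-label antigens
count toward every category they carry, so the percentages may sum to
more than 100.
"""

from __future__ import annotations

import pandas as pd

from .containers import ValidationError
from .simulate import LOCALIZATION_CATEGORIES

__all__ = ["LocalizationAnnotation", "localization_breakdown"]


class LocalizationAnnotation:
    """antigen_id -> nonempty set of localization categories.

    Unknown antigens resolve to ``{"other"}``.
    """

    def __init__(self, mapping: dict[str, tuple[str, ...]]):
        clean: dict[str, frozenset[str]] = {}
        for antigen, cats in mapping.items():
            cats = frozenset(cats)
            if not cats:
                raise ValidationError(f"antigen {antigen!r} has an empty category set")
            unknown = cats - set(LOCALIZATION_CATEGORIES)
            if unknown:
                raise ValidationError(
                    f"antigen {antigen!r} has unknown categories {sorted(unknown)}"
                )
            clean[antigen] = cats
        self._mapping = clean

    def __getitem__(self, antigen: str) -> frozenset[str]:
        return self._mapping.get(antigen, frozenset({"other"}))

    def __len__(self) -> int:
        return len(self._mapping)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LocalizationAnnotation":
        """Build from a two-column table (antigen_id, pipe-separated categories)."""
        mapping = {
            str(row["antigen_id"]): tuple(str(row["categories"]).split("|"))
            for _, row in frame.iterrows()
        }
        return cls(mapping)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "antigen_id": list(self._mapping),
                "categories": ["|".join(sorted(c)) for c in self._mapping.values()],
            }
        )


def localization_breakdown(
    overlap_set, ann: LocalizationAnnotation
) -> pd.Series:
    """Percentage of overlap antigens carrying each localization category.

    Raises on an empty overlap set (there is nothing to partition).
    """
    overlap_set = tuple(overlap_set)
    if not overlap_set:
        raise ValidationError("overlap set is empty; nothing to localize")
    counts = {c: 0 for c in LOCALIZATION_CATEGORIES}
    for antigen in overlap_set:
        for c in ann[antigen]:
            counts[c] += 1
    return pd.Series(
        {c: 100.0 * counts[c] / len(overlap_set) for c in LOCALIZATION_CATEGORIES},
        name="percent",
    )
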