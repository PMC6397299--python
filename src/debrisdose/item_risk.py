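"""Per-debris-type lethality: deaths attributed per item ingested.

A death is *attributed* to a debris type when a confirmed debris-caused
bird (KD) or a probable debris-death bird (Ind with
``probable_debris_death=True``) carries that type as its lethal item.  The
per-item death rate for a type is attributed deaths divided by the number
of items of that type ingested across the whole cohort, and types are
compared as rate ratios against a reference type (hard plastic by
default, the dominant but least lethal material).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .records import DEBRIS_TYPES, Cohort, InvariantError

__all__ = [
    "DeathAttribution",
    "ItemRiskRow",
    "ItemRiskTable",
    "SOFT_VS_HARD_GROUPING",
    "attribute_deaths",
    "risk_ratio_table",
]

#: Soft/pliable items (packaging, balloons, rubbers and foams, rope) versus
#: hard plastic — the published aggregate contrast.  Rope is included in the
#: soft aggregate because rope obstructions count among the soft-item deaths.
SOFT_VS_HARD_GROUPING: dict[str, tuple[str, ...]] = {
    "soft": ("soft_plastic", "balloon", "rubber_foam", "rope_fiber"),
    "hard": ("hard_plastic",),
}


@dataclass
class DeathAttribution:
    """Deaths attributed per debris type."""

    combined: dict[str, int]  # confirmed (KD) + probable
    confirmed_only: dict[str, int]  # KD only


@dataclass
class ItemRiskRow:
    item_type: str
    items_ingested: int
    deaths_confirmed: int
    deaths_combined: int
    rate: float  # deaths_combined / items_ingested
    ratio_vs_reference: float


@dataclass
class ItemRiskTable:
    reference: str
    rows: list[ItemRiskRow]
    rounding: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "type": [r.item_type for r in self.rows],
                "items": [r.items_ingested for r in self.rows],
                "deaths_confirmed": [r.deaths_confirmed for r in self.rows],
                "deaths_combined": [r.deaths_combined for r in self.rows],
                "rate": [r.rate for r in self.rows],
                "ratio_vs_reference": [r.ratio_vs_reference for r in self.rows],
            }
        )
        df["ratio_rounded"] = df["ratio_vs_reference"].round(self.rounding)
        return df

    def row(self, item_type: str) -> ItemRiskRow:
        for r in self.rows:
            if r.item_type == item_type:
                return r
        raise KeyError(item_type)


def attribute_deaths(cohort: Cohort) -> DeathAttribution:
    """Count confirmed and confirmed-plus-probable deaths per debris type."""
    combined = {t: 0 for t in DEBRIS_TYPES}
    confirmed = {t: 0 for t in DEBRIS_TYPES}
    for b in cohort:
        if b.cod == "KD" or b.probable_debris_death:
            if b.lethal_item_type is None:
                raise InvariantError(
                    f"bird {b.bird_id}: attributed debris death without lethal_item_type"
                )
            combined[b.lethal_item_type] += 1
            if b.cod == "KD":
                confirmed[b.lethal_item_type] += 1
    return DeathAttribution(combined=combined, confirmed_only=confirmed)


def _items_by_group(
    cohort: Cohort, grouping: Mapping[str, Sequence[str]]
) -> dict[str, int]:
    type_to_group = {}
    for g, types in grouping.items():
        for t in types:
            if t in type_to_group:
                raise ValueError(f"debris type {t!r} appears in more than one group")
            type_to_group[t] = g
    counts = {g: 0 for g in grouping}
    for b in cohort:
        for it in b.items:
            g = type_to_group.get(it.item_type)
            if g is not None:
                counts[g] += 1
    return counts


def risk_ratio_table(
    cohort: Cohort,
    reference: str = "hard_plastic",
    rounding: int = 0,
    grouping: Optional[Mapping[str, Sequence[str]]] = None,
) -> ItemRiskTable:
    """Per-type (or per-group) item counts, attributed deaths, rates, ratios.

    Raw (unrounded) ratios are the canonical output; ``rounding`` only sets
    the presentation column emitted by :meth:`ItemRiskTable.to_frame`.
    With ``grouping``, debris types are pooled into named groups (e.g. the
    soft-versus-hard aggregate) before rates are formed.
    """
    attr = attribute_deaths(cohort)
    if grouping is None:
        grouping = {t: (t,) for t in DEBRIS_TYPES}
    items = _items_by_group(cohort, grouping)
    deaths_comb = {
        g: sum(attr.combined[t] for t in types) for g, types in grouping.items()
    }
    deaths_conf = {
        g: sum(attr.confirmed_only[t] for t in types) for g, types in grouping.items()
    }
    if reference not in grouping:
        raise ValueError(f"reference {reference!r} is not a listed type/group")
    if items[reference] == 0 or deaths_comb[reference] == 0:
        raise ValueError(
            f"reference {reference!r} has {items[reference]} items and "
            f"{deaths_comb[reference]} attributed deaths; its rate is undefined"
        )
    ref_rate = deaths_comb[reference] / items[reference]
    rows = []
    for g in grouping:
        n_items = items[g]
        rate = deaths_comb[g] / n_items if n_items else float("nan")
        rows.append(
            ItemRiskRow(
                item_type=g,
                items_ingested=n_items,
                deaths_confirmed=deaths_conf[g],
                deaths_combined=deaths_comb[g],
                rate=rate,
                ratio_vs_reference=rate / ref_rate if n_items else float("nan"),
            )
        )
    return ItemRiskTable(reference=reference, rows=rows, rounding=rounding)
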