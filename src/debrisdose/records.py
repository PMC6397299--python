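"""Necropsy-cohort domain types, CSV I/O, debris-volume derivation and summaries.

The unit conventions follow field practice for seabird gut-content work:
debris item masses in milligrams, volumes in cubic millimetres, species mean
adult body mass in grams.  Cause-of-death (COD) categories are

* ``KND`` -- known, non-debris-ingestion related (e.g. fisheries by-catch),
* ``Ind`` -- indeterminate,
* ``KD``  -- known, marine-debris-ingestion related (gut blockage,
  obstruction, perforation attributed to an ingested item).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "DEBRIS_TYPES",
    "KNOWN_DEBRIS_TYPES",
    "COD_CATEGORIES",
    "AGE_CLASSES",
    "MATERIAL_DENSITY_G_CM3",
    "DebrisItem",
    "BirdRecord",
    "Cohort",
    "CohortSummary",
    "CohortSchemaError",
    "CohortParseError",
    "InvariantError",
    "derive_volume",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
]

DEBRIS_TYPES = (
    "hard_plastic",
    "soft_plastic",
    "balloon",
    "rubber_foam",
    "rope_fiber",
    "fishing",
    "other",
    "unknown",
)
#: types whose identity was recorded; "unknown" items are excluded from
#: type-share denominators.
KNOWN_DEBRIS_TYPES = DEBRIS_TYPES[:-1]

COD_CATEGORIES = ("KND", "Ind", "KD")
AGE_CLASSES = ("adult", "immature", "unknown")

#: Average material densities (g/cm^3) used to derive item volume from mass.
#: Only rigid, reliably dense materials are derivable; soft/compressible items
#: require a measured displacement volume.
MATERIAL_DENSITY_G_CM3 = {
    "hard_plastic": 0.95,
    "balloon": 0.91,
    "fishing": 7.7,
}


class CohortSchemaError(ValueError):
    """The CSV header does not match the cohort schema."""


class CohortParseError(ValueError):
    """A CSV row contains an unparseable or unrecognised value."""


class InvariantError(ValueError):
    """A record violates a domain invariant."""


def derive_volume(mass_mg: float, item_type: str) -> float:
    """Derive an item's volume (mm^3) from its mass (mg) and material density.

    ``mg / (g/cm^3)`` equals ``mm^3`` numerically, so the conversion is a
    plain division by the tabulated density.  Only hard plastics, balloons
    and fishing gear have a tabulated density; other materials must carry a
    measured (water-displacement) volume.
    """
    if mass_mg < 0:
        raise ValueError(f"mass must be non-negative, got {mass_mg}")
    try:
        density = MATERIAL_DENSITY_G_CM3[item_type]
    except KeyError:
        raise ValueError(
            f"item type {item_type!r} requires measured volume; "
            f"density-derivable types are {sorted(MATERIAL_DENSITY_G_CM3)}"
        ) from None
    return mass_mg / density


@dataclass(frozen=True)
class DebrisItem:
    """One ingested debris item; mass in mg, volume in mm^3, either optional."""

    item_type: str
    mass: Optional[float] = None
    volume: Optional[float] = None

    def __post_init__(self) -> None:
        if self.item_type not in DEBRIS_TYPES:
            raise InvariantError(
                f"unknown debris type {self.item_type!r}; expected one of {DEBRIS_TYPES}"
            )
        for name in ("mass", "volume"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise InvariantError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class BirdRecord:
    """One necropsied bird with its ingested-debris load and COD call.

    ``probable_debris_death`` marks Ind birds judged very likely to have died
    of debris (obstruction suspected but unconfirmed); ``lethal_item_type``
    is the debris category attributed to a confirmed or probable death.
    """

    bird_id: str
    species: str
    family: str
    age_class: str
    species_weight: float  # grams, species mean adult body mass
    cod: str
    items: tuple[DebrisItem, ...] = ()
    probable_debris_death: bool = False
    lethal_item_type: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if self.age_class not in AGE_CLASSES:
            raise InvariantError(
                f"bird {self.bird_id}: unknown age class {self.age_class!r}"
            )
        if self.cod not in COD_CATEGORIES:
            raise InvariantError(f"bird {self.bird_id}: unknown COD {self.cod!r}")
        if not (math.isfinite(self.species_weight) and self.species_weight > 0):
            raise InvariantError(
                f"bird {self.bird_id}: species_weight must be > 0, got {self.species_weight}"
            )
        if self.lethal_item_type is not None and self.lethal_item_type not in DEBRIS_TYPES:
            raise InvariantError(
                f"bird {self.bird_id}: unknown lethal item type {self.lethal_item_type!r}"
            )
        if self.cod == "KD":
            if not self.items:
                raise InvariantError(
                    f"bird {self.bird_id}: cod=KD requires a non-empty item list"
                )
            if self.lethal_item_type is None:
                raise InvariantError(
                    f"bird {self.bird_id}: cod=KD requires lethal_item_type"
                )
        if self.probable_debris_death:
            if self.cod != "Ind":
                raise InvariantError(
                    f"bird {self.bird_id}: probable_debris_death requires cod=Ind"
                )
            if not self.items:
                raise InvariantError(
                    f"bird {self.bird_id}: probable_debris_death requires ingested items"
                )

    @property
    def n_items(self) -> int:
        return len(self.items)

    def total_mass(self) -> float:
        """Summed recorded item mass (mg); items without mass contribute 0."""
        return float(sum(i.mass for i in self.items if i.mass is not None))

    def total_volume(self) -> float:
        """Summed recorded item volume (mm^3)."""
        return float(sum(i.volume for i in self.items if i.volume is not None))


@dataclass
class Cohort:
    """A necropsy cohort; bird ids are unique."""

    birds: list[BirdRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.birds:
            if b.bird_id in seen:
                raise InvariantError(f"duplicate bird_id {b.bird_id!r} in cohort")
            seen.add(b.bird_id)

    def __len__(self) -> int:
        return len(self.birds)

    def __iter__(self):
        return iter(self.birds)

    def n_by_cod(self) -> dict[str, int]:
        out = {c: 0 for c in COD_CATEGORIES}
        for b in self.birds:
            out[b.cod] += 1
        return out


@dataclass
class CohortSummary:
    n_birds: int
    n_ingesting: int
    pct_ingesting: float
    items_total: int  # items of known type
    items_by_type: dict[str, int]  # includes "unknown"
    pct_by_type: dict[str, float]  # shares of known-type items, percent
    max_load_count: int
    max_load_mass: float  # mg
    max_load_volume: float  # mm^3
    n_by_cod: dict[str, int]


# ---------------------------------------------------------------------------
# CSV serialisation.  One row per bird; the item list is packed into a single
# column as semicolon-separated "type:mass:volume" triplets with empty fields
# for unrecorded values, e.g. "hard_plastic:120:126.3;balloon::".

_CSV_COLUMNS = (
    "bird_id",
    "species",
    "family",
    "age_class",
    "species_weight_g",
    "cod",
    "probable_debris_death",
    "lethal_item_type",
    "items",
)


def _format_items(items: Sequence[DebrisItem]) -> str:
    parts = []
    for it in items:
        m = "" if it.mass is None else repr(float(it.mass))
        v = "" if it.volume is None else repr(float(it.volume))
        parts.append(f"{it.item_type}:{m}:{v}")
    return ";".join(parts)


def _parse_items(text: str, row_no: int) -> tuple[DebrisItem, ...]:
    text = text.strip()
    if not text:
        return ()
    items = []
    for chunk in text.split(";"):
        fields = chunk.split(":")
        if len(fields) != 3:
            raise CohortParseError(
                f"row {row_no}: malformed item triplet {chunk!r} "
                "(expected type:mass:volume)"
            )
        t, m, v = (f.strip() for f in fields)
        if t not in DEBRIS_TYPES:
            raise CohortParseError(
                f"row {row_no}: unknown debris type token {t!r}"
            )
        try:
            mass = float(m) if m else None
            vol = float(v) if v else None
        except ValueError:
            raise CohortParseError(
                f"row {row_no}: non-numeric mass/volume in item {chunk!r}"
            ) from None
        items.append(DebrisItem(t, mass, vol))
    return tuple(items)


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def read_cohort(path: Union[str, Path]) -> Cohort:
    """Read a cohort CSV (schema above); invalid rows raise with row numbers."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _CSV_COLUMNS if c not in header]
        if missing:
            raise CohortSchemaError(
                f"{path.name}: missing required column(s) {missing}; "
                f"expected {list(_CSV_COLUMNS)}"
            )
        birds = []
        for row_no, row in enumerate(reader, start=2):  # header is line 1
            cod = row["cod"].strip()
            if cod not in COD_CATEGORIES:
                raise CohortParseError(
                    f"row {row_no}: unknown COD token {cod!r}; expected one of {COD_CATEGORIES}"
                )
            age = row["age_class"].strip()
            if age not in AGE_CLASSES:
                raise CohortParseError(
                    f"row {row_no}: unknown age class token {age!r}"
                )
            prob_raw = row["probable_debris_death"].strip().lower()
            if prob_raw in _TRUE:
                probable = True
            elif prob_raw in _FALSE:
                probable = False
            else:
                raise CohortParseError(
                    f"row {row_no}: unparseable boolean {row['probable_debris_death']!r}"
                )
            lethal = row["lethal_item_type"].strip() or None
            try:
                weight = float(row["species_weight_g"])
            except ValueError:
                raise CohortParseError(
                    f"row {row_no}: non-numeric species weight {row['species_weight_g']!r}"
                ) from None
            try:
                bird = BirdRecord(
                    bird_id=row["bird_id"].strip(),
                    species=row["species"].strip(),
                    family=row["family"].strip(),
                    age_class=age,
                    species_weight=weight,
                    cod=cod,
                    items=_parse_items(row["items"], row_no),
                    probable_debris_death=probable,
                    lethal_item_type=lethal,
                )
            except InvariantError as err:
                raise InvariantError(f"row {row_no}: {err}") from None
            birds.append(bird)
    return Cohort(birds=birds, provenance=str(path))


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort to CSV; ``read_cohort`` round-trips it field-for-field."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for b in cohort.birds:
            writer.writerow(
                [
                    b.bird_id,
                    b.species,
                    b.family,
                    b.age_class,
                    repr(float(b.species_weight)),
                    b.cod,
                    "true" if b.probable_debris_death else "false",
                    b.lethal_item_type or "",
                    _format_items(b.items),
                ]
            )


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Cohort-level ingestion summary; percentages kept at full precision."""
    n_birds = len(cohort)
    ingesting = [b for b in cohort if b.n_items > 0]
    items_by_type = {t: 0 for t in DEBRIS_TYPES}
    for b in cohort:
        for it in b.items:
            items_by_type[it.item_type] += 1
    items_total = sum(items_by_type[t] for t in KNOWN_DEBRIS_TYPES)
    pct_by_type = {
        t: (100.0 * items_by_type[t] / items_total if items_total else 0.0)
        for t in KNOWN_DEBRIS_TYPES
    }
    return CohortSummary(
        n_birds=n_birds,
        n_ingesting=len(ingesting),
        pct_ingesting=(100.0 * len(ingesting) / n_birds if n_birds else 0.0),
        items_total=items_total,
        items_by_type=items_by_type,
        pct_by_type=pct_by_type,
        max_load_count=max((b.n_items for b in cohort), default=0),
        max_load_mass=max((b.total_mass() for b in cohort), default=0.0),
        max_load_volume=max((b.total_volume() for b in cohort), default=0.0),
        n_by_cod=cohort.n_by_cod(),
    )
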