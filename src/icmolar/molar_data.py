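"""Reading, validation, filtering, and genus-level aggregation of molar tables.

The raw input is a long-format CSV with one row per (specimen, tooth):
``specimen_id,genus,tooth,length,width,source``, lengths and widths in
mm, missing values as empty cells.  Occlusal area is estimated as the
product of maximum length and maximum width; each posterior tooth's area
is scaled by the same specimen's m1 area, and per-specimen ratios are
averaged to a single morphospace point per genus.  Length is never used
as a proxy for area.

Filtering mirrors the sampling rules of the analysis: genera represented
only by isolated molars are dropped (no control over intraspecific
variation), genera whose tooth row has fewer than three molar positions
are dropped, and a specimen is kept only if it preserves at least one
adjacent molar pair (m1-m2 or m2-m3) with both areas measurable.  Every
dropped specimen or genus gets exactly one primary exclusion record, so
kept + excluded always reconciles with the input.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TOOTH_POSITIONS",
    "DIET_CATEGORIES",
    "MolarMeasurement",
    "SpecimenAreas",
    "SpecimenRatios",
    "GenusRecord",
    "GenusMeta",
    "ExclusionRule",
    "ExclusionRecord",
    "MeasurementError",
    "read_measurement_table",
    "read_metadata_table",
    "compute_specimen_areas",
    "filter_specimens",
    "specimen_ratios",
    "aggregate_genus",
    "write_genus_records",
    "read_genus_records",
    "write_exclusions",
]

TOOTH_POSITIONS = ("m1", "m2", "m3")

DIET_CATEGORIES = (
    "folivorous",
    "carnivorous",
    "omnivorous",
    "insectivorous",
    "frugivorous",
    "durophagous",
)


class MeasurementError(ValueError):
    """Validation failure in an input table, naming the offending row."""


@dataclass(frozen=True)
class MolarMeasurement:
    """One tooth's length/width measurement for one specimen."""

    specimen_id: str
    genus: str
    tooth: str  # "m1" | "m2" | "m3"
    length: float | None  # mm
    width: float | None  # mm
    source: str = ""

    def __post_init__(self) -> None:
        if self.tooth not in TOOTH_POSITIONS:
            raise MeasurementError(
                f"unknown tooth position {self.tooth!r} for specimen "
                f"{self.specimen_id!r} (expected one of {TOOTH_POSITIONS})"
            )
        for name, value in (("length", self.length), ("width", self.width)):
            if value is not None and not value > 0:
                raise MeasurementError(
                    f"non-positive {name} {value} for specimen "
                    f"{self.specimen_id!r} tooth {self.tooth}"
                )


@dataclass(frozen=True)
class SpecimenAreas:
    """Occlusal areas (mm^2) for one specimen; missing where either
    dimension is missing.  ``recorded`` lists tooth positions that had a
    measurement row at all, used to attribute exclusions."""

    specimen_id: str
    genus: str
    a1: float | None
    a2: float | None
    a3: float | None
    recorded: frozenset = field(default_factory=frozenset)

    def area(self, tooth: str) -> float | None:
        return {"m1": self.a1, "m2": self.a2, "m3": self.a3}[tooth]


@dataclass(frozen=True)
class SpecimenRatios:
    """Per-specimen area ratios scaled to m1, plus the m2 share.

    ``r21 = a2/a1``, ``r31 = a3/a1``, ``r32 = a3/a2``; each present
    exactly when both constituent areas are.  ``m2_share`` (fraction of
    total molar area) requires all three areas.
    """

    specimen_id: str
    genus: str
    r21: float | None
    r31: float | None
    r32: float | None
    m2_share: float | None


@dataclass(frozen=True)
class GenusRecord:
    """A genus's morphospace point: mean of per-specimen ratios."""

    genus: str
    n_specimens: int
    x: float | None  # mean r21 (m2/m1 area)
    y: float | None  # mean r31 (m3/m1 area)
    m2_share_mean: float | None
    group: str = ""
    diet: str = ""


@dataclass(frozen=True)
class GenusMeta:
    """Genus-level metadata: taxonomic group, dietary guild, and the
    sampling flags driving exclusion."""

    group: str
    diet: str
    isolated_only: bool = False
    molar_count: int = 3


class ExclusionRule(enum.Enum):
    ISOLATED_MOLARS_ONLY = "isolated_molars_only"
    FEWER_THAN_TWO_ADJACENT = "fewer_than_two_adjacent"
    MISSING_LENGTH_OR_WIDTH = "missing_length_or_width"
    FEWER_THAN_THREE_MOLAR_POSITIONS = "fewer_than_three_molar_positions"


@dataclass(frozen=True)
class ExclusionRecord:
    """Why a specimen (or whole genus) was dropped; one per casualty."""

    subject: str  # specimen_id, or genus for genus-level rules
    genus: str
    rule: ExclusionRule
    note: str = ""


def _parse_optional_positive(raw: str, what: str, where: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError as exc:
        raise MeasurementError(f"unparseable {what} {raw!r} at {where}") from exc
    if not math.isfinite(value) or value <= 0:
        raise MeasurementError(f"non-positive {what} {value} at {where}")
    return value


def read_measurement_table(path: str | Path) -> list[MolarMeasurement]:
    """Read a long-format measurement CSV into validated records.

    Duplicate (specimen_id, tooth) pairs, unknown tooth labels, and
    non-positive dimensions raise :class:`MeasurementError` naming the row.
    """
    path = Path(path)
    required = {"specimen_id", "genus", "tooth", "length", "width", "source"}
    records: list[MolarMeasurement] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or ())
            raise MeasurementError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            where = f"{path.name}:{lineno}"
            specimen = row["specimen_id"].strip()
            tooth = row["tooth"].strip()
            if tooth not in TOOTH_POSITIONS:
                raise MeasurementError(f"unknown tooth label {tooth!r} at {where}")
            key = (specimen, tooth)
            if key in seen:
                raise MeasurementError(
                    f"duplicate measurement for specimen {specimen!r} "
                    f"tooth {tooth} at {where}"
                )
            seen.add(key)
            records.append(
                MolarMeasurement(
                    specimen_id=specimen,
                    genus=row["genus"].strip(),
                    tooth=tooth,
                    length=_parse_optional_positive(row["length"], "length", where),
                    width=_parse_optional_positive(row["width"], "width", where),
                    source=row.get("source", "").strip(),
                )
            )
    return records


def read_metadata_table(path: str | Path) -> dict[str, GenusMeta]:
    """Read the genus metadata CSV (genus,group,diet,isolated_only,molar_count)."""
    path = Path(path)
    meta: dict[str, GenusMeta] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"genus", "group", "diet"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or ())
            raise MeasurementError(f"{path}: missing required columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            genus = row["genus"].strip()
            if genus in meta:
                raise MeasurementError(f"duplicate genus {genus!r} at {path.name}:{lineno}")
            diet = row["diet"].strip()
            if diet and diet not in DIET_CATEGORIES:
                raise MeasurementError(
                    f"unknown dietary guild {diet!r} at {path.name}:{lineno}"
                )
            iso = row.get("isolated_only", "").strip().lower()
            meta[genus] = GenusMeta(
                group=row["group"].strip(),
                diet=diet,
                isolated_only=iso in {"1", "true", "yes"},
                molar_count=int(row.get("molar_count", "3") or 3),
            )
    return meta


def compute_specimen_areas(
    measurements: Iterable[MolarMeasurement],
) -> list[SpecimenAreas]:
    """Per-specimen occlusal areas as length x width, missing where either
    dimension is missing (length alone is never used)."""
    by_specimen: dict[str, dict] = {}
    order: list[str] = []
    for m in measurements:
        if m.specimen_id not in by_specimen:
            by_specimen[m.specimen_id] = {"genus": m.genus, "areas": {}, "recorded": set()}
            order.append(m.specimen_id)
        entry = by_specimen[m.specimen_id]
        if entry["genus"] != m.genus:
            raise MeasurementError(
                f"specimen {m.specimen_id!r} assigned to both "
                f"{entry['genus']!r} and {m.genus!r}"
            )
        entry["recorded"].add(m.tooth)
        if m.length is not None and m.width is not None:
            entry["areas"][m.tooth] = m.length * m.width
    return [
        SpecimenAreas(
            specimen_id=sid,
            genus=by_specimen[sid]["genus"],
            a1=by_specimen[sid]["areas"].get("m1"),
            a2=by_specimen[sid]["areas"].get("m2"),
            a3=by_specimen[sid]["areas"].get("m3"),
            recorded=frozenset(by_specimen[sid]["recorded"]),
        )
        for sid in order
    ]


def _has_adjacent_pair(areas: SpecimenAreas) -> bool:
    return (areas.a1 is not None and areas.a2 is not None) or (
        areas.a2 is not None and areas.a3 is not None
    )


def filter_specimens(
    areas: Sequence[SpecimenAreas],
    genus_flags: Mapping[str, GenusMeta],
    missing_metadata: str = "strict",
) -> tuple[list[SpecimenAreas], list[ExclusionRecord]]:
    """Apply the sampling rules; return kept specimens and the exclusion log.

    Genus-level rules (isolated molars only; fewer than three molar
    positions in the row) drop all of a genus's specimens and log one
    record per specimen under the genus rule.  Remaining specimens must
    preserve an adjacent pair among (m1,m2)/(m2,m3); failures are
    attributed to missing dimensions when the teeth were recorded but
    unmeasurable, otherwise to missing teeth.

    ``missing_metadata`` is ``"strict"`` (unknown genus raises) or
    ``"assume"`` (treat as not isolated-only with a 3-molar row).
    """
    if missing_metadata not in {"strict", "assume"}:
        raise ValueError("missing_metadata must be 'strict' or 'assume'")
    kept: list[SpecimenAreas] = []
    excluded: list[ExclusionRecord] = []
    for spec in areas:
        meta = genus_flags.get(spec.genus)
        if meta is None:
            if missing_metadata == "strict":
                raise MeasurementError(
                    f"genus {spec.genus!r} missing from metadata"
                )
            meta = GenusMeta(group="", diet="")
        if meta.isolated_only:
            excluded.append(
                ExclusionRecord(
                    subject=spec.specimen_id,
                    genus=spec.genus,
                    rule=ExclusionRule.ISOLATED_MOLARS_ONLY,
                    note="genus represented only by isolated molars",
                )
            )
            continue
        if meta.molar_count < 3:
            excluded.append(
                ExclusionRecord(
                    subject=spec.specimen_id,
                    genus=spec.genus,
                    rule=ExclusionRule.FEWER_THAN_THREE_MOLAR_POSITIONS,
                    note=f"tooth row has {meta.molar_count} molar positions",
                )
            )
            continue
        if _has_adjacent_pair(spec):
            kept.append(spec)
            continue
        recorded_adjacent = ({"m1", "m2"} <= spec.recorded) or (
            {"m2", "m3"} <= spec.recorded
        )
        rule = (
            ExclusionRule.MISSING_LENGTH_OR_WIDTH
            if recorded_adjacent
            else ExclusionRule.FEWER_THAN_TWO_ADJACENT
        )
        excluded.append(
            ExclusionRecord(
                subject=spec.specimen_id,
                genus=spec.genus,
                rule=rule,
                note="no adjacent molar pair with both areas measurable",
            )
        )
    return kept, excluded


def specimen_ratios(areas: SpecimenAreas) -> SpecimenRatios:
    """Area ratios scaled to m1, and the m2 share of total area."""

    def ratio(num: float | None, den: float | None) -> float | None:
        if num is None or den is None:
            return None
        return num / den

    share = None
    if areas.a1 is not None and areas.a2 is not None and areas.a3 is not None:
        share = areas.a2 / (areas.a1 + areas.a2 + areas.a3)
    return SpecimenRatios(
        specimen_id=areas.specimen_id,
        genus=areas.genus,
        r21=ratio(areas.a2, areas.a1),
        r31=ratio(areas.a3, areas.a1),
        r32=ratio(areas.a3, areas.a2),
        m2_share=share,
    )


def _mean_or_none(values: list[float]) -> float | None:
    return sum(values) / len(values) if values else None


def aggregate_genus(
    ratios: Iterable[SpecimenRatios],
    metadata: Mapping[str, "GenusMeta | tuple[str, str]"],
) -> list[GenusRecord]:
    """Average per-specimen ratios to one record per genus.

    The aggregation is the arithmetic mean of the available per-specimen
    ratios (not the ratio of mean areas, which differs under noise); each
    statistic averages over the specimens that have it, so a genus may
    have x but no y.  Raises for genera absent from ``metadata``.
    """
    by_genus: dict[str, list[SpecimenRatios]] = {}
    order: list[str] = []
    for r in ratios:
        if r.genus not in by_genus:
            by_genus[r.genus] = []
            order.append(r.genus)
        by_genus[r.genus].append(r)
    missing = [g for g in order if g not in metadata]
    if missing:
        raise MeasurementError(f"genera missing from metadata: {missing}")
    records: list[GenusRecord] = []
    for genus in order:
        specs = by_genus[genus]
        meta = metadata[genus]
        if isinstance(meta, tuple):
            group, diet = meta
        else:
            group, diet = meta.group, meta.diet
        records.append(
            GenusRecord(
                genus=genus,
                n_specimens=len(specs),
                x=_mean_or_none([s.r21 for s in specs if s.r21 is not None]),
                y=_mean_or_none([s.r31 for s in specs if s.r31 is not None]),
                m2_share_mean=_mean_or_none(
                    [s.m2_share for s in specs if s.m2_share is not None]
                ),
                group=group,
                diet=diet,
            )
        )
    return records


_GENUS_COLUMNS = ("genus", "n_specimens", "x", "y", "m2_share_mean", "group", "diet")


def write_genus_records(records: Sequence[GenusRecord], path: str | Path) -> None:
    """Write genus records as TSV; missing values as empty fields.

    Floats are written with :func:`repr` so a read-back round-trips
    bit-for-bit.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_GENUS_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.genus,
                    rec.n_specimens,
                    "" if rec.x is None else repr(rec.x),
                    "" if rec.y is None else repr(rec.y),
                    "" if rec.m2_share_mean is None else repr(rec.m2_share_mean),
                    rec.group,
                    rec.diet,
                ]
            )


def read_genus_records(path: str | Path) -> list[GenusRecord]:
    """Read back a genus-records TSV written by :func:`write_genus_records`."""
    records: list[GenusRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                GenusRecord(
                    genus=row["genus"],
                    n_specimens=int(row["n_specimens"]),
                    x=float(row["x"]) if row["x"] else None,
                    y=float(row["y"]) if row["y"] else None,
                    m2_share_mean=(
                        float(row["m2_share_mean"]) if row["m2_share_mean"] else None
                    ),
                    group=row["group"],
                    diet=row["diet"],
                )
            )
    return records


def write_exclusions(records: Sequence[ExclusionRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(("subject", "genus", "rule", "note"))
        for rec in records:
            writer.writerow((rec.subject, rec.genus, rec.rule.value, rec.note))
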