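"""Occurrence-record ingestion, cleaning and lake harmonization.

Raw occurrence tables (GBIF-style Darwin Core columns) are noisy: species
names with unresolved epithets ("Oreochromis spp."), waterbody names in
several languages and spellings ("lac Edouard" vs "Lake Edward"), records
with no waterbody at all, and records whose stated country disagrees with
the lake's location.  This module turns such a table into analysis-ready
lake-by-country units through an ordered, auditable filtering pipeline:

1. drop names with incomplete scientific epithets;
2. drop records with no waterbody and no resolvable coordinates/locality;
3. harmonize waterbody names to canonical English names via the registry
   synonym map;
4. drop records whose waterbody is not in the registry (no determinable
   surface area);
5. drop records whose country conflicts with the registry's
   (lake, country) pairs.

Every stage emits a :class:`FilterReport`, so drops + survivors always
reconcile with the input count.
"""

from __future__ import annotations

import unicodedata
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError, SchemaError

__all__ = [
    "OccurrenceRecord",
    "LakeRegistryEntry",
    "LakeRegistry",
    "FilterReport",
    "LakeCountryUnit",
    "load_occurrences",
    "records_from_frame",
    "apply_overrides",
    "filter_records",
    "build_units",
    "reports_to_frame",
]

#: Cell values treated as "absent" when reading delimited text.
MISSING_MARKERS = {"", "na", "n/a", "nan", "none", "null", "-", "?"}

#: Default source -> canonical column mapping (Darwin Core dialect).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "scientificName": "species_name",
    "species": "species_name",
    "species_name": "species_name",
    "country": "country",
    "waterBody": "waterbody",
    "waterbody": "waterbody",
    "decimalLatitude": "latitude",
    "latitude": "latitude",
    "decimalLongitude": "longitude",
    "longitude": "longitude",
    "locality": "locality_notes",
    "locality_notes": "locality_notes",
    "habitat": "locality_notes",
}

_MANDATORY = ("species_name", "country")


def _fold(text: str) -> str:
    """Case-insensitive, accent-insensitive key for name matching."""
    decomposed = unicodedata.normalize("NFKD", text.casefold())
    return "".join(c for c in decomposed if not unicodedata.combining(c)).strip()


@dataclass(frozen=True)
class OccurrenceRecord:
    """One raw or cleaned species sighting tied to a lake and country."""

    species_name: str
    country: str
    waterbody: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    locality_notes: str | None = None
    record_id: int | None = None


@dataclass(frozen=True)
class LakeRegistryEntry:
    """A (lake, country) pair with the national portion's surface area.

    ``area_km2`` is the surface area of the portion of the lake lying in
    ``country`` — shared lakes appear once per riparian country, each with
    its own area.
    """

    canonical_name: str
    country: str
    area_km2: float
    synonyms: tuple[str, ...] = ()


class LakeRegistry:
    """Lookup structure for canonical lake names, countries and areas.

    Name matching is case-insensitive and accent-folding; every synonym
    must map to exactly one canonical lake name.
    """

    def __init__(self, entries: Iterable[LakeRegistryEntry]):
        self._entries: dict[tuple[str, str], LakeRegistryEntry] = {}
        self._names: dict[str, str] = {}
        for entry in entries:
            if entry.area_km2 <= 0:
                raise InputError(
                    f"registry entry ({entry.canonical_name}, {entry.country}) "
                    f"has nonpositive area {entry.area_km2}"
                )
            key = (_fold(entry.canonical_name), _fold(entry.country))
            if key in self._entries:
                raise InputError(
                    f"duplicate registry entry ({entry.canonical_name}, {entry.country})"
                )
            self._entries[key] = entry
            for name in (entry.canonical_name, *entry.synonyms):
                folded = _fold(name)
                known = self._names.get(folded)
                if known is not None and known != entry.canonical_name:
                    raise InputError(
                        f"synonym {name!r} maps to both {known!r} and "
                        f"{entry.canonical_name!r}"
                    )
                self._names[folded] = entry.canonical_name

    def resolve_name(self, raw_name: str) -> str | None:
        """Canonical English lake name for ``raw_name``, or None if unknown."""
        return self._names.get(_fold(raw_name))

    def lookup(self, lake: str, country: str) -> LakeRegistryEntry | None:
        """Entry for the (lake, country) pair, resolving synonyms first."""
        canonical = self.resolve_name(lake)
        if canonical is None:
            return None
        return self._entries.get((_fold(canonical), _fold(country)))

    def known_names(self) -> list[str]:
        """All canonical names and synonyms (folded form not exposed)."""
        return sorted(set(self._names.values()) | set(self._names.keys()))

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LakeRegistry":
        required = {"canonical_name", "country", "area_km2"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(
                f"registry table missing column(s): {', '.join(sorted(missing))}"
            )
        entries = []
        for row in frame.itertuples(index=False):
            raw_syn = getattr(row, "synonyms", None)
            synonyms: tuple[str, ...] = ()
            if isinstance(raw_syn, str) and raw_syn.strip():
                synonyms = tuple(
                    s.strip() for s in raw_syn.split("|") if s.strip()
                )
            entries.append(
                LakeRegistryEntry(
                    canonical_name=str(row.canonical_name).strip(),
                    country=str(row.country).strip(),
                    area_km2=float(row.area_km2),
                    synonyms=synonyms,
                )
            )
        return cls(entries)

    @classmethod
    def from_csv(cls, path: str | Path, delimiter: str = ",") -> "LakeRegistry":
        try:
            frame = pd.read_csv(path, sep=delimiter, dtype=str).astype(
                {"area_km2": float}, errors="ignore"
            )
        except (OSError, ValueError) as exc:
            raise InputError(f"cannot read registry {path}: {exc}") from exc
        return cls.from_frame(frame)


@dataclass(frozen=True)
class FilterReport:
    """Per-stage accounting: how many records entered, survived, and why."""

    stage_name: str
    records_in: int
    records_out: int
    dropped_reason: str

    @property
    def dropped(self) -> int:
        return self.records_in - self.records_out


@dataclass(frozen=True)
class LakeCountryUnit:
    """The unit of analysis: the national portion of one lake.

    Holds the distinct species set observed there; raw record counts are
    kept only in filter reports because the index scores species sets,
    not abundances.
    """

    lake: str
    country: str
    area_km2: float
    species: frozenset[str] = field(default_factory=frozenset)

    @property
    def richness(self) -> int:
        return len(self.species)


def _clean_cell(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text.casefold() in MISSING_MARKERS:
        return None
    return text


def _clean_float(value) -> float | None:
    text = _clean_cell(value)
    if text is None:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def load_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[OccurrenceRecord]:
    """Read a delimited occurrence table into records.

    Parameters
    ----------
    path:
        CSV/TSV file. The delimiter is taken from the file extension
        (``.tsv`` -> tab) unless given explicitly.
    column_map:
        Source-column -> canonical-field mapping; merged over the Darwin
        Core defaults, so only non-standard headers need mapping. Canonical
        fields are ``species_name``, ``country``, ``waterbody``,
        ``latitude``, ``longitude``, ``locality_notes``.

    Raises
    ------
    InputError
        If the file cannot be read or parsed.
    SchemaError
        If a mandatory column (species, country) is absent; the message
        names the missing canonical column.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str)
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read occurrences {path}: {exc}") from exc
    return records_from_frame(frame, column_map)


def records_from_frame(
    frame: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> list[OccurrenceRecord]:
    """Turn an in-memory occurrence table into records (see load_occurrences)."""
    mapping = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        mapping.update(column_map)
    canonical: dict[str, str] = {}
    for source, target in mapping.items():
        if source in frame.columns and target not in canonical:
            canonical[target] = source
    for target in _MANDATORY:
        if target not in canonical:
            raise SchemaError(f"occurrence table missing mandatory column: {target}")

    records: list[OccurrenceRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row_map = dict(zip(frame.columns, row))
        species = _clean_cell(row_map[canonical["species_name"]])
        country = _clean_cell(row_map[canonical["country"]])
        records.append(
            OccurrenceRecord(
                species_name=species or "",
                country=country or "",
                waterbody=_clean_cell(row_map.get(canonical.get("waterbody", ""), None)),
                latitude=_clean_float(row_map.get(canonical.get("latitude", ""), None)),
                longitude=_clean_float(row_map.get(canonical.get("longitude", ""), None)),
                locality_notes=_clean_cell(
                    row_map.get(canonical.get("locality_notes", ""), None)
                ),
                record_id=i,
            )
        )
    return records


def apply_overrides(
    records: Sequence[OccurrenceRecord],
    overrides: Mapping[int, str] | None,
) -> list[OccurrenceRecord]:
    """Apply expert record_id -> corrected-lake reassignments before filtering.

    Mirrors manual relocation of misassigned records (a species recorded in
    a lake outside its described range moved to the lake where it is
    endemic); the corrections themselves are supplied by the user.
    """
    if not overrides:
        return list(records)
    out = []
    for rec in records:
        if rec.record_id is not None and rec.record_id in overrides:
            rec = replace(rec, waterbody=overrides[rec.record_id])
        out.append(rec)
    return out


def _has_incomplete_epithet(name: str) -> bool:
    tokens = name.split()
    if len(tokens) < 2:
        return True
    return tokens[-1].casefold().rstrip(".") in {"sp", "spp"}


def _resolve_missing_waterbody(
    record: OccurrenceRecord,
    registry: LakeRegistry,
    point_lookup: Mapping[tuple[float, float], str]
    | Callable[[float, float], str | None]
    | None,
) -> str | None:
    """Try to assign a waterbody to a record that lacks one.

    Coordinates are consulted first through the optional user-supplied
    point-in-lake lookup; failing that, the locality/habitat free text is
    scanned for a known lake name (longest folded match wins, ties broken
    lexicographically, so the result is deterministic).
    """
    if point_lookup is not None and record.latitude is not None and record.longitude is not None:
        if callable(point_lookup):
            hit = point_lookup(record.latitude, record.longitude)
        else:
            hit = point_lookup.get((record.latitude, record.longitude))
        if hit is not None:
            return hit
    if record.locality_notes:
        haystack = _fold(record.locality_notes)
        matches = [
            name
            for name in registry.known_names()
            if _fold(name) and _fold(name) in haystack
        ]
        if matches:
            return sorted(matches, key=lambda n: (-len(_fold(n)), _fold(n)))[0]
    return None


def filter_records(
    records: Sequence[OccurrenceRecord],
    registry: LakeRegistry,
    drop_incomplete_epithets: bool = True,
    point_lookup: Mapping[tuple[float, float], str]
    | Callable[[float, float], str | None]
    | None = None,
) -> tuple[list[OccurrenceRecord], list[FilterReport]]:
    """Run the five-stage cleaning pipeline.

    Filtering is total: an empty survivor set is a valid output, and the
    per-stage reports always reconcile (drops + survivors = input count).
    Re-running the pipeline on its own survivors changes nothing.
    """
    reports: list[FilterReport] = []
    current = list(records)

    # Stage 1: incomplete scientific epithets ("Genus sp."/"Genus spp.").
    n_in = len(current)
    if drop_incomplete_epithets:
        current = [r for r in current if not _has_incomplete_epithet(r.species_name)]
    reports.append(
        FilterReport(
            "incomplete_epithet",
            n_in,
            len(current),
            "scientific name lacks a specific epithet (sp./spp. or single token)",
        )
    )

    # Stage 2: no waterbody and no resolvable coordinates/locality.
    n_in = len(current)
    resolved: list[OccurrenceRecord] = []
    for rec in current:
        if rec.waterbody:
            resolved.append(rec)
            continue
        assigned = _resolve_missing_waterbody(rec, registry, point_lookup)
        if assigned is not None:
            resolved.append(replace(rec, waterbody=assigned))
    current = resolved
    reports.append(
        FilterReport(
            "unresolvable_waterbody",
            n_in,
            len(current),
            "no waterbody and no resolvable coordinates or locality",
        )
    )

    # Stage 3: harmonize waterbody names to canonical English names.
    n_in = len(current)
    current = [
        replace(r, waterbody=registry.resolve_name(r.waterbody) or r.waterbody)
        for r in current
    ]
    reports.append(
        FilterReport("harmonize_names", n_in, len(current), "renames only; no drops")
    )

    # Stage 4: waterbody unknown to the registry -> no determinable area.
    n_in = len(current)
    current = [r for r in current if registry.resolve_name(r.waterbody) is not None]
    reports.append(
        FilterReport(
            "unknown_waterbody",
            n_in,
            len(current),
            "waterbody absent from registry (surface area undeterminable)",
        )
    )

    # Stage 5: country conflicts with the registry's (lake, country) pairs.
    n_in = len(current)
    current = [r for r in current if registry.lookup(r.waterbody, r.country) is not None]
    reports.append(
        FilterReport(
            "country_conflict",
            n_in,
            len(current),
            "record country not among the lake's registered countries",
        )
    )
    return current, reports


def build_units(
    records: Sequence[OccurrenceRecord], registry: LakeRegistry
) -> list[LakeCountryUnit]:
    """Aggregate harmonized survivors into lake-by-country units.

    One unit per observed (lake, country); its species set is the distinct
    species among the unit's records, its area the registry's
    country-specific surface area.
    """
    species_by_unit: dict[tuple[str, str], set[str]] = defaultdict(set)
    for rec in records:
        entry = registry.lookup(rec.waterbody or "", rec.country)
        if entry is None:  # unreachable after stage 4/5
            raise RuntimeError(
                f"internal error: unregistered unit ({rec.waterbody}, {rec.country}) "
                "reached build_units"
            )
        species_by_unit[(entry.canonical_name, entry.country)].add(rec.species_name)
    units = [
        LakeCountryUnit(
            lake=lake,
            country=country,
            area_km2=registry.lookup(lake, country).area_km2,
            species=frozenset(species),
        )
        for (lake, country), species in species_by_unit.items()
    ]
    return sorted(units, key=lambda u: (u.country, u.lake))


def reports_to_frame(reports: Sequence[FilterReport]) -> pd.DataFrame:
    """Filter audit log as a table (one row per stage)."""
    return pd.DataFrame(
        {
            "stage_name": [r.stage_name for r in reports],
            "records_in": [r.records_in for r in reports],
            "records_out": [r.records_out for r in reports],
            "dropped": [r.dropped for r in reports],
            "dropped_reason": [r.dropped_reason for r in reports],
        }
    )
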