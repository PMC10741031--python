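"""The packaged in-house compound library of Chebulae Fructus constituents.

122 records transcribed from the reference ion table: identity, retention
time, negative-mode ion formula, observed m/z and mass error, measured and
predicted collision cross-sections, MS/MS fragment list and compound class
(3 other + 20 phenolcarboxylic acids + 28 gallotannins + 25 ellagitannins +
33 chebulic ellagitannins + 4 flavonoids + 9 triterpenoids).

The transcription is verbatim, including quirks of the printed table: two
distinct entries named "MN-18" (records 9 and 84), fragment values printed
at reduced precision, and two rows (8 and 96) whose printed ppm error is
internally inconsistent with their printed formula and observed mass (see
``INCONSISTENT_PPM_RECORDS``).  Absent CCS cells are stored as null.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from .chem_mass import ION_SPECIES, IonSpecies, ion_mz, ppm_error

__all__ = [
    "COMPOUND_CLASSES",
    "TANNIC_CLASSES",
    "INCONSISTENT_PPM_RECORDS",
    "LibraryRecord",
    "LibraryHit",
    "LibraryValidationError",
    "load_library",
    "library_to_csv",
    "library_from_csv",
    "search_precursor",
    "search_fragments",
    "class_partition",
]

COMPOUND_CLASSES = (
    "other",
    "phenolcarboxylic acid",
    "gallotannin",
    "ellagitannin",
    "chebulic ellagitannin",
    "flavonoid",
    "triterpenoid",
)

#: The four phenolcarboxylic/tannic classes (106 records).
TANNIC_CLASSES = (
    "phenolcarboxylic acid",
    "gallotannin",
    "ellagitannin",
    "chebulic ellagitannin",
)

#: Records whose printed ppm error contradicts their own printed formula and
#: observed mass by ~1-3 ppm (a defect of the source table, preserved
#: verbatim); excluded from ppm-recomputation consistency checks.
INCONSISTENT_PPM_RECORDS = frozenset({8, 96})


class LibraryValidationError(ValueError):
    """Raised when a library source fails schema or consistency validation."""


@dataclass(frozen=True)
class LibraryRecord:
    """One library entry (one row of the reference ion table)."""

    record_id: int
    name: str
    rt_min: float
    ion_formula: str
    species: str
    observed_mz: float
    mass_error_ppm: float
    fragments: tuple
    compound_class: str
    measured_ccs: Optional[float] = None
    predicted_ccs: Optional[float] = None
    identified_by_standard: bool = False

    @property
    def charge(self) -> int:
        return ION_SPECIES[self.species].charge_magnitude

    @property
    def theoretical_mz(self) -> float:
        """m/z recomputed from the tabulated ion formula."""
        return ion_mz(self.ion_formula, self.charge)

    @property
    def recomputed_ppm(self) -> float:
        return ppm_error(self.observed_mz, self.theoretical_mz)

    @property
    def is_tannic(self) -> bool:
        return self.compound_class in TANNIC_CLASSES


@dataclass(frozen=True)
class LibraryHit:
    """A ranked search hit."""

    record: LibraryRecord
    ppm_deviation: float
    rank: int
    shared_fragments: int = 0


def _validate(records: List[LibraryRecord]) -> None:
    seen: Dict[int, int] = {}
    for row, rec in enumerate(records, start=1):
        if rec.record_id in seen:
            raise LibraryValidationError(
                f"row {row}: duplicate record id {rec.record_id} (first at row {seen[rec.record_id]})"
            )
        seen[rec.record_id] = row
        if rec.compound_class not in COMPOUND_CLASSES:
            raise LibraryValidationError(
                f"row {row} (id {rec.record_id}): unknown class {rec.compound_class!r}"
            )
        if rec.rt_min <= 0:
            raise LibraryValidationError(
                f"row {row} (id {rec.record_id}): non-positive retention time"
            )
        if rec.species not in ION_SPECIES:
            raise LibraryValidationError(
                f"row {row} (id {rec.record_id}): unknown ion species {rec.species!r}"
            )
        if not rec.fragments:
            raise LibraryValidationError(
                f"row {row} (id {rec.record_id}): empty fragment list"
            )


def _record_from_json(item: dict) -> LibraryRecord:
    return LibraryRecord(
        record_id=int(item["id"]),
        name=str(item["name"]),
        rt_min=float(item["rt_min"]),
        ion_formula=str(item["ion_formula"]),
        species=str(item["species"]),
        observed_mz=float(item["observed_mz"]),
        mass_error_ppm=float(item["mass_error_ppm"]),
        measured_ccs=None if item.get("measured_ccs") is None else float(item["measured_ccs"]),
        predicted_ccs=None if item.get("predicted_ccs") is None else float(item["predicted_ccs"]),
        fragments=tuple(float(x) for x in item["fragments"]),
        compound_class=str(item["class"]),
        identified_by_standard=bool(item.get("standard", False)),
    )


def load_library(source: Optional[str | Path] = None) -> List[LibraryRecord]:
    """Load the library from JSON; the packaged fixture when ``source`` is None.

    Validation is strict: duplicate ids, unknown class labels or species,
    non-positive retention times and empty fragment lists are fatal, with
    row-level messages.
    """
    if source is None:
        text = resources.files("chebutools").joinpath("data/cf_library.json").read_text()
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"library file not found: {path}")
        text = path.read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise LibraryValidationError(f"library source is not valid JSON: {exc}") from exc
    raw = payload["records"] if isinstance(payload, dict) else payload
    records = [_record_from_json(item) for item in raw]
    _validate(records)
    return records


def class_partition(library: Sequence[LibraryRecord]) -> Dict[str, int]:
    """Record count per compound class."""
    counts: Dict[str, int] = {}
    for rec in library:
        counts[rec.compound_class] = counts.get(rec.compound_class, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# CSV flattening (fragments as a semicolon-joined field)
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "id", "name", "rt_min", "ion_formula", "species", "observed_mz",
    "mass_error_ppm", "measured_ccs", "predicted_ccs", "fragments", "class",
    "standard",
]


def library_to_csv(library: Sequence[LibraryRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for rec in library:
            writer.writerow({
                "id": rec.record_id,
                "name": rec.name,
                "rt_min": rec.rt_min,
                "ion_formula": rec.ion_formula,
                "species": rec.species,
                "observed_mz": rec.observed_mz,
                "mass_error_ppm": rec.mass_error_ppm,
                "measured_ccs": "" if rec.measured_ccs is None else rec.measured_ccs,
                "predicted_ccs": "" if rec.predicted_ccs is None else rec.predicted_ccs,
                "fragments": ";".join(repr(f) for f in rec.fragments),
                "class": rec.compound_class,
                "standard": int(rec.identified_by_standard),
            })


def library_from_csv(path: str | Path) -> List[LibraryRecord]:
    records: List[LibraryRecord] = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            records.append(LibraryRecord(
                record_id=int(row["id"]),
                name=row["name"],
                rt_min=float(row["rt_min"]),
                ion_formula=row["ion_formula"],
                species=row["species"],
                observed_mz=float(row["observed_mz"]),
                mass_error_ppm=float(row["mass_error_ppm"]),
                measured_ccs=float(row["measured_ccs"]) if row["measured_ccs"] else None,
                predicted_ccs=float(row["predicted_ccs"]) if row["predicted_ccs"] else None,
                fragments=tuple(float(x) for x in row["fragments"].split(";") if x),
                compound_class=row["class"],
                identified_by_standard=bool(int(row["standard"])),
            ))
    _validate(records)
    return records


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def search_precursor(
    mz: float,
    library: Sequence[LibraryRecord],
    tol_ppm: float = 10.0,
) -> List[LibraryHit]:
    """All records whose *observed* m/z matches within ``tol_ppm``.

    Ranked by absolute ppm deviation; ties broken by record id.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    matches = []
    for rec in library:
        dev = ppm_error(mz, rec.observed_mz)
        if abs(dev) <= tol_ppm:
            matches.append((abs(dev), rec.record_id, dev, rec))
    matches.sort(key=lambda item: (item[0], item[1]))
    return [
        LibraryHit(record=rec, ppm_deviation=dev, rank=rank)
        for rank, (_, _, dev, rec) in enumerate(matches, start=1)
    ]


def search_fragments(
    query_fragments: Sequence[float],
    library: Sequence[LibraryRecord],
    tol: float = 0.01,
    min_shared: int = 1,
    precursor_mz: Optional[float] = None,
) -> List[LibraryHit]:
    """Records sharing at least ``min_shared`` fragment m/z with the query.

    Ranked by shared-fragment count (descending), then by absolute precursor
    deviation when ``precursor_mz`` is given, then record id.
    """
    if not query_fragments:
        raise ValueError("query fragment list is empty")
    if tol <= 0:
        raise ValueError("tol must be positive")
    scored = []
    for rec in library:
        shared = sum(
            1 for q in query_fragments
            if any(abs(q - f) <= tol for f in rec.fragments)
        )
        if shared >= min_shared:
            dev = (
                ppm_error(precursor_mz, rec.observed_mz)
                if precursor_mz is not None else 0.0
            )
            scored.append((-shared, abs(dev), rec.record_id, shared, dev, rec))
    scored.sort(key=lambda item: (item[0], item[1], item[2]))
    return [
        LibraryHit(record=rec, ppm_deviation=dev, rank=rank, shared_fragments=shared)
        for rank, (_, _, _, shared, dev, rec) in enumerate(scored, start=1)
    ]
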