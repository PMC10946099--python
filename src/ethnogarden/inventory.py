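"""Domain model and CSV I/O for homegarden plant inventories.

The central object is the :class:`Inventory`: a validated collection of
:class:`PlantRecord` rows, one per species, carrying taxonomy, life form,
township occurrence, functional use categories, plant parts used and
(optionally) printed use-value (UV) and relative-importance (RI) scores.
Citation matrices (informant x species counts, the raw input to UV) and
graded land-class tables (the input to the land-use degree index La) have
their own light-weight containers.

Three CSV schemas are read and written here:

``inventory.csv``
    one row per species; set-valued cells (townships, use_categories,
    parts_used) are ``;``-separated.
``citations.csv``
    wide integer matrix, first column ``informant_id``, one column per
    species.
``landuse.csv``
    long format with columns region, class_name, grade, proportion; grades
    are integers 1-4 and proportions must sum to 1 per region.

The survey transcription packaged with this module
(:func:`load_laershan_fixture`) covers the 152 homegarden species recorded
in the three Miao townships of the Laershan Plateau (codes HK = Heku,
LL = Lianglin, LES = Laershan).
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    RecordValidationError,
    SchemaError,
    SpeciesNotFoundError,
)

__all__ = [
    "UseCategory",
    "LifeForm",
    "PlantRecord",
    "Inventory",
    "CitationMatrix",
    "LandUseTable",
    "ValidationReport",
    "STUDY_TOWNSHIPS",
    "derive_genus",
    "parse_inventory",
    "write_inventory",
    "validate_inventory_csv",
    "parse_citations",
    "write_citations",
    "parse_landuse",
    "write_landuse",
    "load_laershan_fixture",
]

#: Township occurrence codes used by the Laershan study area.
STUDY_TOWNSHIPS: tuple[str, ...] = ("HK", "LL", "LES")

_TOWNSHIP_ALIASES = {
    "hk": "HK", "heku": "HK",
    "ll": "LL", "lianglin": "LL",
    "les": "LES", "laershan": "LES",
}

_HYBRID_SIGNS = ("×", "x")  # multiplication sign, ascii fallback


class UseCategory(enum.Enum):
    """The five functional classes a homegarden species may serve.

    The classification is closed: every recorded use falls into exactly one
    of these classes, and a species may belong to several.
    """

    EDIBLE = "edible"
    TRADE = "trade"
    MEDICINE = "medicine"
    FORAGE = "forage"
    ORNAMENTAL = "ornamental"

    @classmethod
    def parse(cls, token: str) -> "UseCategory":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValueError(f"unknown use category {token!r}") from None


class LifeForm(enum.Enum):
    """Gross growth habit. 'vine' is accepted as a synonym of liana."""

    HERB = "herb"
    SHRUB = "shrub"
    TREE = "tree"
    LIANA = "liana"

    @classmethod
    def parse(cls, token: str) -> "LifeForm":
        t = token.strip().lower()
        if t == "vine":
            t = "liana"
        try:
            return cls(t)
        except ValueError:
            raise ValueError(f"unknown life form {token!r}") from None


def derive_genus(scientific_name: str) -> str:
    """Return the genus: the first whitespace token, hybrid sign stripped.

    Works for binomials, infraspecific names and named hybrids, e.g.
    ``"Paeonia × suffruticosa Andrews"`` -> ``"Paeonia"``. Idempotent.
    """
    if not scientific_name or not scientific_name.strip():
        raise ValueError("scientific_name must be non-empty")
    tokens = scientific_name.split()
    first = tokens[0]
    # a detached hybrid sign preceding the genus token
    if first in _HYBRID_SIGNS and len(tokens) > 1:
        first = tokens[1]
    return first.lstrip("×")


@dataclass(frozen=True)
class PlantRecord:
    """One inventory row: a species and everything the survey recorded about it.

    ``use_types`` — the finer-grained uses that drive the NT component of the
    relative-importance index — are derived, not stored: each distinct
    (use category, plant part) pair is one type, serialized ``category:part``.
    A record with no recorded parts (purely ornamental rows) contributes one
    type per category with an empty part slot.
    """

    voucher_code: str
    scientific_name: str
    local_name: str
    family: str
    life_form: LifeForm
    townships: frozenset[str]
    use_categories: frozenset[UseCategory]
    parts_used: frozenset[str] = frozenset()
    use_method: str = ""
    cultivated: bool = False
    uv: float | None = None
    ri: float | None = None

    def __post_init__(self) -> None:
        if not self.scientific_name.strip():
            raise ValueError("scientific_name must be non-empty")
        if not self.townships:
            raise ValueError(f"{self.scientific_name}: townships must be non-empty")
        if not self.use_categories:
            raise ValueError(f"{self.scientific_name}: use_categories must be non-empty")
        if self.uv is not None and not (self.uv >= 0):
            raise ValueError(f"{self.scientific_name}: uv must be >= 0, got {self.uv}")
        if self.ri is not None and not (0 < self.ri <= 2):
            raise ValueError(f"{self.scientific_name}: ri must lie in (0, 2], got {self.ri}")

    @property
    def genus(self) -> str:
        return derive_genus(self.scientific_name)

    @property
    def use_types(self) -> frozenset[str]:
        parts = self.parts_used or frozenset({""})
        return frozenset(
            f"{cat.value}:{part}" for cat in self.use_categories for part in parts
        )


@dataclass(frozen=True)
class Inventory:
    """A validated species inventory for one study area.

    Voucher codes and scientific names are unique; every summary and index
    in the package takes an Inventory as its unit of analysis.
    """

    records: tuple[PlantRecord, ...]
    study_area: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen_v: set[str] = set()
        seen_s: set[str] = set()
        for r in self.records:
            if r.voucher_code in seen_v:
                raise ValueError(f"duplicate voucher_code {r.voucher_code!r}")
            if r.scientific_name in seen_s:
                raise ValueError(f"duplicate scientific_name {r.scientific_name!r}")
            seen_v.add(r.voucher_code)
            seen_s.add(r.scientific_name)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PlantRecord]:
        return iter(self.records)

    def species_names(self) -> list[str]:
        return [r.scientific_name for r in self.records]

    def record(self, species: str) -> PlantRecord:
        for r in self.records:
            if r.scientific_name == species or r.voucher_code == species:
                return r
        raise SpeciesNotFoundError(species)

    def townships(self) -> list[str]:
        """All township codes present, study codes first, extras alphabetical."""
        present = {t for r in self.records for t in r.townships}
        ordered = [t for t in STUDY_TOWNSHIPS if t in present]
        ordered += sorted(present.difference(STUDY_TOWNSHIPS))
        return ordered

    def township_species_sets(self) -> dict[str, set[str]]:
        sets: dict[str, set[str]] = {t: set() for t in self.townships()}
        for r in self.records:
            for t in r.townships:
                sets[t].add(r.scientific_name)
        return sets

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voucher_code": r.voucher_code,
                "scientific_name": r.scientific_name,
                "genus": r.genus,
                "family": r.family,
                "life_form": r.life_form.value,
                "townships": ";".join(sorted(r.townships)),
                "use_categories": ";".join(
                    c.value for c in UseCategory if c in r.use_categories
                ),
                "n_use_types": len(r.use_types),
                "cultivated": r.cultivated,
                "uv": r.uv,
                "ri": r.ri,
            }
            for r in self.records
        )


@dataclass
class ValidationReport:
    """Row-level findings from reading a CSV: errors are fatal, warnings are not."""

    errors: list[tuple[int, str, str]] = field(default_factory=list)
    warnings: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def error(self, row: int, col: str, message: str) -> None:
        self.errors.append((row, col, message))

    def warn(self, row: int, col: str, message: str) -> None:
        self.warnings.append((row, col, message))

    def summary(self) -> str:
        lines = [f"row {r}, {c}: {m}" for r, c, m in self.errors]
        lines += [f"row {r}, {c}: {m} (warning)" for r, c, m in self.warnings]
        return "\n".join(lines) or "ok"


@dataclass(frozen=True)
class CitationMatrix:
    """Informant x species citation counts, the raw input to the UV index.

    ``counts[i, j]`` is the number of distinct uses informant ``i`` cited for
    species ``j``; ``n`` is the number of informants.
    """

    informants: tuple[str, ...]
    species: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.informants), len(self.species)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.informants)} informants x {len(self.species)} species"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("citation counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("citation counts must be non-negative")
        if len(set(self.informants)) != len(self.informants):
            raise ValueError("informant ids must be unique")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return len(self.informants)

    def column(self, species: str) -> np.ndarray:
        try:
            j = self.species.index(species)
        except ValueError:
            raise SpeciesNotFoundError(species) from None
        return self.counts[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.species))
        df.insert(0, "informant_id", list(self.informants))
        return df


@dataclass(frozen=True)
class LandUseTable:
    """Graded land-class composition of one region.

    ``classes`` holds (class_name, grade, proportion) triples; grades are the
    ordinal land-use degree levels 1 (unused) .. 4 (built-up) and proportions
    are area shares that must sum to 1.
    """

    region: str
    classes: tuple[tuple[str, int, float], ...]
    tol: float = 1e-6

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if not self.classes:
            raise ValueError(f"{self.region}: land-use table has no classes")
        for name, grade, prop in self.classes:
            if grade not in (1, 2, 3, 4):
                raise ValueError(f"{self.region}/{name}: grade must be 1..4, got {grade}")
            if not (0 <= prop <= 1):
                raise ValueError(f"{self.region}/{name}: proportion must lie in [0,1], got {prop}")
        total = math.fsum(p for _, _, p in self.classes)
        if abs(total - 1.0) > self.tol:
            raise ValueError(
                f"{self.region}: class proportions sum to {total:.6f}, expected 1"
            )

    @property
    def grades(self) -> np.ndarray:
        return np.array([g for _, g, _ in self.classes])

    @property
    def proportions(self) -> np.ndarray:
        return np.array([p for _, _, p in self.classes])


# ---------------------------------------------------------------------------
# CSV schemas

INVENTORY_COLUMNS = (
    "voucher_code",
    "scientific_name",
    "local_name",
    "family",
    "life_form",
    "townships",
    "use_categories",
    "parts_used",
    "use_method",
    "cultivated",
    "uv",
    "ri",
)

LANDUSE_COLUMNS = ("region", "class_name", "grade", "proportion")

_SET_SEP = ";"
_BOOL = {"true": True, "yes": True, "1": True, "false": False, "no": False, "0": False}


def _split_set(cell: str) -> list[str]:
    return [tok.strip() for tok in cell.split(_SET_SEP) if tok.strip()]


def _parse_float(cell: str) -> float | None:
    cell = cell.strip()
    return float(cell) if cell else None


def _read_inventory_rows(
    path: str | Path,
    township_codes: Sequence[str] | None,
) -> tuple[list[PlantRecord], ValidationReport]:
    path = Path(path)
    report = ValidationReport()
    records: list[PlantRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in INVENTORY_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        seen_vouchers: set[str] = set()
        seen_species: set[str] = set()
        for rownum, row in enumerate(reader, start=2):  # header is line 1
            ok = True

            def bad(colname: str, msg: str) -> None:
                nonlocal ok
                ok = False
                report.error(rownum, colname, msg)

            try:
                life = LifeForm.parse(row["life_form"])
            except ValueError as exc:
                bad("life_form", str(exc))
                life = None
            towns: set[str] = set()
            for tok in _split_set(row["townships"]):
                norm = _TOWNSHIP_ALIASES.get(tok.lower(), tok)
                if township_codes is not None and norm not in township_codes:
                    bad("townships", f"unknown township code {tok!r}")
                else:
                    towns.add(norm)
            if not towns and ok:
                bad("townships", "townships must be non-empty")
            cats: set[UseCategory] = set()
            for tok in _split_set(row["use_categories"]):
                try:
                    cats.add(UseCategory.parse(tok))
                except ValueError as exc:
                    bad("use_categories", str(exc))
            if not cats and ok:
                bad("use_categories", "use_categories must be non-empty")
            voucher = row["voucher_code"].strip()
            name = row["scientific_name"].strip()
            if not name:
                bad("scientific_name", "scientific_name must be non-empty")
            if voucher in seen_vouchers:
                bad("voucher_code", f"duplicate voucher_code {voucher!r}")
            if name and name in seen_species:
                bad("scientific_name", f"duplicate scientific_name {name!r}")
            cultivated_cell = row["cultivated"].strip().lower()
            if cultivated_cell not in _BOOL:
                bad("cultivated", f"cannot interpret {row['cultivated']!r} as boolean")
            uv = ri = None
            try:
                uv = _parse_float(row["uv"])
                if uv is not None and uv < 0:
                    bad("uv", f"uv must be >= 0, got {uv}")
            except ValueError:
                bad("uv", f"cannot parse {row['uv']!r}")
            try:
                ri = _parse_float(row["ri"])
                if ri is not None and not (0 < ri <= 2):
                    bad("ri", f"ri must lie in (0, 2], got {ri}")
            except ValueError:
                bad("ri", f"cannot parse {row['ri']!r}")
            if not ok:
                continue
            seen_vouchers.add(voucher)
            seen_species.add(name)
            records.append(
                PlantRecord(
                    voucher_code=voucher,
                    scientific_name=name,
                    local_name=row["local_name"].strip(),
                    family=row["family"].strip(),
                    life_form=life,
                    townships=frozenset(towns),
                    use_categories=frozenset(cats),
                    parts_used=frozenset(_split_set(row["parts_used"])),
                    use_method=row["use_method"],
                    cultivated=_BOOL[cultivated_cell],
                    uv=uv,
                    ri=ri,
                )
            )
    return records, report


def parse_inventory(
    path: str | Path,
    study_area: str = "",
    township_codes: Sequence[str] | None = STUDY_TOWNSHIPS,
) -> Inventory:
    """Read and validate an ``inventory.csv``.

    Township tokens are normalized to the study codes (full names accepted);
    pass ``township_codes=None`` to accept arbitrary codes (e.g. simulated
    multi-township designs). Raises :class:`SchemaError` for structural
    problems and :class:`RecordValidationError` (carrying the full report)
    if any row violates a domain invariant.
    """
    records, report = _read_inventory_rows(path, township_codes)
    if not report.is_valid:
        raise RecordValidationError(
            f"{path}: {len(report.errors)} invalid record(s):\n{report.summary()}",
            report=report,
        )
    return Inventory(records=tuple(records), study_area=study_area or str(path))


def validate_inventory_csv(
    path: str | Path,
    township_codes: Sequence[str] | None = STUDY_TOWNSHIPS,
) -> ValidationReport:
    """Like :func:`parse_inventory` but collect findings instead of raising."""
    try:
        _, report = _read_inventory_rows(path, township_codes)
    except SchemaError as exc:
        report = ValidationReport()
        report.error(1, "<header>", str(exc))
    return report


def write_inventory(inventory: Inventory, path: str | Path) -> None:
    """Write ``inventory.csv``; byte-stable: rows sorted by voucher code,
    uv/ri printed with 2 decimals."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(INVENTORY_COLUMNS)
        for r in sorted(inventory.records, key=lambda r: r.voucher_code):
            writer.writerow(
                [
                    r.voucher_code,
                    r.scientific_name,
                    r.local_name,
                    r.family,
                    r.life_form.value,
                    _SET_SEP.join(
                        [t for t in STUDY_TOWNSHIPS if t in r.townships]
                        + sorted(r.townships.difference(STUDY_TOWNSHIPS))
                    ),
                    _SET_SEP.join(c.value for c in UseCategory if c in r.use_categories),
                    _SET_SEP.join(sorted(r.parts_used)),
                    r.use_method,
                    "true" if r.cultivated else "false",
                    "" if r.uv is None else f"{r.uv:.2f}",
                    "" if r.ri is None else f"{r.ri:.2f}",
                ]
            )


def parse_citations(path: str | Path) -> CitationMatrix:
    """Read a wide ``citations.csv`` (first column ``informant_id``)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), None)
    if not header or header[0] != "informant_id":
        raise SchemaError(f"{path}: first column must be 'informant_id'")
    species = header[1:]
    if len(set(species)) != len(species):
        dupes = sorted({s for s in species if species.count(s) > 1})
        raise SchemaError(f"{path}: duplicate species column(s): {', '.join(dupes)}")
    df = pd.read_csv(path, dtype={"informant_id": str})
    df.columns = header  # undo pandas' mangling of any duplicate-free header
    counts = df[species].to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.isnan(counts).any():
        raise RecordValidationError(f"{path}: citation cells must be integers")
    if np.any(np.mod(counts, 1) != 0):
        raise RecordValidationError(f"{path}: citation cells must be integers")
    counts = counts.astype(np.int64)
    if (counts < 0).any():
        rows = sorted(set((np.where(counts < 0)[0] + 2).tolist()))
        raise RecordValidationError(
            f"{path}: negative citation count(s) at row(s) {rows}"
        )
    return CitationMatrix(
        informants=tuple(df["informant_id"].astype(str)),
        species=tuple(species),
        counts=counts,
    )


def write_citations(matrix: CitationMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, index=False)


def parse_landuse(path: str | Path, tol: float = 1e-6) -> dict[str, LandUseTable]:
    """Read ``landuse.csv`` into one validated :class:`LandUseTable` per region."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in LANDUSE_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        grouped: dict[str, list[tuple[str, int, float]]] = {}
        for rownum, row in enumerate(reader, start=2):
            try:
                grade = int(row["grade"])
                prop = float(row["proportion"])
            except ValueError as exc:
                raise RecordValidationError(f"{path} row {rownum}: {exc}") from None
            grouped.setdefault(row["region"].strip(), []).append(
                (row["class_name"].strip(), grade, prop)
            )
    tables = {}
    for region, classes in grouped.items():
        try:
            tables[region] = LandUseTable(region=region, classes=tuple(classes), tol=tol)
        except ValueError as exc:
            raise RecordValidationError(f"{path}: {exc}") from None
    return tables


def write_landuse(tables: Mapping[str, LandUseTable] | Iterable[LandUseTable], path: str | Path) -> None:
    if isinstance(tables, Mapping):
        tables = tables.values()
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LANDUSE_COLUMNS)
        for t in tables:
            for name, grade, prop in t.classes:
                writer.writerow([t.region, name, grade, repr(prop)])


_FIXTURE_NAME = "laershan_inventory.csv"
_FIXTURE_N_SPECIES = 152


def load_laershan_fixture() -> Inventory:
    """The packaged Laershan Plateau homegarden survey: 152 species across
    the Heku (HK), Lianglin (LL) and Laershan (LES) townships, with the
    printed UV and RI scores."""
    ref = resources.files("ethnogarden.data").joinpath(_FIXTURE_NAME)
    with resources.as_file(ref) as p:
        inv = parse_inventory(p, study_area="Laershan Plateau")
    if len(inv) != _FIXTURE_N_SPECIES:
        raise RecordValidationError(
            f"packaged fixture is corrupted: expected {_FIXTURE_N_SPECIES} records, "
            f"found {len(inv)}"
        )
    return inv
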