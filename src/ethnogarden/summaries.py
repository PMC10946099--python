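"""Descriptive summaries of a homegarden inventory.

Everything here is a deterministic recount of the inventory: taxonomic
richness (species / genera / families), the life-form spectrum, family
frequency ranking, per-category species tallies, the 31-region Venn
partition of species over the five use categories, and value-based
rankings and threshold counts on the stored UV/RI columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

from ._rounding import round_half_up
from .errors import ScoringError
from .inventory import Inventory, LifeForm, UseCategory

__all__ = [
    "TaxonomicSummary",
    "LifeFormSpectrum",
    "VennPartition",
    "RankedList",
    "ThresholdResult",
    "taxonomic_summary",
    "life_form_spectrum",
    "family_richness",
    "use_category_tally",
    "multifunctionality_partition",
    "rank_species",
    "count_above_threshold",
    "subset_key",
]

_CATEGORY_ORDER = tuple(UseCategory)


@dataclass(frozen=True)
class TaxonomicSummary:
    n_species: int
    n_genera: int
    n_families: int


@dataclass(frozen=True)
class LifeFormSpectrum:
    counts: dict[LifeForm, int]
    percentages: dict[LifeForm, float]  # half-up, 1 decimal

    @property
    def n_species(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class VennPartition:
    """Exact partition of species over the 31 non-empty category subsets."""

    region_counts: dict[frozenset[UseCategory], int]
    region_species: dict[frozenset[UseCategory], tuple[str, ...]]

    @property
    def all_five(self) -> tuple[str, ...]:
        return self.region_species[frozenset(UseCategory)]

    @property
    def n_species(self) -> int:
        return sum(self.region_counts.values())

    def category_tally(self) -> dict[UseCategory, int]:
        """Per-category species counts recovered from the partition."""
        tally = {c: 0 for c in UseCategory}
        for subset, count in self.region_counts.items():
            for cat in subset:
                tally[cat] += count
        return tally


@dataclass(frozen=True)
class RankedList:
    criterion: str
    entries: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class ThresholdResult:
    criterion: str
    threshold: float
    species: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.species)


def taxonomic_summary(inventory: Inventory) -> TaxonomicSummary:
    """Distinct species, genus and family counts."""
    return TaxonomicSummary(
        n_species=len(inventory),
        n_genera=len({r.genus for r in inventory}),
        n_families=len({r.family for r in inventory}),
    )


def life_form_spectrum(inventory: Inventory) -> LifeFormSpectrum:
    """Counts and half-up 1-decimal percentages per life form."""
    counts = Counter(r.life_form for r in inventory)
    full = {lf: counts.get(lf, 0) for lf in LifeForm}
    total = len(inventory)
    pct = {
        lf: round_half_up(100.0 * n / total, 1) if total else 0.0
        for lf, n in full.items()
    }
    return LifeFormSpectrum(counts=full, percentages=pct)


def family_richness(inventory: Inventory) -> list[tuple[str, int]]:
    """Families by descending species count, ties broken alphabetically."""
    counts = Counter(r.family for r in inventory)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def use_category_tally(inventory: Inventory) -> dict[UseCategory, int]:
    """Number of species whose use set contains each category."""
    tally = {c: 0 for c in UseCategory}
    for r in inventory:
        for c in r.use_categories:
            tally[c] += 1
    return tally


def subset_key(subset: frozenset[UseCategory]) -> str:
    """Stable label for a category subset, e.g. ``"edible+trade"``."""
    return "+".join(c.value for c in _CATEGORY_ORDER if c in subset)


def multifunctionality_partition(inventory: Inventory) -> VennPartition:
    """Assign every species to the Venn region given by its exact category set.

    All 31 non-empty subsets of the five categories are present as keys
    (unpopulated regions with count 0), so region counts always sum to the
    number of species.
    """
    regions: dict[frozenset[UseCategory], list[str]] = {}
    for size in range(1, len(_CATEGORY_ORDER) + 1):
        for combo in combinations(_CATEGORY_ORDER, size):
            regions[frozenset(combo)] = []
    for r in inventory:
        regions[frozenset(r.use_categories)].append(r.scientific_name)
    return VennPartition(
        region_counts={k: len(v) for k, v in regions.items()},
        region_species={k: tuple(sorted(v)) for k, v in regions.items()},
    )


def _criterion_values(inventory: Inventory, criterion: str) -> list[tuple[str, float]]:
    if criterion not in ("uv", "ri"):
        raise ValueError(f"criterion must be 'uv' or 'ri', got {criterion!r}")
    missing = [r.scientific_name for r in inventory
               if getattr(r, criterion) is None]
    if missing:
        raise ScoringError(
            f"{criterion} missing for {len(missing)} species: "
            + ", ".join(missing[:5])
            + ("..." if len(missing) > 5 else "")
        )
    return [(r.scientific_name, float(getattr(r, criterion))) for r in inventory]


def rank_species(inventory: Inventory, criterion: str, k: int | None = None) -> RankedList:
    """Top-``k`` species by stored UV or RI, descending; ties at the cut are
    all included (so the list may exceed ``k``). ``k=None`` ranks everything."""
    values = sorted(_criterion_values(inventory, criterion),
                    key=lambda sv: (-sv[1], sv[0]))
    if k is not None and 0 <= k < len(values):
        cutoff = values[k - 1][1] if k > 0 else None
        values = [sv for i, sv in enumerate(values) if i < k or (cutoff is not None and sv[1] == cutoff)]
    return RankedList(criterion=criterion, entries=tuple(values))


def count_above_threshold(
    inventory: Inventory, criterion: str, threshold: float
) -> ThresholdResult:
    """Species whose stored UV/RI strictly exceeds ``threshold``."""
    qualifying = sorted(
        s for s, v in _criterion_values(inventory, criterion) if v > threshold
    )
    return ThresholdResult(criterion=criterion, threshold=threshold,
                           species=tuple(qualifying))
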