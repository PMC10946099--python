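"""Quantitative ethnobotany indices.

Five statistics are implemented, each in its conventional form:

* **Use value** ``UV = sum_i(U_i) / n`` — mean citation frequency of a
  species over the ``n`` informants; unbounded above, 0 when never cited.
* **Relative importance** ``RI = NUC + NT`` — the species' use-category
  count and use-type count, each normalized by the corresponding inventory
  maximum. By construction at least one species has NUC = 1 and at least one
  has NT = 1, and RI = 2 exactly when one species attains both maxima.
* **Jaccard similarity** ``JI = c / (a + b - c) * 100`` between two species
  sets of sizes ``a`` and ``b`` sharing ``c`` species; reported on the
  0-100 scale.
* **Comprehensive land-use degree** ``La = 100 * sum_i(A_i * C_i)`` over
  land classes with ordinal grade ``A_i`` in 1..4 and area share ``C_i``;
  ranges from 100 (all unused land) to 400 (fully built-up).
* **Shannon-Wiener diversity** ``H' = -sum_i(p_i ln p_i)``, natural log.

Raw (unrounded) values are kept on the result objects; the printing
conventions of survey tables (1 decimal for JI, 2 for the others) are
applied only via each result's ``rounded`` property.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rounding import round_half_up
from .errors import InternalConsistencyError, ScoringError, SpeciesNotFoundError
from .inventory import CitationMatrix, Inventory, LandUseTable

__all__ = [
    "UVResult",
    "RIResult",
    "SimilarityResult",
    "LandUseResult",
    "DiversityResult",
    "use_value",
    "use_value_table",
    "relative_importance",
    "relative_importance_table",
    "jaccard_index",
    "jaccard_matrix",
    "shannon_wiener",
    "land_use_degree",
    "landuse_from_proportions",
    "DEFAULT_GRADE_MAP",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UVResult:
    species: str
    uv: float
    total_citations: int
    n: int

    @property
    def rounded(self) -> float:
        return round_half_up(self.uv, 2)


@dataclass(frozen=True)
class RIResult:
    species: str
    nuc: float
    nt: float

    @property
    def ri(self) -> float:
        return self.nuc + self.nt

    @property
    def rounded(self) -> float:
        return round_half_up(self.ri, 2)


@dataclass(frozen=True)
class SimilarityResult:
    group_a: str
    group_b: str
    a: int
    b: int
    c: int

    @property
    def ji(self) -> float:
        return self.c / (self.a + self.b - self.c) * 100.0

    @property
    def rounded(self) -> float:
        return round_half_up(self.ji, 1)


@dataclass(frozen=True)
class LandUseResult:
    region: str
    la: float

    @property
    def rounded(self) -> float:
        return round_half_up(self.la, 2)


@dataclass(frozen=True)
class DiversityResult:
    label: str
    shannon_h: float
    richness: int

    @property
    def rounded(self) -> float:
        return round_half_up(self.shannon_h, 2)


def use_value(citations: CitationMatrix, species: str) -> UVResult:
    """UV of one species: its citation-column sum divided by informant count."""
    if citations.n < 1:
        raise ValueError("use_value requires at least one informant")
    column = citations.column(species)  # raises SpeciesNotFoundError
    total = int(column.sum())
    return UVResult(species=species, uv=total / citations.n,
                    total_citations=total, n=citations.n)


def use_value_table(citations: CitationMatrix) -> pd.DataFrame:
    """UV for every species, as a DataFrame sorted by descending UV."""
    if citations.n < 1:
        raise ValueError("use_value_table requires at least one informant")
    totals = citations.counts.sum(axis=0)
    df = pd.DataFrame(
        {
            "species": list(citations.species),
            "total_citations": totals,
            "n": citations.n,
            "uv": totals / citations.n,
        }
    )
    return df.sort_values(["uv", "species"], ascending=[False, True], ignore_index=True)


def _type_and_category_maxima(inventory: Inventory) -> tuple[int, int]:
    max_cats = max(len(r.use_categories) for r in inventory)
    max_types = max(len(r.use_types) for r in inventory)
    if max_types == 0:
        raise ScoringError(
            "inventory has no use types; encode them as category:part pairs "
            "(records need non-empty use_categories, and parts_used where known)"
        )
    return max_cats, max_types


def relative_importance(inventory: Inventory, species: str) -> RIResult:
    """RI = NUC + NT for one species, normalized by the inventory maxima."""
    record = inventory.record(species)
    max_cats, max_types = _type_and_category_maxima(inventory)
    return RIResult(
        species=record.scientific_name,
        nuc=len(record.use_categories) / max_cats,
        nt=len(record.use_types) / max_types,
    )


def relative_importance_table(inventory: Inventory) -> pd.DataFrame:
    """RI for every species, sorted by descending RI."""
    max_cats, max_types = _type_and_category_maxima(inventory)
    df = pd.DataFrame(
        {
            "species": [r.scientific_name for r in inventory],
            "n_categories": [len(r.use_categories) for r in inventory],
            "n_types": [len(r.use_types) for r in inventory],
        }
    )
    df["nuc"] = df["n_categories"] / max_cats
    df["nt"] = df["n_types"] / max_types
    df["ri"] = df["nuc"] + df["nt"]
    return df.sort_values(["ri", "species"], ascending=[False, True], ignore_index=True)


def jaccard_index(
    set_a: Iterable[str],
    set_b: Iterable[str],
    label_a: str = "A",
    label_b: str = "B",
) -> SimilarityResult:
    """Jaccard similarity (x100) between two non-empty species sets."""
    sa, sb = set(set_a), set(set_b)
    if not sa or not sb:
        raise ValueError("jaccard_index requires two non-empty species sets")
    c = len(sa & sb)
    return SimilarityResult(group_a=label_a, group_b=label_b, a=len(sa), b=len(sb), c=c)


def jaccard_matrix(
    inventory: Inventory,
    grouping: str = "township",
) -> tuple[pd.DataFrame, list[SimilarityResult]]:
    """Pairwise JI between the species sets of every township.

    Returns the square similarity matrix (diagonal 100) and the list of
    off-diagonal pair results. Townships with zero species are excluded with
    a logged warning; at least two non-empty groups are required.
    """
    if grouping != "township":
        raise ValueError(f"unsupported grouping {grouping!r}")
    sets = inventory.township_species_sets()
    empty = [g for g, s in sets.items() if not s]
    for g in empty:
        logger.warning("excluding township %s: no species recorded", g)
        del sets[g]
    groups = list(sets)
    if len(groups) < 2:
        raise ValueError("jaccard_matrix requires at least two non-empty townships")
    matrix = pd.DataFrame(100.0, index=groups, columns=groups)
    pairs: list[SimilarityResult] = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            res = jaccard_index(sets[ga], sets[gb], label_a=ga, label_b=gb)
            matrix.loc[ga, gb] = matrix.loc[gb, ga] = res.ji
            pairs.append(res)
    return matrix, pairs


def shannon_wiener(
    abundances: Sequence[float] | np.ndarray,
    label: str = "",
) -> DiversityResult:
    """Shannon-Wiener H' of a count or proportion vector (natural log).

    Entries are normalized to proportions; zero entries contribute nothing.
    """
    arr = np.asarray(abundances, dtype=float)
    if arr.ndim != 1:
        raise ValueError("abundances must be one-dimensional")
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    if not (arr > 0).any():
        raise ValueError("shannon_wiener requires at least one positive abundance")
    # scipy normalizes and applies the -sum(p ln p) convention for us
    h = float(stats.entropy(arr))
    return DiversityResult(label=label, shannon_h=h, richness=int((arr > 0).sum()))


#: Default land-use degree grades: 1 unused/bare land, 2 forest/grass/water,
#: 3 agricultural land, 4 built-up surfaces. Override per class via
#: :func:`landuse_from_proportions` for alternative grading schemes.
DEFAULT_GRADE_MAP: dict[str, int] = {
    "unused": 1,
    "bare": 1,
    "forest": 2,
    "grassland": 2,
    "water": 2,
    "cropland": 3,
    "orchard": 3,
    "built": 4,
    "artificial": 4,
}


def landuse_from_proportions(
    region: str,
    proportions: Mapping[str, float],
    grade_map: Mapping[str, int] | None = None,
) -> LandUseTable:
    """Build a graded :class:`LandUseTable` from bare area proportions.

    Each class name is looked up in ``grade_map`` (default
    :data:`DEFAULT_GRADE_MAP`); unknown class names raise ``KeyError`` so a
    silent mis-grading cannot occur.
    """
    mapping = DEFAULT_GRADE_MAP if grade_map is None else grade_map
    classes = []
    for name, prop in proportions.items():
        if name not in mapping:
            raise KeyError(
                f"no land-use grade defined for class {name!r}; "
                f"supply a grade_map entry"
            )
        classes.append((name, int(mapping[name]), float(prop)))
    return LandUseTable(region=region, classes=tuple(classes))


def land_use_degree(table: LandUseTable) -> LandUseResult:
    """La = 100 * sum(A_i * C_i); guaranteed to lie in [100, 400]."""
    la = 100.0 * float(np.dot(table.grades, table.proportions))
    if not (100.0 - 1e-9 <= la <= 400.0 + 1e-9):
        raise InternalConsistencyError(
            f"{table.region}: computed La={la} outside [100, 400]"
        )
    return LandUseResult(region=table.region, la=min(max(la, 100.0), 400.0))
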