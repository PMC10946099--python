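"""Flat-file export of summaries and index tables (CSV + JSON).

Rounding happens here, at the reporting layer only: JI to 1 decimal, UV, RI
and H' to 2, La to 2. The in-memory result objects keep full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._rounding import round_half_up
from .indices import (
    jaccard_matrix,
    land_use_degree,
    relative_importance_table,
    use_value_table,
)
from .inventory import CitationMatrix, Inventory, LandUseTable, UseCategory
from .summaries import (
    count_above_threshold,
    family_richness,
    life_form_spectrum,
    multifunctionality_partition,
    rank_species,
    subset_key,
    taxonomic_summary,
    use_category_tally,
)

__all__ = ["write_summary_report", "write_index_report"]


def write_summary_report(
    inventory: Inventory,
    outdir: str | Path,
    threshold: float | None = None,
) -> dict:
    """Write the descriptive summaries of ``inventory`` into ``outdir``.

    Emits ``summary.json`` plus one CSV per table (life-form spectrum,
    family richness, category tally, 31-row Venn partition) and returns the
    JSON payload as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tax = taxonomic_summary(inventory)
    spectrum = life_form_spectrum(inventory)
    families = family_richness(inventory)
    tally = use_category_tally(inventory)
    venn = multifunctionality_partition(inventory)

    pd.DataFrame(
        {
            "life_form": [lf.value for lf in spectrum.counts],
            "count": list(spectrum.counts.values()),
            "percent": list(spectrum.percentages.values()),
        }
    ).to_csv(outdir / "life_form_spectrum.csv", index=False)
    pd.DataFrame(families, columns=["family", "n_species"]).to_csv(
        outdir / "family_richness.csv", index=False
    )
    pd.DataFrame(
        {"use_category": [c.value for c in tally], "n_species": list(tally.values())}
    ).to_csv(outdir / "use_category_tally.csv", index=False)
    pd.DataFrame(
        [
            {
                "categories": subset_key(subset),
                "n_categories": len(subset),
                "n_species": venn.region_counts[subset],
                "species": ";".join(venn.region_species[subset]),
            }
            for subset in sorted(
                venn.region_counts, key=lambda s: (len(s), subset_key(s))
            )
        ]
    ).to_csv(outdir / "venn_partition.csv", index=False)

    payload: dict = {
        "study_area": inventory.study_area,
        "n_species": tax.n_species,
        "n_genera": tax.n_genera,
        "n_families": tax.n_families,
        "life_form_percent": {
            lf.value: spectrum.percentages[lf] for lf in spectrum.counts
        },
        "use_category_tally": {c.value: n for c, n in tally.items()},
        "edible_and_trade_intersection": sum(
            1
            for r in inventory
            if {UseCategory.EDIBLE, UseCategory.TRADE} <= r.use_categories
        ),
        "edible_or_trade_union": sum(
            1
            for r in inventory
            if {UseCategory.EDIBLE, UseCategory.TRADE} & r.use_categories
        ),
        "all_five_species": list(venn.all_five),
    }
    for crit in ("uv", "ri"):
        try:
            ranked = rank_species(inventory, crit, k=10)
        except Exception:  # stored value column absent: ranking is optional
            continue
        payload[f"{crit}_ranking"] = [
            {"species": s, crit: v} for s, v in ranked.entries
        ]
    if threshold is not None and len(inventory):
        try:
            above = count_above_threshold(inventory, "ri", threshold)
            payload["ri_above_threshold"] = {
                "threshold": threshold,
                "count": above.count,
                "species": list(above.species),
            }
        except Exception:  # stored RI column absent: skip, not fatal
            pass
    (outdir / "summary.json").write_text(
        json.dumps(payload, indent=2) + "\n", encoding="utf-8"
    )
    return payload


def write_index_report(
    inventory: Inventory,
    outdir: str | Path,
    citations: CitationMatrix | None = None,
    landuse: Mapping[str, LandUseTable] | None = None,
    top_k: int = 10,
) -> dict:
    """Write the index tables: JI matrix (always), RI table (always),
    UV table (if a citation matrix is given), La table (if land-use tables
    are given). Returns a JSON-ready payload, also written to
    ``indices.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload: dict = {"study_area": inventory.study_area}

    matrix, pairs = jaccard_matrix(inventory)
    matrix.round(1).to_csv(outdir / "ji_matrix.csv", index_label="township")
    pd.DataFrame(
        [
            {
                "group_a": p.group_a,
                "group_b": p.group_b,
                "a": p.a,
                "b": p.b,
                "c": p.c,
                "ji": p.rounded,
            }
            for p in pairs
        ]
    ).to_csv(outdir / "ji_pairs.csv", index=False)
    payload["ji"] = {f"{p.group_a}|{p.group_b}": p.rounded for p in pairs}

    ri = relative_importance_table(inventory)
    ri_out = ri.copy()
    ri_out["ri"] = ri_out["ri"].map(lambda v: round_half_up(v, 2))
    ri_out.to_csv(outdir / "ri_table.csv", index=False)
    payload["ri_max"] = round_half_up(float(ri["ri"].max()), 2)
    payload["ri_top"] = [
        {"species": s, "ri": round_half_up(v, 2)}
        for s, v in zip(ri["species"].head(top_k), ri["ri"].head(top_k))
    ]

    if citations is not None:
        uv = use_value_table(citations)
        uv_out = uv.copy()
        uv_out["uv"] = uv_out["uv"].map(lambda v: round_half_up(v, 2))
        uv_out.to_csv(outdir / "uv_table.csv", index=False)
        payload["uv_top"] = [
            {"species": s, "uv": round_half_up(v, 2)}
            for s, v in zip(uv["species"].head(top_k), uv["uv"].head(top_k))
        ]

    if landuse is not None:
        results = [land_use_degree(t) for t in landuse.values()]
        pd.DataFrame(
            {"region": [r.region for r in results], "la": [r.rounded for r in results]}
        ).to_csv(outdir / "la_table.csv", index=False)
        payload["la"] = {r.region: r.rounded for r in results}

    (outdir / "indices.json").write_text(
        json.dumps(payload, indent=2) + "\n", encoding="utf-8"
    )
    return payload
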