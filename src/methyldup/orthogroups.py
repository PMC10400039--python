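"""Orthogroup categorization by phylogenetic breadth and copy number.

Core orthogroups are present in at least a configurable fraction of the
species panel (default 0.879, i.e. 51 of 58 species, tolerating missing
annotations); core groups are split into single-copy (single gene in
>= 70% of species) vs multicopy. Non-core groups are ranked by increasing
lineage specificity: cross-family, family-specific, species/lineage-
specific. Within core single-copy groups, each species' genes are flagged
SC-singleton (exactly one copy) or SC-intermediate (still duplicated).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

CATEGORIES = (
    "core:single-copy",
    "core:multicopy",
    "cross-family",
    "family-specific",
    "species-specific",
)

OGTable = Mapping[str, Mapping[str, Sequence[str]]]


def core_min_species(n_species: int, core_fraction: float = 0.879) -> int:
    """Smallest species count qualifying as core (ceil of the fraction)."""
    return math.ceil(core_fraction * n_species)


def categorize(
    table: OGTable,
    species_family: Mapping[str, str],
    core_min: int | None = None,
    core_fraction: float = 0.879,
    sc_fraction: float = 0.70,
    sc_denominator: str = "present",
) -> pd.DataFrame:
    """Assign each orthogroup one category.

    ``sc_denominator`` sets the base of the single-copy fraction:
    ``present`` (default) uses species in which the group occurs; ``all``
    uses the whole panel.
    """
    n_species = len(set(species_family))
    if core_min is None:
        core_min = core_min_species(n_species, core_fraction)
    rows = []
    for og_id, members in table.items():
        present = [sp for sp, genes in members.items() if genes]
        for sp in present:
            if sp not in species_family:
                raise KeyError(f"species {sp} missing from family map")
        families = {species_family[sp] for sp in present}
        n_present = len(present)
        n_single = sum(1 for sp in present if len(members[sp]) == 1)
        denom = n_present if sc_denominator == "present" else n_species
        if n_present >= core_min:
            single_frac = n_single / denom if denom else 0.0
            cat = "core:single-copy" if single_frac >= sc_fraction else "core:multicopy"
        elif n_present == 1:
            cat = "species-specific"
        elif len(families) == 1:
            cat = "family-specific"
        else:
            cat = "cross-family"
        rows.append(
            {
                "og_id": og_id,
                "n_species": n_present,
                "n_families": len(families),
                "n_single_copy_species": n_single,
                "category": cat,
            }
        )
    return pd.DataFrame(rows).set_index("og_id")


def add_singleton_pseudo_ogs(
    table: OGTable, genes_by_species: Mapping[str, Sequence[str]]
) -> dict[str, dict[str, list[str]]]:
    """Wrap genes absent from every orthogroup into species-specific
    single-gene pseudo-orthogroups."""
    assigned = {
        g for members in table.values() for genes in members.values() for g in genes
    }
    out = {og: {sp: list(genes) for sp, genes in members.items()} for og, members in table.items()}
    i = 0
    for sp, genes in genes_by_species.items():
        for g in genes:
            if g not in assigned:
                out[f"SINGLETON{i:07d}"] = {sp: [g]}
                i += 1
    return out


def sc_status(categories: pd.DataFrame, table: OGTable) -> pd.DataFrame:
    """Per-gene SC-singleton / SC-intermediate flags.

    Only genes of core:single-copy orthogroups are eligible: a species
    with exactly one copy yields an SC-singleton, a species that retained
    several copies yields SC-intermediates.
    """
    rows = []
    sc_ogs = set(categories.index[categories["category"] == "core:single-copy"])
    for og_id, members in table.items():
        if og_id not in sc_ogs:
            continue
        for sp, genes in members.items():
            status = "SC-singleton" if len(genes) == 1 else "SC-intermediate"
            for g in genes:
                rows.append(
                    {"gene_id": g, "species": sp, "og_id": og_id, "status": status}
                )
    return pd.DataFrame(rows, columns=["gene_id", "species", "og_id", "status"])
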