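"""Published headline counts used as inputs for count arithmetic.

These integers are the publicly reported totals of the source
databases: The Plant List (accepted seed-plant names), the GloNAF
naturalized-flora database, the WEP economic-plant catalogue, and the
WCSP checklist used to extrapolate per-continent richness.  They are
inputs, not results: every percentage or ratio derived from them is
computed at run time by :func:`econatur.core.summarize_counts` and the
helpers below.
"""

from __future__ import annotations

from .core import CategoryCount, CountsSummary, Taxon, TaxonTable, USE_CATEGORIES

__all__ = [
    "GLOBAL_FLORA_N",
    "NATURALIZED_N",
    "ECONOMIC_N",
    "ECON_NATURALIZED_N",
    "WCSP_KNOWN_ORIGINS_N",
    "GLONAF_REGIONS_N",
    "WEP_CATEGORY_COUNTS",
    "headline_summary",
    "category_summary",
    "single_use_category_table",
]

#: Accepted seed-plant taxa in The Plant List.
GLOBAL_FLORA_N = 326_101
#: Taxa recorded as naturalized somewhere in GloNAF (seed plants with
#: accepted names).
NATURALIZED_N = 12_013
#: Taxa with at least one economic use in the WEP catalogue.
ECONOMIC_N = 11_685
#: Overlap: economic taxa that are naturalized.
ECON_NATURALIZED_N = 4_792
#: Species with known native origins in the WCSP checklist (basis of
#: the continental-richness extrapolation).
WCSP_KNOWN_ORIGINS_N = 130_641
#: Number of GloNAF regions.
GLONAF_REGIONS_N = 861

#: Per-category (n, n_naturalized) pairs of the WEP catalogue.
WEP_CATEGORY_COUNTS: dict[str, tuple[int, int]] = {
    "animal_food": (836, 580),
    "bee_plants": (202, 149),
    "environmental": (5666, 3139),
    "food_additives": (462, 282),
    "fuels": (206, 130),
    "gene_sources": (2758, 757),
    "human_food": (1360, 757),
    "invertebrate_food": (41, 28),
    "materials": (2190, 906),
    "medicines": (3104, 1621),
    "nonvertebrate_poisons": (44, 32),
    "social": (128, 66),
}


def headline_summary() -> CountsSummary:
    """Global overlap counts as a :class:`CountsSummary`.

    Per-category counts are attached from :data:`WEP_CATEGORY_COUNTS`;
    the headline totals are the published database sizes.
    """
    return CountsSummary(
        n_total=GLOBAL_FLORA_N,
        n_econ=ECONOMIC_N,
        n_naturalized=NATURALIZED_N,
        n_econ_naturalized=ECON_NATURALIZED_N,
        per_category={
            c: CategoryCount(*WEP_CATEGORY_COUNTS[c]) for c in USE_CATEGORIES
        },
    )


def category_summary() -> dict[str, CategoryCount]:
    return {c: CategoryCount(*WEP_CATEGORY_COUNTS[c]) for c in USE_CATEGORIES}


def single_use_category_table() -> TaxonTable:
    """A flora realizing the per-category counts with single-use taxa.

    Each category contributes exactly its published (n, naturalized)
    pair; every synthetic taxon carries a single use, so category
    memberships do not overlap.  This is the reference pool for
    category-level resampling arithmetic; it is synthetic in the sense
    that taxon identities (and the multi-use structure of the real
    catalogue) are not reproduced, only the per-category margins.
    """
    rows = []
    i = 0
    for c in USE_CATEGORIES:
        n, k = WEP_CATEGORY_COUNTS[c]
        for j in range(n):
            nat = j < k
            rows.append(
                Taxon(
                    taxon_id=f"w{i:05d}",
                    name=f"Synthflora taxon{i:05d}",
                    genus=f"Synthgen{c[:6]}",
                    family=f"Synthfam{c[:6]}",
                    uses=frozenset({c}),
                    naturalized=nat,
                    n_regions=1 if nat else 0,
                )
            )
            i += 1
    return TaxonTable(rows=rows, provenance="single-use category margins")
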