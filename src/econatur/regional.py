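"""Region-level summaries and the latitude model.

Each regional naturalized flora is summarized by its size, its share
of taxa with at least one economic use, and its dominant use category.
The latitude model is a quasi-binomial GLM of the economic share
(weighted by flora size) on absolute latitude, island status and their
interaction.  Taxa whose economic status is unknown do not occur in
validated tables; taxa with an empty use set count as non-economic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import USE_CATEGORIES, RegionSet, TaxonTable, ValidationError
from .stats import RegressionResult, fit_binomial_glm

__all__ = [
    "RegionalSummary",
    "regional_summaries",
    "fit_latitude_model",
    "region_count_medians",
]


@dataclass(frozen=True)
class RegionalSummary:
    region_id: str
    n_naturalized: int
    n_econ: int
    prop_econ: float
    latitude: float
    island: bool
    dominant_use: tuple  # all tied top categories, in fixed category order


def regional_summaries(
    regions: RegionSet, table: TaxonTable
) -> tuple[list[RegionalSummary], dict]:
    """Per-region economic shares plus global aggregates.

    Aggregates: the global share of naturalized taxa with an economic
    use, the median regional share, and the number of regions at or
    below the global share.
    """
    info = table.by_id()
    summaries: list[RegionalSummary] = []
    for r in regions:
        missing = [tid for tid in r.taxa if tid not in info]
        if missing:
            raise ValidationError(
                f"region {r.region_id!r}: taxa absent from table: "
                f"{sorted(missing)[:5]}"
            )
        n = len(r.taxa)
        counts = dict.fromkeys(USE_CATEGORIES, 0)
        n_econ = 0
        for tid in r.taxa:
            t = info[tid]
            if t.economic:
                n_econ += 1
            for c in t.uses:
                counts[c] += 1
        top = max(counts.values()) if counts else 0
        dominant = tuple(
            c for c in USE_CATEGORIES if counts[c] == top and top > 0
        )
        summaries.append(
            RegionalSummary(
                region_id=r.region_id,
                n_naturalized=n,
                n_econ=n_econ,
                prop_econ=n_econ / n if n else float("nan"),
                latitude=r.latitude,
                island=r.island,
                dominant_use=dominant,
            )
        )
    nat = table.naturalized()
    global_prop = (
        sum(1 for t in nat if t.economic) / len(nat) if nat else float("nan")
    )
    props = [s.prop_econ for s in summaries if not np.isnan(s.prop_econ)]
    aggregates = {
        "global_prop_econ": global_prop,
        "median_regional_prop": float(np.median(props)) if props else float("nan"),
        "n_regions_above_global": int(
            sum(1 for p in props if p > global_prop)
        ),
        "n_regions": len(summaries),
    }
    return summaries, aggregates


def summaries_frame(summaries: list[RegionalSummary]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "region_id": s.region_id,
                "n_naturalized": s.n_naturalized,
                "n_econ": s.n_econ,
                "prop_econ": s.prop_econ,
                "latitude": s.latitude,
                "island": int(s.island),
                "dominant_use": ";".join(s.dominant_use),
            }
            for s in summaries
        ]
    )


def fit_latitude_model(
    summaries: list[RegionalSummary], quasi: bool = True
) -> RegressionResult:
    """Quasi-binomial GLM: econ share ~ |latitude| * island.

    The response is (economic count, non-economic count) per region, so
    larger floras carry more weight.  With a single island class the
    island terms are dropped with a warning.
    """
    if len(summaries) < 10:
        raise ValidationError("need at least 10 regions")
    lat = np.array([abs(s.latitude) for s in summaries])
    isl = np.array([float(s.island) for s in summaries])
    succ = np.array([s.n_econ for s in summaries], dtype=float)
    fail = np.array([s.n_naturalized - s.n_econ for s in summaries], dtype=float)
    y = np.column_stack([succ, fail])
    if isl.min() == isl.max():
        warnings.warn(
            "single island class: island main effect and interaction dropped"
        )
        X = np.column_stack([np.ones_like(lat), lat])
        names = ["intercept", "abs_latitude"]
    else:
        X = np.column_stack([np.ones_like(lat), lat, isl, lat * isl])
        names = ["intercept", "abs_latitude", "island", "abs_latitude:island"]
    return fit_binomial_glm(y, X, quasi=quasi, names=names)


def region_count_medians(table: TaxonTable) -> dict:
    """Median naturalization extent for economic vs non-economic taxa.

    Computed over naturalized taxa only; an empty class yields ``None``
    for that median.
    """
    econ = [t.n_regions for t in table if t.naturalized and t.economic]
    non = [t.n_regions for t in table if t.naturalized and not t.economic]
    return {
        "median_econ": float(np.median(econ)) if econ else None,
        "median_nonecon": float(np.median(non)) if non else None,
        "n_econ": len(econ),
        "n_nonecon": len(non),
    }
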