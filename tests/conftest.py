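import pytest

from econatur.core import Taxon, TaxonTable
from econatur.synthetic_data import (
    GeneratorConfig,
    sample_published_tips,
    simulate_flora,
    simulate_phylogeny,
    simulate_regions,
)


def make_taxon(tid, genus="Gena", family="Fama", uses=(), nat=False,
               n_regions=None, continents=(), cult=False):
    if n_regions is None:
        n_regions = 1 if nat else 0
    return Taxon(
        taxon_id=tid,
        name=f"{genus} {tid}",
        genus=genus,
        family=family,
        uses=frozenset(uses),
        native_continents=frozenset(continents),
        naturalized=nat,
        n_regions=n_regions,
        cultivation_only=cult,
    )


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        seed=42, n_taxa=300, n_genera=60, n_families=15, n_regions=80
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """A small synthetic world shared across read-only tests."""
    tree = simulate_phylogeny(small_config)
    table = simulate_flora(tree, small_config)
    regions = simulate_regions(table, small_config)
    published = sample_published_tips(tree, small_config)
    return {
        "config": small_config,
        "tree": tree,
        "table": table,
        "regions": regions,
        "published": published,
    }


@pytest.fixture(scope="session")
def medium_world():
    """A flora large enough for region-level signal (≈360 naturalized)."""
    cfg = GeneratorConfig(
        seed=101, n_taxa=5000, n_genera=500, n_families=50, n_regions=300
    )
    tree = simulate_phylogeny(cfg)
    table = simulate_flora(tree, cfg)
    regions = simulate_regions(table, cfg)
    return {"config": cfg, "tree": tree, "table": table, "regions": regions}


@pytest.fixture
def tiny_table():
    rows = [
        make_taxon("a1", "Gena", "Fama", uses={"human_food"}, nat=True,
                   n_regions=3, continents={"EUR"}),
        make_taxon("a2", "Gena", "Fama", uses={"medicines", "human_food"},
                   nat=False, continents={"EUR", "TAS"}),
        make_taxon("b1", "Genb", "Famb", continents={"SAM"}),
    ]
    return TaxonTable(rows=rows)
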