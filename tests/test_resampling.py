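"""Resampling engine vs exact enumeration; category/origin/PD applications."""

import itertools

import numpy as np
import pytest

from econatur.core import CONTINENTS, TaxonTable, ValidationError
from econatur.datasets import single_use_category_table
from econatur.resampling import (
    category_tests,
    continent_origin_test,
    extrapolate_richness,
    pd_ses_test,
    resample_count_test,
    stratified_tip_draws,
)
from econatur.synthetic_data import GeneratorConfig, simulate_flora, simulate_phylogeny

from conftest import make_taxon


def exact_two_sided_p(flags, sample_size, observed):
    """Enumerate all draws and apply the same min-tail-doubling rule."""
    flags = list(flags)
    counts = [
        sum(flags[i] for i in combo)
        for combo in itertools.combinations(range(len(flags)), sample_size)
    ]
    n = len(counts)
    r_low = sum(1 for c in counts if c <= observed) / n
    r_high = sum(1 for c in counts if c >= observed) / n
    return min(1.0, 2.0 * min(r_low, r_high))


def test_engine_matches_exact_enumeration_small_pool():
    flags = [True] * 4 + [False] * 6
    p_exact = exact_two_sided_p(flags, 3, 3)
    res = resample_count_test(flags, 3, 3, n_iter=9999, seed=5)
    # Monte-Carlo SE of the estimated tail at p_exact/2
    se = np.sqrt((p_exact / 2) * (1 - p_exact / 2) / 9999) * 2
    assert res.p_two_sided == pytest.approx(p_exact, abs=3 * se + 2 / 10000)
    # the exact two-sided p is ~0.067: not significant at the 2.5% quantiles
    assert res.direction == "ns"


def test_engine_degenerate_full_pool_draw():
    flags = [True] * 4 + [False] * 6
    res = resample_count_test(flags, 10, 4, n_iter=199, seed=1)
    assert res.p_two_sided == 1.0
    assert res.direction == "ns"
    assert np.isnan(res.ses)


def test_engine_deterministic_and_validates():
    flags = [True, False] * 50
    a = resample_count_test(flags, 20, 15, n_iter=499, seed=9)
    b = resample_count_test(flags, 20, 15, n_iter=499, seed=9)
    assert a == b
    with pytest.raises(ValidationError):
        resample_count_test(flags, 101, 5, n_iter=499, seed=0)
    with pytest.raises(ValidationError):
        resample_count_test(flags, 10, 5, n_iter=10, seed=0)


# ---------------------------------------------------------------------------
# category tests
# ---------------------------------------------------------------------------


def test_category_tests_table1_margins_gene_sources_lower():
    table = single_use_category_table()
    res = category_tests(table, single_use_only=True, n_iter=999, seed=2)
    assert res["gene_sources"].direction == "lower"
    # bee plants sit far above the pool-wide naturalization share
    assert res["bee_plants"].direction == "higher"


def test_category_tests_ground_truth_enrichment():
    beta = {c: 0.8 for c in
            ("animal_food", "bee_plants", "environmental", "food_additives",
             "fuels", "gene_sources", "human_food", "invertebrate_food",
             "materials", "medicines", "nonvertebrate_poisons", "social")}
    beta["environmental"] = 3.5
    cfg = GeneratorConfig(
        seed=31, n_taxa=4000, n_genera=400, n_families=40,
        econ_threshold_quantile=0.3, beta_use=beta,
        gamma_pairwise=np.zeros((12, 12)), beta0=-2.5,
    )
    tree = simulate_phylogeny(cfg)
    table = simulate_flora(tree, cfg)
    res = category_tests(table, n_iter=499, seed=3)
    assert res["environmental"].direction == "higher"


def test_category_tests_calibration_under_equal_effects():
    # equal per-use effects AND single-use floras: with multi-use taxa any
    # positive effect enriches every category via size-biasing (multi-use
    # taxa sit in more categories and naturalize more), which is signal,
    # not a calibration failure.
    beta = {c: 1.0 for c in
            ("animal_food", "bee_plants", "environmental", "food_additives",
             "fuels", "gene_sources", "human_food", "invertebrate_food",
             "materials", "medicines", "nonvertebrate_poisons", "social")}
    rejections = 0
    testable = 0
    for seed in range(6):
        cfg = GeneratorConfig(
            seed=100 + seed, n_taxa=2500, n_genera=300, n_families=30,
            econ_threshold_quantile=0.3, beta_use=beta,
            gamma_pairwise=np.zeros((12, 12)), beta0=-1.5,
            phylo_signal_econ=0.0, mean_uses_per_econ_taxon=1.0,
        )
        tree = simulate_phylogeny(cfg)
        table = simulate_flora(tree, cfg)
        res = category_tests(table, n_iter=499, seed=seed)
        for r in res.values():
            if r.testable:
                testable += 1
                if r.direction != "ns":
                    rejections += 1
    assert testable > 50
    assert rejections / testable < 0.15


def test_category_tests_empty_category_flagged():
    rows = [
        make_taxon(f"t{i}", uses={"human_food"}, nat=(i < 3)) for i in range(10)
    ]
    res = category_tests(TaxonTable(rows=rows), n_iter=199, seed=0)
    assert res["social"].testable is False
    assert res["human_food"].testable is True


# ---------------------------------------------------------------------------
# continental origins
# ---------------------------------------------------------------------------


def _origin_table(rng, n=600, enriched=None):
    rows = []
    for i in range(n):
        cont = CONTINENTS[int(rng.integers(0, 8))]  # skip ANT
        if enriched is not None and rng.random() < 0.5:
            cont = enriched
        rows.append(
            make_taxon(
                f"t{i}", genus=f"g{i % 40}", family=f"f{i % 10}",
                uses={"human_food"}, continents={cont},
            )
        )
    return TaxonTable(rows=rows)


def test_origin_test_calibrated_under_uniform_world():
    rng = np.random.default_rng(0)
    table = _origin_table(rng)
    richness = [1.0] * 8 + [1e-9]
    res = continent_origin_test(table, richness, n_iter=499, seed=1)
    ns = sum(1 for c in CONTINENTS[:8] if res[c].direction == "ns")
    assert ns >= 6


def test_origin_test_detects_enriched_continent():
    rng = np.random.default_rng(1)
    table = _origin_table(rng, enriched="EUR")
    richness = [1.0] * 8 + [1e-9]
    res = continent_origin_test(table, richness, n_iter=499, seed=2)
    assert res["EUR"].direction == "higher"


def test_origin_multi_continent_counting_and_subset():
    rows = [
        make_taxon("t1", uses={"social"}, continents={"EUR", "TAS"}),
        make_taxon("t2", genus="g2", uses={"social"}, continents={"EUR"}),
        make_taxon("t3", genus="g3", uses={"social"}, continents={"AFR"}),
    ]
    table = TaxonTable(rows=rows)
    res = continent_origin_test(table, [1.0] * 9, n_iter=99 + 1, seed=0)
    assert res["EUR"].observed == 2.0  # multi-native taxon counts once per continent
    res_single = continent_origin_test(
        table, [1.0] * 9, single_native_only=True, n_iter=100, seed=0
    )
    assert res_single["EUR"].observed == 1.0


def test_richness_extrapolation_scale():
    known = np.array([10.0, 20.0, 5.0])
    out = extrapolate_richness(known, 130_641, 326_101)
    assert out == pytest.approx(known * (326_101 / 130_641))
    assert out[0] / known[0] == pytest.approx(2.496, abs=5e-4)


# ---------------------------------------------------------------------------
# PD SES
# ---------------------------------------------------------------------------


def test_pd_ses_all_tips_degenerate():
    cfg = GeneratorConfig(seed=77, n_taxa=30, n_genera=8, n_families=3)
    tree = simulate_phylogeny(cfg)
    res = pd_ses_test(tree, set(tree.tip_labels()), n_iter=199, seed=0)
    assert res.degenerate
    assert np.isnan(res.ses)
    assert res.direction == "ns"


def test_pd_ses_detects_built_in_clustering():
    neg = 0
    for seed in range(8):
        cfg = GeneratorConfig(
            seed=seed, n_taxa=300, n_genera=60, n_families=12,
            phylo_signal_econ=1.0, econ_threshold_quantile=0.1,
        )
        tree = simulate_phylogeny(cfg)
        table = simulate_flora(tree, cfg)
        econ = {t.taxon_id for t in table if t.economic}
        res = pd_ses_test(tree, econ, n_iter=199, seed=seed)
        if res.ses < 0:
            neg += 1
    assert neg >= 7


def test_stratified_draws_preserve_stratum_count():
    rng = np.random.default_rng(4)
    flags = np.zeros(50, dtype=bool)
    flags[:18] = True
    sel = stratified_tip_draws(rng, 200, flags, k_flagged=7, k_rest=13)
    assert sel.shape == (200, 50)
    assert np.all(sel[:, :18].sum(axis=1) == 7)
    assert np.all(sel[:, 18:].sum(axis=1) == 13)
    assert np.all(sel.sum(axis=1) == 20)


def test_pd_ses_deterministic(small_world):
    tree = small_world["tree"]
    table = small_world["table"]
    econ = {t.taxon_id for t in table if t.economic}
    a = pd_ses_test(tree, econ, n_iter=199, seed=11)
    b = pd_ses_test(tree, econ, n_iter=199, seed=11)
    assert a == b
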