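"""Grafting, pruning and Faith's PD against hand and brute-force oracles."""

import numpy as np
import pytest

from econatur.core import TaxonTable, ValidationError
from econatur.phylo import (
    PDIndex,
    Phylogeny,
    faith_pd,
    graft_missing_taxa,
    prune,
    read_newick,
)
from econatur.synthetic_data import (
    GeneratorConfig,
    sample_published_tips,
    simulate_flora,
    simulate_phylogeny,
)

from conftest import make_taxon


THREE_TIP = "((A1:1,A2:1):1,B1:2);"


def three_tip_table(extra=()):
    rows = [
        make_taxon("A1", genus="Agen", family="Famx"),
        make_taxon("A2", genus="Agen", family="Famx"),
        make_taxon("B1", genus="Bgen", family="Famx"),
    ]
    rows.extend(extra)
    return TaxonTable(rows=rows)


def test_newick_roundtrip_and_canonical_rotation():
    t1 = read_newick(THREE_TIP)
    t2 = read_newick("(B1:2,(A2:1,A1:1):1);")
    assert t1.to_newick() == t2.to_newick()
    assert read_newick(t1.to_newick()).to_newick() == t1.to_newick()


def test_graft_no_missing_is_identity():
    tree = read_newick(THREE_TIP)
    out, unplaced = graft_missing_taxa(tree, three_tip_table())
    assert unplaced == []
    assert out.to_newick() == tree.to_newick()


def test_graft_congener_attaches_at_genus_crown():
    tree = read_newick(THREE_TIP)
    table = three_tip_table([make_taxon("A3", genus="Agen", family="Famx")])
    out, unplaced = graft_missing_taxa(tree, table)
    assert unplaced == []
    assert sorted(out.tip_labels()) == ["A1", "A2", "A3", "B1"]
    depths = out.tip_depths()
    assert all(d == pytest.approx(2.0) for d in depths.values())
    # A3 hangs off the A1/A2 crown with pendant length 1
    a3 = [n for n in out.tips() if n.label == "A3"][0]
    assert a3.length == pytest.approx(1.0)
    assert out.is_ultrametric(1e-9)


def test_graft_family_fallback_and_unplaced():
    tree = read_newick(THREE_TIP)
    table = three_tip_table(
        [
            make_taxon("C1", genus="Cgen", family="Famx"),
            make_taxon("D1", genus="Dgen", family="Famy"),
        ]
    )
    out, unplaced = graft_missing_taxa(tree, table)
    assert unplaced == ["D1"]
    # C1 attaches at the family crown (here: the root), reaching the present
    assert out.tip_depths()["C1"] == pytest.approx(2.0)
    assert out.is_ultrametric(1e-9)


def test_graft_single_tip_genus_splits_pendant_edge():
    tree = read_newick(THREE_TIP)
    table = three_tip_table([make_taxon("B2", genus="Bgen", family="Famx")])
    out, _ = graft_missing_taxa(tree, table)
    depths = out.tip_depths()
    assert depths["B2"] == pytest.approx(2.0)
    assert depths["B1"] == pytest.approx(2.0)
    b2 = [n for n in out.tips() if n.label == "B2"][0]
    assert b2.length == pytest.approx(1.0)


def test_graft_tip_counting_over_random_worlds():
    for seed in range(5):
        cfg = GeneratorConfig(seed=seed, n_taxa=120, n_genera=25, n_families=8)
        tree = simulate_phylogeny(cfg)
        table = simulate_flora(tree, cfg)
        published = sample_published_tips(tree, cfg)
        out, unplaced = graft_missing_taxa(published, table)
        assert out.n_tips() == published.n_tips() + (
            len(table) - published.n_tips() - len(unplaced)
        )
        assert out.is_ultrametric(1e-6)


def test_graft_rejects_nonultrametric_when_flagged():
    tree = read_newick("((A1:1,A2:3):1,B1:2);")
    with pytest.raises(ValidationError, match="ultrametric"):
        graft_missing_taxa(tree, three_tip_table())


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def test_prune_identity_and_cherry():
    tree = read_newick(THREE_TIP)
    same = prune(tree, {"A1", "A2", "B1"})
    assert same.to_newick() == tree.to_newick()
    cherry = prune(tree, {"A1", "B1"})
    assert sorted(cherry.tip_labels()) == ["A1", "B1"]
    assert all(d == pytest.approx(2.0) for d in cherry.tip_depths().values())


def test_prune_missing_ids_listed():
    tree = read_newick(THREE_TIP)
    with pytest.raises(ValidationError, match="ZZ"):
        prune(tree, {"A1", "ZZ"})


def test_prune_preserves_pairwise_distances():
    cfg = GeneratorConfig(seed=3, n_taxa=50, n_genera=10, n_families=4)
    tree = simulate_phylogeny(cfg)
    labels, D = tree.tip_distance_matrix()
    rng = np.random.default_rng(0)
    keep = sorted(rng.choice(labels, size=10, replace=False))
    sub = prune(tree, keep)
    sub_labels, sub_D = sub.tip_distance_matrix()
    pos = {lab: i for i, lab in enumerate(labels)}
    for i, a in enumerate(sub_labels):
        for j, b in enumerate(sub_labels):
            assert sub_D[i, j] == pytest.approx(D[pos[a], pos[b]], abs=1e-9)


def test_graft_then_prune_recovers_original_distances():
    tree = read_newick(THREE_TIP)
    table = three_tip_table(
        [make_taxon("A3", genus="Agen", family="Famx"),
         make_taxon("B2", genus="Bgen", family="Famx")]
    )
    out, _ = graft_missing_taxa(tree, table)
    back = prune(out, {"A1", "A2", "B1"})
    l1, d1 = tree.tip_distance_matrix()
    l2, d2 = back.tip_distance_matrix()
    p2 = {lab: i for i, lab in enumerate(l2)}
    for i, a in enumerate(l1):
        for j, b in enumerate(l1):
            assert d1[i, j] == pytest.approx(d2[p2[a], p2[b]], abs=1e-9)


# ---------------------------------------------------------------------------
# Faith's PD
# ---------------------------------------------------------------------------


def brute_force_pd(tree: Phylogeny, tips) -> float:
    """Union of root-to-tip edge sets, summed — independent of faith_pd."""
    tip_nodes = {n.label: n for n in tree.tips()}
    edges = set()
    for lab in tips:
        node = tip_nodes[lab]
        while node.parent is not None:
            edges.add(id(node))
            node = node.parent
    lengths = {id(n): n.length for n in tree.postorder()}
    return sum(lengths[e] for e in edges)


def test_faith_pd_total_and_single_tip():
    tree = read_newick(THREE_TIP)
    assert faith_pd(tree, {"A1", "A2", "B1"}) == pytest.approx(
        tree.total_branch_length()
    )
    assert faith_pd(tree, {"B1"}) == pytest.approx(2.0)
    with pytest.raises(ValidationError):
        faith_pd(tree, {"nope"})


def test_faith_pd_matches_brute_force_on_simulated_tree():
    cfg = GeneratorConfig(seed=9, n_taxa=12, n_genera=4, n_families=2)
    tree = simulate_phylogeny(cfg)
    labels = tree.tip_labels()
    rng = np.random.default_rng(1)
    for k in (1, 2, 3, 5, 8, 12):
        subset = set(rng.choice(labels, size=k, replace=False))
        assert faith_pd(tree, subset) == pytest.approx(
            brute_force_pd(tree, subset), rel=1e-12
        )


def test_pd_monotone_and_subadditive():
    cfg = GeneratorConfig(seed=13, n_taxa=30, n_genera=8, n_families=3)
    tree = simulate_phylogeny(cfg)
    labels = tree.tip_labels()
    rng = np.random.default_rng(2)
    total = faith_pd(tree, set(labels))
    for _ in range(10):
        a = set(rng.choice(labels, size=5, replace=False))
        b = set(rng.choice(labels, size=7, replace=False))
        pd_a = faith_pd(tree, a)
        assert pd_a <= faith_pd(tree, a | b) + 1e-12
        assert faith_pd(tree, a | b) <= pd_a + faith_pd(tree, b) + 1e-12
        assert faith_pd(tree, a | b) <= total + 1e-12


def test_pd_index_agrees_with_faith_pd():
    cfg = GeneratorConfig(seed=21, n_taxa=40, n_genera=10, n_families=4)
    tree = simulate_phylogeny(cfg)
    idx = PDIndex(tree)
    labels = tree.tip_labels()
    rng = np.random.default_rng(3)
    sel = np.zeros((6, len(labels)), dtype=bool)
    subsets = []
    for i in range(6):
        subset = set(rng.choice(labels, size=rng.integers(1, 20), replace=False))
        subsets.append(subset)
        for lab in subset:
            sel[i, idx.tip_index[lab]] = True
    batch = idx.pd_batch(sel)
    for i, subset in enumerate(subsets):
        assert batch[i] == pytest.approx(faith_pd(tree, subset), rel=1e-12)
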