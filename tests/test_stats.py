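"""GLMs, the pairwise-use model, Siegel regression and Brownian PGLS."""

import numpy as np
import pytest
from scipy.special import expit, logit

from econatur.core import TaxonTable, ValidationError
from econatur.phylo import PhyloNode, Phylogeny
from econatur.stats import (
    SeparationError,
    fit_binomial_glm,
    fit_pairwise_use_glm,
    fit_pgls,
    fit_use_count_model,
    siegel_regression,
)
from econatur.synthetic_data import GeneratorConfig, simulate_phylogeny

from conftest import make_taxon


def test_intercept_only_closed_form():
    y = np.array([1.0] * 40 + [0.0] * 60)
    X = np.ones((100, 1))
    res = fit_binomial_glm(y, X, names=["intercept"])
    assert res.coefficients["intercept"] == pytest.approx(logit(0.4), abs=1e-8)


def test_quasi_changes_only_uncertainties():
    rng = np.random.default_rng(0)
    n = 200
    x = rng.normal(size=n)
    trials = rng.integers(5, 30, size=n)
    p = expit(0.3 + 0.8 * x + rng.normal(0, 0.7, size=n))  # overdispersed
    succ = rng.binomial(trials, p)
    y = np.column_stack([succ, trials - succ]).astype(float)
    X = np.column_stack([np.ones(n), x])
    plain = fit_binomial_glm(y, X, quasi=False, names=["b0", "b1"])
    quasi = fit_binomial_glm(y, X, quasi=True, names=["b0", "b1"])
    for k in ("b0", "b1"):
        assert quasi.coefficients[k] == pytest.approx(plain.coefficients[k])
        ratio = quasi.standard_errors[k] / plain.standard_errors[k]
        assert ratio == pytest.approx(np.sqrt(quasi.dispersion), rel=1e-10)
    assert quasi.dispersion > 1.5
    assert plain.dispersion == 1.0


def test_logistic_recovery_within_3se():
    rng = np.random.default_rng(42)
    beta = np.array([-1.0, 0.7, -0.4])
    exceed = 0
    for _ in range(30):
        X = np.column_stack([np.ones(5000), rng.normal(size=(5000, 2))])
        y = (rng.random(5000) < expit(X @ beta)).astype(float)
        res = fit_binomial_glm(y, X, names=["b0", "b1", "b2"])
        exceed += sum(
            abs(res.coefficients[k] - b) > 3 * res.standard_errors[k]
            for k, b in zip(["b0", "b1", "b2"], beta)
        )
    # nominal 3-SE exceedance is ~0.3%; allow a generous margin on 90 checks
    assert exceed <= 4


def test_score_equations_at_convergence():
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(500), rng.normal(size=500)])
    y = (rng.random(500) < expit(X @ [0.2, 1.0])).astype(float)
    res = fit_binomial_glm(y, X, names=["b0", "b1"])
    beta = np.array([res.coefficients["b0"], res.coefficients["b1"]])
    mu = expit(X @ beta)
    assert np.max(np.abs(X.T @ (y - mu))) < 1e-6


def test_perfect_separation_raises():
    x = np.linspace(-2, 2, 60)
    y = (x > 0).astype(float)
    X = np.column_stack([np.ones(60), x])
    with pytest.raises(SeparationError):
        fit_binomial_glm(y, X, names=["intercept", "x"])


def test_rank_deficiency_raises():
    rng = np.random.default_rng(5)
    x = rng.normal(size=80)
    X = np.column_stack([np.ones(80), x, 2 * x])
    y = (rng.random(80) < 0.5).astype(float)
    with pytest.raises(ValidationError, match="rank"):
        fit_binomial_glm(y, X)


# ---------------------------------------------------------------------------
# use-count model
# ---------------------------------------------------------------------------


def _use_table(rng, n=800, slope=1.0):
    cats = ["human_food", "medicines", "materials", "fuels"]
    rows = []
    for i in range(n):
        k = 1 + int(rng.integers(0, 4))
        uses = set(rng.choice(cats, size=min(k, 4), replace=False))
        p = expit(-2.0 + slope * len(uses))
        nat = rng.random() < p
        rows.append(
            make_taxon(f"t{i}", genus=f"g{i % 50}", family=f"f{i % 10}",
                       uses=uses, nat=nat)
        )
    return TaxonTable(rows=rows)


def test_use_count_model_positive_slope_and_order_invariance():
    rng = np.random.default_rng(7)
    table = _use_table(rng)
    res = fit_use_count_model(table)
    assert res.coefficients["n_uses"] > 0
    assert res.p_values["n_uses"] < 0.05
    shuffled = TaxonTable(rows=list(reversed(table.rows)))
    res2 = fit_use_count_model(shuffled)
    assert res2.coefficients["n_uses"] == pytest.approx(
        res.coefficients["n_uses"]
    )


def test_use_count_model_requires_variation():
    rows = [make_taxon(f"t{i}", uses={"fuels"}, nat=(i % 2 == 0))
            for i in range(20)]
    with pytest.raises(ValidationError, match="constant"):
        fit_use_count_model(TaxonTable(rows=rows))


# ---------------------------------------------------------------------------
# pairwise-use model
# ---------------------------------------------------------------------------


def test_pairwise_design_structure():
    rng = np.random.default_rng(11)
    rows = []
    i = 0
    # 60 no-use, 40 food, 40 medicines, 25 food+medicines, 3 fuels+social
    for _ in range(60):
        rows.append(make_taxon(f"t{i}", nat=rng.random() < 0.1)); i += 1
    for _ in range(40):
        rows.append(make_taxon(f"t{i}", uses={"human_food"},
                               nat=rng.random() < 0.5)); i += 1
    for _ in range(40):
        rows.append(make_taxon(f"t{i}", uses={"medicines"},
                               nat=rng.random() < 0.5)); i += 1
    for _ in range(25):
        rows.append(make_taxon(f"t{i}", uses={"human_food", "medicines"},
                               nat=rng.random() < 0.6)); i += 1
    for _ in range(3):
        rows.append(make_taxon(f"t{i}", uses={"fuels", "social"},
                               nat=rng.random() < 0.5)); i += 1
    for _ in range(15):
        rows.append(make_taxon(f"t{i}", uses={"fuels"},
                               nat=rng.random() < 0.4)); i += 1
    for _ in range(15):
        rows.append(make_taxon(f"t{i}", uses={"social"},
                               nat=rng.random() < 0.4)); i += 1
    res = fit_pairwise_use_glm(TaxonTable(rows=rows), min_count=10)
    assert "human_food:medicines" in res.coefficients
    # sparse pair dropped from the design but reported
    assert "fuels:social" not in res.coefficients
    assert "fuels:social" in res.extras["dropped_pairs"]
    # a pair absent from the table never appears
    assert "bee_plants:fuels" not in res.coefficients
    net = res.extras["net_effects"]["human_food:medicines"]
    assert net == pytest.approx(
        res.coefficients["human_food"]
        + res.coefficients["medicines"]
        + res.coefficients["human_food:medicines"]
    )


# ---------------------------------------------------------------------------
# Siegel repeated medians
# ---------------------------------------------------------------------------


def brute_force_repeated_medians(x, y):
    n = len(x)
    med_i = []
    for i in range(n):
        slopes = [
            (y[j] - y[i]) / (x[j] - x[i])
            for j in range(n)
            if j != i and x[j] != x[i]
        ]
        med_i.append(np.median(slopes))
    slope = np.median(med_i)
    intercept = np.median([y[i] - slope * x[i] for i in range(n)])
    return slope, intercept


def test_siegel_exact_line():
    x = np.arange(10.0)
    y = 2.0 * x + 1.0
    res = siegel_regression(x, y)
    assert res["slope"] == pytest.approx(2.0)
    assert res["intercept"] == pytest.approx(1.0)
    assert res["tau_p"] < 0.01


def test_siegel_matches_brute_force_n7():
    rng = np.random.default_rng(17)
    for _ in range(5):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        res = siegel_regression(x, y)
        bs, bi = brute_force_repeated_medians(x, y)
        assert res["slope"] == pytest.approx(bs, rel=1e-12)
        assert res["intercept"] == pytest.approx(bi, rel=1e-12)


def test_siegel_outlier_invariance():
    x = np.arange(9.0)
    y = 3.0 * x - 2.0
    res9 = siegel_regression(x, y)
    x10 = np.append(x, 4.5)
    y10 = np.append(y, 1e6)  # gross outlier
    res10 = siegel_regression(x10, y10)
    assert res10["slope"] == pytest.approx(res9["slope"])


def test_siegel_validates():
    with pytest.raises(ValidationError):
        siegel_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValidationError):
        siegel_regression([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


def star_tree(n, depth=1.0):
    root = PhyloNode()
    for i in range(n):
        root.add_child(PhyloNode(label=f"s{i}", length=depth))
    return Phylogeny(root=root, ultrametric=True)


def test_pgls_star_tree_equals_ols():
    rng = np.random.default_rng(19)
    n = 50
    tree = star_tree(n)
    order = [f"s{i}" for i in range(n)]
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [1.0, 0.5] + rng.normal(0, 0.3, size=n)
    res = fit_pgls(y, X, tree, order, names=["b0", "b1"])
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert res.coefficients["b0"] == pytest.approx(ols[0], abs=1e-8)
    assert res.coefficients["b1"] == pytest.approx(ols[1], abs=1e-8)


def test_pgls_branch_scale_invariance():
    cfg = GeneratorConfig(seed=23, n_taxa=40, n_genera=10, n_families=4)
    tree = simulate_phylogeny(cfg)
    order = tree.tip_labels()
    rng = np.random.default_rng(2)
    X = np.column_stack([np.ones(40), rng.normal(size=40)])
    y = X @ [0.3, 1.2] + rng.normal(size=40)
    res1 = fit_pgls(y, X, tree, order, names=["b0", "b1"])
    scaled = tree.copy()
    for node in scaled.postorder():
        node.length *= 7.5
    res2 = fit_pgls(y, X, scaled, order, names=["b0", "b1"])
    for k in ("b0", "b1"):
        assert res2.coefficients[k] == pytest.approx(res1.coefficients[k], rel=1e-9)


def test_pgls_recovers_slope_under_bm_residuals():
    cfg = GeneratorConfig(seed=29, n_taxa=120, n_genera=25, n_families=8)
    tree = simulate_phylogeny(cfg)
    order = tree.tip_labels()
    from econatur.synthetic_data import _brownian_trait

    ok = 0
    for rep in range(10):
        rng = np.random.default_rng(1000 + rep)
        x = rng.normal(size=120)
        resid = _brownian_trait(tree, rng, order)
        y = 0.4 + 0.9 * x + resid
        X = np.column_stack([np.ones(120), x])
        res = fit_pgls(y, X, tree, order, names=["b0", "b1"])
        if abs(res.coefficients["b1"] - 0.9) <= 3 * res.standard_errors["b1"]:
            ok += 1
    assert ok >= 9
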