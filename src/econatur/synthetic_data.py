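"""Synthetic floras, trees and region sets with known ground truth.

The generator emulates the joint structure the analyses assume:

* an ultrametric birth-death phylogeny whose tips fall into
  monophyletic genera nested in monophyletic families;
* economic status assigned by thresholding a latent trait that mixes a
  Brownian-motion component on the tree (weight ``phylo_signal_econ``)
  with independent noise, so phylogenetic clustering of economic use is
  tunable and exactly absent at weight 0;
* per-taxon use categories drawn with category-specific Brownian
  scores, naturalization drawn from a logistic model with per-category
  effects and (by default negative) pairwise interaction terms;
* native continents drawn from a continental-richness vector with a
  configurable share of multi-continent taxa;
* regional naturalized floras whose expected share of economic taxa
  follows a logistic trend in absolute latitude, with membership
  weighted by each taxon's naturalization extent.

Defaults mirror the published margins of the real-world catalogues
where those are known (multi-continent share, island share of regions,
single-use share, tree-sampling gaps) and are otherwise chosen as
plausible for a scaled-down global flora; see ``docs/methods.md``.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core import (
    CONTINENTS,
    USE_CATEGORIES,
    Region,
    RegionSet,
    Taxon,
    TaxonTable,
    ValidationError,
)
from .phylo import PhyloNode, Phylogeny, prune

__all__ = [
    "GeneratorConfig",
    "simulate_phylogeny",
    "simulate_flora",
    "simulate_regions",
    "sample_published_tips",
]

_DEFAULT_CATEGORY_WEIGHTS = (
    836, 202, 5666, 462, 206, 2758, 1360, 41, 2190, 3104, 44, 128,
)

_DEFAULT_BETA_USE = {
    "animal_food": 2.0,
    "bee_plants": 1.8,
    "environmental": 2.2,
    "food_additives": 1.5,
    "fuels": 1.2,
    "gene_sources": 0.5,
    "human_food": 1.5,
    "invertebrate_food": 1.0,
    "materials": 0.8,
    "medicines": 1.5,
    "nonvertebrate_poisons": 1.8,
    "social": 1.0,
}

_DEFAULT_RICHNESS = {
    "AFR": 0.17,
    "TAS": 0.13,
    "TRA": 0.17,
    "AUS": 0.08,
    "EUR": 0.04,
    "NAM": 0.07,
    "SAM": 0.28,
    "PAC": 0.03,
    "ANT": 0.001,
}


def _default_gamma() -> np.ndarray:
    # diminishing returns of a second use; the magnitude is on the order
    # of the main effects, large enough that two-use interactions are
    # detectable at realistic pair counts (tens of taxa per combination)
    g = np.full((12, 12), -1.0)
    np.fill_diagonal(g, 0.0)
    return g


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of the synthetic world.

    The logistic naturalization model is
    ``logit p = beta0 + sum_c beta_use[c] x_c + sum_{c<d} gamma[c,d] x_c x_d``
    over the 12 use indicators; regional economic share follows
    ``logit share = lat_intercept + lat_slope * |latitude|``.
    """

    seed: int
    n_taxa: int = 2000
    n_genera: int = 300
    n_families: int = 60
    tree_birth_rate: float = 0.1  # events / myr
    tree_death_rate: float = 0.0
    frac_missing_congeneric: float = 0.2047  # tips absent but genus sampled
    frac_missing_genus: float = 0.0134  # tips absent with whole genus absent
    econ_threshold_quantile: float = 0.10  # share of taxa with >=1 use
    phylo_signal_econ: float = 0.8  # Brownian weight lambda in [0, 1]
    category_weights: tuple = _DEFAULT_CATEGORY_WEIGHTS
    mean_uses_per_econ_taxon: float = 1.45
    beta0: float = -3.75
    beta_use: dict = field(default_factory=lambda: dict(_DEFAULT_BETA_USE))
    gamma_pairwise: np.ndarray = field(default_factory=_default_gamma)
    continent_richness: dict = field(
        default_factory=lambda: dict(_DEFAULT_RICHNESS)
    )
    multi_continent_prob: float = 0.328
    cultivation_only_prob: float = 0.017
    nbinom_size: float = 0.8
    nbinom_mu_econ: float = 8.0
    nbinom_mu_nonecon: float = 3.0
    #: log-scale increase of the naturalization-extent mean per economic
    #: use beyond the first (extent rises with the number of uses)
    extent_use_slope: float = 0.25
    n_regions: int = 500
    island_fraction: float = 0.37
    lat_intercept: float = 1.1
    lat_slope: float = -0.02  # logit of economic share per degree
    region_size_mu: float = 30.0
    region_size_k: float = 1.5

    @property
    def tip_sampling_fraction(self) -> float:
        """Share of taxa present in the "published" tree before grafting."""
        return 1.0 - self.frac_missing_congeneric - self.frac_missing_genus

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValidationError("n_taxa must be >= 2")
        if self.tree_birth_rate <= 0 or self.tree_death_rate < 0:
            raise ValidationError("rates must be positive (birth) / nonnegative")
        if not 0.0 < self.econ_threshold_quantile < 1.0:
            raise ValidationError("econ_threshold_quantile must be in (0, 1)")
        if not 0.0 <= self.phylo_signal_econ <= 1.0:
            raise ValidationError("phylo_signal_econ must be in [0, 1]")
        w = np.asarray(self.category_weights, dtype=float)
        if w.shape != (12,) or np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("category_weights must be 12 nonnegative values")
        if self.n_regions <= 0:
            raise ValidationError("n_regions must be positive")

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta_use[c] for c in USE_CATEGORIES])

    def richness_vector(self) -> np.ndarray:
        return np.array([self.continent_richness[c] for c in CONTINENTS])


def _rng(config: GeneratorConfig, stage: int, seed: int | None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng([int(base) % (2**31), stage])


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


def _birth_death_tree(
    rng: np.random.Generator, n_taxa: int, birth: float, death: float
) -> Phylogeny | None:
    """Forward birth-death simulation stopped at ``n_taxa`` extant tips."""
    root = PhyloNode()
    a, b = PhyloNode(), PhyloNode()
    root.add_child(a)
    root.add_child(b)
    t = 0.0
    active: list[tuple[PhyloNode, float]] = [(a, 0.0), (b, 0.0)]
    extinct: list[PhyloNode] = []
    while len(active) < n_taxa:
        n = len(active)
        if n == 0:
            return None
        total = n * (birth + death)
        t += rng.exponential(1.0 / total)
        i = int(rng.integers(n))
        node, start = active[i]
        if rng.random() < birth / (birth + death):
            node.length = t - start
            c1, c2 = PhyloNode(), PhyloNode()
            node.add_child(c1)
            node.add_child(c2)
            active[i] = (c1, t)
            active.append((c2, t))
        else:
            node.length = t - start
            extinct.append(node)
            active.pop(i)
    # let the present fall a random waiting time after the last event
    t += rng.exponential(1.0 / (n_taxa * (birth + death)))
    for k, (node, start) in enumerate(active):
        node.length = t - start
        node.label = f"t{k:05d}"
    tree = Phylogeny(root=root, ultrametric=True)
    if extinct:
        for j, node in enumerate(extinct):
            node.label = f"dead{j:05d}"
        tree = prune(tree, [n.label for n, _ in active])
        # relabel in a stable tip order after pruning
        for k, tip in enumerate(tree.tips()):
            tip.label = f"t{k:05d}"
    return tree


def _lineage_partition(
    tree: Phylogeny, n_families: int, n_genera: int
) -> dict[str, tuple[str, str]]:
    """Cut the tree into family and genus clades by refining from the root."""
    depth = tree.depths_from_root()
    counter = 0
    heap: list[tuple[float, int, PhyloNode]] = []

    def push(node: PhyloNode) -> None:
        nonlocal counter
        heapq.heappush(heap, (depth[node], counter, node))
        counter += 1

    push(tree.root)
    frontier: list[PhyloNode] = []  # tips popped with nothing to refine
    family_snapshot: list[PhyloNode] | None = None

    def current() -> list[PhyloNode]:
        return frontier + [n for _, _, n in heap]

    while heap and len(frontier) + len(heap) < n_genera:
        if family_snapshot is None and len(frontier) + len(heap) >= n_families:
            family_snapshot = current()
        d, _, node = heapq.heappop(heap)
        if node.is_tip:
            frontier.append(node)
            continue
        for c in node.children:
            push(c)
    if family_snapshot is None:
        family_snapshot = current()
    genus_clades = current()

    # map every genus clade to the family clade containing it
    tip_family: dict[str, str] = {}
    for i, fam in enumerate(family_snapshot):
        name = f"Fam{i:03d}"
        for node in Phylogeny(root=fam, ultrametric=True).postorder():
            if node.is_tip:
                tip_family[node.label] = name
    lineage: dict[str, tuple[str, str]] = {}
    for g, clade in enumerate(genus_clades):
        gname = f"Gen{g:04d}"
        for node in Phylogeny(root=clade, ultrametric=True).postorder():
            if node.is_tip:
                lineage[node.label] = (gname, tip_family[node.label])
    return lineage


def simulate_phylogeny(
    config: GeneratorConfig, seed: int | None = None
) -> Phylogeny:
    """Simulate an ultrametric birth-death tree with genus/family clades.

    Tip labels are taxon ids; the genus/family membership of each tip
    is stored in ``tree.tip_lineage`` (congeners are monophyletic by
    construction).  Deterministic given the seed.
    """
    config.validate()
    rng = _rng(config, 11, seed)
    tree = None
    for _ in range(100):
        tree = _birth_death_tree(
            rng, config.n_taxa, config.tree_birth_rate, config.tree_death_rate
        )
        if tree is not None:
            break
    if tree is None:
        raise ValidationError(
            "birth-death simulation went extinct in 100 attempts "
            "(death rate too close to or above birth rate)"
        )
    n_gen = min(config.n_genera, config.n_taxa)
    n_fam = min(config.n_families, n_gen)
    tree.tip_lineage = _lineage_partition(tree, n_fam, n_gen)
    return tree


def sample_published_tips(
    tree: Phylogeny, config: GeneratorConfig, seed: int | None = None
) -> Phylogeny:
    """Prune the full tree down to the "published" (sampled) tips.

    Removes roughly ``frac_missing_genus`` of taxa by dropping whole
    genera and ``frac_missing_congeneric`` of taxa individually while
    keeping at least one congener, emulating a backbone tree from
    which missing taxa must be grafted back.
    """
    rng = _rng(config, 12, seed)
    lineage = tree.tip_lineage
    tips = tree.tip_labels()
    n = len(tips)
    by_genus: dict[str, list[str]] = {}
    for lab in tips:
        by_genus.setdefault(lineage[lab][0], []).append(lab)

    drop: set[str] = set()
    # whole-genus removals
    target_genus = config.frac_missing_genus * n
    genera = list(by_genus)
    rng.shuffle(genera)
    removed = 0
    dropped_genera = set()
    for g in genera:
        if removed >= target_genus or len(dropped_genera) >= len(genera) - 1:
            break
        if len(by_genus[g]) <= max(2, int(0.02 * n)):
            drop.update(by_genus[g])
            dropped_genera.add(g)
            removed += len(by_genus[g])
    # individual removals keeping >=1 congener
    target_ind = int(round(config.frac_missing_congeneric * n))
    candidates = []
    for g, labs in by_genus.items():
        if g in dropped_genera or len(labs) < 2:
            continue
        labs = sorted(labs)
        rng.shuffle(labs)
        candidates.extend(labs[:-1])  # always keep one
    rng.shuffle(candidates)
    drop.update(candidates[:target_ind])
    keep = [lab for lab in tips if lab not in drop]
    sub = prune(tree, keep)
    sub.tip_lineage = {lab: lineage[lab] for lab in keep}
    return sub


# ---------------------------------------------------------------------------
# flora
# ---------------------------------------------------------------------------


def _brownian_trait(
    tree: Phylogeny, rng: np.random.Generator, tip_order: list[str]
) -> np.ndarray:
    """Standardized Brownian trait at the tips (unit variance)."""
    vals: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node is tree.root:
            continue
        vals[id(node)] = vals[id(node.parent)] + rng.normal(
            0.0, math.sqrt(max(node.length, 0.0))
        )
    depths = tree.tip_depths()
    scale = math.sqrt(max(np.mean(list(depths.values())), 1e-12))
    tip_vals = {n.label: vals[id(n)] for n in tree.tips()}
    return np.array([tip_vals[lab] / scale for lab in tip_order])


def simulate_flora(
    tree: Phylogeny, config: GeneratorConfig, seed: int | None = None
) -> TaxonTable:
    """Assign uses, naturalization, ranges to the tips of ``tree``."""
    config.validate()
    tips = tree.tip_labels()
    if len(tips) < 10:
        raise ValidationError("tree must have at least 10 tips")
    rng = _rng(config, 13, seed)
    n = len(tips)
    lam = config.phylo_signal_econ

    z = lam * _brownian_trait(tree, rng, tips) + (1.0 - lam) * rng.normal(size=n)
    k_econ = int(round(config.econ_threshold_quantile * n))
    if k_econ == 0:
        raise ValidationError(
            "econ_threshold_quantile too small: no economic taxa"
        )
    econ_idx = np.argsort(z, kind="stable")[-k_econ:]
    is_econ = np.zeros(n, dtype=bool)
    is_econ[econ_idx] = True

    # per-category clustered scores
    w = np.asarray(config.category_weights, dtype=float)
    w = w / w.sum()
    cat_bm = np.column_stack(
        [_brownian_trait(tree, rng, tips) for _ in USE_CATEGORIES]
    )
    extra = rng.poisson(max(config.mean_uses_per_econ_taxon - 1.0, 0.0), size=n)
    n_uses = np.where(is_econ, np.minimum(1 + extra, 12), 0)

    gumbel = rng.gumbel(size=(n, 12))
    scores = np.log(np.where(w > 0, w, 1e-300)) + cat_bm + gumbel
    x = np.zeros((n, 12), dtype=bool)
    for i in np.flatnonzero(is_econ):
        m = n_uses[i]
        top = np.argpartition(-scores[i], m - 1)[:m]
        x[i, top] = True

    beta = config.beta_vector()
    gamma = np.asarray(config.gamma_pairwise, dtype=float)
    xf = x.astype(float)
    eta = config.beta0 + xf @ beta + 0.5 * np.einsum("ij,jk,ik->i", xf, gamma, xf)
    nat = rng.random(n) < expit(eta)

    # naturalization extent: 1 + negative binomial; the mean is class-
    # specific and, for economic taxa, rises with the number of uses
    size = config.nbinom_size
    n_regions = np.zeros(n, dtype=np.int64)
    mu = np.where(
        is_econ,
        config.nbinom_mu_econ
        * np.exp(config.extent_use_slope * np.maximum(n_uses - 1, 0)),
        config.nbinom_mu_nonecon,
    )
    mu_part = np.maximum(mu - 1.0, 1e-6)
    p_nb = size / (size + mu_part)
    n_regions[nat] = 1 + rng.negative_binomial(size, p_nb[nat])

    # native continents
    rich = config.richness_vector()
    pcont = rich / rich.sum()
    logr = np.log(np.where(rich > 0, rich, 1e-300))
    cult_only = is_econ & (rng.random(n) < config.cultivation_only_prob)
    primary = rng.choice(len(CONTINENTS), size=n, p=pcont)
    is_multi = rng.random(n) < config.multi_continent_prob
    n_cont = np.where(is_multi, 2 + rng.poisson(0.4, size=n), 1)
    n_cont = np.minimum(n_cont, len(CONTINENTS))

    lineage = getattr(tree, "tip_lineage", None) or {}
    rows = []
    for i, lab in enumerate(tips):
        genus, family = lineage.get(lab, (f"Gen{i % 97:04d}", f"Fam{i % 23:03d}"))
        if cult_only[i]:
            conts: frozenset = frozenset()
        elif n_cont[i] == 1:
            conts = frozenset({CONTINENTS[primary[i]]})
        else:
            keys = logr + rng.gumbel(size=len(CONTINENTS))
            top = np.argpartition(-keys, n_cont[i] - 1)[: n_cont[i]]
            conts = frozenset(CONTINENTS[j] for j in top)
        uses = frozenset(
            USE_CATEGORIES[j] for j in np.flatnonzero(x[i])
        )
        rows.append(
            Taxon(
                taxon_id=lab,
                name=f"{genus} species{i:05d}",
                genus=genus,
                family=family,
                uses=uses,
                native_continents=conts,
                naturalized=bool(nat[i]),
                n_regions=int(n_regions[i]),
                cultivation_only=bool(cult_only[i]),
            )
        )
    return TaxonTable(
        rows=rows,
        provenance=f"simulate_flora(seed={seed if seed is not None else config.seed})",
    )


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


def simulate_regions(
    table: TaxonTable, config: GeneratorConfig, seed: int | None = None
) -> RegionSet:
    """Sample regional naturalized floras with a latitudinal trend.

    Region membership is drawn per region independently, weighted by
    each taxon's naturalization extent, with the expected economic
    share following ``logit^-1(lat_intercept + lat_slope * |lat|)``.
    """
    config.validate()
    rng = _rng(config, 17, seed)
    econ_pool = [t for t in table if t.naturalized and t.economic]
    non_pool = [t for t in table if t.naturalized and not t.economic]
    if not econ_pool and not non_pool:
        raise ValidationError("table contains no naturalized taxa")

    def log_weights(pool):
        return np.log(np.array([max(t.n_regions, 1) for t in pool], dtype=float))

    lw_econ = log_weights(econ_pool) if econ_pool else np.empty(0)
    lw_non = log_weights(non_pool) if non_pool else np.empty(0)
    rich = config.richness_vector()
    pcont = rich / rich.sum()

    size_k = config.region_size_k
    mu_part = max(config.region_size_mu - 1.0, 1e-6)
    p_size = size_k / (size_k + mu_part)
    total = len(econ_pool) + len(non_pool)

    regions = []
    for r in range(config.n_regions):
        abs_lat = rng.uniform(0.0, 70.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        island = bool(rng.random() < config.island_fraction)
        n_r = min(1 + int(rng.negative_binomial(size_k, p_size)), total)
        p_econ = float(expit(config.lat_intercept + config.lat_slope * abs_lat))
        k_econ = int(rng.binomial(n_r, p_econ))
        k_econ = min(max(k_econ, n_r - len(non_pool)), min(n_r, len(econ_pool)))
        members: set[str] = set()
        for pool, lw, k in (
            (econ_pool, lw_econ, k_econ),
            (non_pool, lw_non, n_r - k_econ),
        ):
            if k <= 0 or not pool:
                continue
            keys = lw + rng.gumbel(size=len(pool))
            top = np.argpartition(-keys, k - 1)[:k]
            members.update(pool[j].taxon_id for j in top)
        regions.append(
            Region(
                region_id=f"r{r:04d}",
                latitude=sign * abs_lat,
                island=island,
                taxa=frozenset(members),
                continent=CONTINENTS[int(rng.choice(len(CONTINENTS), p=pcont))],
            )
        )
    return RegionSet(regions=regions)
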