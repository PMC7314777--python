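"""Draw-without-replacement null models and their four applications.

All tests share one logic: an observed statistic is compared with its
distribution over random draws (without replacement) from a reference
pool.  A result is significantly higher/lower when the observed value
falls in (or beyond) the upper/lower 2.5% quantile of the null draws;
the two-sided p-value doubles the smaller tail with +1 smoothing, so
p is never below 1/(n_iter+1).  The standardized effect size (SES) is
(observed - null mean) / null sd.  No multiple-testing correction is
applied anywhere, deliberately.

Applications:

* :func:`resample_count_test` — enrichment of a flag (e.g. naturalized)
  in a focal subset versus random subsets of the same size;
* :func:`category_tests` — per-use-category naturalization counts
  against draws of the flora-wide naturalized total;
* :func:`continent_origin_test` — native-continent composition of the
  economic flora against richness-proportional random floras;
* :func:`pd_ses_test` — Faith's PD of a tip set against random tip sets,
  optionally stratified to preserve the share of economic tips
  (the "use-constrained" null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CONTINENTS, USE_CATEGORIES, TaxonTable, ValidationError
from .phylo import PDIndex, Phylogeny

__all__ = [
    "ResamplingResult",
    "summarize_null",
    "resample_count_test",
    "category_tests",
    "continent_origin_test",
    "pd_ses_test",
    "extrapolate_richness",
]


@dataclass(frozen=True)
class ResamplingResult:
    """Observed statistic, null summary, two-sided p, SES and direction."""

    observed: float
    null_mean: float
    null_sd: float
    null_q025: float
    null_q975: float
    n_iter: int
    p_two_sided: float
    ses: float  # nan when the null is degenerate (sd == 0)
    direction: str  # "higher", "lower" or "ns"
    seed: int
    testable: bool = True
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_q025": self.null_q025,
            "null_q975": self.null_q975,
            "n_iter": self.n_iter,
            "p_two_sided": self.p_two_sided,
            "ses": self.ses,
            "direction": self.direction,
            "seed": self.seed,
            "testable": self.testable,
            "degenerate": self.degenerate,
        }


def summarize_null(
    observed: float, null: np.ndarray, seed: int
) -> ResamplingResult:
    """Build a :class:`ResamplingResult` from an observed value and draws."""
    null = np.asarray(null, dtype=float)
    n_iter = null.size
    r_low = int(np.sum(null <= observed))
    r_high = int(np.sum(null >= observed))
    p = min(1.0, 2.0 * min(r_low + 1, r_high + 1) / (n_iter + 1))
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_iter > 1 else 0.0
    q025 = float(np.quantile(null, 0.025))
    q975 = float(np.quantile(null, 0.975))
    degenerate = sd == 0.0
    if degenerate:
        ses = float("nan")
        if observed > mean:
            direction = "higher"
        elif observed < mean:
            direction = "lower"
        else:
            direction = "ns"
    else:
        ses = (observed - mean) / sd
        # strict inequalities: a value tying the quantile of a discrete
        # null is not called significant
        if observed > q975:
            direction = "higher"
        elif observed < q025:
            direction = "lower"
        else:
            direction = "ns"
    return ResamplingResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        null_q025=q025,
        null_q975=q975,
        n_iter=n_iter,
        p_two_sided=p,
        ses=ses,
        direction=direction,
        seed=seed,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# flag-count enrichment
# ---------------------------------------------------------------------------


def resample_count_test(
    pool_flags, sample_size: int, observed_count: int,
    n_iter: int = 9999, seed: int = 0,
) -> ResamplingResult:
    """Is a flagged count higher/lower than in random same-size draws?

    Each iteration draws ``sample_size`` items without replacement from
    the pool and counts the flagged ones; the count of flagged items in
    such a uniform draw is exactly hypergeometric, which is how the
    null is sampled.
    """
    flags = np.asarray(pool_flags, dtype=bool)
    n_pool = flags.size
    if sample_size > n_pool:
        raise ValidationError(
            f"sample_size {sample_size} exceeds pool size {n_pool}"
        )
    if n_iter < 99:
        raise ValidationError("n_iter must be at least 99")
    n_good = int(flags.sum())
    rng = np.random.default_rng(seed)
    null = rng.hypergeometric(n_good, n_pool - n_good, sample_size, size=n_iter)
    return summarize_null(float(observed_count), null, seed)


# ---------------------------------------------------------------------------
# per-category naturalization tests
# ---------------------------------------------------------------------------


def _draw_subsets(rng, n_pool: int, k: int, n_iter: int, chunk: int = 256):
    """Yield (chunk_size, idx) index arrays for draws of k from n_pool."""
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        keys = rng.random((m, n_pool))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        yield m, idx
        done += m


def category_tests(
    table: TaxonTable,
    single_use_only: bool = False,
    n_iter: int = 9999,
    seed: int = 0,
) -> dict[str, ResamplingResult]:
    """Per-category naturalized counts vs draws of the naturalized total.

    The reference pool is the economic flora (or its single-use subset
    when ``single_use_only``); each iteration draws the pool-wide number
    of naturalized taxa and tabulates the per-category counts of the
    draw.  Categories with no taxa in the pool are flagged not-testable.
    """
    pool = [t for t in table if t.economic]
    if single_use_only:
        pool = [t for t in pool if t.n_uses == 1]
    if not pool:
        raise ValidationError("no economic taxa in table")
    n_pool = len(pool)
    membership = np.zeros((n_pool, len(USE_CATEGORIES)), dtype=bool)
    nat = np.zeros(n_pool, dtype=bool)
    cat_index = {c: j for j, c in enumerate(USE_CATEGORIES)}
    for i, t in enumerate(pool):
        nat[i] = t.naturalized
        for c in t.uses:
            membership[i, cat_index[c]] = True
    k = int(nat.sum())
    observed = membership[nat].sum(axis=0)

    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, len(USE_CATEGORIES)), dtype=np.int64)
    row = 0
    if k > 0:
        for m, idx in _draw_subsets(rng, n_pool, k, n_iter):
            null[row : row + m] = membership[idx].sum(axis=1)
            row += m
    else:
        null[:] = 0

    results: dict[str, ResamplingResult] = {}
    for c, j in cat_index.items():
        if membership[:, j].sum() == 0:
            results[c] = ResamplingResult(
                observed=0.0, null_mean=0.0, null_sd=0.0,
                null_q025=0.0, null_q975=0.0, n_iter=n_iter,
                p_two_sided=1.0, ses=float("nan"), direction="ns",
                seed=seed, testable=False, degenerate=True,
            )
        else:
            results[c] = summarize_null(float(observed[j]), null[:, j], seed)
    return results


# ---------------------------------------------------------------------------
# continental origins
# ---------------------------------------------------------------------------


def extrapolate_richness(known_counts, known_total: int, target_total: int):
    """Scale per-continent counts from a partial checklist to a flora.

    Multiplies each continent's known count by ``target_total /
    known_total`` — the extrapolation used when per-continent richness
    is only known for a subset of all accepted names.
    """
    counts = np.asarray(known_counts, dtype=float)
    if known_total <= 0:
        raise ValidationError("known_total must be positive")
    return counts * (target_total / known_total)


def continent_origin_test(
    table: TaxonTable,
    continent_richness,
    single_native_only: bool = False,
    n_iter: int = 9999,
    seed: int = 0,
) -> dict[str, ResamplingResult]:
    """Native-continent composition of the economic flora vs richness.

    Observed: the number of economic taxa native to each continent
    (a taxon native to several continents counts once per continent,
    unless restricted to single-native taxa).  Null: the same number of
    pseudo-taxa is drawn, each receiving as many distinct native
    continents as a randomly chosen real taxon has, with inclusion
    probabilities proportional to continental richness.
    """
    richness = np.asarray(continent_richness, dtype=float)
    if richness.shape != (len(CONTINENTS),):
        raise ValidationError(f"richness must have length {len(CONTINENTS)}")
    if np.all(richness <= 0):
        raise ValidationError("all-zero continent richness")

    pool = [t for t in table if t.economic and t.native_continents]
    if single_native_only:
        pool = [t for t in pool if len(t.native_continents) == 1]
    if not pool:
        raise ValidationError("no economic taxa with native continents")
    cont_index = {c: j for j, c in enumerate(CONTINENTS)}
    present = sorted({c for t in pool for c in t.native_continents})
    for c in present:
        if richness[cont_index[c]] <= 0:
            raise ValidationError(
                f"continent {c} present in table but has zero richness"
            )

    observed = np.zeros(len(CONTINENTS))
    mults = np.empty(len(pool), dtype=np.int64)
    for i, t in enumerate(pool):
        mults[i] = len(t.native_continents)
        for c in t.native_continents:
            observed[cont_index[c]] += 1

    rng = np.random.default_rng(seed)
    p = richness / richness.sum()
    logw = np.log(np.where(richness > 0, richness, 1e-300))
    n_draw = len(pool)
    null = np.zeros((n_iter, len(CONTINENTS)), dtype=np.int64)
    max_m = int(mults.max())
    for it in range(n_iter):
        m = rng.choice(mults, size=n_draw, replace=True)
        # single-continent pseudo-taxa: a multinomial over richness
        n_single = int(np.sum(m == 1))
        null[it] = rng.multinomial(n_single, p)
        # multi-continent pseudo-taxa: distinct continents via Gumbel top-m
        for mm in range(2, max_m + 1):
            n_mm = int(np.sum(m == mm))
            if n_mm == 0:
                continue
            keys = logw + rng.gumbel(size=(n_mm, len(CONTINENTS)))
            top = np.argpartition(-keys, mm - 1, axis=1)[:, :mm]
            null[it] += np.bincount(top.ravel(), minlength=len(CONTINENTS))

    results: dict[str, ResamplingResult] = {}
    for c, j in cont_index.items():
        if observed[j] == 0 and richness[j] <= 0:
            results[c] = ResamplingResult(
                observed=0.0, null_mean=0.0, null_sd=0.0,
                null_q025=0.0, null_q975=0.0, n_iter=n_iter,
                p_two_sided=1.0, ses=float("nan"), direction="ns",
                seed=seed, testable=False, degenerate=True,
            )
        else:
            results[c] = summarize_null(float(observed[j]), null[:, j], seed)
    return results


# ---------------------------------------------------------------------------
# phylogenetic clustering (Faith's PD)
# ---------------------------------------------------------------------------


def pd_ses_test(
    tree: Phylogeny,
    focal,
    constrain_on: dict | None = None,
    n_iter: int = 999,
    seed: int = 0,
    index: PDIndex | None = None,
) -> ResamplingResult:
    """Faith's-PD SES of a tip set against random tip sets.

    Unconstrained null: uniform draws of ``|focal|`` tips.  Constrained
    null (``constrain_on`` maps every tip label to a boolean stratum,
    e.g. "has an economic use"): every draw contains exactly the
    observed number of focal tips from the flagged stratum.  Clustering
    is indicated by a negative SES with the observed PD at or below the
    lower 2.5% null quantile.
    """
    idx = index if index is not None else PDIndex(tree)
    focal = set(focal)
    if not focal:
        raise ValidationError("focal set is empty")
    unknown = focal - set(idx.tip_ids)
    if unknown:
        raise ValidationError(f"unknown tip ids: {sorted(unknown)}")
    n_tips = idx.n_tips
    k = len(focal)
    observed = idx.pd_of(focal)
    rng = np.random.default_rng(seed)

    if k == n_tips:
        # the only possible draw is the focal set itself
        null = np.full(n_iter, observed)
        res = summarize_null(observed, null, seed)
        return res

    if constrain_on is None:
        selection = uniform_tip_draws(rng, n_iter, n_tips, k)
    else:
        missing = set(idx.tip_ids) - set(constrain_on)
        if missing:
            raise ValidationError(
                f"constrain_on undefined for tips: {sorted(missing)[:5]} ..."
            )
        strat = np.array([bool(constrain_on[t]) for t in idx.tip_ids])
        k_e = sum(1 for t in focal if constrain_on[t])
        selection = stratified_tip_draws(rng, n_iter, strat, k_e, k - k_e)
    null = idx.pd_batch(selection)
    return summarize_null(observed, null, seed)


def uniform_tip_draws(
    rng: np.random.Generator, n_iter: int, n_tips: int, k: int
) -> np.ndarray:
    """Boolean (n_iter, n_tips) matrix of uniform draws of k tips."""
    selection = np.zeros((n_iter, n_tips), dtype=bool)
    keys = rng.random((n_iter, n_tips))
    order = np.argpartition(keys, k - 1, axis=1)[:, :k]
    np.put_along_axis(selection, order, True, axis=1)
    return selection


def stratified_tip_draws(
    rng: np.random.Generator,
    n_iter: int,
    stratum_flags: np.ndarray,
    k_flagged: int,
    k_rest: int,
) -> np.ndarray:
    """Draws with exactly ``k_flagged`` tips from the flagged stratum."""
    flagged = np.flatnonzero(stratum_flags)
    rest = np.flatnonzero(~np.asarray(stratum_flags, dtype=bool))
    if k_flagged > flagged.size or k_rest > rest.size:
        raise ValidationError("constrained stratum smaller than focal stratum")
    selection = np.zeros((n_iter, stratum_flags.size), dtype=bool)
    for part, kk in ((flagged, k_flagged), (rest, k_rest)):
        if kk == 0 or part.size == 0:
            continue
        keys = rng.random((n_iter, part.size))
        order = np.argpartition(keys, kk - 1, axis=1)[:, :kk]
        rows = np.repeat(np.arange(n_iter), kk)
        cols = part[order.ravel()]
        selection[rows, cols] = True
    return selection
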