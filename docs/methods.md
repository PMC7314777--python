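# Methods

This note documents the models implemented in `econatur`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Resampling nulls

All enrichment tests share one scheme. An observed statistic is
compared against `n_iter` draws **without replacement** from a finite
reference pool (taxa are sampled from finite floras, so sampling with
replacement would be wrong in principle and anticonservative in
practice). The two-sided p-value is

```
p = min(1, 2 * min(r_low + 1, r_high + 1) / (n_iter + 1))
```

where `r_low`/`r_high` count null values ≤/≥ the observed one. The +1
smoothing keeps `p ≥ 1/(n_iter + 1)`, i.e. a result can never look more
significant than the number of draws supports. Direction
(`higher`/`lower`/`ns`) is read from the empirical 2.5% and 97.5% null
quantiles using **strict** inequalities: a value that ties the quantile
of a heavily discrete count null is not called significant (with an
inclusive rule, ties produce "significant" calls at p ≈ 0.7). For
continuous statistics such as PD the two rules coincide almost surely.
The standardized effect size is `(observed − null mean) / null sd`
(sample sd, `ddof=1`); it is flagged undefined when the null is
degenerate. No multiple-testing correction is applied anywhere — the
per-category, per-continent and per-flow-cell tests are reported raw,
deliberately.

For the simple flagged-count test, the count of flagged items in a
uniform draw without replacement is exactly hypergeometric, so the null
is sampled from that distribution directly rather than materializing
index draws; the tests check it against brute-force enumeration of all
subsets of a small pool. Category and flow tests need joint counts and
do materialize index draws (vectorized argpartition of random keys).

The continental-origin null assigns each pseudo-taxon as many distinct
native continents as a randomly chosen real taxon has, with inclusion
probabilities proportional to the continental-richness vector (Gumbel
top-k for multi-continent pseudo-taxa). Richness known only for a
subset of names is scaled up with `extrapolate_richness` (a plain
ratio). The flow null conditions on recipients: for each recipient
continent it redraws the observed number of naturalized economic taxa
from the economic pool and tabulates their donors, so recipient taxon
totals are fixed and only donor composition varies. A taxon may be
drawn for several recipients, as real taxa naturalize on several
continents. Note that when taxa can be native to several continents the
*column sums* of a null draw vary slightly around the observed ones
(they are sums of native-set sizes of the drawn taxa); with
single-native pools they are exactly fixed.

## Trees, grafting, Faith's PD

Trees are rooted, ultrametric, branch lengths in myr. A taxon missing
from a published tree but with congeneric tips is attached at the
**crown node** (MRCA) of its genus with a pendant branch equal to that
node's height, so the tip reaches the present and ultrametricity is
preserved; if the genus is absent, the family crown is used; if the
family is absent the taxon is returned in an "unplaced" report rather
than dropped silently. A genus represented by a single tip has no crown
node, so one is created halfway along that tip's pendant edge.
Attachment points are resolved from the original tips only, making the
result independent of table order. Pendant lengths for grafted taxa are
a modelling choice, not data; SES-based downstream tests compare
observed and null sets on the *same* grafted tree, so the choice
cancels to first order.

Faith's PD uses the rooted convention (the spanning subtree always
includes the root): PD of a single tip is its depth, PD of all tips is
the total branch length, and PD is monotone and subadditive under set
union. Both observed and null sets use the same convention, so SES
results do not depend on it. For the nulls, the tree is compiled once
into postorder arrays and all `n_iter` tip sets are propagated up the
tree as a boolean matrix (`PDIndex.pd_batch`), which makes 10³ draws on
10³–10⁴-tip trees interactive.

The use-constrained null draws, in every iteration, exactly the
observed number of economic tips from the economic stratum and the
remainder from the rest. If economic membership explains part of the
focal set's clustering, the constrained null distribution shifts toward
the observed PD and the |SES| shrinks — the size of the shift measures
how much of the clustering the cultivated flora accounts for.

## Regressions

* Binomial GLM (logit link) is fitted by IRLS via statsmodels; the
  module surface adds design-rank and separation checks (coefficients
  diverging past |β| > 30 raise a `SeparationError` naming the worst
  column). The quasi-binomial variant estimates the dispersion
  φ = Pearson χ²/df, multiplies standard errors by √φ and tests with t
  statistics on the residual df; point estimates are untouched.
* The pairwise-use model restricts to taxa with ≤ 2 uses and fits an
  intercept (no-use baseline), one indicator per category, and one
  indicator per observed two-use combination with ≥ `min_count`
  (default 10) taxa; sparser combinations are dropped from the design
  and reported. Net effects (β_c + β_d + γ_cd) are emitted alongside.
* The regional latitude model is a quasi-binomial GLM of
  (economic, non-economic) counts per region on |latitude| × island,
  so large floras carry more weight. With a single island class the
  island terms are dropped with a warning. Absolute latitude is used;
  hemisphere is not a covariate.
* Siegel repeated-medians regression: scipy's `siegelslopes`
  (hierarchical method — per-point medians of pairwise slopes, median
  of medians, intercept as median of `y − slope·x`, zero-Δx pairs
  skipped), checked against a brute-force enumeration. Association
  significance is a Kendall-tau test; the package does not reproduce
  any package-specific Wilcoxon-type summary statistic, whose
  construction is not defined by a formula we could implement.
* PGLS assumes Brownian residuals: V[i,j] = shared root-to-MRCA path
  length, closed-form GLS through a Cholesky solve, t statistics on
  n − p df. On a star tree V ∝ I and PGLS reduces to OLS; rescaling all
  branch lengths leaves coefficients unchanged. Phylogenetic *logistic*
  regression is intentionally not implemented: the resampling tests and
  PGLS carry the inferential load, and penalized phylogenetic logistic
  likelihood would be out of proportion to its role as a robustness
  check.

## The synthetic world

The generator produces floras whose joint structure matches what the
analyses assume, with every parameter known:

* **Tree** — forward birth–death simulation (default pure birth at
  0.1 events/myr) stopped when the target tip count is reached, plus
  one extra exponential waiting time so the youngest cherry has
  positive pendant length; repeated extinction raises an error after
  100 attempts. Genera and families are monophyletic by construction:
  the tree is cut by refining clades from the root until the requested
  numbers of family and genus clades exist, so every genus falls in
  exactly one family.
* **Economic status** — a latent trait `z = λ·BM + (1−λ)·ε` (Brownian
  motion standardized to unit tip variance, independent standard
  normal noise) thresholded at the top `q_e` quantile. λ = 0 gives an
  exact uniform null for the clustering tests; λ = 1 forces clustering.
  Default λ = 0.8, `q_e` = 0.10 — a deliberately enriched scaled-down
  world (the real economic share of the global flora is ~3.6%, which at
  a few thousand taxa would leave categories nearly empty).
* **Uses** — per-taxon use count 1 + Poisson(mean − 1) capped at 12
  (default mean 1.45, matching a single-use share around 70%);
  identities drawn by Gumbel-perturbed scores combining the category
  weight vector (proportional to the published per-category taxon
  counts) and a category-specific Brownian trait, so individual
  categories are phylogenetically clustered too.
* **Naturalization** — Bernoulli with
  `logit p = β₀ + Σ β_c x_c + Σ_{c<d} γ_cd x_c x_d`. Default β₀ = −3.75
  (the ~2.3% background rate), per-category β between 0.5 (gene
  sources) and 2.2 (environmental), mirroring the reported ordering of
  category success. Default γ = −1 for every pair: diminishing returns
  of additional uses, with a magnitude on the order of the coefficient
  standard error at realistic pair counts — a world with much weaker
  interactions would make the reported all-negative interaction pattern
  statistically invisible at any feasible sample size.
* **Extent** — naturalized taxa receive `1 + NB(size, μ)` regions, with
  μ = 8 for economic and μ = 3 for non-economic taxa (the two observed
  medians), and μ rising by `exp(0.25)` per use beyond the first so the
  extent-vs-uses trend that the Siegel regression targets exists in the
  generator.
* **Ranges** — native continents drawn from a richness vector (rough
  real-world proportions; Antarctica near zero but positive), 32.8% of
  taxa multi-continent, 1.7% of economic taxa cultivation-only (empty
  native set).
* **Regions** — |latitude| ~ U(0, 70) with random hemisphere, island
  flag at 37%; flora size 1 + NB(mean 30), membership drawn per region
  independently, weighted by each taxon's extent, with the expected
  economic share following `logit⁻¹(1.1 − 0.02·|lat|)` (≈75% at the
  equator falling to ≈50% at high latitude). Region floras must
  subsample the naturalized pool — if regions swallow the whole pool,
  every regional share collapses to the global share and the trend
  cannot express itself; the defaults keep regional floras a small
  minority of the pool, as in the real data.
* **Published-tree sampling** — ~20.5% of taxa are removed individually
  (always leaving a congener) and ~1.3% by dropping whole small genera,
  reproducing the grafting workload of a real backbone tree.

What the generator does **not** emulate: spatial autocorrelation among
regions (regions are independent draws, as the regional GLM assumes),
residence times or any propagule-pressure covariate (use effects act
directly on naturalization probability — an interpretation, since no
taxon-level pressure data exist at this scale), taxonomy noise
(synonyms, infraspecific duplicates), and clade-specific diversification.
Passing tests therefore demonstrate that the pipeline recovers known
structure of this idealized world, not that the real data meet these
assumptions.

Determinism: every generator and test takes a seed; the pipeline
derives per-stage seeds by hashing the stage name with the master seed
(sha256, reduced below 2³¹), so disabling one stage never shifts
another's stream, and reruns are byte-identical.

## Problem sizes and numerical choices

The bundled tests and the acceptance script run on scaled worlds chosen
to give each check adequate statistical resolution: 12-tip trees for
exact PD oracles, 2,000-tip trees (100 replicates) for clustering
power/calibration, 1,000-tip trees (50 replicates) for the constrained-
null shift, 20,000 taxa / 500 regions for latitude-slope recovery,
50,000 taxa for pairwise-interaction sign recovery, and 999–9,999
resampling iterations. IRLS runs to relative tolerance 1e-8 (max 100
iterations); ultrametricity is asserted at relative tolerance 1e-9 for
generated trees and 1e-6 after I/O round trips; newick serialization is
canonical with 10 significant digits.

Known limitations: the canonicalizer is a heuristic normalizer (it
strips authorities and hybrid signs and normalizes rank markers), not a
nomenclatural resolver — it treats infraspecific taxa as distinct and
does not consult any checklist; the origin null approximates the
multi-continent membership process rather than resampling real
membership vectors from a 326k-taxon checklist; and the flow null's
recipient conditioning is one of two defensible conventions (donor
conditioning being the other) — it was chosen because the comparison of
interest is donor composition given how many taxa each continent
received.
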