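"""Regression machinery for the naturalization analyses.

Covers the model families used downstream:

* binomial GLM with logit link, plain or quasi-binomial (Pearson
  dispersion, scaled standard errors, t statistics);
* naturalization ~ number of economic uses (logistic);
* the pairwise-use model: main effects for the 12 categories plus an
  interaction indicator per observed two-use combination, fitted on
  taxa with at most two uses;
* Kendall-Theil-Sen-Siegel repeated-medians regression (robust line
  fit for naturalization extent vs number of uses);
* phylogenetic generalized least squares under a Brownian-motion
  covariance (shared root-to-MRCA path lengths).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps
import statsmodels.api as sm

from .core import USE_CATEGORIES, TaxonTable, ValidationError
from .phylo import Phylogeny

__all__ = [
    "RegressionResult",
    "SeparationError",
    "fit_binomial_glm",
    "fit_use_count_model",
    "fit_pairwise_use_glm",
    "siegel_regression",
    "fit_pgls",
]


class SeparationError(RuntimeError):
    """Raised when a logistic fit diverges (perfect separation)."""


@dataclass
class RegressionResult:
    """Named coefficients with uncertainties and fit diagnostics."""

    coefficients: dict
    standard_errors: dict
    test_statistics: dict
    p_values: dict
    dispersion: float
    df_residual: int
    converged: bool
    n_obs: int
    stat_kind: str = "z"  # "z" (binomial) or "t" (quasi / PGLS)
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "term": k,
                "estimate": self.coefficients[k],
                "se": self.standard_errors[k],
                "stat": self.test_statistics[k],
                "p": self.p_values[k],
            }
            for k in self.coefficients
        ]
        return pd.DataFrame.from_records(
            recs, columns=["term", "estimate", "se", "stat", "p"]
        )


def _check_design(X: np.ndarray, names) -> None:
    if X.shape[0] <= X.shape[1]:
        raise ValidationError(
            f"need more observations ({X.shape[0]}) than columns ({X.shape[1]})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(
            f"design matrix rank deficient (rank {rank} < {X.shape[1]} columns: "
            f"{list(names)})"
        )


def fit_binomial_glm(
    y, X, quasi: bool = False, names=None
) -> RegressionResult:
    """Logit-link binomial GLM (IRLS via statsmodels).

    ``y`` is a binary vector or an (n, 2) array of (successes,
    failures) per row.  With ``quasi=True`` the dispersion is the
    Pearson chi-square divided by the residual degrees of freedom,
    standard errors are inflated by its square root and inference uses
    t statistics on the residual df; point estimates are unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    _check_design(X, names)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 30:
        worst = names[int(np.argmax(np.abs(params)))]
        raise SeparationError(
            f"logistic fit diverged (suspected perfect separation on {worst!r})"
        )
    df_resid = int(res.df_resid)
    phi = float(res.pearson_chi2) / df_resid if df_resid > 0 else float("nan")
    cov = np.asarray(res.cov_params(), dtype=float)
    se = np.sqrt(np.diag(cov))
    if quasi:
        se = se * np.sqrt(phi)
        stat = params / se
        p = 2.0 * sps.t.sf(np.abs(stat), df_resid)
        kind = "t"
        dispersion = phi
    else:
        stat = params / se
        p = 2.0 * sps.norm.sf(np.abs(stat))
        kind = "z"
        dispersion = 1.0
    return RegressionResult(
        coefficients=dict(zip(names, params)),
        standard_errors=dict(zip(names, se)),
        test_statistics=dict(zip(names, stat)),
        p_values=dict(zip(names, p)),
        dispersion=dispersion,
        df_residual=df_resid,
        converged=bool(getattr(res, "converged", True)),
        n_obs=int(X.shape[0]),
        stat_kind=kind,
        extras={"pearson_dispersion": phi},
    )


def fit_use_count_model(table: TaxonTable) -> RegressionResult:
    """Logistic regression of naturalization on the number of uses.

    Fitted over the economic taxa only (every row has at least one
    use), mirroring an analysis of naturalization incidence against
    the count of distinct main-category uses.
    """
    econ = table.economic()
    n_uses = np.array([t.n_uses for t in econ], dtype=float)
    if n_uses.size == 0 or np.all(n_uses == n_uses[0]):
        raise ValidationError("n_uses is constant; slope not identifiable")
    y = np.array([t.naturalized for t in econ], dtype=float)
    X = np.column_stack([np.ones_like(n_uses), n_uses])
    return fit_binomial_glm(y, X, names=["intercept", "n_uses"])


def fit_pairwise_use_glm(
    table: TaxonTable, min_count: int = 10
) -> RegressionResult:
    """Naturalization vs single uses and two-use combinations.

    Restricted to taxa with at most two uses.  The design holds an
    intercept (no-use baseline), one indicator per category, and one
    indicator per observed two-use combination with at least
    ``min_count`` taxa; sparser combinations are dropped from the
    design and reported in ``extras['dropped_pairs']``.  The net effect
    of a pair (sum of the two main effects and the interaction) is
    reported in ``extras['net_effects']``.
    """
    subset = [t for t in table if t.n_uses <= 2]
    y = np.array([t.naturalized for t in subset], dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise ValidationError("subset with <=2 uses lacks outcome variation")

    main = np.zeros((len(subset), len(USE_CATEGORIES)))
    cat_index = {c: j for j, c in enumerate(USE_CATEGORIES)}
    pair_counts: dict[tuple[str, str], int] = {}
    for i, t in enumerate(subset):
        for c in t.uses:
            main[i, cat_index[c]] = 1.0
        if t.n_uses == 2:
            pair = tuple(sorted(t.uses))
            pair_counts[pair] = pair_counts.get(pair, 0) + 1

    kept_pairs = sorted(p for p, n in pair_counts.items() if n >= min_count)
    dropped = sorted(p for p, n in pair_counts.items() if n < min_count)
    cols = [np.ones(len(subset))]
    names = ["intercept"]
    used_cats = [c for c in USE_CATEGORIES if main[:, cat_index[c]].any()]
    for c in used_cats:
        cols.append(main[:, cat_index[c]])
        names.append(c)
    for a, b in kept_pairs:
        cols.append(main[:, cat_index[a]] * main[:, cat_index[b]])
        names.append(f"{a}:{b}")
    X = np.column_stack(cols)
    if X.shape[1] <= 1:
        raise ValidationError("empty design after filtering")
    res = fit_binomial_glm(y, X, names=names)
    net = {}
    for a, b in kept_pairs:
        net[f"{a}:{b}"] = (
            res.coefficients[a]
            + res.coefficients[b]
            + res.coefficients[f"{a}:{b}"]
        )
    res.extras["net_effects"] = net
    res.extras["dropped_pairs"] = [f"{a}:{b}" for a, b in dropped]
    res.extras["pair_terms"] = [f"{a}:{b}" for a, b in kept_pairs]
    return res


def siegel_regression(x, y) -> dict:
    """Repeated-medians (Siegel) line fit with a Kendall-tau p-value.

    For each point i, take the median of the pairwise slopes to all
    other points (skipping ties in x); the slope is the median of those
    per-point medians, and the intercept the median of ``y - slope*x``.
    Association significance comes from Kendall's tau between x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValidationError("x is constant")
    slope, intercept = sps.siegelslopes(y, x, method="hierarchical")
    tau, tau_p = sps.kendalltau(x, y)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "tau": float(tau),
        "tau_p": float(tau_p),
        "n": int(x.size),
    }


def _brownian_covariance(tree: Phylogeny, order) -> np.ndarray:
    """V[i, j] = shared root-to-MRCA path length of tips i and j."""
    tips = {n.label: n for n in tree.tips()}
    missing = [lab for lab in order if lab not in tips]
    if missing:
        raise ValidationError(f"tips not in tree: {missing[:5]}")
    depth = tree.depths_from_root()
    pos = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    V = np.zeros((n, n))
    # accumulate per internal node: pairs of tips split across children
    # share that node as (at least) an ancestor; processing nodes
    # root-to-tip overwrites with the true MRCA depth.
    node_tips: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            if node.label in pos:
                node_tips[id(node)] = [pos[node.label]]
            else:
                node_tips[id(node)] = []
        else:
            node_tips[id(node)] = [
                i for c in node.children for i in node_tips[id(c)]
            ]
    for node in tree.preorder():
        if node.is_tip:
            continue
        d = depth[node]
        kids = [node_tips[id(c)] for c in node.children]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                if kids[a] and kids[b]:
                    V[np.ix_(kids[a], kids[b])] = d
                    V[np.ix_(kids[b], kids[a])] = d
    for lab, i in pos.items():
        V[i, i] = depth[tips[lab]]
    return V


def fit_pgls(y, X, tree: Phylogeny, tip_order, names=None) -> RegressionResult:
    """GLS with Brownian covariance from the tree (closed form).

    ``tip_order`` gives the tip label for each row of ``y``/``X``.
    Standard errors use the residual-based estimate of the Brownian
    rate; t statistics are on n - p degrees of freedom.  Coefficients
    are invariant to rescaling all branch lengths.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    _check_design(X, names)
    V = _brownian_covariance(tree, list(tip_order))
    try:
        c, low = linalg.cho_factor(V)
    except np.linalg.LinAlgError as e:
        raise ValidationError(f"singular Brownian covariance: {e}") from e
    Vi_X = linalg.cho_solve((c, low), X)
    Vi_y = linalg.cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    Vi_r = linalg.cho_solve((c, low), resid)
    n, p = X.shape
    sigma2 = float(resid @ Vi_r) / (n - p)
    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    stat = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(stat), n - p)
    return RegressionResult(
        coefficients=dict(zip(names, beta)),
        standard_errors=dict(zip(names, se)),
        test_statistics=dict(zip(names, stat)),
        p_values=dict(zip(names, pvals)),
        dispersion=sigma2,
        df_residual=n - p,
        converged=True,
        n_obs=n,
        stat_kind="t",
    )
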