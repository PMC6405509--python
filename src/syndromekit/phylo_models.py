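"""Phylogenetic generalized least squares with ML Pagel's lambda.

Population-level responses (trait means, or per-population Fisher-z
covariations) are regressed on environmental predictors while the residual
covariance follows the population tree: V(lambda) multiplies the
off-diagonal shared-path covariances by lambda in [0, 1], leaving the
diagonal untouched.  lambda = 0 recovers ordinary least squares; lambda = 1
is the full Brownian expectation.  Environmental candidate models are ranked
by AIC with a delta-AIC < 4 best set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)


def tree_to_cov(tree: dendropy.Tree, populations: list[str] | None = None):
    """Brownian covariance matrix implied by the tree.

    C[i, j] is the shared path length from the root to the most recent common
    ancestor of tips i and j; C[i, i] is the root-to-tip depth.  The tree is
    taken as rooted at its seed node (for complete-linkage dendrograms this
    is the deepest merge).  Returns (labels, C) with labels sorted
    lexicographically.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if populations is not None:
        extra = sorted(set(labels) - set(populations))
        absent = sorted(set(populations) - set(labels))
        if extra or absent:
            raise ValueError(
                f"tree/population mismatch: extra tips {extra}, missing tips {absent}"
            )
    pdm = {}
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    n = len(labels)
    C = np.zeros((n, n))
    mrca_depth = _pairwise_mrca_depths(tree)
    for i, a in enumerate(labels):
        C[i, i] = leaves[a].root_distance
        for j in range(i + 1, n):
            b = labels[j]
            C[i, j] = C[j, i] = mrca_depth[frozenset((a, b))]
    return labels, C


def _pairwise_mrca_depths(tree: dendropy.Tree) -> dict:
    """Depth (root distance) of the MRCA of every tip pair."""
    out = {}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) < 2:
            continue
        depth = node.root_distance
        leaf_sets = [
            {lf.taxon.label for lf in ch.leaf_iter()} for ch in children
        ]
        for i in range(len(leaf_sets)):
            for j in range(i + 1, len(leaf_sets)):
                for a in leaf_sets[i]:
                    for b in leaf_sets[j]:
                        out[frozenset((a, b))] = depth
    return out


@dataclass
class PglsFit:
    lambda_: float
    beta: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    lambda_p: float
    n: int
    k: int
    lambda_identifiable: bool = True
    names: list = field(default_factory=list)


def _v_lambda(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C.copy()
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls_profile_loglik(y, X, V):
    """ML log-likelihood of the GLS model with sigma^2 profiled out.
    Returns (loglik, beta, sigma2)."""
    n = len(y)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf, None, None
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    A = XtVi @ X
    try:
        beta = np.linalg.solve(A, XtVi @ y)
    except np.linalg.LinAlgError:
        raise ValueError("singular design matrix in GLS")
    r = y - X @ beta
    sigma2 = float(r @ Vi @ r) / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return ll, beta, sigma2


def pgls_fit(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    lambda_: float | None = None,
    boundary_halved_p: bool = False,
    names: list | None = None,
) -> PglsFit:
    """Fit PGLS with Pagel's lambda estimated by profile ML on [0, 1].

    *X* must include the intercept column.  When *lambda_* is given it is
    held fixed.  The lambda p-value is a likelihood-ratio test against
    lambda = 0 on chi-square(1) (optionally with the halved boundary p).
    AIC counts the fixed coefficients plus sigma^2 and lambda.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("y/X length mismatch")
    if n < X.shape[1] + 2:
        raise ValueError("too few populations for the design")

    def ll_at(lam):
        return _gls_profile_loglik(y, X, _v_lambda(C, lam))[0]

    ll0 = ll_at(0.0)
    if lambda_ is not None:
        lam_hat = float(lambda_)
        ll_hat = ll_at(lam_hat)
    else:
        res = optimize.minimize_scalar(
            lambda lam: -ll_at(lam), bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-8},
        )
        candidates = [(ll0, 0.0), (ll_at(1.0), 1.0), (-res.fun, float(res.x))]
        ll_hat, lam_hat = max(candidates, key=lambda t: t[0])
    ll_hat_final, beta, sigma2 = _gls_profile_loglik(y, X, _v_lambda(C, lam_hat))
    k = X.shape[1] + 2
    aic = -2.0 * ll_hat_final + 2 * k
    lrt = max(0.0, 2.0 * (ll_hat_final - ll0))
    lambda_p = float(stats.chi2.sf(lrt, 1))
    if boundary_halved_p:
        lambda_p = lambda_p / 2.0 if lrt > 0 else 1.0
    identifiable = not math.isclose(ll_at(1.0), ll0, abs_tol=1e-8) or abs(
        ll_at(0.5) - ll0
    ) > 1e-8
    return PglsFit(
        lambda_=lam_hat, beta=beta, sigma2=sigma2, loglik=ll_hat_final,
        aic=aic, lambda_p=lambda_p, n=n, k=k,
        lambda_identifiable=bool(identifiable),
        names=list(names) if names else [f"b{i}" for i in range(X.shape[1])],
    )


def fit_lambda_only(y: np.ndarray, C: np.ndarray, **kw) -> PglsFit:
    """Intercept-only PGLS: the phylogenetic-conservatism (lambda) estimate
    for one population-level quantity.  Degenerate (constant) responses give
    lambda = 0 flagged non-identifiable."""
    y = np.asarray(y, dtype=float)
    if np.allclose(y, y[0]):
        log.warning("constant response: lambda not identifiable")
        return PglsFit(
            lambda_=0.0, beta=np.array([y[0]]), sigma2=0.0, loglik=np.inf,
            aic=-np.inf, lambda_p=1.0, n=len(y), k=3,
            lambda_identifiable=False, names=["intercept"],
        )
    X = np.ones((len(y), 1))
    return pgls_fit(y, X, C, names=["intercept"], **kw)


MODEL_SET = (
    "null",
    "temperature",
    "predation",
    "temperature+predation",
    "temperature*predation",
)


def _design(model: str, temp: np.ndarray, pred: np.ndarray):
    one = np.ones_like(temp)
    if model == "null":
        return np.column_stack([one]), ["intercept"]
    if model == "temperature":
        return np.column_stack([one, temp]), ["intercept", "temperature"]
    if model == "predation":
        return np.column_stack([one, pred]), ["intercept", "predation"]
    if model == "temperature+predation":
        return (np.column_stack([one, temp, pred]),
                ["intercept", "temperature", "predation"])
    if model == "temperature*predation":
        return (np.column_stack([one, temp, pred, temp * pred]),
                ["intercept", "temperature", "predation", "temperature:predation"])
    raise ValueError(f"unknown model {model!r}")


def model_selection(
    y: np.ndarray,
    env: pd.DataFrame,
    C: np.ndarray,
    populations: list[str],
    delta_aic_threshold: float = 4.0,
) -> pd.DataFrame:
    """Fit the five-candidate environmental model set by lambda-ML PGLS and
    rank by AIC.

    Candidates: null; temperature; predation; temperature+predation;
    temperature*predation (with main effects).  Returns a table with one row
    per model: aic, delta_aic, in_best_set (delta < threshold), lambda, and
    fitted coefficients.  *y* is ordered like *populations*, which must match
    the rows of *env* and the tree labels behind *C*.
    """
    env = env.set_index("population_id").loc[list(populations)]
    temp = env["temperature"].to_numpy(float)
    pred = env["predation"].to_numpy(float)
    if np.allclose(np.corrcoef(temp, pred)[0, 1] ** 2, 1.0):
        raise ValueError("temperature and predation are collinear")
    rows = []
    for model in MODEL_SET:
        X, names = _design(model, temp, pred)
        fit = pgls_fit(y, X, C, names=names)
        rows.append(
            {
                "model": model,
                "aic": fit.aic,
                "lambda": fit.lambda_,
                "loglik": fit.loglik,
                "k": fit.k,
                "coef": dict(zip(names, fit.beta)),
            }
        )
    tab = pd.DataFrame(rows)
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    tab["in_best_set"] = tab["delta_aic"] < delta_aic_threshold
    return tab
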