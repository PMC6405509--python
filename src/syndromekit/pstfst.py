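"""P_ST estimation and the P_ST vs F_ST drift test.

P_ST is the phenotypic analogue of Q_ST for wild populations:
sigma2_B / (sigma2_B + sigma2_W), the among-population share of trait
variance, estimated by REML from a random-intercept mixed model.  For a
trait *covariation*, the model gains a random slope of the covariable trait
per population, and sigma2_B is the among-population variance of that slope
(sigma2_W the residual variance), so P_ST measures how much the covariation
itself differs among populations.

A P_ST credibly above the neutral-marker F_ST indicates differentiation
beyond genetic drift (selection and/or plasticity); cluster-bootstrap CIs on
both sides make the comparison.  No heritability scaling is applied: P_ST
deliberately mixes genetic and developmental components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import TRAITS
from .popgen import FstResult

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    sigma2_between: float
    sigma2_within: float
    converged: bool = True
    boundary: bool = False

    def pst(self) -> float:
        return pst(self)


def pst(vc: VarianceComponents) -> float:
    """sigma2_B / (sigma2_B + sigma2_W)."""
    tot = vc.sigma2_between + vc.sigma2_within
    if tot <= 0:
        raise ValueError("degenerate: both variance components are zero")
    return vc.sigma2_between / tot


# ---------------------------------------------------------------------------
# random-intercept REML (trait P_ST)


def varcomp_intercept(y: np.ndarray, pops: np.ndarray) -> VarianceComponents:
    """REML variance components of y_ij = mu + b_j + e_ij, b ~ N(0, s2B),
    e ~ N(0, s2W).

    The restricted likelihood is profiled down to the single variance ratio
    gamma = s2B/s2W, which is maximised on a log grid + bounded refinement;
    the inner GLS step is closed-form.
    """
    y = np.asarray(y, dtype=float)
    pops = np.asarray(pops)
    ok = np.isfinite(y)
    y, pops = y[ok], pops[ok]
    labels, inv = np.unique(pops, return_inverse=True)
    G = len(labels)
    if G < 2:
        raise ValueError("need >= 2 populations")
    n_j = np.bincount(inv).astype(float)
    if np.any(n_j < 2):
        small = labels[n_j < 2]
        raise ValueError(f"populations with < 2 observations: {list(small)}")
    ybar_j = np.bincount(inv, weights=y) / n_j
    ss_j = np.bincount(inv, weights=y * y) - n_j * ybar_j**2
    return _varcomp_intercept_stats(n_j, ybar_j, float(np.sum(ss_j)))


def _varcomp_intercept_stats(
    n_j: np.ndarray, ybar_j: np.ndarray, ss_within: float
) -> VarianceComponents:
    """Profile-REML fit from the per-population sufficient statistics
    (group sizes, group means, total within-group sum of squares)."""
    N = float(np.sum(n_j))

    def neg2_profile(log_gamma: float) -> float:
        g = math.exp(log_gamma)
        d = 1.0 + n_j * g
        wj = n_j / d
        mu = np.sum(wj * ybar_j) / np.sum(wj)
        rss = ss_within + float(np.sum(wj * (ybar_j - mu) ** 2))
        return (
            (N - 1) * math.log(rss)
            + float(np.sum(np.log(d)))
            + math.log(float(np.sum(wj)))
        )

    # coarse log-scale grid then bounded refinement around the best knot
    grid = np.linspace(-14, 10, 49)
    vals = [neg2_profile(t) for t in grid]
    i = int(np.argmin(vals))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(
        neg2_profile, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    gamma = math.exp(float(res.x))
    # boundary check: gamma -> 0
    if neg2_profile(-30.0) <= res.fun + 1e-12:
        gamma = 0.0
    d = 1.0 + n_j * gamma
    wj = n_j / d
    mu = np.sum(wj * ybar_j) / np.sum(wj)
    rss = ss_within + float(np.sum(wj * (ybar_j - mu) ** 2))
    s2w = rss / (N - 1)
    return VarianceComponents(
        sigma2_between=gamma * s2w, sigma2_within=s2w, boundary=(gamma == 0.0)
    )


# ---------------------------------------------------------------------------
# random-slope REML (covariation P_ST)


def _group_suffstats(y, x, inv, G):
    """Stacked per-group sufficient statistics for Z = [1, x] (the fixed
    design equals the random design): A = Z'Z (G,2,2), Zty (G,2), yty (G,)."""
    ones = np.ones_like(x)
    n_j = np.bincount(inv, minlength=G).astype(float)
    sx = np.bincount(inv, weights=x, minlength=G)
    sxx = np.bincount(inv, weights=x * x, minlength=G)
    sy = np.bincount(inv, weights=y, minlength=G)
    sxy = np.bincount(inv, weights=x * y, minlength=G)
    syy = np.bincount(inv, weights=y * y, minlength=G)
    A = np.empty((G, 2, 2))
    A[:, 0, 0] = n_j
    A[:, 0, 1] = A[:, 1, 0] = sx
    A[:, 1, 1] = sxx
    Zty = np.stack([sy, sxy], axis=1)
    return A, Zty, syy


def _reml_slope_pieces(Gam, A, Zty, yty):
    """GLS building blocks for the random intercept+slope model at a given
    Gamma = Psi / s2W, via batched 2x2 Woodbury algebra.

    Returns (sum log det(I + Gamma A_j), SXX, SXy, Syy) or None when some
    det(I + Gamma A_j) <= 0.
    """
    M = np.eye(2)[None] + A @ Gam                      # I + A Gamma, per group
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    if np.any(det <= 1e-300):
        return None
    Minv = np.empty_like(M)
    Minv[:, 0, 0] = M[:, 1, 1]
    Minv[:, 1, 1] = M[:, 0, 0]
    Minv[:, 0, 1] = -M[:, 0, 1]
    Minv[:, 1, 0] = -M[:, 1, 0]
    Minv /= det[:, None, None]
    K = Gam[None] @ Minv                               # Gamma (I + A Gamma)^-1
    AK = A @ K
    SXX = np.sum(A - AK @ A, axis=0)
    SXy = np.sum(Zty - np.einsum("gij,gj->gi", AK, Zty), axis=0)
    Syy = float(np.sum(yty) - np.einsum("gi,gij,gj->", Zty, K, Zty))
    return float(np.sum(np.log(det))), SXX, SXy, Syy


def _neg2_reml_slope(theta, A, Zty, yty, N):
    """-2 restricted log-likelihood (up to a constant) for the random
    intercept+slope model, with residual variance profiled out.

    theta parameterises Gamma = Psi/s2W via its Cholesky factor
    [[l11, 0], [l21, l22]].
    """
    l11, l21, l22 = theta
    L = np.array([[l11, 0.0], [l21, l22]])
    Gam = L @ L.T
    p = 2
    pieces = _reml_slope_pieces(Gam, A, Zty, yty)
    if pieces is None:
        return np.inf
    ld, SXX, SXy, Syy = pieces
    sign, ld_xx = np.linalg.slogdet(SXX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(SXX, SXy)
    rss = Syy - float(beta @ SXy)
    if rss <= 0:
        return np.inf
    return ld + ld_xx + (N - p) * math.log(rss / (N - p))


def varcomp_slope(
    y: np.ndarray, x: np.ndarray, pops: np.ndarray
) -> VarianceComponents:
    """REML variance components of the random-slope model

        y_ij = b0 + b1 x_ij + u0_j + u1_j x_ij + e_ij,
        (u0, u1) ~ N(0, Psi) correlated, e ~ N(0, s2W).

    sigma2_between is Var(u1), the among-population variance of the slope of
    y on x; sigma2_within is the residual variance.  Optimised over the
    Cholesky factor of Psi/s2W from three fixed start points; a near-zero
    slope variance at the optimum is flagged as a boundary fit.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    pops = np.asarray(pops)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x, pops = y[ok], x[ok], pops[ok]
    labels, inv = np.unique(pops, return_inverse=True)
    G = len(labels)
    if G < 3:
        raise ValueError("need >= 3 populations for a random slope")
    for j, lab in enumerate(labels):
        if np.var(x[inv == j]) <= 0:
            raise ValueError(f"no variance in covariable within population {lab}")
    A, Zty, yty = _group_suffstats(y, x, inv, G)
    vc, _theta = _varcomp_slope_stats(A, Zty, yty)
    return vc


def _varcomp_slope_stats(
    A: np.ndarray, Zty: np.ndarray, yty: np.ndarray, starts=None
) -> tuple[VarianceComponents, np.ndarray]:
    """Random-slope REML fit from stacked per-population sufficient
    statistics; returns the components and the optimal Cholesky parameters
    (reusable as a warm start for bootstrap refits)."""
    N = float(A[:, 0, 0].sum())
    if starts is None:
        starts = ((0.3, 0.0, 0.3), (0.05, 0.0, 0.05))
    best = None
    for start in starts:
        res = optimize.minimize(
            _neg2_reml_slope, np.asarray(start, float), args=(A, Zty, yty, N),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    l11, l21, l22 = best.x
    L = np.array([[l11, 0.0], [l21, l22]])
    Gam = L @ L.T
    # residual variance at the optimum
    _, SXX, SXy, Syy = _reml_slope_pieces(Gam, A, Zty, yty)
    beta = np.linalg.solve(SXX, SXy)
    s2w = (Syy - float(beta @ SXy)) / (N - 2)
    s2_slope = Gam[1, 1] * s2w
    boundary = Gam[1, 1] < 1e-8
    if boundary:
        log.info("random-slope variance at boundary (~0)")
    vc = VarianceComponents(
        sigma2_between=float(s2_slope),
        sigma2_within=float(s2w),
        converged=bool(best.success or best.fun < np.inf),
        boundary=bool(boundary),
    )
    return vc, np.asarray(best.x, float)


# ---------------------------------------------------------------------------
# P_ST with cluster bootstrap


def standardize_global(t: pd.DataFrame, traits=TRAITS) -> pd.DataFrame:
    """Grand-mean z-scores of the transformed traits (mean 0, SD 1 across all
    individuals).  Used for covariation P_ST so slopes are on a correlation
    scale while keeping the among-population signal the random effects need."""
    out = t.copy()
    for trait in traits:
        v = out[trait].astype(float)
        out[trait] = (v - v.mean()) / v.std(ddof=1)
    return out


@dataclass
class PstResult:
    pst: float
    ci_low: float
    ci_high: float
    n_boot: int
    kind: str  # "trait" | "covariation"
    target: str

    @property
    def ci(self):
        return (self.ci_low, self.ci_high)


def _pst_once(t: pd.DataFrame, target) -> float:
    pops = t["population_id"].to_numpy()
    if isinstance(target, str):
        vc = varcomp_intercept(t[target].to_numpy(float), pops)
    else:
        resp, covar = target
        sub = t.dropna(subset=[resp, covar])
        vc = varcomp_slope(
            sub[resp].to_numpy(float), sub[covar].to_numpy(float),
            sub["population_id"].to_numpy(),
        )
    return pst(vc)


def pst_bootstrap(
    t: pd.DataFrame, target, n_boot: int = 1000, seed=0
) -> PstResult:
    """P_ST with a 95% cluster-bootstrap percentile CI.

    *target* is a trait name (random-intercept P_ST on the transformed trait)
    or a (response, covariable) trait pair (random-slope P_ST on globally
    standardized traits — standardize before calling).  Populations are
    resampled with replacement and relabelled; because each cluster enters a
    replicate whole, the fit works from per-population sufficient statistics
    computed once.  Replicates that draw a single distinct population (or
    fail to fit) are redrawn up to 10 times.
    """
    rng = np.random.default_rng(seed)
    if isinstance(target, str):
        sub = t.dropna(subset=[target])
        y = sub[target].to_numpy(float)
        labels, inv = np.unique(sub["population_id"].to_numpy(), return_inverse=True)
        G = len(labels)
        n_j = np.bincount(inv).astype(float)
        if np.any(n_j < 2):
            raise ValueError("populations with < 2 observations")
        ybar_j = np.bincount(inv, weights=y) / n_j
        ss_j = np.bincount(inv, weights=y * y) - n_j * ybar_j**2
        point = pst(_varcomp_intercept_stats(n_j, ybar_j, float(ss_j.sum())))

        def refit(idx):
            return pst(
                _varcomp_intercept_stats(n_j[idx], ybar_j[idx], float(ss_j[idx].sum()))
            )

    else:
        resp, covar = target
        sub = t.dropna(subset=[resp, covar])
        y = sub[resp].to_numpy(float)
        x = sub[covar].to_numpy(float)
        labels, inv = np.unique(sub["population_id"].to_numpy(), return_inverse=True)
        G = len(labels)
        A, Zty, yty = _group_suffstats(y, x, inv, G)
        vc0, theta0 = _varcomp_slope_stats(A, Zty, yty)
        point = pst(vc0)
        warm = (tuple(theta0), (0.3, 0.0, 0.3))

        def refit(idx):
            vc, _ = _varcomp_slope_stats(A[idx], Zty[idx], yty[idx], starts=warm)
            return pst(vc)

    reps = []
    n_failed = 0
    for _ in range(n_boot):
        for _retry in range(10):
            idx = rng.integers(0, G, size=G)
            if len(np.unique(idx)) < 2:
                continue
            try:
                reps.append(refit(idx))
                break
            except (ValueError, np.linalg.LinAlgError):
                continue
        else:
            n_failed += 1
    if n_failed > n_boot / 2:
        raise RuntimeError(f"{n_failed}/{n_boot} P_ST bootstrap replicates failed")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    if isinstance(target, str):
        kind, name = "trait", target
    else:
        kind, name = "covariation", f"{target[0]}~{target[1]}"
    return PstResult(
        pst=point, ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, kind=kind, target=name,
    )


@dataclass
class DriftVerdict:
    exceeds_drift: bool
    overlaps: bool


def compare_pst_fst(p: PstResult, f: FstResult) -> DriftVerdict:
    """Compare the P_ST and F_ST 95% CIs (closed intervals).

    exceeds_drift: the whole P_ST CI lies above the F_ST CI — differentiation
    beyond the drift expectation.  Touching endpoints count as overlap.
    """
    exceeds = p.ci_low > f.ci_high
    overlaps = (p.ci_low <= f.ci_high) and (f.ci_low <= p.ci_high)
    return DriftVerdict(exceeds_drift=bool(exceeds), overlaps=bool(overlaps))
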