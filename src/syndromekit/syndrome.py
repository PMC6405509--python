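"""Trait transforms, among-population ANOVA, and per-population trait
covariance matrices with an among-population homogeneity test.

The "syndrome" of a population is the pattern of covariation among its four
functional traits.  With traits standardized within population, a saturated
path model is exactly the sample covariance (= correlation) matrix, so each
population's syndrome is summarised by its 4x4 matrix S_g plus entry-wise
significance tests; heterogeneity of the matrices across populations is then
assessed with multivariate-normal ML fit indices (chi2, RMSEA, CFI, SRMR).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import TRAITS
from .metacov import fisher_z

log = logging.getLogger(__name__)

#: transform applied per trait so residuals are approximately Gaussian
TRANSFORMS = {
    "body_mass": "log",
    "metabolic_rate": "log",
    "excretion_rate": "log",
    "boldness": "sqrt",
}


def transform_traits(t: pd.DataFrame) -> pd.DataFrame:
    """Apply the per-trait normalising transforms (natural log for mass,
    metabolic and excretion rates; square root for boldness).

    Missing values propagate.  Nonpositive values of a log trait cannot be
    transformed; they are set to missing for that trait and counted in a
    warning.
    """
    out = t.copy()
    for trait, kind in TRANSFORMS.items():
        vals = out[trait].astype(float)
        if kind == "log":
            bad = vals.notna() & (vals <= 0)
            if bad.any():
                log.warning(
                    "%d nonpositive %s values excluded before log", int(bad.sum()), trait
                )
                vals = vals.where(~bad)
            out[trait] = np.log(vals)
        else:
            out[trait] = np.sqrt(vals)
    return out


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def anova_by_population(t: pd.DataFrame, trait: str) -> AnovaResult:
    """One-way fixed-effects ANOVA of a (transformed) trait on population.

    Populations with no non-missing value for the trait are dropped (logged).
    """
    groups = []
    for pop, sub in t.groupby("population_id", sort=True):
        vals = sub[trait].dropna().to_numpy()
        if len(vals) == 0:
            log.info("population %s has no data for %s; dropped from ANOVA", pop, trait)
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError(f"fewer than 2 populations with data for {trait}")
    F, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(gr) for gr in groups)
    return AnovaResult(F=float(F), df_between=k - 1, df_within=n - k, p=float(p))


def standardize_within(t: pd.DataFrame, traits=TRAITS) -> pd.DataFrame:
    """Z-score each trait within each population (mean 0, SD 1 per population,
    SD with denominator n-1).  Missing values stay missing and are excluded
    from the population's mean/SD."""
    out = t.copy()
    for pop, sub in t.groupby("population_id", sort=True):
        for trait in traits:
            vals = sub[trait].astype(float)
            m = vals.mean()
            s = vals.std(ddof=1)
            if not np.isfinite(s) or s == 0:
                raise ValueError(f"zero variance for {trait} in population {pop}")
            out.loc[sub.index, trait] = (vals - m) / s
    return out


@dataclass
class PopulationCovariance:
    population_id: str
    S: np.ndarray          # 4x4, correlation form (unit diagonal)
    n: int                 # complete cases used
    z: np.ndarray          # Fisher-scale z statistics, off-diagonals
    p: np.ndarray          # two-sided p per entry (diagonal = nan)


def population_cov_matrices(
    std: pd.DataFrame, traits=TRAITS, deletion: str = "listwise", min_n: int = 10
) -> dict[str, PopulationCovariance]:
    """Per-population covariance matrix of the standardized traits with
    entry-wise normal-theory tests.

    The saturated path model reproduces the ML sample covariance matrix
    exactly, so the matrix itself (rescaled to unit diagonal, i.e. the
    correlation matrix) is the fitted syndrome.  Each off-diagonal entry gets
    z = atanh(r) * sqrt(n-3) and a two-sided p.  *deletion* is "listwise"
    (default) or "pairwise".
    """
    if deletion not in ("listwise", "pairwise"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    traits = list(traits)
    k = len(traits)
    out = {}
    for pop, sub in std.groupby("population_id", sort=True):
        X = sub[traits].astype(float)
        if deletion == "listwise":
            X = X.dropna()
            n = len(X)
            if n < 4:
                raise ValueError(
                    f"population {pop}: only {n} complete cases (need >= 4)"
                )
            # ML covariance (denominator n) then correlation rescale
            A = X.to_numpy()
            A = A - A.mean(axis=0)
            S = A.T @ A / n
            d = np.sqrt(np.diag(S))
            R = S / np.outer(d, d)
            n_eff = np.full((k, k), n)
        else:
            R = X.corr(min_periods=4).to_numpy()
            n_eff = np.array(
                [[X[[a, b]].dropna().shape[0] for b in traits] for a in traits]
            )
            n = int(n_eff.min())
        if n < min_n:
            log.warning("population %s has only %d usable cases", pop, n)
        np.fill_diagonal(R, 1.0)
        z = np.full((k, k), np.nan)
        p = np.full((k, k), np.nan)
        for i, j in itertools.combinations(range(k), 2):
            r = R[i, j]
            nij = n_eff[i, j]
            zz = fisher_z(r) * math.sqrt(nij - 3)
            pp = 2 * stats.norm.sf(abs(zz))
            z[i, j] = z[j, i] = zz
            p[i, j] = p[j, i] = pp
        out[pop] = PopulationCovariance(population_id=pop, S=R, n=n, z=z, p=p)
    return out


def covariances_long(covs: dict[str, PopulationCovariance], traits=TRAITS) -> pd.DataFrame:
    """Long-format table: population, trait_i, trait_j, cov, z, p, n."""
    traits = list(traits)
    rows = []
    for pop in sorted(covs):
        c = covs[pop]
        for i, j in itertools.combinations(range(len(traits)), 2):
            rows.append(
                (pop, traits[i], traits[j], c.S[i, j], c.z[i, j], c.p[i, j], c.n)
            )
    return pd.DataFrame(
        rows, columns=["population_id", "trait_i", "trait_j", "cov", "z", "p", "n"]
    )


@dataclass
class FitIndices:
    chi2: float
    df: int
    rmsea: float
    cfi: float
    srmr: float
    heterogeneous: bool
    chi2_baseline: float
    df_baseline: int


def homogeneity_fit(
    covs: dict[str, PopulationCovariance],
    rmsea_threshold: float = 0.06,
    srmr_threshold: float = 0.09,
    cfi_threshold: float = 0.96,
) -> FitIndices:
    """Test of homogeneity of covariance matrices across populations.

    Fits the constrained model "one pooled covariance matrix for all G
    groups" by multivariate-normal ML and measures its misfit:

        chi2 = sum_g n_g [ ln|pooled| - ln|S_g| + tr(S_g pooled^-1) - p ]
        df   = (G-1) p(p+1)/2

    RMSEA uses the multi-group sqrt(G) correction with N = total
    observations; CFI uses a per-group diagonal (independence) baseline;
    SRMR is the root-mean-square pooled-vs-group correlation residual
    averaged over groups.  The verdict is "heterogeneous" when RMSEA, SRMR
    exceed or CFI falls below the conventional cutoffs.
    """
    pops = sorted(covs)
    G = len(pops)
    if G < 2:
        raise ValueError("need >= 2 populations")
    p = covs[pops[0]].S.shape[0]
    ns = np.array([covs[g].n for g in pops], dtype=float)
    N = float(ns.sum())
    pooled = sum(covs[g].n * covs[g].S for g in pops) / N

    sign, logdet_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise ValueError("pooled covariance matrix is singular")
    pooled_inv = np.linalg.inv(pooled)

    chi2 = 0.0
    chi2_b = 0.0
    srmr_groups = []
    pooled_corr = _to_corr(pooled)
    for g in pops:
        S = covs[g].S
        n_g = covs[g].n
        sgn, logdet_g = np.linalg.slogdet(S)
        if sgn <= 0:
            raise ValueError(f"singular covariance matrix in population {g}")
        chi2 += n_g * (logdet_pooled - logdet_g + np.trace(S @ pooled_inv) - p)
        D = np.diag(np.diag(S))
        chi2_b += n_g * (
            float(np.sum(np.log(np.diag(S)))) - logdet_g
            + np.trace(S @ np.linalg.inv(D)) - p
        )
        resid = _to_corr(S) - pooled_corr
        tri = resid[np.tril_indices(p)]
        srmr_groups.append(math.sqrt(float(np.mean(tri**2))))

    chi2 = max(0.0, float(chi2))
    df = (G - 1) * p * (p + 1) // 2
    df_b = G * p * (p - 1) // 2
    rmsea = math.sqrt(G) * math.sqrt(max(chi2 - df, 0.0) / (df * N))
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    srmr = float(np.mean(srmr_groups))
    verdict = rmsea > rmsea_threshold or srmr > srmr_threshold or cfi < cfi_threshold
    return FitIndices(
        chi2=chi2, df=df, rmsea=rmsea, cfi=cfi, srmr=srmr,
        heterogeneous=bool(verdict), chi2_baseline=float(chi2_b), df_baseline=df_b,
    )


def _to_corr(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
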