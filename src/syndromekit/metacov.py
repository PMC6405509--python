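"""Meta-analytic heterogeneity of pairwise trait covariations.

Each population contributes one effect per trait pair: the covariance of the
within-population standardized traits (a correlation-scale quantity), Fisher
z-transformed with sampling variance 1/(n-3).  Among-population heterogeneity
is then Cochran's Q under fixed-effects weights, with a REML random-effects
tau^2 and the derived percentage-of-heterogeneity index (I^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


def fisher_z(cov: float) -> float:
    """Variance-stabilising Fisher transform, 0.5 ln((1+r)/(1-r)).

    Odd and strictly increasing on (-1, 1).
    """
    if not -1 < cov < 1:
        raise ValueError(f"|cov| must be < 1, got {cov}")
    return 0.5 * math.log((1 + cov) / (1 - cov))


def zr_se(n: int) -> float:
    """Standard error of Fisher z for sample size n: 1/sqrt(n-3)."""
    if n <= 3:
        raise ValueError(f"need n >= 4, got {n}")
    return 1.0 / math.sqrt(n - 3)


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    p: float
    tau2: float
    i2_percent: float       # tau^2-based I^2 (REML), the reported "H"
    i2_q_percent: float     # raw (Q - df)/Q form, for reference
    pooled_zr: float


def heterogeneity_test(effects) -> HeterogeneityResult:
    """Heterogeneity of k Fisher-z effects with known sampling errors.

    *effects* is a sequence of (zr, se) pairs.  Computes fixed-effects
    Cochran's Q with weights 1/se^2 and its chi-square(k-1) p-value, a REML
    estimate of the between-population variance tau^2 under
    z_i ~ N(mu, tau^2 + se_i^2), and the percentage of heterogeneity

        I^2 = 100 * tau^2 / (tau^2 + s2_typ),
        s2_typ = (k-1) * sum(w) / ((sum w)^2 - sum w^2)

    (the typical within-population sampling variance).  The raw
    max(Q-df, 0)/Q form is reported alongside.
    """
    z = np.array([e[0] for e in effects], dtype=float)
    se = np.array([e[1] for e in effects], dtype=float)
    k = len(z)
    if k < 2:
        raise ValueError("need at least 2 effects")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    v = se**2
    w = 1.0 / v
    pooled = float(np.sum(w * z) / np.sum(w))
    Q = float(np.sum(w * (z - pooled) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(Q, df))
    tau2 = reml_tau2(z, v)
    s2_typ = df * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))
    i2 = 100.0 * tau2 / (tau2 + s2_typ) if tau2 + s2_typ > 0 else 0.0
    i2_q = 100.0 * max(Q - df, 0.0) / Q if Q > 0 else 0.0
    return HeterogeneityResult(
        Q=Q, df=df, p=p, tau2=tau2, i2_percent=float(i2),
        i2_q_percent=float(i2_q), pooled_zr=pooled,
    )


def reml_tau2(z: np.ndarray, v: np.ndarray, upper: float = 10.0) -> float:
    """REML between-study variance for the random-effects model
    z_i ~ N(mu, tau^2 + v_i), by bounded 1-D maximisation of the restricted
    log-likelihood on [0, upper]."""
    z = np.asarray(z, dtype=float)
    v = np.asarray(v, dtype=float)

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        mu = np.sum(wi * z) / np.sum(wi)
        return -(
            -0.5 * np.sum(np.log(v + tau2))
            - 0.5 * math.log(np.sum(wi))
            - 0.5 * np.sum(wi * (z - mu) ** 2)
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    # the bounded optimiser never returns the exact boundary; snap when the
    # boundary value is at least as good
    if neg_restricted_ll(0.0) <= res.fun:
        tau2 = 0.0
    return tau2
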