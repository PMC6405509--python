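"""Synthetic genotype, environment, and trait data with the statistical
structure the pipeline assumes.

The generator emulates the study design: 13 riverine populations (coded A..M)
of ~30 individuals, 17 microsatellite loci, drift-structured allele
frequencies at a target F_ST (Balding-Nichols), population trait means driven
by a mix of tree-correlated Brownian drift and environmental effects
(temperature, predation), population-specific 4x4 trait covariance matrices
with a tunable heterogeneity knob, and observation-scale noise such that the
pipeline's log/sqrt transforms recover the latent Gaussian scale.

Named scenarios (`drift_only`, `selection`, `heterogeneous_cov`) fix the knobs
for calibration and power tests.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import TRAITS

#: latent-scale defaults: mean and within-population SD per trait, on the
#: transformed scale the pipeline works on (ln g, ln mg O2/hr, ln ug/L/hr,
#: sqrt-seconds).  Means reflect adult European-minnow magnitudes (a ~2.7 g
#: fish, sub-mg/hr oxygen consumption, tens-of-ug ammonium excretion,
#: boldness around 225 s of 900).
LATENT_MEAN = {"body_mass": 1.0, "metabolic_rate": -0.5,
               "excretion_rate": 3.0, "boldness": 15.0}
LATENT_SD = {"body_mass": 0.35, "metabolic_rate": 0.35,
             "excretion_rate": 0.45, "boldness": 4.0}

#: base within-population correlation structure: positive mass-metabolism and
#: mass-excretion allometry, weaker links to boldness
BASE_CORR = np.array(
    [
        [1.00, 0.45, 0.35, 0.10],
        [0.45, 1.00, 0.30, 0.15],
        [0.35, 0.30, 1.00, 0.05],
        [0.10, 0.15, 0.05, 1.00],
    ]
)


@dataclass
class ScenarioConfig:
    n_pops: int = 13
    n_ind: int = 30
    n_loci: int = 17
    alleles_per_locus: int = 8
    target_fst: float = 0.05
    #: per-trait (temperature, predation) effects, in within-population trait
    #: SDs per predictor SD
    env_effect: dict = field(default_factory=lambda: {t: (0.0, 0.0) for t in TRAITS})
    #: SD of tree-correlated drift in population means, in within-population
    #: trait SDs at unit tree depth
    brownian_scale: float = 0.23
    #: delta in [0, 1] mixing BASE_CORR with population-specific random
    #: correlation structures
    cov_heterogeneity: float = 0.0
    #: coefficient of standardized temperature x predation on the
    #: mass-metabolism within-population slope
    interaction_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pops < 2 or self.n_ind < 2 or self.n_loci < 1:
            raise ValueError("counts too small")
        if not 0 <= self.target_fst <= 0.5:
            raise ValueError("target_fst must be in [0, 0.5]")
        if not 0 <= self.cov_heterogeneity <= 1:
            raise ValueError("cov_heterogeneity must be in [0, 1]")

    def population_ids(self) -> list[str]:
        letters = string.ascii_uppercase
        if self.n_pops <= 26:
            return list(letters[: self.n_pops])
        return [f"P{i:03d}" for i in range(self.n_pops)]


def drift_only(seed: int = 0, target_fst: float = 0.05) -> ScenarioConfig:
    """Neutral scenario: trait differentiation from tree-correlated drift
    alone, magnitude set so the expected P_ST equals the genetic target
    (E[P_ST] = F under sB2 = F/(1-F) * sW2)."""
    return ScenarioConfig(
        target_fst=target_fst,
        brownian_scale=float(np.sqrt(target_fst / (1 - target_fst))),
        env_effect={t: (0.0, 0.0) for t in TRAITS},
        seed=seed,
    )


def selection(seed: int = 0, target_fst: float = 0.05) -> ScenarioConfig:
    """Adaptive scenario: a strong temperature effect on body mass
    (1.5 within-population SD per temperature SD) on top of weak drift."""
    cfg = drift_only(seed=seed, target_fst=target_fst)
    cfg.env_effect = {**cfg.env_effect, "body_mass": (-1.5, 0.0)}
    return cfg


def heterogeneous_cov(seed: int = 0, delta: float = 0.8) -> ScenarioConfig:
    """Scenario with population-specific covariance structure (syndrome
    heterogeneity)."""
    cfg = drift_only(seed=seed)
    cfg.cov_heterogeneity = delta
    return cfg


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(cfg: ScenarioConfig, n_ind_per_pop=None) -> pd.DataFrame:
    """Balding-Nichols genotypes at the target F_ST.

    Ancestral allele frequencies per locus ~ Dirichlet(1, ..., 1); population
    frequencies ~ Dirichlet(p * (1-F)/F); genotypes drawn in HWE within
    populations.  target_fst = 0 means every population shares the ancestral
    frequencies exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    pops = cfg.population_ids()
    if n_ind_per_pop is None:
        n_ind_per_pop = {p: cfg.n_ind for p in pops}
    rows = []
    for locus_i in range(cfg.n_loci):
        locus = f"loc{locus_i + 1:02d}"
        anc = rng.dirichlet(np.ones(cfg.alleles_per_locus))
        for pop in pops:
            if cfg.target_fst == 0:
                freq = anc
            else:
                conc = anc * (1 - cfg.target_fst) / cfg.target_fst
                freq = rng.dirichlet(np.maximum(conc, 1e-8))
            n = n_ind_per_pop[pop]
            draws = rng.choice(cfg.alleles_per_locus, size=(n, 2), p=freq) + 1
            for i in range(n):
                rows.append(
                    (f"{pop}_{i + 1:03d}", pop, locus, draws[i, 0], draws[i, 1])
                )
    g = pd.DataFrame(
        rows,
        columns=["individual_id", "population_id", "locus_id", "allele_a", "allele_b"],
    )
    g["allele_a"] = g["allele_a"].astype("Int64")
    g["allele_b"] = g["allele_b"].astype("Int64")
    return g


# ---------------------------------------------------------------------------
# environment


def simulate_environment(cfg: ScenarioConfig, correlation: float = 0.0) -> pd.DataFrame:
    """Site environment: temperature ~ U(15.5, 21.5) degC, predation
    ~ U(0, 0.1) predators/m2, optionally rank-correlated via a Gaussian
    copula (*correlation* is the copula correlation)."""
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_pops
    z = rng.standard_normal((n, 2))
    if correlation:
        L = np.linalg.cholesky([[1.0, correlation], [correlation, 1.0]])
        z = z @ L.T
    from scipy.stats import norm

    u = norm.cdf(z)
    temp = 15.5 + 6.0 * u[:, 0]
    pred = 0.1 * u[:, 1]
    return pd.DataFrame(
        {"population_id": cfg.population_ids(), "temperature": temp, "predation": pred}
    )


# ---------------------------------------------------------------------------
# traits


def _random_correlation(rng: np.random.Generator, base: np.ndarray) -> np.ndarray:
    """Random correlation matrix sharing base's eigenvalue spectrum, via a
    random orthogonal rotation of its eigenvectors, renormalised to unit
    diagonal."""
    evals, _ = np.linalg.eigh(base)
    Q, _ = np.linalg.qr(rng.standard_normal(base.shape))
    S = Q @ np.diag(np.maximum(evals, 1e-6)) @ Q.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def simulate_traits(
    cfg: ScenarioConfig,
    C: np.ndarray | None = None,
    env: pd.DataFrame | None = None,
    n_ind_per_pop=None,
    return_latent: bool = False,
):
    """Individual trait table with the configured among-population structure.

    Population latent means = brownian_scale * (Brownian draw on the tree,
    unit-depth-normalised C) + env_effect * standardized environment, both in
    within-population SD units.  Individual latent traits ~ MVN(mu_j, S_j)
    with S_j = (1-delta) * BASE_CORR + delta * R_j (population-specific
    random correlation), scaled by the per-trait latent SDs.  Observation
    scale: mass/metabolism/excretion = exp(latent); boldness = latent^2
    clamped to [0, 900] (latent floored at 0), so log/sqrt transforms recover
    the latent scale.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    pops = cfg.population_ids()
    G = len(pops)
    if n_ind_per_pop is None:
        n_ind_per_pop = {p: cfg.n_ind for p in pops}
    if C is None:
        C = np.eye(G)  # star phylogeny: independent population effects
    Cn = C / np.mean(np.diag(C))
    Lc = np.linalg.cholesky(Cn + 1e-10 * np.eye(G))

    if env is not None:
        e = env.set_index("population_id").loc[pops]
        t_std = _zscore(e["temperature"].to_numpy(float))
        p_std = _zscore(e["predation"].to_numpy(float))
    else:
        t_std = p_std = np.zeros(G)
    tp_std = _zscore(t_std * p_std) if env is not None else np.zeros(G)

    sd = np.array([LATENT_SD[t] for t in TRAITS])
    mean = np.array([LATENT_MEAN[t] for t in TRAITS])
    # tree-correlated drift per trait (independent across traits)
    brown = cfg.brownian_scale * (Lc @ rng.standard_normal((G, len(TRAITS))))
    env_shift = np.column_stack(
        [
            cfg.env_effect.get(t, (0.0, 0.0))[0] * t_std
            + cfg.env_effect.get(t, (0.0, 0.0))[1] * p_std
            for t in TRAITS
        ]
    )
    mu = mean + sd * (brown + env_shift)  # G x 4

    delta = cfg.cov_heterogeneity
    rows = []
    mass_i, met_i = TRAITS.index("body_mass"), TRAITS.index("metabolic_rate")
    for j, pop in enumerate(pops):
        R = BASE_CORR
        if delta > 0:
            for _attempt in range(20):
                Rj = (1 - delta) * BASE_CORR + delta * _random_correlation(rng, BASE_CORR)
                if np.all(np.linalg.eigvalsh(Rj) > 1e-8):
                    R = Rj
                    break
        S = np.outer(sd, sd) * R
        n = n_ind_per_pop[pop]
        z = rng.multivariate_normal(mu[j], S, size=n)
        if cfg.interaction_effect:
            # temperature x predation modulates the mass-metabolism slope
            dev = z[:, mass_i] - z[:, mass_i].mean()
            z[:, met_i] += (
                cfg.interaction_effect * tp_std[j] * dev
                * sd[met_i] / sd[mass_i]
            )
        for i in range(n):
            mass, met, exc, bold = z[i]
            rows.append(
                (
                    f"{pop}_{i + 1:03d}",
                    pop,
                    float(np.exp(mass)),
                    float(np.exp(met)),
                    float(np.exp(exc)),
                    float(np.clip(max(bold, 0.0) ** 2, 0.0, 900.0)),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["individual_id", "population_id"] + list(TRAITS),
    )
    if return_latent:
        latent = pd.DataFrame(mu, index=pops, columns=list(TRAITS))
        latent.index.name = "population_id"
        return df, latent
    return df


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std(ddof=1)
    return (v - v.mean()) / s if s > 0 else np.zeros_like(v)


# ---------------------------------------------------------------------------
# study-shaped fixture


def make_study_fixture(seed: int = 0, cfg: ScenarioConfig | None = None, out_dir=None):
    """One deterministic study-shaped bundle: 13 populations A..M with 28-40
    individuals each, 17 loci, genotypes + tree-driven traits + environment,
    plus a ground-truth manifest.

    Returns (traits, genotypes, env, truth).  If *out_dir* is given, writes
    traits.csv, geno.gen, env.csv, tree.nwk and truth.json there.
    """
    from . import popgen
    from .io_formats import write_genepop, write_newick
    from .phylo_models import tree_to_cov

    if cfg is None:
        cfg = drift_only(seed=seed)
    else:
        cfg.seed = seed
    rng = np.random.default_rng(seed + 3)
    pops = cfg.population_ids()
    n_per_pop = {p: int(rng.integers(28, 41)) for p in pops}

    geno = simulate_genotypes(cfg, n_ind_per_pop={p: cfg.n_ind for p in pops})
    pnames, D = popgen.nei_distance_matrix(geno, cap_infinite=5.0)
    tree = popgen.build_tree(pnames, D)
    labels, C = tree_to_cov(tree)
    env = simulate_environment(cfg)
    traits = simulate_traits(cfg, C=C, env=env, n_ind_per_pop=n_per_pop)

    truth = {
        "config": {k: v for k, v in asdict(cfg).items() if k != "env_effect"},
        "env_effect": {t: list(v) for t, v in cfg.env_effect.items()},
        "n_per_pop": n_per_pop,
        "populations": pops,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traits.to_csv(out / "traits.csv", index=False)
        write_genepop(geno, out / "geno.gen")
        env.to_csv(out / "env.csv", index=False)
        write_newick(tree, out / "tree.nwk")
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return traits, geno, env, truth
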