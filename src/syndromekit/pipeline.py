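"""End-to-end orchestration: genotypes + traits + environment in, report
tables out.

Stages: population genetics (tree, global F_ST with bootstrap CI) ->
trait transforms and ANOVA -> per-population syndromes and the covariance
homogeneity test -> pairwise-covariation heterogeneity meta-analysis ->
lambda-PGLS model selection against temperature/predation -> the ten P_ST
estimates (4 traits + 6 covariations) with bootstrap CIs and drift verdicts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import TRAITS, TRAIT_PAIRS, __version__
from . import io_formats, metacov, phylo_models, popgen, pstfst, syndrome

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    traits_path: str | None = None
    genepop_path: str | None = None
    env_path: str | None = None
    out_dir: str | None = None
    deletion: str = "listwise"
    n_boot_fst: int = 1000
    n_boot_pst: int = 1000
    seed: int = 0
    alpha: float = 0.05
    delta_aic_threshold: float = 4.0
    rmsea_threshold: float = 0.06
    srmr_threshold: float = 0.09
    cfi_threshold: float = 0.96


def run_all(
    cfg: RunConfig,
    traits: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
    env: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis; returns a result bundle (dict of DataFrames /
    dataclasses) and, when cfg.out_dir is set, writes CSV/JSON reports."""
    if traits is None:
        traits = io_formats.read_trait_table(cfg.traits_path)
    else:
        traits = io_formats.validate_trait_table(traits.copy())
    if genotypes is None:
        genotypes = io_formats.read_genepop(cfg.genepop_path, pop_names="prefix")
    pops = sorted(traits["population_id"].unique())
    if env is None:
        env = io_formats.read_env_table(cfg.env_path, populations=pops)

    geno_pops = sorted(genotypes["population_id"].unique())
    if geno_pops != pops:
        raise ValueError(
            f"trait/genotype population mismatch: {pops} vs {geno_pops}"
        )

    rng = np.random.default_rng(cfg.seed)

    # --- population genetics
    pnames, D = popgen.nei_distance_matrix(genotypes, cap_infinite=5.0)
    tree = popgen.build_tree(pnames, D)
    fst = popgen.cluster_bootstrap_fst(
        genotypes, n_boot=cfg.n_boot_fst, seed=int(rng.integers(2**31))
    )

    # --- trait transforms + ANOVA
    tt = syndrome.transform_traits(traits)
    anova = {
        trait: syndrome.anova_by_population(tt, trait) for trait in TRAITS
    }

    # --- syndromes
    std = syndrome.standardize_within(tt)
    covs = syndrome.population_cov_matrices(std, deletion=cfg.deletion)
    fit = syndrome.homogeneity_fit(
        covs,
        rmsea_threshold=cfg.rmsea_threshold,
        srmr_threshold=cfg.srmr_threshold,
        cfi_threshold=cfg.cfi_threshold,
    )
    cov_long = syndrome.covariances_long(covs)

    # --- pairwise-covariation heterogeneity
    het_rows = []
    zr_by_pair = {}
    for ti, tj in TRAIT_PAIRS:
        effects = []
        for pop in sorted(covs):
            i, j = TRAITS.index(ti), TRAITS.index(tj)
            r = covs[pop].S[i, j]
            n = covs[pop].n
            effects.append((metacov.fisher_z(r), metacov.zr_se(n)))
        zr_by_pair[(ti, tj)] = [e[0] for e in effects]
        h = metacov.heterogeneity_test(effects)
        het_rows.append(
            {
                "pair": f"{ti}~{tj}", "Q": h.Q, "df": h.df, "p": h.p,
                "tau2": h.tau2, "i2_percent": h.i2_percent,
                "i2_q_percent": h.i2_q_percent, "pooled_zr": h.pooled_zr,
            }
        )
    heterogeneity = pd.DataFrame(het_rows)

    # --- phylogenetic models
    labels, C = phylo_models.tree_to_cov(tree, populations=pops)
    pop_means = tt.groupby("population_id")[list(TRAITS)].mean().loc[labels]
    responses: dict[str, np.ndarray] = {
        trait: pop_means[trait].to_numpy(float) for trait in TRAITS
    }
    for (ti, tj), zr in zr_by_pair.items():
        responses[f"{ti}~{tj}"] = np.asarray(zr, float)

    lambda_rows = []
    aic_rows = []
    for name, y in responses.items():
        lam = phylo_models.fit_lambda_only(y, C)
        lambda_rows.append(
            {"response": name, "lambda": lam.lambda_, "lambda_p": lam.lambda_p}
        )
        sel = phylo_models.model_selection(
            y, env, C, labels, delta_aic_threshold=cfg.delta_aic_threshold
        )
        for _, row in sel.iterrows():
            aic_rows.append(
                {
                    "response": name, "model": row["model"], "aic": row["aic"],
                    "delta_aic": row["delta_aic"],
                    "in_best_set": row["in_best_set"], "lambda": row["lambda"],
                }
            )
    lambda_table = pd.DataFrame(lambda_rows)
    model_table = pd.DataFrame(aic_rows)

    # --- P_ST / F_ST
    std_global = pstfst.standardize_global(tt)
    pst_rows = []
    verdicts = {}
    for trait in TRAITS:
        r = pstfst.pst_bootstrap(
            tt.dropna(subset=[trait]), trait,
            n_boot=cfg.n_boot_pst, seed=int(rng.integers(2**31)),
        )
        v = pstfst.compare_pst_fst(r, fst)
        verdicts[trait] = (r, v)
        pst_rows.append(_pst_row(r, v))
    for ti, tj in TRAIT_PAIRS:
        r = pstfst.pst_bootstrap(
            std_global, (ti, tj),
            n_boot=cfg.n_boot_pst, seed=int(rng.integers(2**31)),
        )
        v = pstfst.compare_pst_fst(r, fst)
        verdicts[f"{ti}~{tj}"] = (r, v)
        pst_rows.append(_pst_row(r, v))
    pst_table = pd.DataFrame(pst_rows)

    bundle = {
        "tree": tree,
        "distance_matrix": pd.DataFrame(D, index=pnames, columns=pnames),
        "fst": fst,
        "anova": anova,
        "covariances": cov_long,
        "fit_indices": fit,
        "heterogeneity": heterogeneity,
        "lambda_table": lambda_table,
        "model_table": model_table,
        "pst_table": pst_table,
        "config": cfg,
    }
    if cfg.out_dir is not None:
        _write_bundle(bundle, cfg)
    return bundle


def _pst_row(r, v):
    return {
        "target": r.target, "kind": r.kind, "pst": r.pst,
        "ci_low": r.ci_low, "ci_high": r.ci_high,
        "exceeds_drift": v.exceeds_drift, "overlaps": v.overlaps,
    }


def _write_bundle(bundle: dict, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_newick(bundle["tree"], out / "tree.nwk")
    bundle["distance_matrix"].to_csv(out / "nei_distances.csv")
    bundle["covariances"].to_csv(out / "population_covariances.csv", index=False)
    bundle["heterogeneity"].to_csv(out / "covariation_heterogeneity.csv", index=False)
    bundle["lambda_table"].to_csv(out / "lambda.csv", index=False)
    bundle["model_table"].to_csv(out / "model_selection.csv", index=False)
    pst_tab = bundle["pst_table"].copy()
    fst = bundle["fst"]
    pst_tab.loc[len(pst_tab)] = {
        "target": "global_fst", "kind": "fst", "pst": fst.fst,
        "ci_low": fst.ci_low, "ci_high": fst.ci_high,
        "exceeds_drift": False, "overlaps": True,
    }
    pst_tab.to_csv(out / "pst_fst.csv", index=False)

    fit = bundle["fit_indices"]
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "global_fst": {"fst": fst.fst, "ci": [fst.ci_low, fst.ci_high],
                       "n_boot": fst.n_boot},
        "anova": {
            t: dataclasses.asdict(a) for t, a in bundle["anova"].items()
        },
        "fit_indices": dataclasses.asdict(fit),
        "heterogeneity": bundle["heterogeneity"].to_dict(orient="records"),
        "lambda": bundle["lambda_table"].to_dict(orient="records"),
        "pst_fst": pst_tab.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, default=float))
    log.info("report written to %s", out)
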