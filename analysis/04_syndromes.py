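#!/usr/bin/env python
"""Per-population functional syndromes and their homogeneity.

Standardizes the transformed traits within each population, estimates the
per-population 4x4 covariance (correlation) matrix with entry-wise
significance tests — the saturated-path summary of each population's
syndrome — and tests whether the thirteen matrices can be treated as one
(multivariate-normal ML chi2 with RMSEA / CFI / SRMR).  Writes
population_covariances.csv and fit_indices.json under results/syndromes/.
"""

import dataclasses
import json
from pathlib import Path

from syndromekit import io_formats, syndrome

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "syndromes"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    traits = io_formats.read_trait_table(ROOT / "synthetic_study" / "traits.csv")
    tt = syndrome.transform_traits(traits)
    std = syndrome.standardize_within(tt)
    covs = syndrome.population_cov_matrices(std)
    long = syndrome.covariances_long(covs)
    long.to_csv(OUT / "population_covariances.csv", index=False)
    n_sig = int((long["p"] < 0.05).sum())
    print(f"{len(covs)} population syndromes; {n_sig}/{len(long)} "
          "covariances individually significant at alpha = 0.05")

    fit = syndrome.homogeneity_fit(covs)
    (OUT / "fit_indices.json").write_text(
        json.dumps(dataclasses.asdict(fit), indent=2))
    verdict = "heterogeneous" if fit.heterogeneous else "homogeneous"
    print(f"covariance homogeneity: chi2 = {fit.chi2:.1f} (df {fit.df}), "
          f"RMSEA = {fit.rmsea:.3f}, CFI = {fit.cfi:.3f}, "
          f"SRMR = {fit.srmr:.3f} -> {verdict}")
    print("note: with ~30 individuals per population SRMR has a sampling "
          "floor of ~0.1 even under a shared covariance matrix; chi2, RMSEA "
          "and CFI are the calibrated indices at this sample size")


if __name__ == "__main__":
    main()
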