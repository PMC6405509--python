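#!/usr/bin/env python
"""P_ST vs F_ST: is the phenotypic differentiation more than drift explains?

Estimates the ten P_ST quantities (4 traits from random-intercept models,
6 covariations from random-slope models on globally standardized traits)
with 1,000-iteration cluster-bootstrap CIs, and compares each against the
global F_ST CI from step 02.  Writes pst_fst.csv under results/pstfst/.
"""

import json
from pathlib import Path

import pandas as pd

from syndromekit import TRAITS, TRAIT_PAIRS, io_formats, popgen, pstfst, syndrome

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "pstfst"
SEED = 6
N_BOOT = 1000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    traits = io_formats.read_trait_table(ROOT / "synthetic_study" / "traits.csv")
    fst_info = json.loads((ROOT / "genetics" / "fst.json").read_text())
    fst = popgen.FstResult(fst=fst_info["fst"], ci_low=fst_info["ci"][0],
                           ci_high=fst_info["ci"][1], n_boot=fst_info["n_boot"])
    tt = syndrome.transform_traits(traits)
    std_global = pstfst.standardize_global(tt)

    rows = []
    for k, trait in enumerate(TRAITS):
        r = pstfst.pst_bootstrap(tt.dropna(subset=[trait]), trait,
                                 n_boot=N_BOOT, seed=SEED + k)
        v = pstfst.compare_pst_fst(r, fst)
        rows.append({"target": trait, "kind": "trait", "pst": r.pst,
                     "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "exceeds_drift": v.exceeds_drift, "overlaps": v.overlaps})
    for k, (ti, tj) in enumerate(TRAIT_PAIRS):
        r = pstfst.pst_bootstrap(std_global, (ti, tj), n_boot=N_BOOT,
                                 seed=SEED + 10 + k)
        v = pstfst.compare_pst_fst(r, fst)
        rows.append({"target": f"{ti}~{tj}", "kind": "covariation",
                     "pst": r.pst, "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "exceeds_drift": v.exceeds_drift, "overlaps": v.overlaps})
    tab = pd.DataFrame(rows)
    tab.loc[len(tab)] = {"target": "global_fst", "kind": "fst",
                         "pst": fst.fst, "ci_low": fst.ci_low,
                         "ci_high": fst.ci_high, "exceeds_drift": False,
                         "overlaps": True}
    tab.to_csv(OUT / "pst_fst.csv", index=False)

    n_exceed = int(tab["exceeds_drift"].sum())
    n_overlap = int(tab[tab["kind"] != "fst"]["overlaps"].sum())
    print(f"F_ST = {fst.fst:.4f} (CI {fst.ci_low:.4f}-{fst.ci_high:.4f})")
    print(f"{n_exceed}/10 P_ST exceed the drift expectation; "
          f"{n_overlap}/10 CIs overlap the F_ST CI")
    print("(drift-only data: overlap, not excess, is the expected outcome)")


if __name__ == "__main__":
    main()
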