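import math

import numpy as np
import pandas as pd
import pytest

from syndromekit import popgen, synthetic_data


def _geno(rows):
    df = pd.DataFrame(
        rows,
        columns=["individual_id", "population_id", "locus_id",
                 "allele_a", "allele_b"],
    )
    df["allele_a"] = df["allele_a"].astype("Int64")
    df["allele_b"] = df["allele_b"].astype("Int64")
    return df


class TestAlleleFrequencies:
    def test_counts_both_alleles(self):
        g = _geno([("i1", "A", "L1", 1, 1), ("i2", "A", "L1", 1, 2)])
        f = popgen.allele_frequencies(g)
        assert f[("A", "L1")] == {1: 0.75, 2: 0.25}

    def test_monomorphic(self):
        g = _geno([("i1", "A", "L1", 3, 3), ("i2", "A", "L1", 3, 3)])
        assert popgen.allele_frequencies(g)[("A", "L1")] == {3: 1.0}

    def test_missing_genotypes_excluded_from_denominator(self):
        g = _geno([("i1", "A", "L1", 1, 2), ("i2", "A", "L1", None, None)])
        assert popgen.allele_frequencies(g)[("A", "L1")] == {1: 0.5, 2: 0.5}


class TestHwe:
    def test_monomorphic_locus_returns_one(self):
        g = _geno([(f"i{k}", "A", "L1", 1, 1) for k in range(10)])
        assert popgen.hwe_exact_mc(g, "A", "L1", n_perm=100, seed=0) == 1.0

    def test_extreme_heterozygote_excess_rejected(self):
        # 20 individuals all (1,2): allele freq 0.5 but zero homozygotes
        g = _geno([(f"i{k}", "A", "L1", 1, 2) for k in range(20)])
        p = popgen.hwe_exact_mc(g, "A", "L1", n_perm=10_000, seed=3)
        assert p < 0.05

    def test_determinism(self):
        rng = np.random.default_rng(0)
        g = _geno(
            [(f"i{k}", "A", "L1", *rng.choice([1, 2, 3], 2)) for k in range(30)]
        )
        p1 = popgen.hwe_exact_mc(g, "A", "L1", n_perm=500, seed=11)
        p2 = popgen.hwe_exact_mc(g, "A", "L1", n_perm=500, seed=11)
        assert p1 == p2

    def test_type_one_error_near_nominal_under_hwe(self):
        # loci simulated in exact HWE: rejection rate at alpha=.05 should sit
        # near nominal (wide band for Monte-Carlo discreteness)
        rng = np.random.default_rng(42)
        n_loci, n_ind = 400, 25
        rejections = 0
        for _ in range(n_loci):
            freq = rng.dirichlet([1.0, 1.0, 1.0])
            draws = rng.choice(3, size=(n_ind, 2), p=freq) + 1
            g = _geno(
                [(f"i{k}", "A", "L1", draws[k, 0], draws[k, 1])
                 for k in range(n_ind)]
            )
            p = popgen.hwe_exact_mc(g, "A", "L1", n_perm=199,
                                    seed=rng.integers(2**31))
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_loci <= 0.07


class TestHolm:
    def test_hand_computed_thresholds(self):
        flags = popgen.holm_screen({"a": 0.001, "b": 0.04, "c": 0.5}, alpha=0.05)
        # Holm: 0.001 < 0.05/3 rejects; then 0.04 > 0.05/2 stops
        assert flags == {"a": True, "b": False, "c": False}

    def test_all_ones_no_flags(self):
        assert popgen.holm_screen({"a": 1.0, "b": 1.0}) == {"a": False, "b": False}

    def test_single_p_flagged(self):
        assert popgen.holm_screen({"a": 0.04}, alpha=0.05) == {"a": True}

    def test_empty_family(self):
        assert popgen.holm_screen({}) == {}


class TestNeiDistance:
    def test_identical_frequencies_give_zero(self):
        f = {("A", "L1"): {1: 0.3, 2: 0.7}, ("B", "L1"): {1: 0.3, 2: 0.7}}
        assert popgen.nei_distance(f, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_hand_case(self):
        # A fixed for allele 1; B at (0.5, 0.5): D = -ln(0.5/sqrt(0.5))
        f = {("A", "L1"): {1: 1.0}, ("B", "L1"): {1: 0.5, 2: 0.5}}
        assert popgen.nei_distance(f, "A", "B") == pytest.approx(
            0.34657359, abs=1e-8
        )

    def test_disjoint_alleles_error_and_cap(self):
        f = {("A", "L1"): {1: 1.0}, ("B", "L1"): {2: 1.0}}
        with pytest.raises(ValueError, match="infinite"):
            popgen.nei_distance(f, "A", "B")
        assert popgen.nei_distance(f, "A", "B", cap_infinite=5.0) == 5.0

    def test_symmetry_property(self, toy_genotypes):
        pops, D = popgen.nei_distance_matrix(toy_genotypes)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)


class TestBuildTree:
    def test_three_taxon_hand_trace(self):
        D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
        tree = popgen.build_tree(["A", "B", "C"], D)
        s = tree.as_string(schema="newick")
        # A,B merge first at height 1 (node depth 0.5), then with C at 4
        assert "(A:0.5,B:0.5):1.5" in s.replace("'", "")

    def test_two_populations(self):
        D = np.array([[0, 2.0], [2.0, 0]])
        tree = popgen.build_tree(["A", "B"], D)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert depths == pytest.approx([1.0, 1.0])

    def test_zero_distance_merges_first(self):
        D = np.array([[0, 0, 3], [0, 0, 3], [3, 3, 0]], float)
        tree = popgen.build_tree(["A", "B", "C"], D)
        assert "(A:0.0,B:0.0)" in tree.as_string(schema="newick").replace("'", "")

    def test_ultrametric(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((13, 4))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        tree = popgen.build_tree([f"p{i:02d}" for i in range(13)], D)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_matches_scipy_complete_linkage_heights(self):
        # independent cross-check: the multiset of internal-node cophenetic
        # heights (2 x height above the tips) must equal scipy's complete-
        # linkage merge distances
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 4))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        tree = popgen.build_tree([f"p{i}" for i in range(10)], D)
        depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
        heights = sorted(
            2 * (depth - n.distance_from_root())
            for n in tree.preorder_internal_node_iter()
        )
        Z = linkage(D[np.triu_indices(10, 1)], method="complete")
        assert np.allclose(heights, sorted(Z[:, 2]), atol=1e-9)


class TestGlobalFst:
    def test_fixed_alternative_alleles_approach_one(self):
        rows = []
        for pop, allele in (("A", 1), ("B", 2)):
            rows += [(f"{pop}{k}", pop, "L1", allele, allele) for k in range(200)]
        assert popgen.global_fst(_geno(rows)) > 0.99

    def test_panmictic_split_near_zero(self):
        rng = np.random.default_rng(1)
        rows = []
        for pop in ("A", "B"):
            for k in range(500):
                a, b = rng.choice([1, 2, 3], size=2, p=[0.5, 0.3, 0.2])
                rows.append((f"{pop}{k}", pop, "L1", a, b))
        assert abs(popgen.global_fst(_geno(rows))) < 0.01

    def test_matches_independent_component_oracle(self, toy_genotypes):
        ours = popgen.global_fst(toy_genotypes)
        oracle = _wc_theta_oracle(toy_genotypes)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_allele_relabeling_and_pop_order(self, toy_genotypes):
        base = popgen.global_fst(toy_genotypes)
        relab = toy_genotypes.copy()
        relab["allele_a"] = relab["allele_a"].map({1: 7, 2: 3}).astype("Int64")
        relab["allele_b"] = relab["allele_b"].map({1: 7, 2: 3}).astype("Int64")
        assert popgen.global_fst(relab) == pytest.approx(base, abs=1e-12)
        shuffled = toy_genotypes.sample(frac=1, random_state=0)
        assert popgen.global_fst(shuffled) == pytest.approx(base, abs=1e-12)

    def test_monomorphic_data_errors(self):
        g = _geno([("i1", "A", "L1", 1, 1), ("i2", "B", "L1", 1, 1)])
        with pytest.raises(ValueError, match="polymorphism"):
            popgen.global_fst(g)

    def test_increases_with_target_fst(self):
        means = []
        for target in (0.01, 0.05, 0.15):
            ests = []
            for seed in range(15):
                cfg = synthetic_data.ScenarioConfig(
                    n_pops=8, n_ind=25, n_loci=8, target_fst=target, seed=seed
                )
                ests.append(popgen.global_fst(synthetic_data.simulate_genotypes(cfg)))
            means.append(np.mean(ests))
        assert means[0] < means[1] < means[2]


class TestClusterBootstrap:
    def test_determinism(self, toy_genotypes):
        r1 = popgen.cluster_bootstrap_fst(toy_genotypes, n_boot=50, seed=7)
        r2 = popgen.cluster_bootstrap_fst(toy_genotypes, n_boot=50, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_default_iterations(self, toy_genotypes):
        import inspect

        sig = inspect.signature(popgen.cluster_bootstrap_fst)
        assert sig.parameters["n_boot"].default == 1000


def _wc_theta_oracle(g: pd.DataFrame) -> float:
    """Independent implementation of the two-level variance-component theta
    from the textbook per-allele component formulas, looping naively."""
    num = den = 0.0
    for locus in g["locus_id"].unique():
        sub = g[g["locus_id"] == locus].dropna(subset=["allele_a", "allele_b"])
        pops = sorted(sub["population_id"].unique())
        r = len(pops)
        n = np.array(
            [len(sub[sub["population_id"] == p]) for p in pops], float
        )
        nbar = n.mean()
        nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
        alleles = sorted(
            set(sub["allele_a"].astype(int)) | set(sub["allele_b"].astype(int))
        )
        if len(alleles) < 2:
            continue
        for al in alleles:
            p_i, h_i = [], []
            for p in pops:
                s = sub[sub["population_id"] == p]
                a = s["allele_a"].astype(int).to_numpy()
                b = s["allele_b"].astype(int).to_numpy()
                p_i.append(((a == al).sum() + (b == al).sum()) / (2 * len(s)))
                h_i.append(((a == al) ^ (b == al)).sum() / len(s))
            p_i, h_i = np.array(p_i), np.array(h_i)
            pbar = (n * p_i).sum() / (r * nbar)
            s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n * h_i).sum() / (r * nbar)
            a_c = nbar / nc * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - h_i.mean() * 0
                      - hbar / 4) / (nbar - 1)
            )
            b_c = nbar / (nbar - 1) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c_c = hbar / 2
            num += a_c
            den += a_c + b_c + c_c
    return num / den
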