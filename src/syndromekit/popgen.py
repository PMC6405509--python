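"""Population-genetic summaries of the microsatellite data.

Provides allele-frequency processing, a Monte-Carlo exact test of
Hardy-Weinberg equilibrium with Holm correction for locus QC, Nei's standard
genetic distance, a complete-linkage population tree, and the global F_ST
(Weir-Cockerham variance-component estimator) with a cluster-bootstrap CI.

F_ST here is the inter-population variance component in allele frequencies at
neutral markers: the differentiation expected under genetic drift alone, and
the yardstick the P_ST comparison uses downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# allele counts / frequencies


def allele_counts(g: pd.DataFrame) -> dict[tuple[str, str], dict[int, int]]:
    """Per (population, locus) map of allele code -> count.

    Both alleles of every called genotype are counted; missing genotypes do
    not enter the denominator.  (population, locus) combinations with zero
    calls are absent from the result.
    """
    called = g.dropna(subset=["allele_a", "allele_b"])
    counts: dict[tuple[str, str], dict[int, int]] = {}
    for (pop, locus), sub in called.groupby(
        ["population_id", "locus_id"], sort=True
    ):
        c: dict[int, int] = {}
        for col in ("allele_a", "allele_b"):
            for a, n in sub[col].value_counts().items():
                c[int(a)] = c.get(int(a), 0) + int(n)
        counts[(pop, locus)] = c
    return counts


def allele_frequencies(g: pd.DataFrame) -> dict[tuple[str, str], dict[int, float]]:
    """Per (population, locus) relative allele frequencies (sum to 1)."""
    freqs = {}
    for key, c in allele_counts(g).items():
        tot = sum(c.values())
        freqs[key] = {a: n / tot for a, n in c.items()}
    return freqs


# ---------------------------------------------------------------------------
# Hardy-Weinberg screening


def hwe_exact_mc(
    g: pd.DataFrame, population: str, locus: str, n_perm: int = 1000, seed=0
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium.

    Permutes the 2n observed allele labels, re-pairs them into genotypes, and
    ranks outcomes by the Levene conditional probability of the genotype
    array given the allele counts (higher heterozygosity excess or deficit
    both give low-probability arrays).  p = (1 + #{permuted arrays at most as
    probable as observed}) / (1 + n_perm).  Monomorphic loci return 1.0.
    """
    sub = g[(g["population_id"] == population) & (g["locus_id"] == locus)]
    sub = sub.dropna(subset=["allele_a", "allele_b"])
    alleles = np.concatenate(
        [sub["allele_a"].to_numpy(int), sub["allele_b"].to_numpy(int)]
    )
    if len(np.unique(alleles)) < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    obs = _log_levene(sub["allele_a"].to_numpy(int), sub["allele_b"].to_numpy(int))
    hits = 0
    arr = alleles.copy()
    for _ in range(n_perm):
        rng.shuffle(arr)
        a, b = arr[0::2], arr[1::2]
        if _log_levene(a, b) <= obs + 1e-9:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def _log_levene(a: np.ndarray, b: np.ndarray) -> float:
    """Log conditional probability of a genotype array given allele counts,
    up to terms that are invariant under permutation of the allele labels:
    n_het * ln 2 - sum_g ln(count_g!)."""
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    het = int(np.sum(lo != hi))
    # genotype multiplicities
    key = lo.astype(np.int64) * 1_000_003 + hi.astype(np.int64)
    _, cnt = np.unique(key, return_counts=True)
    return het * math.log(2.0) - float(np.sum([math.lgamma(c + 1) for c in cnt]))


@dataclass
class HweScreenResult:
    pvalues: pd.DataFrame  # columns population_id, locus_id, p
    flags: pd.DataFrame  # columns population_id, locus_id, p, significant
    discard: list[str] = field(default_factory=list)


def holm_screen(pvals: dict, alpha: float = 0.05) -> dict:
    """Holm step-down correction over a family of p-values.

    *pvals* maps an arbitrary key to a raw p-value; returns key -> bool
    (significant after correction).  Empty input gives an empty result.
    """
    if not pvals:
        return {}
    keys = sorted(pvals)
    p = np.array([pvals[k] for k in keys], dtype=float)
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return dict(zip(keys, (bool(r) for r in reject)))


def hwe_screen(
    g: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_failing_pops: int = 5,
    seed=0,
    manual_discard: list[str] | None = None,
) -> HweScreenResult:
    """Run the HWE exact test per (population, locus) and flag loci failing
    (after per-population Holm correction) in at least *min_failing_pops*
    populations.  *manual_discard* adds loci known bad from external QC
    (null-allele or linkage screening done outside this package)."""
    rng = np.random.default_rng(seed)
    rows = []
    for pop in sorted(g["population_id"].unique()):
        for locus in sorted(g["locus_id"].unique()):
            p = hwe_exact_mc(g, pop, locus, n_perm=n_perm, seed=rng.integers(2**31))
            rows.append((pop, locus, p))
    pvalues = pd.DataFrame(rows, columns=["population_id", "locus_id", "p"])
    flag_rows = []
    for pop, sub in pvalues.groupby("population_id"):
        fam = dict(zip(sub["locus_id"], sub["p"]))
        sig = holm_screen(fam, alpha=alpha)
        for locus, p in fam.items():
            flag_rows.append((pop, locus, p, sig[locus]))
    flags = pd.DataFrame(
        flag_rows, columns=["population_id", "locus_id", "p", "significant"]
    )
    fail_counts = flags.groupby("locus_id")["significant"].sum()
    discard = sorted(fail_counts[fail_counts >= min_failing_pops].index)
    for locus in manual_discard or []:
        if locus not in discard:
            discard.append(locus)
    return HweScreenResult(pvalues=pvalues, flags=flags, discard=sorted(discard))


# ---------------------------------------------------------------------------
# Nei's standard genetic distance


def nei_distance(freqs: dict, pop_a: str, pop_b: str, cap_infinite: float | None = None) -> float:
    """Nei's standard genetic distance D between two populations.

    D = -ln( Jxy / sqrt(Jx * Jy) ) where Jxy, Jx, Jy are the across-locus
    means of the raw allele identities sum_a x_a y_a, sum_a x_a^2 and
    sum_a y_a^2 (the "standard" variant: average identities first, one log).
    """
    loci = sorted(
        {l for (p, l) in freqs if p == pop_a} & {l for (p, l) in freqs if p == pop_b}
    )
    if not loci:
        raise ValueError(f"no shared typed loci between {pop_a} and {pop_b}")
    jxy = jx = jy = 0.0
    for locus in loci:
        x = freqs[(pop_a, locus)]
        y = freqs[(pop_b, locus)]
        jxy += sum(x.get(a, 0.0) * y.get(a, 0.0) for a in set(x) | set(y))
        jx += sum(v * v for v in x.values())
        jy += sum(v * v for v in y.values())
    jxy /= len(loci)
    jx /= len(loci)
    jy /= len(loci)
    if jxy <= 0:
        if cap_infinite is not None:
            log.warning("no shared alleles between %s and %s; capping D at %g",
                        pop_a, pop_b, cap_infinite)
            return cap_infinite
        raise ValueError(
            f"infinite distance: no shared alleles between {pop_a} and {pop_b}"
        )
    return max(0.0, -math.log(jxy / math.sqrt(jx * jy)))


def nei_distance_matrix(g: pd.DataFrame, cap_infinite: float | None = None):
    """Symmetric matrix of pairwise Nei distances; returns (pops, matrix)."""
    freqs = allele_frequencies(g)
    pops = sorted(g["population_id"].unique())
    n = len(pops)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = nei_distance(freqs, pops[i], pops[j], cap_infinite=cap_infinite)
            D[i, j] = D[j, i] = d
    return pops, D


# ---------------------------------------------------------------------------
# complete-linkage population tree


def build_tree(pops: list[str], D: np.ndarray) -> dendropy.Tree:
    """Agglomerative complete-linkage clustering of the distance matrix,
    exported as an ultrametric dendropy tree.

    Node heights follow the hclust/as.phylo convention: a merge at cophenetic
    height h places the internal node at depth h/2 above the tips, so the
    tree distance between two tips equals their cophenetic distance.  Ties in
    merge distance are broken by the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest member).
    """
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite entries in distance matrix")
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    taxa = dendropy.TaxonNamespace(sorted(pops))
    idx = {p: i for i, p in enumerate(pops)}

    # active clusters: label -> (member labels, tree node, node height)
    nodes: dict[str, tuple[list[str], dendropy.Node, float]] = {}
    for p in pops:
        node = dendropy.Node(taxon=taxa.get_taxon(p))
        nodes[p] = ([p], node, 0.0)

    def linkage(mem_a, mem_b):
        return max(D[idx[x], idx[y]] for x in mem_a for y in mem_b)

    while len(nodes) > 1:
        labels = sorted(nodes)
        best = None
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                d = linkage(nodes[a][0], nodes[b][0])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        mem_a, node_a, h_a = nodes.pop(a)
        mem_b, node_b, h_b = nodes.pop(b)
        h = d / 2.0
        parent = dendropy.Node()
        node_a.edge.length = h - h_a
        node_b.edge.length = h - h_b
        parent.add_child(node_a)
        parent.add_child(node_b)
        nodes[min(a, b)] = (mem_a + mem_b, parent, h)

    (_, root, _), = nodes.values()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    root.edge.length = None
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# global F_ST (Weir-Cockerham variance components)


def _genotype_summaries(g: pd.DataFrame):
    """Per (pop, locus): sample size n_i (called genotypes), allele counts and
    heterozygote counts per allele."""
    called = g.dropna(subset=["allele_a", "allele_b"]).copy()
    called["allele_a"] = called["allele_a"].astype(int)
    called["allele_b"] = called["allele_b"].astype(int)
    out = {}
    for (pop, locus), sub in called.groupby(["population_id", "locus_id"], sort=True):
        a = sub["allele_a"].to_numpy()
        b = sub["allele_b"].to_numpy()
        n_i = len(sub)
        ac: dict[int, int] = {}
        het: dict[int, int] = {}
        for allele in np.unique(np.concatenate([a, b])):
            allele = int(allele)
            ac[allele] = int(np.sum(a == allele) + np.sum(b == allele))
            het[allele] = int(np.sum((a == allele) ^ (b == allele)))
        out[(pop, locus)] = (n_i, ac, het)
    return out


def global_fst_from_summaries(summ: dict, pops: list[str], loci: list[str]) -> float:
    """Global Weir-Cockerham theta as a ratio of sums of variance components
    over all loci and alleles.

    Components per locus/allele (r populations typed, n_i genotypes in pop i,
    p_i allele frequency, h_i observed heterozygote frequency):

        nbar  = mean n_i                     nc = (r*nbar - sum n_i^2/(r*nbar)) / (r-1)
        pbar  = sum n_i p_i / (r*nbar)       s2 = sum n_i (p_i-pbar)^2 / ((r-1)*nbar)
        hbar  = sum n_i h_i / (r*nbar)

        a = nbar/nc * (s2 - (pbar(1-pbar) - (r-1)/r*s2 - hbar/4) / (nbar-1))
        b = nbar/(nbar-1) * (pbar(1-pbar) - (r-1)/r*s2 - (2nbar-1)/(4nbar)*hbar)
        c = hbar/2

    theta = sum a / sum (a+b+c).  Negative estimates are reported as computed.
    """
    sum_a = sum_abc = 0.0
    any_poly = False
    for locus in loci:
        present = [p for p in pops if (p, locus) in summ]
        r = len(present)
        if r < 2:
            continue
        n = np.array([summ[(p, locus)][0] for p in present], dtype=float)
        nbar = n.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
        alleles = sorted({a for p in present for a in summ[(p, locus)][1]})
        if len(alleles) < 2:
            continue
        any_poly = True
        for allele in alleles:
            p_i = np.array(
                [summ[(p, locus)][1].get(allele, 0) / (2 * summ[(p, locus)][0])
                 for p in present]
            )
            h_i = np.array(
                [summ[(p, locus)][2].get(allele, 0) / summ[(p, locus)][0]
                 for p in present]
            )
            pbar = float(np.sum(n * p_i) / (r * nbar))
            s2 = float(np.sum(n * (p_i - pbar) ** 2) / ((r - 1) * nbar))
            hbar = float(np.sum(n * h_i) / (r * nbar))
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
            b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
    if not any_poly:
        raise ValueError("no polymorphism: cannot estimate F_ST")
    return sum_a / sum_abc


def global_fst(g: pd.DataFrame) -> float:
    """Global F_ST over all loci (see :func:`global_fst_from_summaries`)."""
    pops = sorted(g["population_id"].unique())
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    loci = sorted(g["locus_id"].unique())
    return global_fst_from_summaries(_genotype_summaries(g), pops, loci)


@dataclass
class FstResult:
    fst: float
    ci_low: float
    ci_high: float
    n_boot: int

    @property
    def ci(self):
        return (self.ci_low, self.ci_high)


def cluster_bootstrap_fst(g: pd.DataFrame, n_boot: int = 1000, seed=0) -> FstResult:
    """Global F_ST with a 95% cluster-bootstrap percentile CI.

    Populations (clusters) are resampled with replacement to the original
    count, duplicates relabelled uniquely, and theta recomputed per replicate;
    the CI is the 2.5/97.5 percentile of the replicate distribution.
    Replicates without polymorphism are redrawn up to 10 times, then dropped
    with a warning.
    """
    pops = sorted(g["population_id"].unique())
    loci = sorted(g["locus_id"].unique())
    summ = _genotype_summaries(g)
    point = global_fst_from_summaries(summ, pops, loci)
    rng = np.random.default_rng(seed)
    reps = []
    n_failed = 0
    for _ in range(n_boot):
        for _retry in range(10):
            chosen = [pops[k] for k in rng.integers(0, len(pops), size=len(pops))]
            # relabel duplicates: each draw is its own cluster
            relabelled = {f"{p}#{i}": p for i, p in enumerate(chosen)}
            boot_summ = {
                (lab, locus): summ[(orig, locus)]
                for lab, orig in relabelled.items()
                for locus in loci
                if (orig, locus) in summ
            }
            try:
                reps.append(
                    global_fst_from_summaries(boot_summ, sorted(relabelled), loci)
                )
                break
            except ValueError:
                continue
        else:
            n_failed += 1
    if n_failed > n_boot / 2:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap replicates failed")
    if n_failed:
        log.warning("%d/%d F_ST bootstrap replicates dropped", n_failed, n_boot)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    if not (lo <= point <= hi):
        log.info("F_ST percentile CI (%g, %g) excludes point estimate %g", lo, hi, point)
    return FstResult(fst=point, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)
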