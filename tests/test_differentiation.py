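"""Differentiation: WC F_ST vs an independent oracle, R_ST invariances, the
allele-size permutation test, IBD regressions, and NJ trees."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ssrphylo.datasets import NUCLEAR, GenotypeDataset, Locus, PopulationMeta
from ssrphylo.differentiation import (allele_size_permutation_test,
                                      bootstrap_support, fst_matrix,
                                      global_rst, haversine_matrix,
                                      ibd_regression, nj_tree, pairwise_fst,
                                      pairwise_rst, tree_bipartitions)
from conftest import make_dataset


# ---------------------------------------------------------------------------
# Independent Weir-Cockerham 1984 oracle (textbook formulas, scalar loops)
# ---------------------------------------------------------------------------

def wc_theta_oracle(pop_genotype_lists):
    """Multilocus WC theta computed allele by allele with plain loops.

    ``pop_genotype_lists``: per locus, a list (one entry per population) of
    genotype tuples.  Deliberately written scalar-style, independently of the
    package's vectorised implementation.
    """
    sum_a = sum_abc = 0.0
    for per_pop in pop_genotype_lists:
        r = len(per_pop)
        n = [len(g) for g in per_pop]
        if min(n) < 1 or r < 2:
            continue
        nbar = sum(n) / r
        nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
        alleles = sorted({a for pop in per_pop for pair in pop for a in pair})
        if len(alleles) < 2:
            continue
        for al in alleles:
            p = []
            h = []
            for pop in per_pop:
                copies = [a for pair in pop for a in pair]
                p.append(copies.count(al) / len(copies))
                h.append(sum(1 for pair in pop if (pair[0] == al) != (pair[1] == al))
                         / len(pop))
            pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
            s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
            hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
            a = nbar / nc * (s2 - 1 / (nbar - 1)
                             * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
            b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
    return sum_a / sum_abc


def random_two_pop_dataset(seed, n_loci=4, n_ind=12):
    rng = np.random.default_rng(seed)
    loci = [Locus(f"L{j}", NUCLEAR, 2) for j in range(n_loci)]
    pops = {}
    for p in ("a", "b"):
        freqs = rng.dirichlet(np.ones(4), size=n_loci)
        inds = []
        for _ in range(n_ind):
            inds.append([tuple(rng.choice(4, 2, p=freqs[j]) + 1)
                         for j in range(n_loci)])
        pops[p] = inds
    return make_dataset(pops, loci)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_wc_fst_matches_independent_oracle(seed):
    ds = random_two_pop_dataset(seed)
    theta = pairwise_fst(ds, "a", "b")
    per_locus = []
    for j in range(ds.n_loci):
        per_locus.append([
            [tuple(pair) for pair in ds.genotypes(j, p)] for p in ("a", "b")])
    assert theta == pytest.approx(wc_theta_oracle(per_locus), abs=1e-10)


def test_fst_extremes():
    loci = [Locus("L", NUCLEAR, 2)]
    fixed = make_dataset({
        "a": [[(1, 1)]] * 20, "b": [[(2, 2)]] * 20}, loci)
    assert pairwise_fst(fixed, "a", "b") == pytest.approx(1.0, abs=1e-9)
    rng = np.random.default_rng(0)
    g = rng.choice([1, 2, 3], size=(50, 2), p=[0.5, 0.3, 0.2])
    same = make_dataset({
        "a": [[tuple(x)] for x in g], "b": [[tuple(x)] for x in g]}, loci)
    assert abs(pairwise_fst(same, "a", "b")) < 0.02
    mono = make_dataset({"a": [[(1, 1)]] * 5, "b": [[(1, 1)]] * 5}, loci)
    assert np.isnan(pairwise_fst(mono, "a", "b"))


# ---------------------------------------------------------------------------
# R_ST
# ---------------------------------------------------------------------------

def shifted_size_dataset(shift=10, seed=1, n=25):
    """Two populations whose allele sizes differ by a mean shift (SMM-like
    divergence): R_ST should far exceed F_ST."""
    rng = np.random.default_rng(seed)
    loci = [Locus(f"L{j}", NUCLEAR, 2, allele_unit="repeat_count") for j in range(3)]
    pops = {}
    for p, centre in (("a", 20), ("b", 20 + shift)):
        inds = [[tuple(centre + rng.integers(-1, 2, size=2)) for _ in loci]
                for _ in range(n)]
        pops[p] = inds
    return make_dataset(pops, loci)


def test_rst_exceeds_fst_under_size_divergence():
    ds = shifted_size_dataset()
    rst = pairwise_rst(ds, "a", "b", loci=list(range(3)))
    fst = pairwise_fst(ds, "a", "b")
    assert rst > fst + 0.2
    assert rst > 0.8


def test_rst_invariant_to_affine_size_changes():
    ds = shifted_size_dataset(seed=2)
    base = pairwise_rst(ds, "a", "b", loci=list(range(3)))
    shifted = GenotypeDataset(
        loci=ds.loci, pop_ids=ds.pop_ids, individuals=ds.individuals,
        pop_index=ds.pop_index, alleles=ds.alleles + 100)
    assert pairwise_rst(shifted, "a", "b", loci=list(range(3))) == pytest.approx(base, abs=1e-12)
    scaled = GenotypeDataset(
        loci=ds.loci, pop_ids=ds.pop_ids, individuals=ds.individuals,
        pop_index=ds.pop_index, alleles=ds.alleles * 3)
    assert pairwise_rst(scaled, "a", "b", loci=list(range(3))) == pytest.approx(base, abs=1e-12)


def test_rst_missing_for_monomorphic_locus():
    loci = [Locus("L", NUCLEAR, 2, allele_unit="repeat_count")]
    mono = make_dataset({"a": [[(5, 5)]] * 5, "b": [[(5, 5)]] * 5}, loci)
    assert np.isnan(pairwise_rst(mono, "a", "b", loci=[0]))


# ---------------------------------------------------------------------------
# Allele-size permutation test
# ---------------------------------------------------------------------------

def test_permutation_test_detects_stepwise_divergence():
    ds = shifted_size_dataset(shift=12, seed=3)
    res = allele_size_permutation_test(ds, n_perm=199, seed=0)
    assert res.p_value < 0.05


def test_permutation_test_null_calibration():
    """When sizes are random labels the test should reject at ~5%."""
    rng = np.random.default_rng(0)
    rejections = 0
    n_rep = 60
    for rep in range(n_rep):
        loci = [Locus(f"L{j}", NUCLEAR, 2, allele_unit="repeat_count")
                for j in range(3)]
        pops = {}
        for p in ("a", "b"):
            freqs = rng.dirichlet(np.ones(5), size=3)
            pops[p] = [[tuple(rng.choice(5, 2, p=freqs[j]) + 10)
                        for j in range(3)] for _ in range(15)]
        ds = make_dataset(pops, loci)
        res = allele_size_permutation_test(ds, n_perm=99, seed=rep)
        if res.p_value <= 0.05:
            rejections += 1
    assert rejections / n_rep < 0.15  # ~5% nominal, allow Monte-Carlo slack


def test_permutation_requires_enough_permutations():
    ds = shifted_size_dataset()
    with pytest.raises(ValueError):
        allele_size_permutation_test(ds, n_perm=10)


# ---------------------------------------------------------------------------
# Geographic distances and IBD
# ---------------------------------------------------------------------------

def test_haversine_basics():
    metas = [PopulationMeta("o", latitude=0.0, longitude=0.0),
             PopulationMeta("e", latitude=0.0, longitude=1.0),
             PopulationMeta("o2", latitude=0.0, longitude=0.0)]
    km = haversine_matrix(metas)
    assert km.loc["o", "o2"] == 0.0
    assert km.loc["o", "e"] == pytest.approx(111.19, abs=0.01)
    assert np.allclose(km.to_numpy(), km.to_numpy().T)
    with pytest.raises(ValueError, match="bad"):
        haversine_matrix([PopulationMeta("bad")])


def exact_linear_matrices(n=6):
    rng = np.random.default_rng(4)
    lat = 42 + rng.uniform(0, 2, n)
    lon = rng.uniform(-1, 3, n)
    metas = [PopulationMeta(f"p{i}", latitude=lat[i], longitude=lon[i])
             for i in range(n)]
    km = haversine_matrix(metas)
    stat = km * 0.001
    return stat, km


def test_ibd_exact_linear_relation():
    stat, km = exact_linear_matrices()
    res = ibd_regression(stat, km, n_perm=199, seed=0)
    assert res.slope == pytest.approx(0.001, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0)
    assert res.p_value < 0.05


def test_ibd_constant_stat():
    _, km = exact_linear_matrices()
    stat = km * 0.0
    res = ibd_regression(stat, km, n_perm=99, seed=0)
    assert res.slope == 0.0
    assert res.p_value == 1.0


def test_ibd_positive_slope_detected_with_noise():
    rng = np.random.default_rng(8)
    detected = 0
    for rep in range(10):
        stat, km = exact_linear_matrices(8)
        noise = rng.normal(0, 0.01, stat.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        res = ibd_regression(stat + noise, km, n_perm=199, seed=rep)
        if res.p_value < 0.05 and res.slope > 0:
            detected += 1
    assert detected >= 8


def test_ibd_slope_difference_null():
    stat, km = exact_linear_matrices()
    res = ibd_regression(stat, km, n_perm=99, seed=1, stat2=stat * 1.0)
    assert res.slope_difference == pytest.approx(0.0, abs=1e-15)
    assert res.slope_difference_p > 0.5


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxa_closed_form():
    d = pd.DataFrame([[0, 5, 9], [5, 0, 10], [9, 10, 0]],
                     index=list("ABC"), columns=list("ABC"))
    res = nj_tree(d)
    tree = res.tree
    # additive 3-taxon metric: tip-to-tip path lengths reproduce the input
    for x, y in itertools.combinations("ABC", 2):
        assert tree.find(x).distance(tree.find(y)) == pytest.approx(d.loc[x, y])


def random_additive_matrix(rng, n):
    """Distances from a random binary tree with positive branch lengths."""
    import skbio
    nodes = [skbio.TreeNode(name=chr(65 + i)) for i in range(n)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = skbio.TreeNode(children=[a, b])
        a.length = float(rng.uniform(0.5, 2.0))
        b.length = float(rng.uniform(0.5, 2.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = nodes[0]
    taxa = [chr(65 + i) for i in range(n)]
    m = np.zeros((n, n))
    for i, x in enumerate(taxa):
        for j, y in enumerate(taxa):
            if i < j:
                m[i, j] = m[j, i] = tree.find(x).distance(tree.find(y))
    return tree, pd.DataFrame(m, index=taxa, columns=taxa)


@pytest.mark.parametrize("seed,n", [(0, 5), (1, 6), (2, 8), (3, 7), (4, 5)])
def test_nj_recovers_additive_trees(seed, n):
    rng = np.random.default_rng(seed)
    true_tree, d = random_additive_matrix(rng, n)
    res = nj_tree(d)
    taxa = list(d.index)
    assert tree_bipartitions(res.tree, taxa) == tree_bipartitions(true_tree, taxa)
    # branch lengths: pairwise path distances reproduced
    for x, y in itertools.combinations(taxa, 2):
        assert res.tree.find(x).distance(res.tree.find(y)) == pytest.approx(
            d.loc[x, y], abs=1e-9)


def test_nj_duplicate_taxa_form_cherry():
    d = pd.DataFrame([[0, 0, 4, 5], [0, 0, 4, 5], [4, 4, 0, 3], [5, 5, 3, 0]],
                     index=list("ABCD"), columns=list("ABCD"), dtype=float)
    res = nj_tree(d)
    assert frozenset("AB") in tree_bipartitions(res.tree, list("ABCD")) or \
        res.tree.find("A").distance(res.tree.find("B")) == pytest.approx(0.0, abs=1e-9)


def test_bootstrap_support_for_clear_split():
    rng = np.random.default_rng(2)
    loci = [Locus(f"L{j}", NUCLEAR, 2) for j in range(6)]
    pops = {}
    for p, freqs in (("a1", [0.9, 0.1]), ("a2", [0.85, 0.15]),
                     ("b1", [0.1, 0.9]), ("b2", [0.15, 0.85])):
        pops[p] = [[tuple(rng.choice([1, 2], 2, p=freqs)) for _ in loci]
                   for _ in range(15)]
    ds = make_dataset(pops, loci)
    res = bootstrap_support(ds, n_boot=100, seed=0)
    split = frozenset({"a1", "a2"})
    assert res.support.get(split, 0.0) > 0.7
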