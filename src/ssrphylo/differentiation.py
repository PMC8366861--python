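"""Population differentiation and phylogeographic-signal testing.

Weir-Cockerham theta (F_ST) from variance components, Slatkin's R_ST from
allele-size variance components, the allele-size permutation test (sizes
shuffled over allelic states to ask whether R_ST exceeds its permutational
null, i.e. whether stepwise mutation contributes to differentiation),
isolation-by-distance regressions on great-circle distances, and a
neighbor-joining population tree with locus bootstraps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .datasets import GenotypeDataset

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components_diploid(pop_genotypes: list[np.ndarray]):
    """Per-allele WC (1984) variance components (a, b, c) for one locus.

    ``pop_genotypes``: one (n_i, 2) array of observed diploid genotypes per
    population.  Returns summed components over alleles.
    """
    r = len(pop_genotypes)
    n = np.array([len(g) for g in pop_genotypes], dtype=float)
    if (n < 1).sum() or r < 2:
        return 0.0, 0.0, 0.0
    nbar = n.mean()
    nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in pop_genotypes]))
    K = len(alleles)
    if K < 2:
        return 0.0, 0.0, 0.0
    P = np.empty((r, K))   # allele frequencies per population
    H = np.zeros((r, K))   # heterozygote frequencies per allele
    for i, g in enumerate(pop_genotypes):
        idx = np.searchsorted(alleles, g.ravel())
        P[i] = np.bincount(idx, minlength=K) / (2.0 * n[i])
        het = g[:, 0] != g[:, 1]
        if het.any():
            hidx = np.searchsorted(alleles, g[het].ravel())
            H[i] = np.bincount(hidx, minlength=K) / n[i]
    w = n / n.sum()
    pbar = w @ P
    s2 = (n[:, None] * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = w @ H
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _wc_components_haploid(pop_alleles: list[np.ndarray]):
    """Haploid analogue of the WC components: (a, b) from a one-way ANOVA on
    allele indicators with gene copies as units."""
    r = len(pop_alleles)
    n = np.array([len(g) for g in pop_alleles], dtype=float)
    if r < 2 or (n < 2).any():
        return 0.0, 0.0
    nbar = n.mean()
    nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
    alleles = np.unique(np.concatenate(pop_alleles))
    K = len(alleles)
    if K < 2:
        return 0.0, 0.0
    P = np.empty((r, K))
    for i, g in enumerate(pop_alleles):
        idx = np.searchsorted(alleles, g)
        P[i] = np.bincount(idx, minlength=K) / n[i]
    w = n / n.sum()
    pbar = w @ P
    s2 = (n[:, None] * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    return float(a.sum()), float(b.sum())


def pairwise_fst(ds: GenotypeDataset, pop_a: str, pop_b: str,
                 loci: list[int] | None = None) -> float:
    """Multilocus Weir-Cockerham theta between two populations.

    Variance components are summed across loci (and alleles) before the
    ratio is taken.  Haploid loci contribute haploid components.  Returns NaN
    when no shared polymorphic locus exists.
    """
    if loci is None:
        loci = list(range(ds.n_loci))
    num = den = 0.0
    informative = False
    for j in loci:
        if ds.loci[j].ploidy == 2:
            gs = [ds.genotypes(j, p) for p in (pop_a, pop_b)]
            if min(len(g) for g in gs) < 2:
                continue
            a, b, c = _wc_components_diploid(gs)
            if a == b == c == 0.0:
                continue
            num += a
            den += a + b + c
        else:
            gs = [ds.genotypes(j, p).ravel() for p in (pop_a, pop_b)]
            if min(len(g) for g in gs) < 2:
                continue
            a, b = _wc_components_haploid(gs)
            if a == b == 0.0:
                continue
            num += a
            den += a + b
        informative = True
    if not informative or den == 0:
        return float("nan")
    return num / den


def fst_matrix(ds: GenotypeDataset, loci: list[int] | None = None) -> pd.DataFrame:
    pops = ds.pop_ids
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            v = pairwise_fst(ds, pops[i], pops[j], loci)
            m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# R_ST (allele-size variance components)
# ---------------------------------------------------------------------------

def _size_components(pop_sizes: list[np.ndarray]):
    """ANOVA components of allele-size variance: (sigma2_among, sigma2_within)."""
    r = len(pop_sizes)
    n = np.array([len(s) for s in pop_sizes], dtype=float)
    if r < 2 or (n < 2).any():
        return 0.0, 0.0
    N = n.sum()
    nc = (N - (n ** 2).sum() / N) / (r - 1)
    means = np.array([s.mean() for s in pop_sizes])
    grand = np.concatenate(pop_sizes).mean()
    ss_within = sum(((s - m) ** 2).sum() for s, m in zip(pop_sizes, means))
    ss_among = (n * (means - grand) ** 2).sum()
    msw = ss_within / (N - r)
    msa = ss_among / (r - 1)
    s2_a = (msa - msw) / nc
    return s2_a, msw


def _locus_sizes(ds: GenotypeDataset, j: int, pops: list[str],
                 size_map: dict[int, float] | None = None) -> list[np.ndarray]:
    loc = ds.loci[j]
    out = []
    for p in pops:
        g = ds.genotypes(j, p).ravel().astype(float)
        if size_map is not None:
            g = np.array([size_map[int(a)] for a in g], dtype=float)
        if loc.allele_unit == "fragment_bp":
            g = g / loc.motif_length
        out.append(g)
    return out


def pairwise_rst(ds: GenotypeDataset, pop_a: str, pop_b: str,
                 loci: list[int] | None = None,
                 size_maps: dict[int, dict[int, float]] | None = None) -> float:
    """Slatkin's R_ST between two populations from repeat-unit allele sizes.

    R_ST = sigma2_among / (sigma2_among + sigma2_within), components summed
    over loci.  ``size_maps`` optionally reassigns sizes to allelic states
    (used by the permutation test).
    """
    if loci is None:
        loci = ds.nuclear_locus_indices()
    num = den = 0.0
    informative = False
    for j in loci:
        sm = size_maps.get(j) if size_maps else None
        sizes = _locus_sizes(ds, j, [pop_a, pop_b], sm)
        if min(len(s) for s in sizes) < 2:
            continue
        if len({float(x) for s in sizes for x in s}) < 2:
            continue
        s2a, s2w = _size_components(sizes)
        num += s2a
        den += s2a + s2w
        informative = True
    if not informative or den == 0:
        return float("nan")
    return num / den


def global_rst(ds: GenotypeDataset, loci: list[int] | None = None,
               size_maps=None) -> float:
    """Global multilocus R_ST over all populations."""
    if loci is None:
        loci = ds.nuclear_locus_indices()
    num = den = 0.0
    informative = False
    for j in loci:
        sm = size_maps.get(j) if size_maps else None
        sizes = _locus_sizes(ds, j, ds.pop_ids, sm)
        sizes = [s for s in sizes if len(s) >= 2]
        if len(sizes) < 2:
            continue
        if len({float(x) for s in sizes for x in s}) < 2:
            continue
        s2a, s2w = _size_components(sizes)
        num += s2a
        den += s2a + s2w
        informative = True
    if not informative or den == 0:
        return float("nan")
    return num / den


@dataclass
class PermutationTestResult:
    observed_rst: float
    null_rst: np.ndarray
    p_value: float
    n_permutations: int


def allele_size_permutation_test(ds: GenotypeDataset, n_perm: int = 1000,
                                 scope: str = "global",
                                 pops: tuple[str, str] | None = None,
                                 loci: list[int] | None = None,
                                 seed: int | None = None) -> PermutationTestResult:
    """Test for phylogeographic signal by permuting allele sizes over states.

    Within each locus the size labels are shuffled among the distinct allelic
    states (allele identities preserved, sizes reassigned) and R_ST is
    recomputed; under the null that sizes carry no history, the observed R_ST
    behaves like an F_ST analogue.  One-sided p with the +1 correction.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    if loci is None:
        loci = ds.nuclear_locus_indices()
    # loci with at least two distinct sizes
    usable = []
    states: dict[int, list[int]] = {}
    for j in loci:
        al = sorted(ds.allele_counts(j))
        if len(al) >= 2:
            usable.append(j)
            states[j] = al
    if scope == "global":
        def stat(maps):
            return global_rst(ds, usable, maps)
    elif scope == "pairwise":
        if pops is None:
            raise ValueError("pairwise scope requires pops=(a, b)")
        def stat(maps):
            return pairwise_rst(ds, pops[0], pops[1], usable, maps)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    observed = stat(None)
    null = np.empty(n_perm)
    for k in range(n_perm):
        maps = {}
        for j in usable:
            al = states[j]
            perm = rng.permutation(al)
            maps[j] = {a: float(s) for a, s in zip(al, perm)}
        null[k] = stat(maps)
    p = (1 + np.sum(null >= observed)) / (n_perm + 1)
    return PermutationTestResult(observed, null, float(p), n_perm)


# ---------------------------------------------------------------------------
# Geography and isolation by distance
# ---------------------------------------------------------------------------

def haversine_matrix(meta) -> pd.DataFrame:
    """Great-circle distance matrix in km (sphere radius 6371 km)."""
    ids, lats, lons = [], [], []
    for m in meta:
        if not (np.isfinite(m.latitude) and np.isfinite(m.longitude)):
            raise ValueError(f"missing coordinates for population {m.pop_id}")
        ids.append(m.pop_id)
        lats.append(np.radians(m.latitude))
        lons.append(np.radians(m.longitude))
    lat = np.array(lats)[:, None]
    lon = np.array(lons)[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class IbdResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_permutations: int
    slope_difference: float = float("nan")
    slope_difference_p: float = float("nan")


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def _ols(x: np.ndarray, y: np.ndarray):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    vx = np.var(x)
    if vx == 0:
        raise ValueError("zero-variance distances")
    slope = np.cov(x, y, bias=True)[0, 1] / vx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, r2


def ibd_regression(stat: pd.DataFrame, km: pd.DataFrame, n_perm: int = 1000,
                   seed: int | None = None,
                   stat2: pd.DataFrame | None = None,
                   linearized: bool = False, log_distance: bool = False) -> IbdResult:
    """Isolation-by-distance regression with a Mantel permutation test.

    OLS of the lower triangle of ``stat`` on geographic distance; significance
    by permuting population labels of the stat matrix (two-sided on the
    slope).  With ``stat2`` (e.g. R_ST vs F_ST matrices) the slope difference
    stat2-slope minus stat-slope is tested under the same joint permutations.
    ``linearized`` regresses F/(1-F); ``log_distance`` uses log km.
    """
    if stat.shape[0] < 4:
        raise ValueError("need at least 4 populations")
    S = stat.to_numpy().astype(float)
    D = km.loc[stat.index, stat.columns].to_numpy().astype(float)
    if linearized:
        S = S / (1 - S)
    if log_distance:
        with np.errstate(divide="ignore"):
            D = np.log(D)
            D[~np.isfinite(D)] = np.nan
    S2 = stat2.to_numpy().astype(float) if stat2 is not None else None
    if S2 is not None and linearized:
        S2 = S2 / (1 - S2)

    x = _lower_triangle(D)
    slope, intercept, r2 = _ols(x, _lower_triangle(S))
    obs_diff = float("nan")
    if S2 is not None:
        slope2, _, _ = _ols(x, _lower_triangle(S2))
        obs_diff = slope2 - slope

    rng = np.random.default_rng(seed)
    n = S.shape[0]
    count = 0
    count_diff = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sp = S[np.ix_(perm, perm)]
        s_slope, _, _ = _ols(x, _lower_triangle(sp))
        if abs(s_slope) >= abs(slope):
            count += 1
        if S2 is not None:
            s2p = S2[np.ix_(perm, perm)]
            s2_slope, _, _ = _ols(x, _lower_triangle(s2p))
            if abs(s2_slope - s_slope) >= abs(obs_diff):
                count_diff += 1
    p = (1 + count) / (n_perm + 1)
    p_diff = (1 + count_diff) / (n_perm + 1) if S2 is not None else float("nan")
    return IbdResult(float(slope), float(intercept), float(r2), float(p),
                     n_perm, obs_diff, p_diff)


# ---------------------------------------------------------------------------
# Neighbor-joining tree and locus bootstrap
# ---------------------------------------------------------------------------

@dataclass
class PopulationTree:
    tree: TreeNode
    taxa: list[str]
    support: dict[frozenset, float] = field(default_factory=dict)

    def newick(self) -> str:
        return str(self.tree).strip()


def nj_tree(distance: pd.DataFrame) -> PopulationTree:
    """Saitou-Nei neighbor joining on a distance matrix (F_ST units).

    Small negative entries (WC estimator noise) are clipped to zero.
    """
    taxa = list(distance.index)
    m = distance.to_numpy().astype(float)
    m = np.clip((m + m.T) / 2, 0.0, None)
    np.fill_diagonal(m, 0.0)
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa")
    if len(taxa) == 2:
        t = TreeNode.read([f"({taxa[0]}:{m[0, 1] / 2},{taxa[1]}:{m[0, 1] / 2});"])
        return PopulationTree(t, taxa)
    dm = DistanceMatrix(m, ids=taxa)
    tree = nj(dm)
    return PopulationTree(tree, taxa)


def tree_bipartitions(tree: TreeNode, taxa: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the smaller side's taxa."""
    all_taxa = frozenset(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            other = all_taxa - side
            canonical = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
            parts.add(canonical)
    return parts


def bootstrap_support(ds: GenotypeDataset, n_boot: int = 1000,
                      loci: list[int] | None = None,
                      seed: int | None = None,
                      extra_distances: pd.DataFrame | None = None) -> PopulationTree:
    """NJ tree on the F_ST matrix with bipartition support from locus bootstraps.

    Loci (the exchangeable unit for a distance-matrix tree) are resampled
    with replacement; the F_ST matrix and tree are recomputed and bipartition
    occurrences tallied.  ``extra_distances`` is unsupported here (outgroups
    enter by augmenting the input matrix before calling :func:`nj_tree`).
    """
    if loci is None:
        loci = list(range(ds.n_loci))
    base = fst_matrix(ds, loci)
    result = nj_tree(base)
    tally: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        samp = [loci[i] for i in rng.integers(0, len(loci), size=len(loci))]
        bm = fst_matrix(ds, samp)
        bt = nj_tree(bm.fillna(0.0))
        for part in tree_bipartitions(bt.tree, bt.taxa):
            tally[part] = tally.get(part, 0) + 1
    result.support = {p: c / n_boot for p, c in tally.items()}
    return result
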