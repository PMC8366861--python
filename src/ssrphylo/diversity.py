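"""Within-population diversity statistics for microsatellite data.

Implements Nei's sample-size-corrected gene diversity, effective allele
number, the unique-allele proportion, the inbreeding coefficient, rarefied
allelic and private-allelic richness (exact combinatorial rarefaction on the
observed allele counts), and a PCA on individual allele-dosage vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.decomposition import PCA

from .datasets import MISSING, GenotypeDataset


# ---------------------------------------------------------------------------
# Single-locus statistics on allele counts
# ---------------------------------------------------------------------------

def expected_heterozygosity(counts: dict[int, int] | np.ndarray) -> float:
    """Nei's unbiased gene diversity H_e = n/(n-1) * (1 - sum p_i^2).

    ``counts`` are observed gene copies per allele; returns NaN for n < 2.
    """
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=float)
    n = c.sum()
    if n < 2:
        return float("nan")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p ** 2)))


def effective_alleles(counts: dict[int, int] | np.ndarray, unbiased: bool = True) -> float:
    """Effective number of alleles N_Ae.

    Default uses the sample-size-corrected gene diversity, N_Ae = 1/(1-H_e);
    ``unbiased=False`` gives the naive 1/sum(p_i^2).  H_e = 1 exactly returns
    inf (saturated).
    """
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=float)
    n = c.sum()
    if n < 2:
        return float("nan")
    if unbiased:
        he = expected_heterozygosity(c)
        if he >= 1.0:
            return float("inf")
        return float(1.0 / (1.0 - he))
    p = c / n
    return float(1.0 / np.sum(p ** 2))


def observed_heterozygosity(genotypes: np.ndarray) -> float:
    """Proportion of heterozygous genotypes among (n, 2) diploid rows."""
    g = np.asarray(genotypes)
    if len(g) == 0:
        return float("nan")
    return float(np.mean(g[:, 0] != g[:, 1]))


# ---------------------------------------------------------------------------
# Rarefied richness (exact combinatorics, log-space binomials)
# ---------------------------------------------------------------------------

def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _presence_prob(counts: np.ndarray, g: int) -> np.ndarray:
    """P(allele present in a random subsample of g of N gene copies), per allele."""
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    prob = np.ones_like(counts)
    can_miss = N - counts >= g
    prob[can_miss] = 1.0 - np.exp(_log_choose(N - counts[can_miss], g) - _log_choose(N, g))
    return prob


def rarefied_richness(counts: dict[int, int] | np.ndarray, g: int) -> float:
    """Expected number of distinct alleles in a subsample of g gene copies."""
    if g < 2:
        raise ValueError("g must be >= 2")
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=float)
    c = c[c > 0]
    if c.sum() < g:
        raise ValueError(f"g={g} exceeds observed gene copies N={int(c.sum())}")
    return float(_presence_prob(c, g).sum())


def private_rarefied_richness(counts_by_pop: dict[str, dict[int, int]], g: int) -> dict[str, float]:
    """Expected number of alleles private to each population at rarefaction g.

    For population j: sum over alleles of P(present in j's subsample) times
    the product over other populations of P(absent from their subsamples).
    Populations with fewer than g gene copies are dropped (with the alleles
    they carry still counted as potentially shared by the remaining ones only
    through their own samples, matching the rarefaction definition).
    """
    if g < 2:
        raise ValueError("g must be >= 2")
    pops = {p: c for p, c in counts_by_pop.items()
            if sum(c.values()) >= g}
    alleles = sorted({a for c in pops.values() for a in c})
    a_idx = {a: i for i, a in enumerate(alleles)}
    pres = {}
    for p, c in pops.items():
        vec = np.zeros(len(alleles))
        for a, n in c.items():
            vec[a_idx[a]] = n
        N = vec.sum()
        prob = np.zeros(len(alleles))
        nz = vec > 0
        can_miss = (N - vec >= g) & nz
        prob[can_miss] = 1.0 - np.exp(_log_choose(N - vec[can_miss], g) - _log_choose(N, g))
        prob[nz & ~can_miss] = 1.0
        pres[p] = prob
    out = {}
    for p in pops:
        absent_others = np.ones(len(alleles))
        for q in pops:
            if q != p:
                absent_others *= 1.0 - pres[q]
        out[p] = float(np.sum(pres[p] * absent_others))
    return out


# ---------------------------------------------------------------------------
# Population-level summaries
# ---------------------------------------------------------------------------

def unique_allele_proportion(ds: GenotypeDataset, pop_id: str,
                             loci: list[int] | None = None) -> float:
    """Proportion of the population's alleles carried by a single individual.

    An allele homozygous in one individual and absent elsewhere still counts
    (the unit is the individual, not the gene copy).
    """
    if loci is None:
        loci = list(range(ds.n_loci))
    sel = ds.pop_index == ds.pop_number(pop_id)
    n_unique = 0
    n_total = 0
    for j in loci:
        g = ds.alleles[sel, j, : ds.loci[j].ploidy]
        carriers: dict[int, int] = {}
        for row in g:
            for a in set(int(x) for x in row if x != MISSING):
                carriers[a] = carriers.get(a, 0) + 1
        n_total += len(carriers)
        n_unique += sum(1 for c in carriers.values() if c == 1)
    if n_total == 0:
        return float("nan")
    return n_unique / n_total


def inbreeding_fi(ds: GenotypeDataset, pop_id: str) -> tuple[dict[str, float], float]:
    """Inbreeding coefficient F_i = 1 - H_o/H_e per nuclear locus and multilocus.

    The multilocus value uses the ratio of summed H_o to summed H_e over loci
    with H_e > 0.
    """
    per_locus: dict[str, float] = {}
    sum_ho = sum_he = 0.0
    for j in ds.nuclear_locus_indices():
        g = ds.genotypes(j, pop_id)
        if len(g) < 2:
            per_locus[ds.loci[j].name] = float("nan")
            continue
        he = expected_heterozygosity(ds.allele_counts(j, pop_id))
        ho = observed_heterozygosity(g)
        if not np.isfinite(he) or he == 0:
            per_locus[ds.loci[j].name] = float("nan")
            continue
        per_locus[ds.loci[j].name] = 1.0 - ho / he
        sum_ho += ho
        sum_he += he
    multi = 1.0 - sum_ho / sum_he if sum_he > 0 else float("nan")
    return per_locus, multi


@dataclass
class DiversityStats:
    pop_id: str
    n_a: float
    n_ae: float
    h_e: float
    a_u: float
    f_i: float
    ar: float = float("nan")
    par: float = float("nan")


def population_diversity(ds: GenotypeDataset, pop_id: str,
                         loci: list[int] | None = None,
                         g_rarefaction: int | None = None) -> DiversityStats:
    """Locus-averaged diversity summary for one population.

    All per-locus statistics are averaged unweighted over loci with data.
    ``g_rarefaction`` adds rarefied allelic richness (private richness is a
    cross-population quantity; see :func:`diversity_table`).
    """
    if loci is None:
        loci = list(range(ds.n_loci))
    nas, naes, hes, ars = [], [], [], []
    for j in loci:
        counts = ds.allele_counts(j, pop_id)
        n = sum(counts.values())
        if n < 2:
            continue
        nas.append(len(counts))
        hes.append(expected_heterozygosity(counts))
        naes.append(effective_alleles(counts))
        if g_rarefaction is not None and n >= g_rarefaction:
            ars.append(rarefied_richness(counts, g_rarefaction))
    _, fi = inbreeding_fi(ds, pop_id)
    return DiversityStats(
        pop_id=pop_id,
        n_a=float(np.mean(nas)) if nas else float("nan"),
        n_ae=float(np.mean(naes)) if naes else float("nan"),
        h_e=float(np.mean(hes)) if hes else float("nan"),
        a_u=unique_allele_proportion(ds, pop_id, loci),
        f_i=fi,
        ar=float(np.mean(ars)) if ars else float("nan"),
    )


def diversity_table(ds: GenotypeDataset, loci: list[int] | None = None,
                    g_rarefaction: int | None = None) -> pd.DataFrame:
    """Per-population DiversityStats as a DataFrame, including private AR."""
    if loci is None:
        loci = list(range(ds.n_loci))
    rows = [population_diversity(ds, p, loci, g_rarefaction).__dict__ for p in ds.pop_ids]
    df = pd.DataFrame(rows).set_index("pop_id")
    if g_rarefaction is not None:
        pars = {p: [] for p in ds.pop_ids}
        for j in loci:
            counts_by_pop = {p: ds.allele_counts(j, p) for p in ds.pop_ids}
            pr = private_rarefied_richness(counts_by_pop, g_rarefaction)
            for p, v in pr.items():
                pars[p].append(v)
        df["par"] = [float(np.mean(pars[p])) if pars[p] else float("nan") for p in ds.pop_ids]
    return df


# ---------------------------------------------------------------------------
# PCA on individual allele dosages
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame            # individuals x axes
    explained_variance: np.ndarray  # proportion per axis
    centroids: pd.DataFrame         # population x axes
    covariances: dict[str, np.ndarray] = field(default_factory=dict)
    loadings_columns: list[str] = field(default_factory=list)


def allele_dosage_matrix(ds: GenotypeDataset, loci: list[int] | None = None):
    """Individuals x alleles dosage matrix (0/0.5/1 diploid; 0/1 haploid).

    Missing genotypes are imputed with the population-mean dosage.
    """
    if loci is None:
        loci = list(range(ds.n_loci))
    cols = []
    names = []
    for j in loci:
        loc = ds.loci[j]
        alleles = sorted(ds.allele_counts(j))
        if not alleles:
            continue
        g = ds.alleles[:, j, : loc.ploidy]
        observed = (g != MISSING).all(axis=1)
        block = np.zeros((ds.n_individuals, len(alleles)))
        for k, a in enumerate(alleles):
            block[:, k] = (g == a).sum(axis=1) / loc.ploidy
        # population-mean imputation for missing rows
        for p in range(len(ds.pop_ids)):
            sel = ds.pop_index == p
            obs = sel & observed
            mean = block[obs].mean(axis=0) if obs.any() else block[observed].mean(axis=0)
            miss = sel & ~observed
            block[miss] = mean
        cols.append(block)
        names.extend(f"{loc.name}.{a}" for a in alleles)
    return np.hstack(cols), names


def pca_allele_freqs(ds: GenotypeDataset, n_axes: int = 10, scale: bool = False,
                     loci: list[int] | None = None) -> PcaResult:
    """Centered PCA on individual allele dosages.

    Optionally unit-variance scaled.  Returns scores, explained-variance
    proportions, and per-population centroids with dosage-score covariance
    matrices (for 95% dispersion ellipses).
    """
    X, names = allele_dosage_matrix(ds, loci)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    if np.allclose(X, 0):
        raise ValueError("constant dosage matrix: PCA undefined")
    n_axes = min(n_axes, min(X.shape) - 1)
    pca = PCA(n_components=n_axes)
    scores = pca.fit_transform(X)
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    sdf = pd.DataFrame(scores, index=ds.individuals, columns=axes)
    sdf["population"] = [ds.pop_ids[i] for i in ds.pop_index]
    centroids = sdf.groupby("population")[axes].mean()
    covs = {}
    for p in ds.pop_ids:
        sub = sdf.loc[sdf["population"] == p, axes[:2]].to_numpy()
        covs[p] = np.cov(sub.T) if len(sub) > 1 else np.zeros((2, 2))
    return PcaResult(
        scores=sdf,
        explained_variance=pca.explained_variance_ratio_,
        centroids=centroids,
        covariances=covs,
        loadings_columns=names,
    )
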