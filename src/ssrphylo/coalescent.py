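"""Backward-time coalescent simulation of microsatellites under four
divergence/admixture scenarios with generalized stepwise mutation.

The demographic model follows four sampled demes -- a reference Alpine deme
("alps"), Eastern and Western Pyrenean demes ("east", "west") and an admixed
contact-zone deme ("adm") -- whose history is one of four scenarios:

S1  Simple split: alps, east and west diverge simultaneously at T1; the
    admixed deme forms by secondary contact of east and west at T2.
S2  Hierarchical split: alps/Pyrenees divergence at T1, east/west divergence
    at T2, secondary contact forming the admixed deme at T3.
S3  Alps-East split at T1; west formed by admixture of alps and east at T2;
    admixed deme formed from east and west at T3.
S4  As S3 with east and west exchanged (Alps-West split first).

Every sampled deme may change size once along its terminal branch (times
Ta..Td), which is what the theta-ratio statistic (current vs ancestral
diversity) later interrogates.  Time is continuous, measured in generations;
the coalescent rate in a deme of (diploid) size N is C(k,2)/(2N) for nuclear
loci and C(k,2)/(c*N) for chloroplast loci with effective copy number c*N
(default c = 1: paternally inherited, one transmitted copy per individual).

Mutations follow the generalized stepwise model: events are Poisson on
branches with per-generation rate mu and each event shifts the repeat count
by +/- k where k - 1 is geometric with parameter P (P = 0 recovers the
strict single-step model); repeat counts are floored at 2 by reflection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import CHLOROPLAST, MISSING, NUCLEAR, GenotypeDataset, Locus

DEMES = ("alps", "east", "west", "adm")


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prior:
    """One-dimensional prior: truncnormal (>low), loguniform, uniform, fixed."""

    family: str
    a: float
    b: float = 0.0
    low: float = 0.0

    def sample(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray | float:
        size = n or 1
        if self.family == "truncnormal":
            out = np.empty(size)
            filled = 0
            while filled < size:
                draw = rng.normal(self.a, self.b, size=2 * (size - filled) + 8)
                draw = draw[draw > self.low]
                take = min(len(draw), size - filled)
                out[filled:filled + take] = draw[:take]
                filled += take
        elif self.family == "loguniform":
            out = np.exp(rng.uniform(math.log(self.a), math.log(self.b), size=size))
        elif self.family == "uniform":
            out = rng.uniform(self.a, self.b, size=size)
        elif self.family == "fixed":
            out = np.full(size, self.a)
        else:
            raise ValueError(f"unknown prior family {self.family!r}")
        return out if n is not None else float(out[0])


def default_priors() -> dict[str, Prior]:
    """Study priors: times ~ N(25000, 12500) truncated > 10 generations;
    sizes ~ N(5000, 2500) truncated > 0; mu_nu ~ logU(1e-4, 1e-3);
    mu_cp ~ logU(1e-8, 1e-3); GSM P ~ U(0, 0.9); admixture r ~ U(0.05, 0.95).
    """
    pri: dict[str, Prior] = {}
    for t in ("T1", "T2", "T3", "Ta", "Tb", "Tc", "Td"):
        pri[t] = Prior("truncnormal", 25_000.0, 12_500.0, low=10.0)
    for nsize in ("N_alps", "N_east", "N_west", "N_adm",
                  "N_alps_anc", "N_east_anc", "N_west_anc", "N_adm_anc",
                  "N_pyr_anc", "N_anc"):
        pri[nsize] = Prior("truncnormal", 5_000.0, 2_500.0, low=1.0)
    pri["mu_nu"] = Prior("loguniform", 1e-4, 1e-3)
    pri["mu_cp"] = Prior("loguniform", 1e-8, 1e-3)
    pri["p_nu"] = Prior("uniform", 0.0, 0.9)
    pri["p_cp"] = Prior("uniform", 0.0, 0.9)
    pri["r1"] = Prior("uniform", 0.05, 0.95)
    pri["r2"] = Prior("uniform", 0.05, 0.95)
    return pri


@dataclass
class PriorSpec:
    priors: dict[str, Prior] = field(default_factory=default_priors)
    generation_time_years: tuple[float, float] = (30.0, 40.0)

    def replace_prior(self, name: str, prior: Prior) -> "PriorSpec":
        new = dict(self.priors)
        new[name] = prior
        return replace(self, priors=new)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    time: float
    kind: str            # "resize" | "merge" | "admix"
    deme: str            # resized deme / merge source / admixture child
    target: str = ""     # merge sink / admixture parent1
    target2: str = ""    # admixture parent2
    size: float = 0.0    # resize new size
    rate: float = 0.0    # admixture: P(lineage -> target)


# per-scenario parameter lists and time-ordering constraints
_SCEN_PARAMS = {
    "S1": ["T1", "T2", "Ta", "Tb", "Tc", "Td", "r1",
           "N_alps", "N_east", "N_west", "N_adm",
           "N_alps_anc", "N_east_anc", "N_west_anc", "N_adm_anc", "N_anc"],
    "S2": ["T1", "T2", "T3", "Ta", "Tb", "Tc", "Td", "r1",
           "N_alps", "N_east", "N_west", "N_adm",
           "N_alps_anc", "N_east_anc", "N_west_anc", "N_adm_anc",
           "N_pyr_anc", "N_anc"],
    "S3": ["T1", "T2", "T3", "Ta", "Tb", "Tc", "Td", "r1", "r2",
           "N_alps", "N_east", "N_west", "N_adm",
           "N_alps_anc", "N_east_anc", "N_west_anc", "N_adm_anc", "N_anc"],
    "S4": ["T1", "T2", "T3", "Ta", "Tb", "Tc", "Td", "r1", "r2",
           "N_alps", "N_east", "N_west", "N_adm",
           "N_alps_anc", "N_east_anc", "N_west_anc", "N_adm_anc", "N_anc"],
}
_MUT_PARAMS = ["mu_nu", "p_nu", "mu_cp", "p_cp"]


@dataclass(frozen=True)
class DemographicScenario:
    """One of the four divergence/admixture scenarios (S1-S4)."""

    scenario_id: str

    def __post_init__(self):
        if self.scenario_id not in _SCEN_PARAMS:
            raise ValueError(f"unknown scenario {self.scenario_id!r}")

    @property
    def param_names(self) -> list[str]:
        return _SCEN_PARAMS[self.scenario_id] + _MUT_PARAMS

    def satisfies_ordering(self, p: dict[str, float]) -> bool:
        """Time-ordering and final-branch constraints (enforced by prior
        rejection): divergence times strictly ordered, each deme's resize on
        its own terminal branch."""
        s = self.scenario_id
        if s == "S1":
            return (p["T1"] > p["T2"]
                    and p["Td"] < p["T2"]
                    and max(p["Ta"], p["Tb"], p["Tc"]) < p["T1"])
        if s == "S2":
            return (p["T1"] > p["T2"] > p["T3"]
                    and p["Td"] < p["T3"] and p["Tc"] < p["T2"]
                    and p["Tb"] < p["T2"] and p["Ta"] < p["T1"])
        if s == "S3":
            return (p["T1"] > p["T2"] > p["T3"]
                    and p["Td"] < p["T3"] and p["Tc"] < p["T2"]
                    and p["Tb"] < p["T1"] and p["Ta"] < p["T1"])
        # S4
        return (p["T1"] > p["T2"] > p["T3"]
                and p["Td"] < p["T3"] and p["Tb"] < p["T2"]
                and p["Tc"] < p["T1"] and p["Ta"] < p["T1"])

    def build(self, p: dict[str, float]) -> tuple[dict[str, float], list[Event]]:
        """Initial deme sizes and the backward-time event list."""
        sizes = {d: p[f"N_{d}"] for d in DEMES}
        ev = [
            Event(p["Ta"], "resize", "alps", size=p["N_alps_anc"]),
            Event(p["Tb"], "resize", "east", size=p["N_east_anc"]),
            Event(p["Tc"], "resize", "west", size=p["N_west_anc"]),
            Event(p["Td"], "resize", "adm", size=p["N_adm_anc"]),
        ]
        s = self.scenario_id
        if s == "S1":
            ev += [
                Event(p["T2"], "admix", "adm", "east", "west", rate=p["r1"]),
                Event(p["T1"], "merge", "east", "alps"),
                Event(p["T1"], "merge", "west", "alps"),
                Event(p["T1"], "resize", "alps", size=p["N_anc"]),
            ]
        elif s == "S2":
            ev += [
                Event(p["T3"], "admix", "adm", "east", "west", rate=p["r1"]),
                Event(p["T2"], "merge", "west", "east"),
                Event(p["T2"], "resize", "east", size=p["N_pyr_anc"]),
                Event(p["T1"], "merge", "east", "alps"),
                Event(p["T1"], "resize", "alps", size=p["N_anc"]),
            ]
        elif s == "S3":
            ev += [
                Event(p["T3"], "admix", "adm", "east", "west", rate=p["r1"]),
                Event(p["T2"], "admix", "west", "alps", "east", rate=p["r2"]),
                Event(p["T1"], "merge", "east", "alps"),
                Event(p["T1"], "resize", "alps", size=p["N_anc"]),
            ]
        else:  # S4
            ev += [
                Event(p["T3"], "admix", "adm", "east", "west", rate=p["r1"]),
                Event(p["T2"], "admix", "east", "alps", "west", rate=p["r2"]),
                Event(p["T1"], "merge", "west", "alps"),
                Event(p["T1"], "resize", "alps", size=p["N_anc"]),
            ]
        ev.sort(key=lambda e: (e.time, e.kind == "resize"))
        return sizes, ev


def sample_priors(spec: PriorSpec, scenario: DemographicScenario,
                  n: int, rng: np.random.Generator,
                  max_tries: int = 1000) -> list[dict[str, float]]:
    """Draw n parameter dictionaries satisfying the scenario's ordering
    constraints (rejection sampling)."""
    draws: list[dict[str, float]] = []
    names = scenario.param_names
    tries = 0
    while len(draws) < n:
        tries += 1
        if tries > max_tries * max(n, 1):
            raise RuntimeError("ordering constraints appear unsatisfiable")
        p = {nm: spec.priors[nm].sample(rng) for nm in names}
        if scenario.satisfies_ordering(p):
            draws.append(p)
    return draws


# ---------------------------------------------------------------------------
# Gene-tree simulation
# ---------------------------------------------------------------------------

class GeneTree:
    """A coalescent gene tree: parent pointers, node times, leaf demes."""

    __slots__ = ("parents", "times", "n_leaves", "leaf_demes")

    def __init__(self, parents, times, n_leaves, leaf_demes):
        self.parents = parents
        self.times = times
        self.n_leaves = n_leaves
        self.leaf_demes = leaf_demes


def simulate_gene_tree(initial_sizes: dict[str, float], events: list[Event],
                       sample_sizes: dict[str, int], size_multiplier: float,
                       rng: np.random.Generator) -> GeneTree:
    """Simulate one gene tree under piecewise-constant deme sizes and events.

    ``size_multiplier`` converts a deme's nominal size N into effective gene
    copies (2 for diploid nuclear loci, the chloroplast copy-number factor
    for haploid loci).  Between events each deme coalesces independently.
    """
    parents: list[int] = []
    times: list[float] = []
    leaf_demes: list[str] = []
    lineages: dict[str, list[int]] = {}
    nid = 0
    for deme in DEMES:
        k = sample_sizes.get(deme, 0)
        lineages[deme] = list(range(nid, nid + k))
        leaf_demes += [deme] * k
        nid += k
    n_leaves = nid
    parents = [-1] * n_leaves
    times = [0.0] * n_leaves
    sizes = dict(initial_sizes)

    def coalesce(deme: str, t0: float, t1: float) -> float:
        nonlocal nid
        lin = lineages[deme]
        N = sizes[deme] * size_multiplier
        t = t0
        while len(lin) >= 2:
            k = len(lin)
            t += rng.exponential(N / (k * (k - 1) / 2.0))
            if t >= t1:
                break
            i = rng.integers(k)
            j = rng.integers(k - 1)
            if j >= i:
                j += 1
            parents.append(-1)
            times.append(t)
            parents[lin[i]] = nid
            parents[lin[j]] = nid
            hi, lo = max(i, j), min(i, j)
            lin[hi] = lin[-1]
            lin.pop()
            lin[lo] = nid
            nid += 1
        return t

    t_now = 0.0
    for ev in sorted(events, key=lambda e: e.time):
        for deme in list(lineages):
            coalesce(deme, t_now, ev.time)
        if ev.kind == "resize":
            if ev.deme in sizes:
                sizes[ev.deme] = ev.size
        elif ev.kind == "merge":
            lineages.setdefault(ev.target, [])
            lineages[ev.target] += lineages.pop(ev.deme, [])
            sizes.setdefault(ev.target, sizes.get(ev.deme, 1.0))
        elif ev.kind == "admix":
            kids = lineages.pop(ev.deme, [])
            for lid in kids:
                dest = ev.target if rng.random() < ev.rate else ev.target2
                lineages[dest].append(lid)
        t_now = ev.time
    remaining = [d for d, lin in lineages.items() if lin]
    if len(remaining) > 1:
        # all demes must have merged by the root; collapse defensively
        root_deme = remaining[0]
        for d in remaining[1:]:
            lineages[root_deme] += lineages.pop(d)
    else:
        root_deme = remaining[0]
    coalesce(root_deme, t_now, math.inf)
    return GeneTree(np.asarray(parents), np.asarray(times), n_leaves,
                    np.asarray(leaf_demes))


def mutate_gene_tree(tree: GeneTree, mu: float, p_gsm: float,
                     rng: np.random.Generator, root_state: int = 100,
                     floor: int = 2) -> np.ndarray:
    """Drop GSM mutations on a gene tree; returns leaf repeat counts.

    Mutation counts are Poisson per branch; each mutation steps the repeat
    count by +/- (1 + Geometric(P)).  Repeat counts below ``floor`` reflect.
    """
    parents = tree.parents
    times = tree.times
    n_nodes = len(parents)
    has_parent = parents >= 0
    branch = np.zeros(n_nodes)
    branch[has_parent] = times[parents[has_parent]] - times[has_parent]
    m = np.zeros(n_nodes, dtype=int)
    if mu > 0:
        m[has_parent] = rng.poisson(mu * branch[has_parent])
    total = int(m.sum())
    net = np.zeros(n_nodes, dtype=int)
    if total:
        if p_gsm > 0:
            steps = rng.geometric(1.0 - p_gsm, size=total)
        else:
            steps = np.ones(total, dtype=int)
        signs = rng.integers(0, 2, size=total) * 2 - 1
        signed = steps * signs
        ends = np.cumsum(m)
        starts = ends - m
        nz = np.nonzero(m)[0]
        for i in nz:
            net[i] = signed[starts[i]:ends[i]].sum()
    values = np.empty(n_nodes, dtype=int)
    for i in range(n_nodes - 1, -1, -1):
        if parents[i] < 0:
            values[i] = root_state
        else:
            v = values[parents[i]] + net[i]
            while v < floor:
                v = 2 * floor - v
            values[i] = v
    return values[:tree.n_leaves]


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LociConfig:
    """Marker panel emulated by default: 8 nuclear SSRs (seven dinucleotide,
    one trinucleotide) and 3 fully linked chloroplast SSRs."""

    nuclear_motifs: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 2, 3)
    n_chloroplast: int = 3
    cp_copy_multiplier: float = 1.0
    root_repeats_nuclear: int = 100
    root_repeats_cp: int = 50
    rate_gamma_shape: float | None = None  # per-locus rate dispersion, off by default

    def loci(self) -> list[Locus]:
        out = [Locus(f"nu{i + 1}", NUCLEAR, motif_length=m, allele_unit="repeat_count")
               for i, m in enumerate(self.nuclear_motifs)]
        out += [Locus(f"cp{i + 1}", CHLOROPLAST, motif_length=1, allele_unit="repeat_count")
                for i in range(self.n_chloroplast)]
        return out


def _locus_rates(mu: float, n: int, shape: float | None, rng) -> np.ndarray:
    if shape is None:
        return np.full(n, mu)
    return mu * rng.gamma(shape, 1.0 / shape, size=n)


def simulate_dataset(scenario: DemographicScenario | str, params: dict[str, float],
                     sample_sizes: dict[str, int],
                     loci_config: LociConfig = LociConfig(),
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> GenotypeDataset:
    """Simulate a full genotype dataset (nuclear diploid + linked cpSSRs).

    ``sample_sizes`` counts diploid individuals per deme.  Nuclear loci each
    get an independent gene tree on 2n copies; the chloroplast loci share a
    single gene tree on n copies (full linkage), with effective copy number
    ``cp_copy_multiplier * N``.
    """
    if isinstance(scenario, str):
        scenario = DemographicScenario(scenario)
    if rng is None:
        rng = np.random.default_rng(seed)
    sizes, events = scenario.build(params)
    demes = [d for d in DEMES if sample_sizes.get(d, 0) > 0]
    n_ind = {d: sample_sizes[d] for d in demes}
    total_ind = sum(n_ind.values())
    loci = loci_config.loci()
    n_nu = len(loci_config.nuclear_motifs)
    n_cp = loci_config.n_chloroplast
    alleles = np.zeros((total_ind, n_nu + n_cp, 2), dtype=int)

    nu_rates = _locus_rates(params["mu_nu"], n_nu, loci_config.rate_gamma_shape, rng)
    for j in range(n_nu):
        tree = simulate_gene_tree(sizes, events, {d: 2 * n_ind[d] for d in demes},
                                  size_multiplier=2.0, rng=rng)
        leaf_vals = mutate_gene_tree(tree, nu_rates[j], params["p_nu"], rng,
                                     root_state=loci_config.root_repeats_nuclear)
        alleles[:, j, 0] = leaf_vals[0::2]
        alleles[:, j, 1] = leaf_vals[1::2]

    if n_cp:
        cp_rates = _locus_rates(params["mu_cp"], n_cp, loci_config.rate_gamma_shape, rng)
        cp_tree = simulate_gene_tree(sizes, events, {d: n_ind[d] for d in demes},
                                     size_multiplier=loci_config.cp_copy_multiplier,
                                     rng=rng)
        for j in range(n_cp):
            leaf_vals = mutate_gene_tree(cp_tree, cp_rates[j], params["p_cp"], rng,
                                         root_state=loci_config.root_repeats_cp)
            alleles[:, n_nu + j, 0] = leaf_vals
            alleles[:, n_nu + j, 1] = MISSING

    individuals = []
    pop_index = []
    for k, d in enumerate(demes):
        individuals += [f"{d}_{i + 1}" for i in range(n_ind[d])]
        pop_index += [k] * n_ind[d]
    return GenotypeDataset(
        loci=loci,
        pop_ids=list(demes),
        individuals=individuals,
        pop_index=np.array(pop_index),
        alleles=alleles,
    )


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

SINGLE_STATS = ("nal", "het", "var", "mgw", "rng")
PAIR_STATS = ("fst", "div", "dmu2", "das", "pnal", "pvar", "pmgw")


@dataclass(frozen=True)
class StatsCatalog:
    """Which summary statistics feed the ABC fit and which are held out for
    posterior-predictive model checking (the two sets must stay disjoint).

    Single-population statistics (per marker class, averaged over loci):
    ``nal`` mean allele number, ``het`` mean genic diversity, ``var`` mean
    allele-size variance, ``mgw`` mean Garza-Williamson M (alleles per unit
    of allele-size range), ``rng`` mean allele-size range.  Two-population
    statistics: ``fst`` (WC theta), ``div`` pooled-pair genic diversity,
    ``dmu2`` Goldstein's (delta mu)^2, ``das`` shared-allele distance, and
    pooled-pair allele number / size variance / M (``pnal``, ``pvar``,
    ``pmgw``).  The default fit set is the eight classic families (four
    single-population, four two-population); the model check runs on
    additional statistics never used in fitting.
    """

    fit_single: tuple[str, ...] = ("nal", "het", "var", "mgw")
    fit_pair: tuple[str, ...] = ("fst", "div", "dmu2", "das")
    check_single: tuple[str, ...] = ("rng",)
    check_pair: tuple[str, ...] = ("pnal", "pvar", "pmgw")

    def __post_init__(self):
        if set(self.fit_single) & set(self.check_single) or \
           set(self.fit_pair) & set(self.check_pair):
            raise ValueError("fitting and checking statistics must be disjoint")


def _locus_stats(counts: dict[int, int]) -> tuple[float, float, float, float, float]:
    """(n_alleles, genic diversity, size variance, GW M, size range) for one
    locus in one population."""
    sizes = np.array(list(counts.keys()), dtype=float)
    c = np.array(list(counts.values()), dtype=float)
    n = c.sum()
    if n < 2 or len(c) == 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    p = c / n
    het = n / (n - 1) * (1 - np.sum(p ** 2))
    mean = np.sum(p * sizes)
    var = np.sum(p * (sizes - mean) ** 2) * n / (n - 1) if len(c) > 1 else 0.0
    rng_ = sizes.max() - sizes.min()
    mgw = len(c) / (rng_ + 1.0)
    return float(len(c)), float(het), float(var), float(mgw), float(rng_)


def summary_stats(ds: GenotypeDataset, catalog: StatsCatalog = StatsCatalog(),
                  which: str = "fit") -> pd.Series:
    """Summary-statistic vector over demes and deme pairs, by marker class.

    ``which`` selects the fitting set, the held-out checking set, or "all".
    Undefined statistics (e.g. monomorphic data) are 0.
    """
    if which == "fit":
        single, pair = catalog.fit_single, catalog.fit_pair
    elif which == "check":
        single, pair = catalog.check_single, catalog.check_pair
    elif which == "all":
        single = tuple(dict.fromkeys(catalog.fit_single + catalog.check_single))
        pair = tuple(dict.fromkeys(catalog.fit_pair + catalog.check_pair))
    else:
        raise ValueError(f"unknown set {which!r}")

    classes = {"nu": ds.nuclear_locus_indices(), "cp": ds.chloroplast_locus_indices()}
    pops = ds.pop_ids
    out: dict[str, float] = {}
    per_pop_counts = {
        (cls, p): [ds.allele_counts(j, p) for j in idxs]
        for cls, idxs in classes.items() if idxs for p in pops
    }
    for cls, idxs in classes.items():
        if not idxs:
            continue
        for p in pops:
            mat = np.array([_locus_stats(c) for c in per_pop_counts[(cls, p)]])
            means = mat.mean(axis=0)
            by_name = dict(zip(SINGLE_STATS, means))
            for s in single:
                out[f"{cls}_{s}_{p}"] = float(by_name[s])
        for ia in range(len(pops)):
            for ib in range(ia + 1, len(pops)):
                pa, pb = pops[ia], pops[ib]
                pair_vals = _pair_stats(ds, cls, idxs, pa, pb,
                                        per_pop_counts[(cls, pa)],
                                        per_pop_counts[(cls, pb)], pair)
                for s in pair:
                    out[f"{cls}_{s}_{pa}-{pb}"] = pair_vals[s]
    return pd.Series(out)


def _pair_stats(ds, cls, idxs, pa, pb, counts_a, counts_b, wanted):
    from .differentiation import pairwise_fst
    vals: dict[str, float] = {}
    if "fst" in wanted:
        v = pairwise_fst(ds, pa, pb, idxs)
        vals["fst"] = float(v) if np.isfinite(v) else 0.0
    pooled_wanted = {"div", "pnal", "pvar", "pmgw"} & set(wanted)
    if pooled_wanted:
        acc = {k: [] for k in pooled_wanted}
        for ca, cb in zip(counts_a, counts_b):
            pooled: dict[int, int] = dict(ca)
            for k, v in cb.items():
                pooled[k] = pooled.get(k, 0) + v
            nal, het, var, mgw, _ = _locus_stats(pooled)
            for k, v in (("div", het), ("pnal", nal), ("pvar", var), ("pmgw", mgw)):
                if k in acc:
                    acc[k].append(v)
        for k, vs in acc.items():
            vals[k] = float(np.mean(vs)) if vs else 0.0
    if "dmu2" in wanted:
        d2 = []
        for ca, cb in zip(counts_a, counts_b):
            if not ca or not cb:
                continue
            ma = np.average(list(ca.keys()), weights=list(ca.values()))
            mb = np.average(list(cb.keys()), weights=list(cb.values()))
            d2.append((ma - mb) ** 2)
        vals["dmu2"] = float(np.mean(d2)) if d2 else 0.0
    if "das" in wanted:
        shared = []
        for ca, cb in zip(counts_a, counts_b):
            na, nb = sum(ca.values()), sum(cb.values())
            if na == 0 or nb == 0:
                continue
            ps = sum(min(ca.get(a, 0) / na, cb.get(a, 0) / nb)
                     for a in set(ca) | set(cb))
            shared.append(1.0 - ps)
        vals["das"] = float(np.mean(shared)) if shared else 0.0
    return vals
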