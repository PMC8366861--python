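"""Study-shaped synthetic inputs with known ground truth.

Generates genotype datasets under a known divergence/admixture demography
(populations arrayed on a west-east longitudinal axis and partitioned among
the four demes), Q-membership matrices with a longitudinal cline and central
admixture band, environment tables with planted associations, and clustering
log-probability tables with a known cluster number.  Every generator is a
pure function of (config, seed), and each truth record carries the
generating values needed by recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import DemographicScenario, LociConfig, simulate_dataset
from .datasets import GenotypeDataset, PopulationMeta

RANGE_LABELS = {"west": "PYR_W", "adm": "PYR_C", "east": "PYR_E", "alps": "WesternAlps"}
PERIODS = ("cur", "midholo", "lgm", "lig")
N_BIOCLIM = 19


def default_true_params() -> dict[str, float]:
    """Generating demography: hierarchical split (S2) with an eastern
    expansion and a western contraction, divergence times in the study's
    inferred range."""
    return {
        "T1": 28_000.0, "T2": 24_000.0, "T3": 22_000.0,
        "Ta": 5_000.0, "Tb": 5_000.0, "Tc": 5_000.0, "Td": 5_000.0,
        "r1": 0.5,
        "N_alps": 8_000.0, "N_east": 8_000.0, "N_west": 2_000.0, "N_adm": 5_000.0,
        "N_alps_anc": 5_000.0, "N_east_anc": 800.0, "N_west_anc": 8_000.0,
        "N_adm_anc": 5_000.0, "N_pyr_anc": 5_000.0, "N_anc": 5_000.0,
        "mu_nu": 5e-4, "p_nu": 0.22, "mu_cp": 1e-5, "p_cp": 0.0,
    }


@dataclass
class SyntheticStudyConfig:
    pops_per_deme: dict[str, int] = field(
        default_factory=lambda: {"west": 15, "adm": 9, "east": 15, "alps": 6})
    individuals_per_pop: int = 30
    loci_config: LociConfig = field(default_factory=LociConfig)
    scenario_id: str = "S2"
    params: dict[str, float] = field(default_factory=default_true_params)
    # environment-association spec: planted partial correlations with Q_w
    env_effects: dict[str, float] = field(
        default_factory=lambda: {"longitude": -1.0, "bio8_lig": -0.8})
    env_noise_sd: float = 1.0
    seed: int = 0

    def n_populations(self) -> int:
        return sum(self.pops_per_deme.values())


@dataclass
class TruthRecord:
    scenario_id: str
    params: dict[str, float]
    pop_deme: dict[str, str]
    env_effects: dict[str, float]
    seed: int


def _population_layout(cfg: SyntheticStudyConfig,
                       rng: np.random.Generator) -> list[PopulationMeta]:
    """West-east layout: Pyrenean demes span ~4 degrees of longitude (the
    range's ~400 km extent), Alpine references sit to the northeast."""
    metas: list[PopulationMeta] = []
    lon_bands = {"west": (-1.5, -0.3), "adm": (-0.3, 0.7), "east": (0.7, 2.5),
                 "alps": (5.5, 7.0)}
    lat_centre = {"west": 43.0, "adm": 42.8, "east": 42.5, "alps": 44.3}
    elev_centre = {"west": 1_100, "adm": 1_500, "east": 1_400, "alps": 1_300}
    for deme in ("west", "adm", "east", "alps"):
        n = cfg.pops_per_deme.get(deme, 0)
        lo, hi = lon_bands[deme]
        lons = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
        for i in range(n):
            metas.append(PopulationMeta(
                pop_id=f"{deme}{i + 1:02d}",
                range_label=RANGE_LABELS[deme],
                latitude=float(lat_centre[deme] + rng.normal(0, 0.15)),
                longitude=float(lons[i] + rng.normal(0, 0.02)),
                elevation=float(elev_centre[deme] + rng.normal(0, 200)),
                n_sampled=cfg.individuals_per_pop,
            ))
    return metas


def generate_study_like_dataset(cfg: SyntheticStudyConfig
                                ) -> tuple[GenotypeDataset, list[PopulationMeta], TruthRecord]:
    """Genotype dataset whose populations are samples from the scenario demes.

    Each population is an independent sample of ``individuals_per_pop``
    diploids from its deme; all populations of a deme share that deme's
    coalescent history, so within-deme populations are exchangeable.
    """
    rng = np.random.default_rng(cfg.seed)
    metas = _population_layout(cfg, rng)
    n_ind = cfg.individuals_per_pop
    sample_sizes = {d: cfg.pops_per_deme.get(d, 0) * n_ind
                    for d in ("alps", "east", "west", "adm")}
    sample_sizes = {d: n for d, n in sample_sizes.items() if n > 0}
    big = simulate_dataset(cfg.scenario_id, cfg.params, sample_sizes,
                           cfg.loci_config, rng=rng)
    # split each deme's block of individuals into its populations
    pop_ids: list[str] = []
    pop_deme: dict[str, str] = {}
    new_index = np.empty(big.n_individuals, dtype=int)
    individuals: list[str] = []
    deme_order = [m for m in metas]
    # big's individuals are grouped by deme in the order of its pop_ids
    offset = {d: 0 for d in big.pop_ids}
    starts = {}
    pos = 0
    for d in big.pop_ids:
        starts[d] = pos
        pos += sample_sizes[d]
    perm = np.empty(big.n_individuals, dtype=int)
    row = 0
    for m in metas:
        deme = {v: k for k, v in RANGE_LABELS.items()}[m.range_label]
        pop_ids.append(m.pop_id)
        pop_deme[m.pop_id] = deme
        k = len(pop_ids) - 1
        for i in range(n_ind):
            src = starts[deme] + offset[deme]
            offset[deme] += 1
            perm[row] = src
            new_index[row] = k
            individuals.append(f"{m.pop_id}_{i + 1}")
            row += 1
    ds = GenotypeDataset(
        loci=big.loci,
        pop_ids=pop_ids,
        individuals=individuals,
        pop_index=new_index,
        alleles=big.alleles[perm],
        populations=metas,
    )
    truth = TruthRecord(cfg.scenario_id, dict(cfg.params), pop_deme,
                        dict(cfg.env_effects), cfg.seed)
    return ds, metas, truth


def generate_q_matrix(metas: list[PopulationMeta], midpoint: float = 0.2,
                      steepness: float = 3.0, noise_sd: float = 0.05,
                      seed: int = 0) -> pd.DataFrame:
    """Two-cluster Q matrix: western membership declines logistically with
    longitude (admixture band around the midpoint); rows renormalised."""
    rng = np.random.default_rng(seed)
    rows = {}
    for m in metas:
        z = np.clip(steepness * (m.longitude - midpoint), -700, 700)
        qw = 1.0 / (1.0 + np.exp(z))
        qw = float(np.clip(qw + rng.normal(0, noise_sd), 1e-6, 1 - 1e-6))
        rows[m.pop_id] = [qw, 1.0 - qw]
    q = pd.DataFrame.from_dict(rows, orient="index", columns=["west", "east"])
    return q.div(q.sum(axis=1), axis=0)


def generate_env_table(cfg: SyntheticStudyConfig, metas: list[PopulationMeta],
                       q_west: pd.Series | None = None) -> tuple[pd.DataFrame, dict]:
    """Environment table: 19 bioclimatic variables x 4 periods + geography.

    Variables named in ``cfg.env_effects`` get the stated partial correlation
    with the western membership coefficient (or with longitude for the
    geographic columns); the rest are independent noise.  Returns the table
    and the generating coefficients.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    idx = [m.pop_id for m in metas]
    df = pd.DataFrame(index=idx)
    df["longitude"] = [m.longitude for m in metas]
    df["latitude"] = [m.latitude for m in metas]
    df["altitude"] = [m.elevation for m in metas]
    df["slope"] = rng.uniform(0, 35, len(metas))
    if q_west is None:
        q_west = pd.Series(0.5, index=idx)
    qz = (q_west - q_west.mean())
    qsd = qz.std(ddof=0)
    qz = qz / qsd if qsd > 0 else qz * 0.0
    for b in range(1, N_BIOCLIM + 1):
        for per in PERIODS:
            name = f"bio{b}_{per}"
            eff = cfg.env_effects.get(name, 0.0)
            noise = rng.normal(0, 1.0, len(metas))
            vals = eff * qz.loc[idx].to_numpy() + np.sqrt(max(1 - eff ** 2, 0.0)) * noise
            df[name] = vals * cfg.env_noise_sd
    return df, dict(cfg.env_effects)


def generate_cluster_runs(true_k: int = 3, k_range: tuple[int, int] = (1, 8),
                          replicates: int = 10, signal: float = 4000.0,
                          noise_sd: float = 40.0, seed: int = 0) -> pd.DataFrame:
    """Clustering log-probability table with a sharp elbow at ``true_k``.

    L(K) rises steeply up to the true number of clusters then plateaus;
    replicate noise gives the sd that normalises delta-K.
    """
    lo, hi = k_range
    if not (lo < true_k < hi):
        raise ValueError("true_k must be interior to k_range")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(lo, hi + 1):
        mean_l = -50_000.0 + signal * min(k, true_k) + 10.0 * k
        for rep in range(replicates):
            rows.append({"K": k, "replicate": rep,
                         "L": mean_l + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)
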