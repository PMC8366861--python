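"""Core containers for microsatellite genotype data.

Diploid nuclear loci store an unordered allele pair per individual; haploid
chloroplast loci store a single allele.  Allele codes are positive integers
kept exactly as read (fragment sizes in bp or repeat counts, per
``Locus.allele_unit``); 0 marks missing data everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = 0

NUCLEAR = "nuclear"
CHLOROPLAST = "chloroplast"


@dataclass
class Locus:
    """A microsatellite locus.

    Parameters
    ----------
    name : str
        Locus label.
    genome : {"nuclear", "chloroplast"}
        Nuclear loci are diploid, chloroplast loci haploid.
    motif_length : int
        Repeat-motif length in bp (2 or 3 for the nuclear loci emulated here;
        1 or 18 for chloroplast variants).
    allele_unit : {"fragment_bp", "repeat_count"}
        Whether allele codes are PCR fragment sizes or repeat numbers.
    """

    name: str
    genome: str = NUCLEAR
    motif_length: int = 2
    allele_unit: str = "fragment_bp"

    def __post_init__(self) -> None:
        if self.genome not in (NUCLEAR, CHLOROPLAST):
            raise ValueError(f"unknown genome {self.genome!r}")
        if self.motif_length < 1:
            raise ValueError("motif_length must be >= 1")
        if self.allele_unit not in ("fragment_bp", "repeat_count"):
            raise ValueError(f"unknown allele_unit {self.allele_unit!r}")

    @property
    def ploidy(self) -> int:
        return 2 if self.genome == NUCLEAR else 1


@dataclass
class PopulationMeta:
    """Population-level metadata (location and sampling effort)."""

    pop_id: str
    range_label: str = "other"
    latitude: float = float("nan")
    longitude: float = float("nan")
    elevation: float = float("nan")
    n_sampled: int = 0

    def __post_init__(self) -> None:
        if np.isfinite(self.latitude) and abs(self.latitude) > 90:
            raise ValueError(f"latitude out of range for {self.pop_id}")
        if np.isfinite(self.longitude) and abs(self.longitude) > 180:
            raise ValueError(f"longitude out of range for {self.pop_id}")


@dataclass
class GenotypeDataset:
    """Genotypes for individuals grouped into populations.

    ``alleles`` has shape (n_individuals, n_loci, 2).  For haploid loci only
    slot 0 is meaningful and slot 1 is always ``MISSING``.  A diploid genotype
    is missing when either slot is ``MISSING``.
    """

    loci: list[Locus]
    pop_ids: list[str]
    individuals: list[str]
    pop_index: np.ndarray  # (n_individuals,) int, index into pop_ids
    alleles: np.ndarray  # (n_individuals, n_loci, 2) int
    populations: list[PopulationMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pop_index = np.asarray(self.pop_index, dtype=int)
        self.alleles = np.asarray(self.alleles, dtype=int)
        n, L, two = self.alleles.shape
        if two != 2 or L != len(self.loci) or n != len(self.individuals):
            raise ValueError("alleles array shape inconsistent with metadata")
        if (self.alleles < 0).any():
            raise ValueError("allele codes must be non-negative integers")
        if not self.populations:
            counts = np.bincount(self.pop_index, minlength=len(self.pop_ids))
            self.populations = [
                PopulationMeta(pop_id=p, n_sampled=int(c))
                for p, c in zip(self.pop_ids, counts)
            ]

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, name: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.name == name:
                return i
        raise KeyError(f"no locus named {name!r}")

    def pop_number(self, pop_id: str) -> int:
        try:
            return self.pop_ids.index(pop_id)
        except ValueError:
            raise KeyError(f"no population named {pop_id!r}") from None

    def nuclear_locus_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.loci) if l.genome == NUCLEAR]

    def chloroplast_locus_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.loci) if l.genome == CHLOROPLAST]

    # -- views -------------------------------------------------------------
    def genotypes(self, locus: str | int, pop_id: str | None = None) -> np.ndarray:
        """Genotype rows (n, ploidy) at one locus, missing rows removed.

        For diploid loci a row is dropped if either allele is missing; for
        haploid loci the single allele must be observed.
        """
        j = locus if isinstance(locus, int) else self.locus_index(locus)
        sel = np.ones(self.n_individuals, dtype=bool)
        if pop_id is not None:
            sel = self.pop_index == self.pop_number(pop_id)
        g = self.alleles[sel, j, : self.loci[j].ploidy]
        keep = (g != MISSING).all(axis=1)
        return g[keep]

    def allele_counts(self, locus: str | int, pop_id: str | None = None) -> dict[int, int]:
        """Counts of observed gene copies per allele at one locus."""
        g = self.genotypes(locus, pop_id)
        vals, counts = np.unique(g.ravel(), return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def subset_populations(self, pop_ids: list[str]) -> "GenotypeDataset":
        keep_nums = [self.pop_number(p) for p in pop_ids]
        mask = np.isin(self.pop_index, keep_nums)
        remap = {old: new for new, old in enumerate(keep_nums)}
        meta = {m.pop_id: m for m in self.populations}
        return GenotypeDataset(
            loci=list(self.loci),
            pop_ids=list(pop_ids),
            individuals=[ind for ind, m in zip(self.individuals, mask) if m],
            pop_index=np.array([remap[i] for i in self.pop_index[mask]]),
            alleles=self.alleles[mask].copy(),
            populations=[meta[p] for p in pop_ids if p in meta],
        )

    def check_motif_consistency(self) -> dict[str, bool]:
        """Flag loci whose fragment-size alleles do not differ by whole motifs.

        Violations are reported, not fatal: real datasets contain off-ladder
        indel variants (e.g. an 18-bp indel on a mononucleotide background).
        """
        report: dict[str, bool] = {}
        for j, loc in enumerate(self.loci):
            if loc.allele_unit != "fragment_bp":
                report[loc.name] = True
                continue
            sizes = sorted(self.allele_counts(j))
            ok = all((s - sizes[0]) % loc.motif_length == 0 for s in sizes) if sizes else True
            report[loc.name] = ok
        return report
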