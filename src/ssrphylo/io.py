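"""GENEPOP input/output, chloroplast haplotype assembly, and null-allele
estimation with the locus-discard rule.

The GENEPOP dialect accepted here: a title line, one locus name per line (or
a single comma-separated line), ``POP`` separators, and individual rows
``label , 0101 0202 ...``.  Allele codes use 2 or 3 digits per allele
(auto-detected per column); ``0`` is missing.  Haploid (chloroplast) loci are
written as single 2- or 3-digit codes and detected from token width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datasets import CHLOROPLAST, MISSING, NUCLEAR, GenotypeDataset, Locus, PopulationMeta


class GenepopParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GENEPOP reading / writing
# ---------------------------------------------------------------------------

def read_genepop(path, loci_meta: list[Locus] | None = None) -> GenotypeDataset:
    """Parse a GENEPOP file into a :class:`GenotypeDataset`.

    Token widths of 4 or 6 digits denote diploid genotypes, 2 or 3 digits a
    haploid allele (flagged as chloroplast unless ``loci_meta`` overrides).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise GenepopParseError("empty file")
    it = iter(enumerate(lines[1:], start=2))  # skip title line

    locus_names: list[str] = []
    first_pop_line = None
    for lineno, ln in it:
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            first_pop_line = lineno
            break
        if "," in stripped and len(locus_names) == 0 and " " not in stripped.split(",")[0].strip():
            locus_names.extend(tok.strip() for tok in stripped.split(",") if tok.strip())
        else:
            locus_names.append(stripped)
    if first_pop_line is None:
        raise GenepopParseError("no POP separator found (malformed header)")
    if not locus_names:
        raise GenepopParseError(f"no locus names before POP at line {first_pop_line}")

    n_loci = len(locus_names)
    pop_blocks: list[list[tuple[str, list[str]]]] = [[]]
    for lineno, ln in it:
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_blocks.append([])
            continue
        if "," not in stripped:
            raise GenepopParseError(f"line {lineno}: expected 'label , genotypes'")
        label, rest = stripped.split(",", 1)
        toks = rest.split()
        if len(toks) != n_loci:
            raise GenepopParseError(
                f"line {lineno}: individual {label.strip()!r} has {len(toks)} "
                f"genotype fields, expected {n_loci}"
            )
        pop_blocks[-1].append((label.strip(), toks))
    pop_blocks = [b for b in pop_blocks if b]
    if not pop_blocks:
        raise GenepopParseError("no individuals found")

    # per-column token width -> ploidy and digit count
    col_width: list[int] = []
    col_ploidy: list[int] = []
    for j in range(n_loci):
        ws = {len(toks[j]) for blk in pop_blocks for (_, toks) in blk}
        if not ws <= {2, 3, 4, 6}:
            raise GenepopParseError(f"locus {locus_names[j]}: bad genotype width(s) {sorted(ws)}")
        if len(ws) > 1:
            raise GenepopParseError(f"locus {locus_names[j]}: inconsistent genotype widths {sorted(ws)}")
        w = ws.pop()
        if w in (4, 6):
            col_ploidy.append(2)
            col_width.append(w // 2)
        else:
            col_ploidy.append(1)
            col_width.append(w)

    if loci_meta is not None:
        if len(loci_meta) != n_loci:
            raise GenepopParseError("loci_meta length does not match file")
        loci = loci_meta
    else:
        loci = [
            Locus(name=nm, genome=NUCLEAR if p == 2 else CHLOROPLAST,
                  motif_length=2 if p == 2 else 1)
            for nm, p in zip(locus_names, col_ploidy)
        ]

    individuals: list[str] = []
    pop_index: list[int] = []
    rows: list[np.ndarray] = []
    pop_ids = [f"pop{k + 1}" for k in range(len(pop_blocks))]
    for k, blk in enumerate(pop_blocks):
        # GENEPOP convention: population named after its last individual
        pop_ids[k] = blk[-1][0]
        for label, toks in blk:
            individuals.append(label)
            pop_index.append(k)
            row = np.zeros((n_loci, 2), dtype=int)
            for j, tok in enumerate(toks):
                if not tok.isdigit():
                    raise GenepopParseError(f"non-numeric genotype {tok!r} for {label}")
                if col_ploidy[j] == 2:
                    w = col_width[j]
                    row[j, 0] = int(tok[:w])
                    row[j, 1] = int(tok[w:])
                else:
                    row[j, 0] = int(tok)
                    row[j, 1] = MISSING
            rows.append(row)

    return GenotypeDataset(
        loci=loci,
        pop_ids=pop_ids,
        individuals=individuals,
        pop_index=np.array(pop_index),
        alleles=np.stack(rows),
    )


def write_genepop(ds: GenotypeDataset, path, title: str = "ssrphylo export") -> None:
    """Write a dataset in GENEPOP format (round-trips through read_genepop)."""
    widths = []
    for j, loc in enumerate(ds.loci):
        mx = max([a for a in ds.allele_counts(j)] or [1])
        widths.append(3 if mx > 99 else 2)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in ds.loci:
            fh.write(loc.name + "\n")
        prev_pop = None
        for i, label in enumerate(ds.individuals):
            if ds.pop_index[i] != prev_pop:
                fh.write("POP\n")
                prev_pop = ds.pop_index[i]
            toks = []
            for j, loc in enumerate(ds.loci):
                w = widths[j]
                if loc.ploidy == 2:
                    toks.append(f"{ds.alleles[i, j, 0]:0{w}d}{ds.alleles[i, j, 1]:0{w}d}")
                else:
                    toks.append(f"{ds.alleles[i, j, 0]:0{w}d}")
            fh.write(f"{label} , " + " ".join(toks) + "\n")


def read_population_meta(path) -> list[PopulationMeta]:
    """Read population metadata CSV (pop_id, range_label, lat, lon, elevation)."""
    df = pd.read_csv(path)
    metas = []
    for _, r in df.iterrows():
        metas.append(PopulationMeta(
            pop_id=str(r["pop_id"]),
            range_label=str(r.get("range_label", "other")),
            latitude=float(r.get("latitude", np.nan)),
            longitude=float(r.get("longitude", np.nan)),
            elevation=float(r.get("elevation", np.nan)),
            n_sampled=int(r.get("n_sampled", 0)),
        ))
    return metas


# ---------------------------------------------------------------------------
# Chloroplast haplotypes
# ---------------------------------------------------------------------------

def combine_cp_haplotypes(ds: GenotypeDataset) -> pd.DataFrame:
    """Assemble multilocus chloroplast haplotypes and tabulate frequencies.

    Individuals with any missing chloroplast allele are excluded.  Returns a
    table with one row per (population, haplotype) plus pooled "overall" rows;
    haplotype labels join per-locus alleles with '-'.
    """
    cp = ds.chloroplast_locus_indices()
    if not cp:
        raise ValueError("dataset has no chloroplast loci")
    alleles = ds.alleles[:, cp, 0]
    ok = (alleles != MISSING).all(axis=1)
    recs: list[tuple[str, str, int]] = []
    for scope_pop in list(ds.pop_ids) + ["overall"]:
        if scope_pop == "overall":
            sel = ok
        else:
            sel = ok & (ds.pop_index == ds.pop_number(scope_pop))
        sub = alleles[sel]
        if sub.size == 0:
            continue
        uniq, counts = np.unique(sub, axis=0, return_counts=True)
        for hap, c in zip(uniq, counts):
            recs.append((scope_pop, "-".join(str(a) for a in hap), int(c)))
    out = pd.DataFrame(recs, columns=["population", "haplotype", "count"])
    out["frequency"] = out.groupby("population")["count"].transform(lambda s: s / s.sum())
    return out


# ---------------------------------------------------------------------------
# Null-allele EM (single unobservable null allele under HWE)
# ---------------------------------------------------------------------------

@dataclass
class NullAlleleEstimate:
    locus: str
    pop_id: str
    null_freq: float
    loglik: float
    n_iterations: int
    monomorphic: bool = False


def _null_em_counts(het_counts: dict[tuple[int, int], int],
                    hom_counts: dict[int, int],
                    n_blank: int,
                    blanks_are_null: bool,
                    tol: float, max_iter: int):
    """EM for allele frequencies with one null allele under HWE.

    Observed homozygotes are a mixture of true homozygotes and null
    heterozygotes.  When ``blanks_are_null`` is False the likelihood is
    conditioned on the genotype being observable (not null/null); the EM then
    augments the data with the expected number of unobserved null homozygotes
    (standard EM for a truncated multinomial).
    """
    visible = sorted({a for pair in het_counts for a in pair} | set(hom_counts))
    k = len(visible)
    idx = {a: i for i, a in enumerate(visible)}
    n_obs = sum(het_counts.values()) + sum(hom_counts.values())
    if blanks_are_null:
        n_obs += n_blank

    # initial frequencies: uniform visible + small null
    p = np.full(k + 1, 1.0 / (k + 1))

    def loglik(p):
        pv, pn = p[:k], p[k]
        ll = 0.0
        for (a, b), c in het_counts.items():
            ll += c * math.log(max(2 * pv[idx[a]] * pv[idx[b]], 1e-300))
        for a, c in hom_counts.items():
            ll += c * math.log(max(pv[idx[a]] ** 2 + 2 * pv[idx[a]] * pn, 1e-300))
        if blanks_are_null:
            if n_blank:
                ll += n_blank * math.log(max(pn ** 2, 1e-300))
        else:
            ll -= (sum(het_counts.values()) + sum(hom_counts.values())) * math.log(max(1 - pn ** 2, 1e-300))
        return ll

    ll_old = loglik(p)
    trace = [ll_old]
    it = 0
    for it in range(1, max_iter + 1):
        pv, pn = p[:k], p[k]
        counts = np.zeros(k + 1)
        for (a, b), c in het_counts.items():
            counts[idx[a]] += c
            counts[idx[b]] += c
        for a, c in hom_counts.items():
            i = idx[a]
            denom = pv[i] + 2 * pn
            w_true = pv[i] / denom if denom > 0 else 1.0  # P(true hom | apparent hom)
            counts[i] += c * (2 * w_true + (1 - w_true))
            counts[k] += c * (1 - w_true)
        n_tot = sum(het_counts.values()) + sum(hom_counts.values())
        if blanks_are_null:
            counts[k] += 2 * n_blank
            n_tot += n_blank
        else:
            # expected unobserved null homozygotes under truncation
            n_aug = n_tot * pn ** 2 / max(1 - pn ** 2, 1e-12)
            counts[k] += 2 * n_aug
            n_tot += n_aug
        p = counts / (2 * n_tot)
        ll_new = loglik(p)
        if ll_new < ll_old - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        trace.append(ll_new)
        if abs(ll_new - ll_old) < tol:
            ll_old = ll_new
            break
        ll_old = ll_new
    return float(p[k]), float(ll_old), it, trace


def estimate_null_alleles_em(ds: GenotypeDataset, locus: str, pop_id: str,
                             tol: float = 1e-8, max_iter: int = 10_000,
                             blanks_are_null: bool = False) -> NullAlleleEstimate:
    """Estimate the null-allele frequency at one locus in one population.

    Maximum-likelihood EM assuming HWE with a single unobservable null allele.
    Missing genotypes count as putative null homozygotes only when
    ``blanks_are_null`` is set (default: excluded).
    """
    j = ds.locus_index(locus)
    sel = ds.pop_index == ds.pop_number(pop_id)
    g = ds.alleles[sel, j, :2]
    observed = (g != MISSING).all(axis=1)
    n_blank = int((~observed).sum())
    g = g[observed]
    if len(g) < 5:
        raise ValueError(f"fewer than 5 observed genotypes at {locus} in {pop_id}")
    het_counts: dict[tuple[int, int], int] = {}
    hom_counts: dict[int, int] = {}
    for a, b in g:
        if a == b:
            hom_counts[a] = hom_counts.get(a, 0) + 1
        else:
            key = (min(a, b), max(a, b))
            het_counts[key] = het_counts.get(key, 0) + 1
    distinct = {a for pair in het_counts for a in pair} | set(hom_counts)
    if len(distinct) == 1 and n_blank == 0:
        return NullAlleleEstimate(locus, pop_id, 0.0, 0.0, 0, monomorphic=True)
    nf, ll, it, _ = _null_em_counts(het_counts, hom_counts, n_blank,
                                    blanks_are_null, tol, max_iter)
    return NullAlleleEstimate(locus, pop_id, nf, ll, it)


def null_loglik_surface(het_counts, hom_counts, blanks_are_null=False, n_blank=0):
    """Conditional log-likelihood maximised numerically (independent of EM).

    Exposed for cross-checking; optimises over the frequency simplex via a
    softmax parametrisation.
    """
    visible = sorted({a for pair in het_counts for a in pair} | set(hom_counts))
    k = len(visible)
    idx = {a: i for i, a in enumerate(visible)}
    n_obs = sum(het_counts.values()) + sum(hom_counts.values())

    def nll(x):
        z = np.concatenate([x, [0.0]])
        p = np.exp(z - z.max())
        p /= p.sum()
        pv, pn = p[:k], p[k]
        ll = 0.0
        for (a, b), c in het_counts.items():
            ll += c * math.log(max(2 * pv[idx[a]] * pv[idx[b]], 1e-300))
        for a, c in hom_counts.items():
            ll += c * math.log(max(pv[idx[a]] ** 2 + 2 * pv[idx[a]] * pn, 1e-300))
        if blanks_are_null:
            ll += n_blank * math.log(max(pn ** 2, 1e-300))
        else:
            ll -= n_obs * math.log(max(1 - pn ** 2, 1e-300))
        return -ll

    best = None
    for start in (np.zeros(k), np.linspace(-1, 1, k)):
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    z = np.concatenate([best.x, [0.0]])
    p = np.exp(z - z.max())
    p /= p.sum()
    return float(p[k]), -float(best.fun)


def filter_loci_by_null_freq(estimates: list[NullAlleleEstimate],
                             freq_threshold: float = 0.05,
                             pop_fraction: float = 0.5):
    """Apply the locus-discard rule on null-allele frequencies.

    A locus is discarded when its estimated null-allele frequency exceeds
    ``freq_threshold`` in strictly more than ``pop_fraction`` of the
    populations it was scored in.  Returns (kept, discarded, report) where the
    report lists per-locus offending-population counts.
    """
    if not estimates:
        raise ValueError("empty estimate list")
    by_locus: dict[str, list[NullAlleleEstimate]] = {}
    for e in estimates:
        by_locus.setdefault(e.locus, []).append(e)
    kept, discarded = [], []
    rows = []
    for locus, ests in by_locus.items():
        n_pops = len(ests)
        n_off = sum(1 for e in ests if e.null_freq > freq_threshold)
        drop = n_off > pop_fraction * n_pops
        (discarded if drop else kept).append(locus)
        rows.append({"locus": locus, "n_populations": n_pops,
                     "n_exceeding": n_off, "discarded": drop})
    report = pd.DataFrame(rows)
    return kept, discarded, report
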