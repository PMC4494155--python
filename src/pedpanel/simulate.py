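"""Gene-dropping simulator: pedigrees, genotypes, read counts.

The simulator emulates a captive breeding colony descended from a small
founder generation: founder haplotypes are drawn i.i.d. per site from a
founder allele frequency, then dropped through the pedigree meiosis by
meiosis, recombining between adjacent sites at the rate given by
Haldane's map function r = (1 - exp(-2 d / 100)) / 2 for an inter-site
distance of d centimorgans.  Sequencing is modelled at the level of
per-site allele counts: read depth is Poisson around the individual's
planned coverage tier, and each read reports the allele of a uniformly
chosen haplotype, flipped with the per-base error probability.
Genotypes produced by the drop are Mendelian-consistent by construction,
which is what makes downstream error rates measurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, PedigreeError
from .panel import MISSING, SITE_COLUMNS, SitePanel

__all__ = [
    "TrueGenotypes",
    "ReadData",
    "simulate_pedigree",
    "default_sites",
    "default_genetic_map",
    "gene_drop",
    "simulate_reads",
    "inject_decoys",
]

_BASES = np.array(list("ACGT"))

MAP_COLUMNS = ["marker_id", "chrom", "pos_bp", "pos_cM"]


@dataclass
class TrueGenotypes:
    """Phased truth: haps[i, j, k] is the allele (0 ref / 1 alt) of
    haplotype k (0 paternal, 1 maternal) of sample j at site i."""

    sites: pd.DataFrame
    samples: list[str]
    haps: np.ndarray  # (n_sites, n_samples, 2) int8

    @property
    def gt(self) -> np.ndarray:
        return self.haps.sum(axis=2).astype(np.int8)

    def to_panel(self) -> SitePanel:
        return SitePanel(self.sites, list(self.samples), self.gt)


@dataclass
class ReadData:
    """Per-sample per-site depth and alt-supporting read counts."""

    samples: list[str]
    dp: np.ndarray  # (n_sites, n_samples) int32
    ad: np.ndarray  # alt reads, (n_sites, n_samples) int32

    def __post_init__(self):
        if np.any(self.ad > self.dp) or np.any(self.ad < 0) or np.any(self.dp < 0):
            raise ValueError("require 0 <= alt_reads <= depth")

    def mean_depth(self) -> np.ndarray:
        return self.dp.mean(axis=0)


# ---------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------

def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    mean_offspring: float = 2.0,
    seed: int = 0,
    start_year: int = 1976,
    generation_gap: int = 7,
    max_size: int = 2000,
) -> Pedigree:
    """Random-mating multigeneration pedigree on *n_founders* founders.

    Parents of generation g are drawn uniformly from generation g-1, so
    parent-offspring age gaps stay near ``generation_gap`` years (the
    default of 7 keeps every true gap inside the 4-15 year plausibility
    window used by parentage assignment).  Deterministic under a fixed
    seed.
    """
    if n_founders < 2:
        raise PedigreeError("need at least 2 founders")
    if n_generations < 1:
        raise PedigreeError("need at least 1 generation")
    rng = np.random.default_rng(seed)

    individuals: list[Individual] = []
    generation: list[list[Individual]] = []

    founders = []
    for k in range(n_founders):
        sex = "M" if k % 2 == 0 else "F"  # guarantee both sexes among founders
        founders.append(Individual(
            iid=f"G00_{k:04d}", sex=sex,
            birth_year=start_year + int(rng.integers(-1, 2)),
        ))
    generation.append(founders)
    individuals.extend(founders)

    for g in range(1, n_generations + 1):
        prev = generation[-1]
        males = [i for i in prev if i.sex == "M"]
        females = [i for i in prev if i.sex == "F"]
        if not males or not females:
            raise PedigreeError(
                f"generation {g - 1} has no opposite-sex pairs; cannot breed"
            )
        n_children = int(rng.poisson(mean_offspring * len(females)))
        n_children = max(2, min(n_children, max_size - len(individuals)))
        if n_children <= 0:
            break
        kids = []
        sexes = rng.integers(0, 2, size=n_children)
        if n_children >= 2:  # keep the line breedable
            sexes[0], sexes[1] = 0, 1
        year_base = start_year + g * generation_gap
        for k in range(n_children):
            father = males[int(rng.integers(len(males)))]
            mother = females[int(rng.integers(len(females)))]
            kids.append(Individual(
                iid=f"G{g:02d}_{k:04d}",
                sex="M" if sexes[k] == 0 else "F",
                birth_year=year_base + int(rng.integers(-1, 2)),
                father=father.iid,
                mother=mother.iid,
            ))
        generation.append(kids)
        individuals.extend(kids)

    return Pedigree(individuals)


# ---------------------------------------------------------------------
# sites and genetic map
# ---------------------------------------------------------------------

def default_sites(
    n_chromosomes: int = 4,
    sites_per_chromosome: int = 5000,
    chromosome_length_bp: int = 50_000_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> pd.DataFrame:
    """Biallelic SNV site table with founder allele frequencies.

    Returns columns chrom, pos, ref, alt, founder_maf; positions are
    strictly increasing within each chromosome and founder_maf is drawn
    Uniform over ``maf_range``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for c in range(1, n_chromosomes + 1):
        pos = np.sort(rng.choice(
            np.arange(1, chromosome_length_bp, dtype=np.int64),
            size=sites_per_chromosome, replace=False))
        ref_idx = rng.integers(0, 4, size=sites_per_chromosome)
        alt_idx = (ref_idx + rng.integers(1, 4, size=sites_per_chromosome)) % 4
        frames.append(pd.DataFrame({
            "chrom": f"chr{c}",
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "founder_maf": rng.uniform(*maf_range, size=sites_per_chromosome),
        }))
    return pd.concat(frames, ignore_index=True)


def default_genetic_map(
    sites: pd.DataFrame,
    cm_per_chromosome: float = 100.0,
    anchors_per_chromosome: int = 12,
) -> pd.DataFrame:
    """Evenly spaced STR-style anchor table spanning each chromosome.

    Anchors run linearly from 0 cM at the chromosome's first site to
    ``cm_per_chromosome`` at its last.
    """
    rows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
        bp = np.linspace(lo, hi, anchors_per_chromosome).round().astype(np.int64)
        cm = np.linspace(0.0, cm_per_chromosome, anchors_per_chromosome)
        for k, (b, c) in enumerate(zip(bp, cm)):
            rows.append((f"STR_{chrom}_{k:03d}", chrom, int(b), float(c)))
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


def write_genetic_map(gmap: pd.DataFrame, path) -> None:
    gmap.to_csv(path, sep="\t", index=False)


def read_genetic_map(path) -> pd.DataFrame:
    gmap = pd.read_csv(path, sep="\t")
    missing = [c for c in MAP_COLUMNS if c not in gmap.columns]
    if missing:
        raise ValueError(f"genetic map missing columns: {missing}")
    return gmap


# ---------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------

def _recombination_fractions(sites: pd.DataFrame, gmap: pd.DataFrame) -> np.ndarray:
    """Haldane recombination fraction between consecutive sites.

    Chromosome boundaries get r = 1/2 (independent assortment).
    """
    from .mapset import interpolate_map

    imap = interpolate_map(gmap, sites)
    cm = imap["pos_cM"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    d = np.diff(cm)
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    r[chrom[:-1] != chrom[1:]] = 0.5
    return r


def _meiosis(haps: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a (n_sites, 2) haplotype pair."""
    n = haps.shape[0]
    switch = np.empty(n, dtype=np.int8)
    switch[0] = rng.integers(0, 2)
    switch[1:] = rng.random(n - 1) < r
    src = np.cumsum(switch) % 2
    return haps[np.arange(n), src]


def gene_drop(
    ped: Pedigree,
    sites: pd.DataFrame,
    gmap: pd.DataFrame,
    seed: int = 0,
) -> TrueGenotypes:
    """Drop founder alleles through the pedigree with recombination.

    Founder haplotype alleles are i.i.d. Bernoulli(founder_maf) per
    site; each transmission is a meiosis over the recombination-fraction
    vector derived from the genetic map.  The result is phased truth for
    every pedigree member, Mendelian-consistent by construction.
    """
    if "founder_maf" not in sites.columns:
        raise ValueError("site table requires a founder_maf column")
    rng = np.random.default_rng(seed)
    r = _recombination_fractions(sites, gmap)
    n_sites = len(sites)
    order = ped.topological_order()
    samples = sorted(ped.ids)
    col = {iid: j for j, iid in enumerate(samples)}
    haps = np.zeros((n_sites, len(samples), 2), dtype=np.int8)
    maf = sites["founder_maf"].to_numpy()

    for iid in order:
        ind = ped[iid]
        j = col[iid]
        if ind.father is None and ind.mother is None:
            haps[:, j, 0] = rng.random(n_sites) < maf
            haps[:, j, 1] = rng.random(n_sites) < maf
        else:
            # unknown single parents are treated as draws from the founder pool
            if ind.father is not None:
                haps[:, j, 0] = _meiosis(haps[:, col[ind.father]], r, rng)
            else:
                haps[:, j, 0] = rng.random(n_sites) < maf
            if ind.mother is not None:
                haps[:, j, 1] = _meiosis(haps[:, col[ind.mother]], r, rng)
            else:
                haps[:, j, 1] = rng.random(n_sites) < maf

    site_cols = sites[SITE_COLUMNS].reset_index(drop=True)
    return TrueGenotypes(site_cols, samples, haps)


# ---------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------

def simulate_reads(
    truth: TrueGenotypes,
    mean_depth,
    base_error: float = 0.005,
    seed: int = 0,
) -> ReadData:
    """Poisson depths and binomial alt-read counts.

    ``mean_depth`` is either a scalar or a mapping / sequence of
    per-sample planned depths (the coverage tiers).  Each read samples
    one of the two haplotypes uniformly and reports its allele, flipped
    with probability ``base_error``.
    """
    if not 0.0 <= base_error < 0.5:
        raise ValueError("base_error must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_sites, n_samples, _ = truth.haps.shape
    if np.isscalar(mean_depth):
        mu = np.full(n_samples, float(mean_depth))
    elif isinstance(mean_depth, dict):
        mu = np.array([float(mean_depth[s]) for s in truth.samples])
    else:
        mu = np.asarray(mean_depth, dtype=float)
        if mu.shape != (n_samples,):
            raise ValueError("mean_depth length != number of samples")
    dp = rng.poisson(mu, size=(n_sites, n_samples)).astype(np.int32)
    p_true = truth.haps.mean(axis=2)  # P(read drawn from an alt-carrying haplotype)
    p_alt = p_true * (1.0 - base_error) + (1.0 - p_true) * base_error
    ad = rng.binomial(dp, p_alt).astype(np.int32)
    return ReadData(list(truth.samples), dp, ad)


# ---------------------------------------------------------------------
# decoy records for filter fixtures
# ---------------------------------------------------------------------

def inject_decoys(
    panel: SitePanel,
    n_multiallelic: int = 0,
    n_mnp: int = 0,
    seed: int = 0,
) -> SitePanel:
    """Append literal multi-allelic / multi-nucleotide decoy records.

    These records carry no modelled variation (all-missing genotypes,
    zero depth); they exist solely so the first QC filter has something
    real to remove.  The result is re-sorted by position.
    """
    rng = np.random.default_rng(seed)
    rows = []
    chroms = panel.sites["chrom"].unique()
    used = set(zip(panel.sites["chrom"], panel.sites["pos"]))
    max_pos = int(panel.sites["pos"].max()) + 1000

    def fresh_pos(chrom):
        while True:
            p = int(rng.integers(1, max_pos))
            if (chrom, p) not in used:
                used.add((chrom, p))
                return p

    for _ in range(n_multiallelic):
        c = chroms[int(rng.integers(len(chroms)))]
        ref, a1, a2 = rng.choice(_BASES, size=3, replace=False)
        rows.append((c, fresh_pos(c), ref, f"{a1},{a2}"))
    for _ in range(n_mnp):
        c = chroms[int(rng.integers(len(chroms)))]
        ref = "".join(rng.choice(_BASES, size=2))
        alt = "".join(rng.choice(_BASES, size=2))
        rows.append((c, fresh_pos(c), ref, alt))

    if not rows:
        return panel.copy()
    extra = pd.DataFrame(rows, columns=SITE_COLUMNS)
    sites = pd.concat([panel.sites, extra], ignore_index=True)
    m = panel.n_samples
    gt = np.vstack([panel.gt, np.full((len(rows), m), MISSING, dtype=np.int8)])
    dp = None if panel.dp is None else np.vstack(
        [panel.dp, np.zeros((len(rows), m), dtype=np.int32)])
    ad = None if panel.ad is None else np.vstack(
        [panel.ad, np.zeros((len(rows), m), dtype=np.int32)])
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    return SitePanel(sites.iloc[order], list(panel.samples), gt[order],
                     None if dp is None else dp[order],
                     None if ad is None else ad[order])
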