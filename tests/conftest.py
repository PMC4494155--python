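"""Shared simulated fixtures.

Everything is generated at test time from fixed seeds; the heavier
colony-scale simulations are session-scoped so the relatedness and
acceptance tests share one realization.
"""

import numpy as np
import pytest

from pedpanel import refine, relatedness, simulate
from pedpanel.panel import SitePanel
from pedpanel.pedigree import Individual, Pedigree


@pytest.fixture()
def trio_pedigree():
    return Pedigree([
        Individual("DAD", "M", 1980),
        Individual("MOM", "F", 1981),
        Individual("KID", "U", 1990, father="DAD", mother="MOM"),
    ])


@pytest.fixture(scope="session")
def trio_reads():
    """One trio sequenced deep (30x) over ~2,400 sites on 2 chromosomes;
    the raw material of the down-sampling experiments."""
    ped = Pedigree([
        Individual("DAD", "M", 1980),
        Individual("MOM", "F", 1981),
        Individual("KID", "U", 1990, father="DAD", mother="MOM"),
    ])
    sites = simulate.default_sites(2, 1200, seed=7)
    gmap = simulate.default_genetic_map(sites)
    truth = simulate.gene_drop(ped, sites, gmap, seed=8)
    unit = [u for u in ped.decompose_units() if u.kind == "trio"][0]
    reads = simulate.simulate_reads(
        truth, {"DAD": 30.0, "MOM": 30.0, "KID": 30.0}, 0.0075, seed=9)
    return ped, unit, truth, reads


@pytest.fixture(scope="session")
def colony():
    """A ~140-member colony over 3 descent generations from 30 founders,
    genotyped at 15x over 29 autosomes (120 sites and 115 cM each —
    primate-scale total map length, so LD pruning leaves enough
    independent markers for relatedness work)."""
    ped = simulate.simulate_pedigree(30, 3, 2.2, seed=21)
    sites = simulate.default_sites(29, 120, chromosome_length_bp=30_000_000,
                                   seed=22)
    gmap = simulate.default_genetic_map(sites, cm_per_chromosome=115.0)
    truth = simulate.gene_drop(ped, sites, gmap, seed=23)
    reads = simulate.simulate_reads(truth, 15.0, 0.005, seed=24)
    gt = refine.call_naive(reads.dp, reads.ad, 0.005)
    panel = SitePanel(truth.sites, list(truth.samples), gt, reads.dp, reads.ad)
    return ped, truth, reads, panel


@pytest.fixture(scope="session")
def colony_ibd(colony):
    """LD-pruned panel and all-pairs IBD estimates for the colony."""
    ped, truth, reads, panel = colony
    pruned = relatedness.ld_prune_for_ibd(panel)
    ibd = relatedness.estimate_ibd_all_pairs(panel, pruned)
    return pruned, ibd


def strip_parents(ped, kids):
    """Copy of *ped* with the parent links of *kids* removed."""
    inds = []
    for i in ped.members.values():
        if i.iid in kids:
            inds.append(Individual(i.iid, i.sex, i.birth_year, None, None,
                                   i.sequenced))
        else:
            inds.append(Individual(i.iid, i.sex, i.birth_year, i.father,
                                   i.mother, i.sequenced))
    return Pedigree(inds)


@pytest.fixture(scope="session")
def deparented(colony, colony_ibd):
    """20 last-generation children stripped of their parent links, with
    behavior/housing record tables derived from the true pedigree (the
    housing table lists the true father plus two decoy males)."""
    import pandas as pd

    ped, truth, reads, panel = colony
    _, ibd = colony_ibd
    kids = sorted(i for i in ped.ids
                  if ped[i].father and i.startswith("G03"))[:20]
    truth_parents = {k: (ped[k].mother, ped[k].father) for k in kids}
    stripped = strip_parents(ped, kids)
    rng = np.random.default_rng(79)
    males = [i.iid for i in ped.members.values() if i.sex == "M"]
    behavior = pd.DataFrame(
        [{"child": k, "candidate": truth_parents[k][0]} for k in kids])
    housing_rows = []
    for k in kids:
        cands = {truth_parents[k][1], *rng.choice(males, 2, replace=False)}
        housing_rows += [{"child": k, "candidate": c} for c in cands]
    housing = pd.DataFrame(housing_rows)
    return kids, truth_parents, stripped, ibd, behavior, housing


def make_panel(gt, chrom="chr1", start=100, step=1000, dp=None, ad=None,
               samples=None):
    """Small hand-built SitePanel from a (n_sites, n_samples) gt array."""
    import pandas as pd

    gt = np.asarray(gt, dtype=np.int8)
    n, m = gt.shape
    if samples is None:
        samples = [f"S{j}" for j in range(m)]
    if np.isscalar(chrom):
        chrom = [chrom] * n
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": start + step * np.arange(n),
        "ref": ["A"] * n,
        "alt": ["G"] * n,
    })
    return SitePanel(sites, list(samples), gt,
                     None if dp is None else np.asarray(dp, dtype=np.int32),
                     None if ad is None else np.asarray(ad, dtype=np.int32))
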