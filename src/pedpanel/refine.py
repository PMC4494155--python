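"""Genotype calling and trio-constrained refinement.

Three layers:

* ``genotype_likelihoods`` / ``call_naive`` — a single-sample
  maximum-posterior caller.  Per site the three genotype likelihoods are
  Binomial(depth, p) with p in {e, 1/2, 1-e} for per-base error e, and
  the prior is Hardy-Weinberg at a supplied population allele frequency.
* ``refine_unit`` — joint-posterior maximization over the 27 trio (or 9
  duo) genotype configurations, combining Hardy-Weinberg founder priors
  on the parents, Mendelian transmission probabilities to the child, and
  the members' read likelihoods.  Configurations that are Mendelian
  impossible carry zero transmission probability, so refined calls can
  never introduce a trio inconsistency at fully observed sites.
* ``build_consensus`` — an individual refined in several units carries
  one haplotype pair per unit; the replicates are pooled, split into two
  clusters (one haplotype per pair per cluster) minimizing within-cluster
  Hamming distance, and each cluster is collapsed by per-locus majority
  vote (ties become missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .panel import MISSING
from .pedigree import NuclearUnit

__all__ = [
    "genotype_likelihoods",
    "call_naive",
    "refine_unit",
    "RefinedUnit",
    "HaplotypeBundle",
    "build_consensus",
    "mendel_error_mask",
    "trio_mendel_errors",
    "concordance",
]


# ---------------------------------------------------------------------
# transmission / legality tables
# ---------------------------------------------------------------------

def _transmission_table() -> np.ndarray:
    """T[gf, gm, gc] = P(child gc | father gf, mother gm)."""
    T = np.zeros((3, 3, 3))
    for gf, gm in product(range(3), range(3)):
        pf, pm = gf / 2.0, gm / 2.0
        T[gf, gm, 0] = (1 - pf) * (1 - pm)
        T[gf, gm, 1] = pf * (1 - pm) + (1 - pf) * pm
        T[gf, gm, 2] = pf * pm
    return T


TRIO_TRANSMISSION = _transmission_table()
TRIO_LEGAL = TRIO_TRANSMISSION > 0

# duo legality: child must share an allele with the parent
DUO_LEGAL = np.ones((3, 3), dtype=bool)
DUO_LEGAL[0, 2] = DUO_LEGAL[2, 0] = False


def _phase_tables():
    """Per trio configuration: child (paternal, maternal) alleles and the
    allele each parent transmitted.  Unresolvable child phase puts the
    alt allele in the paternal slot (fixed tie rule)."""
    child = np.zeros((3, 3, 3, 2), dtype=np.int8)
    trans = np.zeros((3, 3, 3, 2), dtype=np.int8)  # transmitted by (father, mother)
    for gf, gm, gc in product(range(3), range(3), range(3)):
        if not TRIO_LEGAL[gf, gm, gc]:
            continue
        if gc == 0:
            af, am = 0, 0
        elif gc == 2:
            af, am = 1, 1
        else:
            if gf == 0:
                af = 0
            elif gf == 2:
                af = 1
            elif gm == 0:
                af = 1
            elif gm == 2:
                af = 0
            else:
                af = 1  # both parents het: alt to the paternal slot
            am = 1 - af
        child[gf, gm, gc] = (af, am)
        trans[gf, gm, gc] = (af, am)
    return child, trans


_CHILD_PHASE, _TRANSMITTED = _phase_tables()


# ---------------------------------------------------------------------
# single-sample calling
# ---------------------------------------------------------------------

def genotype_likelihoods(dp: np.ndarray, ad: np.ndarray, base_error: float) -> np.ndarray:
    """Normalized genotype likelihoods, shape ``dp.shape + (3,)``.

    Zero-depth entries get a flat triple (no read information).
    """
    if not 0.0 < base_error < 0.5:
        raise ValueError("base_error must be in (0, 0.5)")
    dp = np.asarray(dp)
    ad = np.asarray(ad)
    ps = (base_error, 0.5, 1.0 - base_error)
    L = np.stack([binom.pmf(ad, dp, p) for p in ps], axis=-1)
    L[dp == 0] = 1.0 / 3.0
    total = L.sum(axis=-1, keepdims=True)
    total[total == 0] = 1.0
    return L / total


def _hw_prior(alt_freq) -> np.ndarray:
    q = np.atleast_1d(np.asarray(alt_freq, dtype=float))
    q = np.clip(q, 1e-6, 1 - 1e-6)
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)


def call_naive(dp: np.ndarray, ad: np.ndarray, base_error: float,
               prior_maf=0.25) -> np.ndarray:
    """Maximum-posterior single-sample calls; missing at depth 0.

    ``prior_maf`` is the alt allele frequency of the Hardy-Weinberg
    prior — a scalar, or an array broadcastable over sites (axis 0).
    """
    L = genotype_likelihoods(dp, ad, base_error)
    prior = _hw_prior(prior_maf)
    while prior.ndim < L.ndim:
        prior = prior[..., None, :] if prior.shape[0] != 1 else prior[None]
    post = L * prior
    gt = post.argmax(axis=-1).astype(np.int8)
    gt[np.asarray(dp) == 0] = MISSING
    return gt


# ---------------------------------------------------------------------
# unit refinement
# ---------------------------------------------------------------------

@dataclass
class RefinedUnit:
    """Refined calls and phased haplotypes for one nuclear unit.

    ``gt`` maps member id -> (n_sites,) int8 calls; ``haps`` maps member
    id -> (n_sites, 2) int8 haplotypes (slot 0 paternal for the child,
    transmitted-allele-first for parents).  Members with zero depth at a
    site keep a missing call there but still constrain / are constrained
    by the joint model.
    """

    unit: NuclearUnit
    gt: dict
    haps: dict


def refine_unit(
    unit: NuclearUnit,
    dp: dict,
    ad: dict,
    base_error: float,
    pop_alt_freq,
) -> RefinedUnit:
    """Joint-posterior refinement of a trio, duo or singleton.

    ``dp`` / ``ad`` map member id -> (n_sites,) arrays.  ``pop_alt_freq``
    is the population alt allele frequency per site (scalar or array):
    it sets the Hardy-Weinberg prior on parental genotypes and the
    untransmitted-allele distribution in duos.
    """
    child = unit.child
    n_sites = len(dp[child])
    prior = _hw_prior(np.broadcast_to(np.asarray(pop_alt_freq, dtype=float),
                                      (n_sites,)))
    L = {m: genotype_likelihoods(dp[m], ad[m], base_error) for m in unit.member_ids}

    if unit.kind == "trio":
        f, m = unit.father, unit.mother
        joint = (
            prior[:, :, None, None] * L[f][:, :, None, None]
            * prior[:, None, :, None] * L[m][:, None, :, None]
            * TRIO_TRANSMISSION[None] * L[child][:, None, None, :]
        )
        flat = joint.reshape(n_sites, 27).argmax(axis=1)
        gf, gm, gc = np.unravel_index(flat, (3, 3, 3))
        gt = {f: gf.astype(np.int8), m: gm.astype(np.int8), child: gc.astype(np.int8)}
        haps = {child: _CHILD_PHASE[gf, gm, gc]}
        # parents: transmitted allele first, the rest of the genotype second
        tf = _TRANSMITTED[gf, gm, gc, 0]
        tm = _TRANSMITTED[gf, gm, gc, 1]
        haps[f] = np.stack([tf, gf - tf], axis=-1).astype(np.int8)
        haps[m] = np.stack([tm, gm - tm], axis=-1).astype(np.int8)
    elif unit.kind == "duo":
        p = unit.parents[0]
        q = np.clip(np.broadcast_to(np.asarray(pop_alt_freq, dtype=float),
                                    (n_sites,)), 1e-6, 1 - 1e-6)
        # child = one allele from the parent + one from the population
        pp = np.array([0.0, 0.5, 1.0])
        T = np.zeros((n_sites, 3, 3))
        for gp in range(3):
            T[:, gp, 0] = (1 - pp[gp]) * (1 - q)
            T[:, gp, 1] = pp[gp] * (1 - q) + (1 - pp[gp]) * q
            T[:, gp, 2] = pp[gp] * q
        joint = (prior[:, :, None] * L[p][:, :, None]
                 * T * L[child][:, None, :])
        flat = joint.reshape(n_sites, 9).argmax(axis=1)
        gp, gc = np.unravel_index(flat, (3, 3))
        gt = {p: gp.astype(np.int8), child: gc.astype(np.int8)}
        # transmitted allele: forced by hom parent or hom child; ties alt-first
        trans = np.where(gp == 0, 0, np.where(gp == 2, 1,
                         np.where(gc == 0, 0, np.where(gc == 2, 1, 1))))
        other = gc - trans
        slot0 = trans if unit.father is not None else other
        slot1 = other if unit.father is not None else trans
        haps = {child: np.stack([slot0, slot1], axis=-1).astype(np.int8),
                p: np.stack([trans, gp - trans], axis=-1).astype(np.int8)}
    elif unit.kind == "singleton":
        post = prior * L[child]
        gc = post.argmax(axis=1).astype(np.int8)
        # het phase unresolvable for a singleton: alt to the paternal slot
        h0 = np.where(gc == 2, 1, np.where(gc == 1, 1, 0))
        h1 = np.where(gc == 2, 1, 0)
        gt = {child: gc}
        haps = {child: np.stack([h0, h1], axis=-1).astype(np.int8)}
    else:  # pragma: no cover
        raise ValueError(f"unknown unit kind {unit.kind!r}")

    # family information imputes through zero-depth sites in trios and
    # duos; a singleton has no such information, so its zero-depth calls
    # stay missing
    if unit.kind == "singleton":
        gt[child] = gt[child].copy()
        gt[child][np.asarray(dp[child]) == 0] = MISSING
    return RefinedUnit(unit, gt, haps)


# ---------------------------------------------------------------------
# consensus haplotypes
# ---------------------------------------------------------------------

@dataclass
class HaplotypeBundle:
    """Replicated haplotype pairs of one individual across its units."""

    iid: str
    replicates: list  # list of (n_sites, 2) int8 arrays

    def __post_init__(self):
        lengths = {r.shape for r in self.replicates}
        if len(lengths) > 1:
            raise ValueError(f"bundle {self.iid}: replicate shape mismatch {lengths}")


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def _cluster_cost(cluster: list[np.ndarray]) -> int:
    cost = 0
    for i in range(len(cluster)):
        for j in range(i + 1, len(cluster)):
            cost += _hamming(cluster[i], cluster[j])
    return cost


def _majority(cluster: list[np.ndarray]) -> np.ndarray:
    stack = np.stack(cluster)
    ones = (stack == 1).sum(axis=0)
    zeros = (stack == 0).sum(axis=0)
    out = np.full(stack.shape[1], MISSING, dtype=np.int8)
    out[ones > zeros] = 1
    out[zeros > ones] = 0
    return out


def _orient_replicates(reps: list, exact_max_k: int) -> list:
    """Orientation bits: replicate i contributes haplotype orient[i] to
    cluster A and the other to cluster B.  Exact (minimum total
    within-cluster Hamming distance, first-found on ties) for k <=
    exact_max_k, greedy against running majority consensi beyond."""
    k = len(reps)
    if k <= exact_max_k:
        best, best_orient = None, None
        for bits in range(2 ** (k - 1)):
            orient = [0] + [(bits >> i) & 1 for i in range(k - 1)]
            a = [reps[i][:, orient[i]] for i in range(k)]
            b = [reps[i][:, 1 - orient[i]] for i in range(k)]
            cost = _cluster_cost(a) + _cluster_cost(b)
            if best is None or cost < best:
                best, best_orient = cost, orient
        return best_orient
    orient = [0]
    for i in range(1, k):
        a = [reps[j][:, orient[j]] for j in range(i)]
        b = [reps[j][:, 1 - orient[j]] for j in range(i)]
        ca, cb = _majority(a), _majority(b)
        keep = _hamming(reps[i][:, 0], ca) + _hamming(reps[i][:, 1], cb)
        swap = _hamming(reps[i][:, 1], ca) + _hamming(reps[i][:, 0], cb)
        orient.append(0 if keep <= swap else 1)
    return orient


def orientation_cost(reps: list, orient: list) -> int:
    """Total within-cluster Hamming distance of a replicate orientation."""
    a = [reps[i][:, orient[i]] for i in range(len(reps))]
    b = [reps[i][:, 1 - orient[i]] for i in range(len(reps))]
    return _cluster_cost(a) + _cluster_cost(b)


def build_consensus(bundle: HaplotypeBundle, exact_max_k: int = 6):
    """Two consensus haplotypes from replicated pairs.

    The 2k pooled haplotypes are split into two clusters with exactly
    one haplotype of each pair per cluster.  For k <= ``exact_max_k``
    the optimal split (minimum total within-cluster Hamming distance) is
    found by enumerating the 2^(k-1) orientations; larger bundles are
    seeded with the first pair and oriented greedily against running
    majority consensi.  Per-locus majority collapses each cluster; exact
    ties become missing.
    """
    reps = [np.asarray(r, dtype=np.int8) for r in bundle.replicates]
    if not reps:
        raise ValueError(f"bundle {bundle.iid}: no replicates")
    k = len(reps)
    if k == 1:
        return reps[0][:, 0].copy(), reps[0][:, 1].copy()
    orient = _orient_replicates(reps, exact_max_k)
    cluster_a = [reps[i][:, orient[i]] for i in range(k)]
    cluster_b = [reps[i][:, 1 - orient[i]] for i in range(k)]
    return _majority(cluster_a), _majority(cluster_b)


def consensus_genotype(h0: np.ndarray, h1: np.ndarray) -> np.ndarray:
    """Genotype implied by a consensus pair; missing if either side is."""
    gt = (h0 + h1).astype(np.int8)
    gt[(h0 == MISSING) | (h1 == MISSING)] = MISSING
    return gt


# ---------------------------------------------------------------------
# panel-level refinement
# ---------------------------------------------------------------------

def refine_panel(
    panel,
    units: Sequence[NuclearUnit],
    base_error: float,
    pop_alt_freq=None,
):
    """Refine a whole panel through its nuclear units.

    Every unit is refined jointly; each individual then receives one
    haplotype pair per unit it appears in, and the replicates are
    collapsed into two consensus haplotypes whose implied genotype is
    the final call.  Zero-depth sites of family-connected individuals
    are imputed through the joint model; individuals with no trio/duo
    membership keep missing calls at zero depth.  Returns a new
    SitePanel (refined genotypes, original reads) and the per-individual
    consensus haplotypes as an (n_sites, n_samples, 2) array.
    """
    from .panel import SitePanel

    if panel.dp is None or panel.ad is None:
        raise ValueError("refinement requires read depths (dp, ad)")
    if pop_alt_freq is None:
        naive = call_naive(panel.dp, panel.ad, base_error)
        called = naive >= 0
        with np.errstate(invalid="ignore"):
            pop_alt_freq = (np.where(called, naive, 0).sum(axis=1)
                            / np.maximum(2 * called.sum(axis=1), 1))
    col = {s: j for j, s in enumerate(panel.samples)}
    bundles: dict[str, list[np.ndarray]] = {s: [] for s in panel.samples}
    own_unit_gt: dict[str, np.ndarray] = {}
    family_informed: set[str] = set()
    for unit in units:
        dp = {m: panel.dp[:, col[m]] for m in unit.member_ids}
        ad = {m: panel.ad[:, col[m]] for m in unit.member_ids}
        refined = refine_unit(unit, dp, ad, base_error, pop_alt_freq)
        if unit.kind != "singleton":
            family_informed.update(unit.member_ids)
        own_unit_gt[unit.child] = refined.gt[unit.child]
        for member, haps in refined.haps.items():
            bundles[member].append(haps)

    n_sites, n_samples = panel.gt.shape
    gt = np.full((n_sites, n_samples), MISSING, dtype=np.int8)
    haps_out = np.full((n_sites, n_samples, 2), MISSING, dtype=np.int8)
    for s, reps in bundles.items():
        if not reps:
            continue
        h0, h1 = build_consensus(HaplotypeBundle(s, reps))
        j = col[s]
        haps_out[:, j, 0], haps_out[:, j, 1] = h0, h1
        g = consensus_genotype(h0, h1)
        # consensus vote ties (frequent for individuals in exactly two
        # units) fall back to the call of the individual's own
        # child-unit, the unit combining its reads with both parents
        if s in own_unit_gt:
            tie = g == MISSING
            g[tie] = own_unit_gt[s][tie]
        if s not in family_informed:  # no family data: cannot impute
            g[panel.dp[:, j] == 0] = MISSING
        gt[:, j] = g
    refined_panel = SitePanel(panel.sites, list(panel.samples), gt,
                              panel.dp.copy(), panel.ad.copy())
    return refined_panel, haps_out


# ---------------------------------------------------------------------
# Mendelian error counting and concordance
# ---------------------------------------------------------------------

def mendel_error_mask(unit: NuclearUnit, gt: dict) -> np.ndarray:
    """Boolean mask of sites with an impossible child genotype.

    Only sites where every required member is non-missing are eligible.
    """
    gc = np.asarray(gt[unit.child])
    if unit.kind == "trio":
        gf, gm = np.asarray(gt[unit.father]), np.asarray(gt[unit.mother])
        observed = (gf >= 0) & (gm >= 0) & (gc >= 0)
        legal = TRIO_LEGAL[gf.clip(0), gm.clip(0), gc.clip(0)]
        return observed & ~legal
    if unit.kind == "duo":
        gp = np.asarray(gt[unit.parents[0]])
        observed = (gp >= 0) & (gc >= 0)
        legal = DUO_LEGAL[gp.clip(0), gc.clip(0)]
        return observed & ~legal
    return np.zeros(gc.shape, dtype=bool)


def trio_mendel_errors(unit: NuclearUnit, gt: dict) -> tuple[int, float]:
    """(error count, rate over comparable non-missing sites)."""
    if unit.kind == "singleton":
        raise ValueError("Mendelian check requires a trio or duo")
    mask = mendel_error_mask(unit, gt)
    members = [np.asarray(gt[m]) >= 0 for m in unit.member_ids]
    comparable = np.logical_and.reduce(members)
    n = int(comparable.sum())
    count = int(mask.sum())
    return count, (count / n if n else 0.0)


def concordance(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of agreeing calls over sites non-missing in both."""
    a, b = np.asarray(a), np.asarray(b)
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    return float((a[both] == b[both]).mean()) if n else float("nan")
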