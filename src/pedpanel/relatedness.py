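"""Sample-level QC: IBD estimation, contamination flagging, parentage.

Pairwise relatedness is estimated by the method-of-moments decomposition
of identity-by-state (IBS) into identity-by-descent (IBD) probabilities
(Z0, Z1, Z2) using sample allele frequencies from an LD-pruned panel,
summarized as pi-hat = Z1/2 + Z2.  Samples whose genome-wide estimates
disagree with the pedigree kinship for many pairs are flagged as likely
contamination or mislabeling.  Parentage of individuals with unknown
parents is assigned by four rules applied jointly: (1) parent-offspring
level IBD sharing with at most one candidate per sex, (2) behavioral
(mother) record compatibility, (3) housing (father) record
compatibility, and (4) a plausible parent-offspring age difference
(default 4-15 years).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ld import sliding_window_prune
from .panel import SitePanel
from .pedigree import Pedigree

__all__ = [
    "IBDEstimate",
    "ParentageCall",
    "ld_prune_for_ibd",
    "estimate_ibd",
    "estimate_ibd_all_pairs",
    "flag_sample_issues",
    "assign_parentage",
]


def ld_prune_for_ibd(
    panel: SitePanel,
    r2_max: float = 0.1,
    window: int = 50,
    shift: int = 20,
) -> np.ndarray:
    """Indices of a near-independent SNP subset (default r² <= 0.1)."""
    return sliding_window_prune(panel.dosage(), r2_max, window, shift)


@dataclass(frozen=True)
class IBDEstimate:
    pair: tuple[str, str]
    z0: float
    z1: float
    z2: float
    n_sites: int
    reliable: bool = True

    @property
    def pi_hat(self) -> float:
        return self.z1 / 2.0 + self.z2


def _ibs_expectations(p: np.ndarray):
    """Per-site P(IBS state | IBD state) under sample allele freq p."""
    q = 1.0 - p
    e0 = np.stack([2 * p**2 * q**2,
                   4 * p**3 * q + 4 * p * q**3,
                   p**4 + q**4 + 4 * p**2 * q**2])
    e1 = np.stack([np.zeros_like(p), 2 * p * q, p**2 + q**2])
    return e0, e1


def _project_simplex(z: np.ndarray) -> np.ndarray:
    z = np.clip(z, 0.0, None)
    s = z.sum()
    return z / s if s > 0 else np.array([1.0, 0.0, 0.0])


def estimate_ibd(
    gt_a: np.ndarray,
    gt_b: np.ndarray,
    alt_freq: np.ndarray,
    pair: tuple[str, str] = ("A", "B"),
    min_sites: int = 100,
) -> IBDEstimate:
    """Method-of-moments (Z0, Z1, Z2) for one pair of genotype vectors.

    Observed IBS-state counts are matched against their expectations
    under IBD 0/1/2 (chained solve), then projected onto the simplex.
    Estimates from fewer than *min_sites* shared non-missing,
    polymorphic sites are flagged unreliable.
    """
    gt_a, gt_b = np.asarray(gt_a), np.asarray(gt_b)
    p = np.asarray(alt_freq, dtype=float)
    use = (gt_a >= 0) & (gt_b >= 0) & (p > 0) & (p < 1)
    n = int(use.sum())
    if n == 0:
        return IBDEstimate(pair, 1.0, 0.0, 0.0, 0, reliable=False)
    ibs = 2 - np.abs(gt_a[use] - gt_b[use])
    counts = np.bincount(ibs, minlength=3).astype(float)
    e0, e1 = _ibs_expectations(p[use])
    s0, s1 = e0.sum(axis=1), e1.sum(axis=1)
    z0 = counts[0] / s0[0] if s0[0] > 0 else 0.0
    z1 = (counts[1] - z0 * s0[1]) / s1[1] if s1[1] > 0 else 0.0
    z2 = (counts[2] - z0 * s0[2] - z1 * s1[2]) / n
    z = _project_simplex(np.array([z0, z1, z2]))
    return IBDEstimate(pair, float(z[0]), float(z[1]), float(z[2]), n,
                       reliable=n >= min_sites)


def estimate_ibd_all_pairs(
    panel: SitePanel,
    site_index: Optional[np.ndarray] = None,
    min_sites: int = 100,
) -> pd.DataFrame:
    """All-pairs IBD table (id1, id2, Z0, Z1, Z2, PI_HAT, N).

    Column-compatible with the familiar ``.genome`` tabular layout.
    Allele frequencies come from the supplied (pruned) site subset.
    """
    sub = panel if site_index is None else panel.subset_sites(site_index)
    p = sub.alt_frequency()
    rows = []
    for i in range(sub.n_samples):
        for j in range(i + 1, sub.n_samples):
            est = estimate_ibd(sub.gt[:, i], sub.gt[:, j], p,
                               (sub.samples[i], sub.samples[j]), min_sites)
            rows.append((est.pair[0], est.pair[1], est.z0, est.z1, est.z2,
                         est.pi_hat, est.n_sites))
    return pd.DataFrame(rows, columns=["id1", "id2", "Z0", "Z1", "Z2",
                                       "PI_HAT", "N"])


def flag_sample_issues(
    ibd: pd.DataFrame,
    ped: Pedigree,
    discordance_threshold: float = 0.15,
    min_discordant_pairs: int = 10,
    external_concordance: Optional[dict] = None,
    concordance_floor: float = 0.9,
    min_reliable_sites: int = 500,
) -> list[str]:
    """Samples whose genetic relatedness contradicts the pedigree.

    A pair is discordant when |pi_hat - 2*phi| exceeds the threshold;
    samples in at least *min_discordant_pairs* discordant pairs are
    flagged, as are samples whose concordance with an external genotype
    set (when provided) falls below the floor.  Pairs whose estimate
    rests on fewer than *min_reliable_sites* shared sites (column N,
    when present) carry no exclusion-grade evidence and are skipped:
    with the method-of-moments estimator the pi-hat noise floor is
    roughly 0.03 * sqrt(1500/n), so ~500 sites keep 3 sigma inside the
    0.15 discordance threshold.
    """
    has_n = "N" in ibd.columns
    discord: dict[str, int] = {}
    for row in ibd.itertuples(index=False):
        if has_n and row.N < min_reliable_sites:
            continue
        expected = 2.0 * ped.kinship(row.id1, row.id2)
        if abs(row.PI_HAT - expected) > discordance_threshold:
            discord[row.id1] = discord.get(row.id1, 0) + 1
            discord[row.id2] = discord.get(row.id2, 0) + 1
    flagged = {s for s, n in discord.items() if n >= min_discordant_pairs}
    if external_concordance:
        flagged |= {s for s, c in external_concordance.items()
                    if c < concordance_floor}
    return sorted(flagged)


@dataclass
class ParentageCall:
    child: str
    mother: Optional[str] = None
    father: Optional[str] = None
    mother_evidence: dict = field(default_factory=dict)
    father_evidence: dict = field(default_factory=dict)
    provisional: bool = False

    @property
    def resolved(self) -> bool:
        return self.mother is not None and self.father is not None


def _age_plausible(parent_year, child_year, age_range) -> bool:
    if parent_year is None or child_year is None:
        return False
    gap = child_year - parent_year
    return age_range[0] <= gap <= age_range[1]


def assign_parentage(
    unknowns: Sequence[str],
    ibd: pd.DataFrame,
    ped: Pedigree,
    behavior_records: Optional[pd.DataFrame] = None,
    housing_records: Optional[pd.DataFrame] = None,
    pi_window: tuple[float, float] = (0.35, 0.65),
    z0_max: float = 0.1,
    age_range: tuple[int, int] = (4, 15),
) -> list[ParentageCall]:
    """Four-rule parentage assignment for individuals of unknown parents.

    ``behavior_records`` / ``housing_records`` are (child, candidate)
    tables asserting record compatibility for mothers and fathers
    respectively; when a table is absent its rule is skipped and the
    resulting calls are marked provisional.  An assignment of one parent
    requires a single surviving candidate of that sex; several
    candidates leave that slot unresolved.  A candidate born less than
    ``age_range[0]`` years before the child (including any born after
    the child) is always rejected.
    """
    pi = {}
    for row in ibd.itertuples(index=False):
        pi[(row.id1, row.id2)] = (row.PI_HAT, row.Z0)
        pi[(row.id2, row.id1)] = (row.PI_HAT, row.Z0)

    def compat(records, child, cand) -> bool:
        return bool(((records["child"] == child)
                     & (records["candidate"] == cand)).any())

    calls = []
    for child in unknowns:
        cy = ped[child].birth_year
        call = ParentageCall(child=child,
                             provisional=behavior_records is None
                             or housing_records is None)
        survivors = {"F": [], "M": []}
        for other in ped.ids:
            if other == child or (other, child) not in pi:
                continue
            sex = ped[other].sex
            if sex not in ("M", "F"):
                continue
            pihat, z0 = pi[(other, child)]
            evidence = {
                "ibd_level": pi_window[0] <= pihat <= pi_window[1] and z0 < z0_max,
                "age_window": _age_plausible(ped[other].birth_year, cy, age_range),
            }
            if sex == "F":
                evidence["behavior_record"] = (
                    True if behavior_records is None
                    else compat(behavior_records, child, other))
            else:
                evidence["housing_record"] = (
                    True if housing_records is None
                    else compat(housing_records, child, other))
            if all(evidence.values()):
                survivors[sex].append((other, evidence))
        if len(survivors["F"]) == 1:
            call.mother, call.mother_evidence = survivors["F"][0]
        if len(survivors["M"]) == 1:
            call.father, call.father_evidence = survivors["M"][0]
        calls.append(call)
    return calls


def parentage_table(calls: Sequence[ParentageCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "child": c.child,
            "mother": c.mother or "unresolved",
            "father": c.father or "unresolved",
            "provisional": c.provisional,
            **{f"mother_{k}": v for k, v in c.mother_evidence.items()},
            **{f"father_{k}": v for k, v in c.father_evidence.items()},
        })
    return pd.DataFrame(rows)
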