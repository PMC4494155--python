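"""Hierarchical sequencing-coverage design and its down-sampling harness.

The ranking problem: given a pedigree and the subset of individuals that
will be sequenced, order them so that deep coverage goes to the
individuals whose accurate genotypes constrain the most other samples.
The greedy rule ranks first the individual with the most direct
(one-generation) sequenced descendants, then repeatedly picks the
individual adding the most *new* ids to the growing offspring-set;
ties go to the older individual (unknown birth year last), then to the
lexicographically smaller id.  Rank 1 means sequenced deepest.

The down-sampling harness thins a trio's reads to a target depth per
role and measures, over replicates, the trio Mendelian-inconsistency
rate and per-role concordance against the full-depth calls — the
experiment that motivates putting parents, not children, at higher
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pedigree import NuclearUnit, Pedigree
from .refine import call_naive, concordance, trio_mendel_errors
from .simulate import ReadData

__all__ = [
    "CoveragePlan",
    "TrioMetrics",
    "greedy_rank",
    "assign_tiers",
    "downsample_reads",
    "evaluate_scheme",
]

TIER_DEPTHS = {"high": 30.0, "medium": 5.0, "low": 1.0}


@dataclass
class CoveragePlan:
    ranked_ids: list[str]
    tier: dict  # id -> 'high' | 'medium' | 'low'
    target_depth: dict = field(default_factory=lambda: dict(TIER_DEPTHS))

    def depth_of(self, iid: str) -> float:
        return self.target_depth[self.tier[iid]]

    def tier_sizes(self) -> dict:
        sizes = {"high": 0, "medium": 0, "low": 0}
        for t in self.tier.values():
            sizes[t] += 1
        return sizes


def _age_key(ped: Pedigree, iid: str):
    by = ped[iid].birth_year
    return (0, by) if by is not None else (1, 0)


def greedy_rank(ped: Pedigree, sequenced: Optional[Sequence[str]] = None) -> list[str]:
    """Rank individuals by marginal contribution of new sequenced children.

    Restricted to the sequenced subgraph.  The offspring-set is a set of
    unique child ids; each pick maximizes the number of ids it would add.
    Deterministic: ties broken by birth year ascending (older first,
    unknown last), then id ascending.
    """
    if sequenced is None:
        sequenced = ped.sequenced_ids()
    pool = set(sequenced)
    unknown = pool - set(ped.ids)
    if unknown:
        raise KeyError(f"sequenced ids not in pedigree: {sorted(unknown)[:3]}")
    children = {i: ped.direct_children(i) & pool for i in pool}

    ranked: list[str] = []
    offspring: set[str] = set()
    remaining = set(pool)
    while remaining:
        best = min(
            remaining,
            key=lambda c: (-len(children[c] - offspring), _age_key(ped, c), c),
        )
        ranked.append(best)
        offspring |= children[best]
        remaining.discard(best)
    return ranked


def assign_tiers(
    ranking: Sequence[str],
    n_high: int,
    n_medium: int,
    target_depth: Optional[dict] = None,
) -> CoveragePlan:
    """First *n_high* ranked ids to high coverage, next *n_medium* to
    medium, the remainder to low."""
    if n_high < 0 or n_medium < 0:
        raise ValueError("tier sizes must be non-negative")
    if n_high + n_medium > len(ranking):
        raise ValueError(
            f"n_high + n_medium = {n_high + n_medium} exceeds "
            f"ranking length {len(ranking)}"
        )
    tier = {}
    for k, iid in enumerate(ranking):
        tier[iid] = "high" if k < n_high else "medium" if k < n_high + n_medium else "low"
    return CoveragePlan(list(ranking), tier,
                        dict(target_depth) if target_depth else dict(TIER_DEPTHS))


def downsample_reads(
    reads: ReadData,
    iid: str,
    target_depth: float,
    seed: int = 0,
) -> ReadData:
    """Thin one sample's reads to *target_depth* mean coverage.

    Each read is retained independently with probability
    target/achieved; depth is thinned binomially and the alt count by a
    hypergeometric draw of the retained reads (reads are exchangeable,
    so this is uniform read sampling).  Other samples are untouched.
    """
    j = reads.samples.index(iid)
    achieved = float(reads.dp[:, j].mean())
    if target_depth > achieved:
        raise ValueError(
            f"cannot down-sample {iid}: target {target_depth}x exceeds "
            f"achieved {achieved:.2f}x"
        )
    rng = np.random.default_rng(seed)
    frac = target_depth / achieved if achieved > 0 else 0.0
    dp = reads.dp.copy()
    ad = reads.ad.copy()
    new_dp = rng.binomial(dp[:, j], frac).astype(np.int32)
    new_ad = rng.hypergeometric(
        np.maximum(ad[:, j], 0), dp[:, j] - ad[:, j], new_dp,
    ).astype(np.int32) if len(new_dp) else new_dp
    # hypergeometric draws with nsample=0 are 0; guard empty-depth sites
    new_ad[new_dp == 0] = 0
    dp[:, j] = new_dp
    ad[:, j] = new_ad
    return ReadData(list(reads.samples), dp, ad)


@dataclass
class TrioMetrics:
    mendelian_inconsistency_rate: float
    concordance: dict  # role -> mean concordance vs full-depth calls
    replicates: int
    per_replicate_rates: list = field(default_factory=list)


def evaluate_scheme(
    unit: NuclearUnit,
    reads: ReadData,
    scheme: dict,
    replicates: int = 3,
    seed: int = 0,
    base_error: float = 0.005,
    prior_maf=0.25,
) -> TrioMetrics:
    """Down-sample a trio per *scheme* and measure the damage.

    ``scheme`` maps roles ('father', 'mother', 'child') to target mean
    depths; roles absent from the scheme keep their full coverage.
    Metrics use the single-sample maximum-posterior calls: the trio
    Mendelian-inconsistency rate (over sites where all three calls are
    non-missing) and per-role concordance against the calls made from
    the full-depth reads, averaged over replicates.
    """
    if unit.kind != "trio":
        raise ValueError("down-sampling evaluation requires a trio unit")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    roles = {"father": unit.father, "mother": unit.mother, "child": unit.child}
    cols = {r: reads.samples.index(iid) for r, iid in roles.items()}

    def calls(rd: ReadData) -> dict:
        return {
            iid: call_naive(rd.dp[:, cols[r]], rd.ad[:, cols[r]], base_error, prior_maf)
            for r, iid in roles.items()
        }

    baseline = calls(reads)
    rates, conc = [], {r: [] for r in roles}
    master = np.random.default_rng(seed)
    for _ in range(replicates):
        thinned = reads
        for role, target in scheme.items():
            thinned = downsample_reads(
                thinned, roles[role], float(target),
                seed=int(master.integers(2**31)),
            )
        gt = calls(thinned)
        _, rate = trio_mendel_errors(unit, gt)
        rates.append(rate)
        for role, iid in roles.items():
            conc[role].append(concordance(gt[iid], baseline[iid]))
    return TrioMetrics(
        mendelian_inconsistency_rate=float(np.mean(rates)),
        concordance={r: float(np.mean(v)) for r, v in conc.items()},
        replicates=replicates,
        per_replicate_rates=[float(r) for r in rates],
    )
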