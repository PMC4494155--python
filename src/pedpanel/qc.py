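"""Variant QC filter cascades with per-filter accounting ledgers.

Three cascades mirror the study design:

* Stage 1 screens the discovery set from the high-coverage (HC)
  samples: biallelic SNVs only, cumulative-depth window, MAF >= 25 % in
  the HC set, no missing HC calls, and removal of sites within 5 bp of
  each other.
* Stage 2 screens the pedigree-wide call set: depth window, MAF >= 10 %,
  <= 50 % missingness, per-site Mendelian-error budget across nuclear
  units, heterozygote excess, and sex-chromosome exclusion.
* Stage 4 finalizes after pedigree updates: Mendelian-error budget,
  heterozygote excess, masking of sporadic Mendelian-error child calls,
  then a 5 % missingness ceiling.

Every cascade returns the filtered panel together with a FilterReport —
an ordered ledger of (filter name, removed, remaining) whose
conservation (start - sum(removed) = end) is asserted on construction.
Cascades are deterministic and idempotent; the step order is fixed and
matters (the proximity filter sees only the sites alive when it runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .panel import MISSING, SitePanel
from .pedigree import NuclearUnit
from .refine import mendel_error_mask

__all__ = [
    "FilterStep",
    "FilterReport",
    "stage1_filter",
    "stage2_filter",
    "stage4_final_filter",
    "mendel_unit_counts",
    "report_render",
    "report_parse",
]

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


@dataclass(frozen=True)
class FilterStep:
    name: str
    removed: int
    remaining_after: int

    def __post_init__(self):
        if self.removed < 0:
            raise ValueError(f"step {self.name!r}: negative removal count")


@dataclass
class FilterReport:
    stage: str
    start_count: int
    steps: list[FilterStep] = field(default_factory=list)

    def __post_init__(self):
        remaining = self.start_count
        for step in self.steps:
            remaining -= step.removed
            if step.remaining_after != remaining:
                raise ValueError(
                    f"stage {self.stage}, step {step.name!r}: ledger breaks "
                    f"conservation ({step.remaining_after} != {remaining})"
                )
        if remaining < 0:
            raise ValueError("ledger removed more sites than existed")

    @property
    def end_count(self) -> int:
        return self.start_count - self.total_removed

    @property
    def total_removed(self) -> int:
        return sum(s.removed for s in self.steps)


class _Cascade:
    """Applies ordered boolean drop-masks to a panel, keeping the ledger."""

    def __init__(self, stage: str, panel: SitePanel):
        self.stage = stage
        self.panel = panel
        self.steps: list[FilterStep] = []
        self.start = panel.n_sites

    def drop(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        removed = int(mask.sum())
        if removed:
            self.panel = self.panel.subset_sites(~mask)
        self.steps.append(FilterStep(name, removed, self.panel.n_sites))

    def report(self) -> FilterReport:
        return FilterReport(self.stage, self.start, self.steps)


def _coverage_window_mask(panel: SitePanel) -> np.ndarray:
    """Sites with cumulative depth outside [median/2, 2*median]."""
    cum = panel.cumulative_depth()
    m = float(np.median(cum))
    return (cum < m / 2.0) | (cum > 2.0 * m)


def _proximity_mask(panel: SitePanel, max_dist: int = 5) -> np.ndarray:
    """Both members of any same-chromosome pair within *max_dist* bp."""
    chrom = panel.sites["chrom"].to_numpy()
    pos = panel.sites["pos"].to_numpy()
    mask = np.zeros(panel.n_sites, dtype=bool)
    order = np.lexsort((pos, chrom))
    oc, op = chrom[order], pos[order]
    close = (oc[:-1] == oc[1:]) & (np.diff(op) <= max_dist)
    mask[order[:-1][close]] = True
    mask[order[1:][close]] = True
    return mask


def mendel_unit_counts(
    panel: SitePanel, units: Sequence[NuclearUnit]
) -> tuple[np.ndarray, dict]:
    """Per-site count of nuclear units showing a Mendelian error.

    Returns (counts, unit_masks) where unit_masks maps each trio/duo
    unit to its per-site error mask (used by Stage 4 masking).
    """
    counts = np.zeros(panel.n_sites, dtype=np.int32)
    unit_masks: dict = {}
    col = {s: j for j, s in enumerate(panel.samples)}
    for unit in units:
        if unit.kind == "singleton":
            continue
        gt = {m: panel.gt[:, col[m]] for m in unit.member_ids}
        mask = mendel_error_mask(unit, gt)
        unit_masks[unit] = mask
        counts += mask
    return counts, unit_masks


# ---------------------------------------------------------------------
# cascades
# ---------------------------------------------------------------------

def stage1_filter(
    panel: SitePanel,
    hc_ids: Sequence[str],
    maf_min: float = 0.25,
    proximity_bp: int = 5,
) -> tuple[SitePanel, FilterReport]:
    """Discovery-set screen in the high-coverage samples."""
    if not len(hc_ids):
        raise ValueError("stage 1 requires a non-empty high-coverage id set")
    panel.sample_index(hc_ids)  # raises on unknown ids
    c = _Cascade("stage1", panel)
    c.drop("Multi-allelic or multi-nucleotide", ~c.panel.is_biallelic_snv())
    c.drop("Cumulative coverage outside of twofold range of global median coverage",
           _coverage_window_mask(c.panel))
    c.drop(f"MAF in {len(hc_ids)} samples <{maf_min:.0%}",
           c.panel.maf(hc_ids) < maf_min)
    c.drop(">0 % missing data", c.panel.missing_rate(hc_ids) > 0)
    c.drop(f"Within {proximity_bp} bp of another site",
           _proximity_mask(c.panel, proximity_bp))
    return c.panel, c.report()


def stage2_filter(
    panel: SitePanel,
    units: Sequence[NuclearUnit],
    maf_ids: Optional[Sequence[str]] = None,
    maf_min: float = 0.10,
    missing_max: float = 0.50,
    mendel_max_units: int = 5,
    het_max: float = 0.6,
) -> tuple[SitePanel, FilterReport]:
    """Pedigree-wide call-set screen.

    ``maf_ids`` restricts the MAF computation to a sample subset
    (defaults to all samples in the panel).  The alignment-caller row is
    kept in the ledger as a pass-through for structural fidelity: no
    alignment layer exists here, so it removes nothing.
    """
    c = _Cascade("stage2", panel)
    c.drop("Not passing alignment-caller filters (no alignment layer; pass-through)",
           np.zeros(c.panel.n_sites, dtype=bool))
    c.drop("Cumulative coverage outside of twofold range of global median coverage",
           _coverage_window_mask(c.panel))
    n_maf = len(maf_ids) if maf_ids is not None else c.panel.n_samples
    c.drop(f"MAF in {n_maf} samples <{maf_min:.0%}",
           c.panel.maf(maf_ids) < maf_min)
    c.drop(f"Missing >{missing_max:.0%} of data",
           c.panel.missing_rate() > missing_max)
    counts, _ = mendel_unit_counts(c.panel, units)
    c.drop(f">={mendel_max_units} Mendel errors in parent-child comparisons",
           counts >= mendel_max_units)
    c.drop(f">{het_max:.0%} heterozygous calls", c.panel.het_fraction() > het_max)
    c.drop("Sex chromosome SNPs",
           c.panel.sites["chrom"].isin(SEX_CHROMS).to_numpy())
    return c.panel, c.report()


def stage4_final_filter(
    panel: SitePanel,
    units: Sequence[NuclearUnit],
    mendel_max_units: int = 5,
    het_max: float = 0.6,
    missing_max: float = 0.05,
) -> tuple[SitePanel, FilterReport]:
    """Final screen after pedigree updates and re-refinement.

    Step 3 masks (sets to missing) the child call of each remaining
    sporadic Mendelian-error unit — it removes no sites itself, but the
    masking feeds the 5 % missingness ceiling of step 4.
    """
    c = _Cascade("stage4", panel)
    counts, _ = mendel_unit_counts(c.panel, units)
    c.drop(f">={mendel_max_units} Mendel errors between parents and offspring",
           counts >= mendel_max_units)
    c.drop(f"Excess heterozygosity (heterozygous fraction>{het_max})",
           c.panel.het_fraction() > het_max)
    # step 3: mask sporadic Mendelian-error child genotypes in place
    c.panel = c.panel.copy()
    _, unit_masks = mendel_unit_counts(c.panel, units)
    col = {s: j for j, s in enumerate(c.panel.samples)}
    for unit, mask in unit_masks.items():
        c.panel.gt[mask, col[unit.child]] = MISSING
    c.steps.append(FilterStep(
        "Sporadic parent-offspring Mendelian-error genotypes marked missing",
        0, c.panel.n_sites))
    c.drop(f"Missing rate >{missing_max:.0%}",
           c.panel.missing_rate() > missing_max)
    return c.panel, c.report()


# ---------------------------------------------------------------------
# ledger rendering
# ---------------------------------------------------------------------

def report_render(report: FilterReport) -> str:
    """Ledger as TSV: caption line, per-step rows, TOTAL row."""
    lines = [
        f"# {report.stage}: start {report.start_count}, end {report.end_count}",
        "procedure\tremoved",
    ]
    for step in report.steps:
        lines.append(f"{step.name}\t{step.removed}")
    lines.append(f"TOTAL\t{report.total_removed}")
    return "\n".join(lines) + "\n"


def report_parse(text: str) -> FilterReport:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    head = lines[0]
    if not head.startswith("#"):
        raise ValueError("ledger missing caption line")
    stage = head[1:].split(":")[0].strip()
    start = int(head.split("start")[1].split(",")[0].strip())
    steps = []
    remaining = start
    for ln in lines[2:]:
        name, removed = ln.rsplit("\t", 1)
        if name == "TOTAL":
            continue
        remaining -= int(removed)
        steps.append(FilterStep(name, int(removed), remaining))
    return FilterReport(stage, start, steps)
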