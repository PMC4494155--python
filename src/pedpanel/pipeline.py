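"""End-to-end orchestration of the synthetic study.

Runs simulate → rank/tier → sequence → Stage 1 (discovery screen in the
high-coverage samples) → Stage 2 (pedigree-wide refined calls and
screen) → Stage 3 (sample QC and exclusions) → Stage 4 (final screen and
LD-thinned association / linkage panels), writing per-stage VCFs and
ledgers plus a manifest of output hashes.  Every stochastic step draws
its seed deterministically from the master seed, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import coverage, mapset, qc, refine, relatedness, simulate
from .panel import SitePanel
from .pedigree import Pedigree, write_pedigree

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 0
    # simulator
    n_founders: int = 20
    n_generations: int = 4
    mean_offspring: float = 1.6
    n_chromosomes: int = 29
    sites_per_chromosome: int = 125
    chromosome_length_bp: int = 50_000_000
    cm_per_chromosome: float = 115.0
    base_error: float = 0.005
    n_decoy_multiallelic: int = 5
    n_decoy_mnp: int = 3
    # coverage design
    n_high: int = 6
    n_medium: int = 40
    tier_depths: dict = field(default_factory=lambda: dict(coverage.TIER_DEPTHS))
    # filters
    stage1_maf: float = 0.25
    stage2_maf: float = 0.10
    stage2_missing: float = 0.50
    proximity_bp: int = 5
    mendel_max_units: int = 5
    het_max: float = 0.6
    stage4_missing: float = 0.05
    # pruning
    r2_ibd: float = 0.1
    r2_association: float = 0.9
    r2_linkage: float = 0.4
    ld_window: int = 50
    ld_shift: int = 20
    skip_stage3_exclusions: bool = False
    outdir: str = "pedpanel_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if self.n_high < 0 or self.n_medium < 0:
            raise ValueError("tier sizes must be non-negative")
        if not 0 < self.base_error < 0.5:
            raise ValueError("base_error must be in (0, 0.5)")
        for r2 in (self.r2_ibd, self.r2_association, self.r2_linkage):
            if not 0 < r2 <= 1:
                raise ValueError("r2 thresholds must be in (0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(master).generate_state(n) % (2**31)]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds = _seeds(config.seed, 6)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, **info) -> None:
        files = info.pop("files", [])
        manifest["stages"][stage] = {
            **info, "files": {f.name: _sha256(f) for f in files},
        }

    # -- setup: simulate the colony ------------------------------------
    ped = simulate.simulate_pedigree(
        config.n_founders, config.n_generations, config.mean_offspring,
        seed=seeds[0])
    sequenced = ped.sequenced_ids()
    if config.n_high + config.n_medium > len(sequenced):
        raise ValueError(
            f"n_high + n_medium = {config.n_high + config.n_medium} exceeds "
            f"the {len(sequenced)} sequenced individuals")
    sites = simulate.default_sites(
        config.n_chromosomes, config.sites_per_chromosome,
        config.chromosome_length_bp, seed=seeds[1])
    gmap = simulate.default_genetic_map(sites, config.cm_per_chromosome)
    truth = simulate.gene_drop(ped, sites, gmap, seed=seeds[2])
    write_pedigree(ped, out / "pedigree.tsv")
    simulate.write_genetic_map(gmap, out / "genetic_map.tsv")

    # -- coverage design and sequencing --------------------------------
    ranking = coverage.greedy_rank(ped, sequenced)
    plan = coverage.assign_tiers(ranking, config.n_high, config.n_medium,
                                 config.tier_depths)
    depths = {s: plan.depth_of(s) for s in truth.samples}
    reads = simulate.simulate_reads(truth, depths, config.base_error,
                                    seed=seeds[3])
    with open(out / "coverage_plan.tsv", "w") as fh:
        fh.write("rank\tid\ttier\ttarget_depth\n")
        for k, iid in enumerate(plan.ranked_ids, start=1):
            fh.write(f"{k}\t{iid}\t{plan.tier[iid]}\t{plan.depth_of(iid)}\n")
    record("design", tier_sizes=plan.tier_sizes(),
           files=[out / "pedigree.tsv", out / "coverage_plan.tsv",
                  out / "genetic_map.tsv"])

    # -- stage 1: discovery screen in the HC samples -------------------
    hc_ids = [s for s in truth.samples if plan.tier[s] == "high"]
    naive = refine.call_naive(reads.dp, reads.ad, config.base_error)
    panel0 = SitePanel(truth.sites, list(truth.samples), naive,
                       reads.dp, reads.ad)
    panel0 = simulate.inject_decoys(panel0, config.n_decoy_multiallelic,
                                    config.n_decoy_mnp, seed=seeds[4])
    panel1, rep1 = qc.stage1_filter(panel0, hc_ids, config.stage1_maf,
                                    config.proximity_bp)
    (out / "stage1_ledger.tsv").write_text(qc.report_render(rep1))
    panel1.to_vcf(out / "stage1.vcf")
    record("stage1", start=rep1.start_count, end=rep1.end_count,
           files=[out / "stage1_ledger.tsv", out / "stage1.vcf"])

    # -- stage 2: pedigree-wide refined calls and screen ---------------
    units = ped.decompose_units(sequenced_only=True)
    refined, _ = refine.refine_panel(panel1, units, config.base_error)
    panel2, rep2 = qc.stage2_filter(
        refined, units, maf_min=config.stage2_maf,
        missing_max=config.stage2_missing,
        mendel_max_units=config.mendel_max_units, het_max=config.het_max)
    (out / "stage2_ledger.tsv").write_text(qc.report_render(rep2))
    panel2.to_vcf(out / "stage2.vcf")
    record("stage2", start=rep2.start_count, end=rep2.end_count,
           files=[out / "stage2_ledger.tsv", out / "stage2.vcf"])

    # -- stage 3: sample QC --------------------------------------------
    pruned_idx = relatedness.ld_prune_for_ibd(
        panel2, config.r2_ibd, config.ld_window, config.ld_shift)
    ibd = relatedness.estimate_ibd_all_pairs(panel2, pruned_idx)
    ibd.to_csv(out / "ibd_pairs.tsv", sep="\t", index=False,
               float_format="%.4f")
    flagged = ([] if config.skip_stage3_exclusions
               else relatedness.flag_sample_issues(ibd, ped))
    keep = [s for s in panel2.samples if s not in flagged]
    panel3 = panel2.subset_samples(keep) if flagged else panel2
    record("stage3", n_pruned_snps=int(len(pruned_idx)),
           excluded=sorted(flagged), n_samples=len(keep),
           files=[out / "ibd_pairs.tsv"])

    # -- stage 4: final screen and mapping panels ----------------------
    # excluded samples leave the cohort: units degrade (trio -> duo ->
    # singleton) rather than disappear, so their children keep family
    # context where one parent survives
    from .pedigree import Individual

    ped3 = Pedigree([
        Individual(i.iid, i.sex, i.birth_year, i.father, i.mother,
                   sequenced=i.sequenced and i.iid not in flagged)
        for i in ped.members.values()
    ])
    units3 = [u for u in ped3.decompose_units(sequenced_only=True)]
    refined4, _ = refine.refine_panel(panel3, units3, config.base_error)
    panel4, rep4 = qc.stage4_final_filter(
        refined4, units3, config.mendel_max_units, config.het_max,
        config.stage4_missing)
    (out / "stage4_ledger.tsv").write_text(qc.report_render(rep4))
    assoc, linkage = mapset.build_map_sets(
        panel4, config.r2_association, config.r2_linkage,
        config.ld_window, config.ld_shift)
    bad = set(mapset.pedigree_mendel_check(panel4, units3))
    assoc = np.array([i for i in assoc if i not in bad], dtype=int)
    linkage = np.array([i for i in linkage if i not in bad], dtype=int)
    for name, idx in (("association", assoc), ("linkage", linkage)):
        sub = panel4.subset_sites(idx)
        sub.sites.to_csv(out / f"{name}_sites.tsv", sep="\t", index=False)
        summary = mapset.summarize_panel(panel4, idx)
        summary.to_csv(out / f"{name}_summary.tsv", sep="\t", index=False,
                       float_format="%.4f")
    imap = mapset.interpolate_map(gmap, panel4.subset_sites(linkage).sites)
    imap.to_csv(out / "linkage_genetic_map.tsv", sep="\t", index=False,
                float_format="%.4f")
    record("stage4", start=rep4.start_count, end=rep4.end_count,
           association_snps=int(len(assoc)), linkage_snps=int(len(linkage)),
           files=[out / "stage4_ledger.tsv",
                  out / "association_sites.tsv", out / "association_summary.tsv",
                  out / "linkage_sites.tsv", out / "linkage_summary.tsv",
                  out / "linkage_genetic_map.tsv"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
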