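"""Filter cascades: planted-violation bookkeeping, boundaries, ledgers."""

import numpy as np
import pytest

from conftest import make_panel
from pedpanel import qc, simulate
from pedpanel.panel import MISSING
from pedpanel.pedigree import Individual, Pedigree
from pedpanel.qc import (
    FilterReport,
    FilterStep,
    report_parse,
    report_render,
    stage1_filter,
    stage2_filter,
    stage4_final_filter,
)


class TestLedger:
    def test_conservation_enforced(self):
        with pytest.raises(ValueError, match="conservation"):
            FilterReport("stage1", 100, [FilterStep("a", 10, 80)])

    def test_render_parse_roundtrip(self):
        rep = FilterReport("stage2", 1000, [
            FilterStep("drop some", 100, 900),
            FilterStep("drop more\twith tab-free name", 0, 900),
            FilterStep("final", 13, 887),
        ])
        again = report_parse(report_render(rep))
        assert again == rep

    def test_render_parse_roundtrip_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(st.lists(st.integers(min_value=0, max_value=1000),
                        min_size=0, max_size=8))
        def roundtrip(removals):
            start = sum(removals) + 17
            steps, remaining = [], start
            for k, r in enumerate(removals):
                remaining -= r
                steps.append(FilterStep(f"step {k}", r, remaining))
            rep = FilterReport("stage2", start, steps)
            assert report_parse(report_render(rep)) == rep

        roundtrip()

    def test_empty_cascade(self):
        rep = FilterReport("stage4", 42, [])
        text = report_render(rep)
        assert "TOTAL\t0" in text
        assert rep.end_count == 42


def hc_panel(gt_hc, gt_rest=None, **kw):
    """Panel whose first columns are the 'high coverage' samples."""
    gt_hc = np.asarray(gt_hc, dtype=np.int8)
    gt = gt_hc if gt_rest is None else np.hstack([gt_hc, gt_rest])
    dp = np.full(gt.shape, 30, dtype=np.int32)
    ad = np.where(gt > 0, 15, 0).astype(np.int32)
    return make_panel(gt, dp=dp, ad=ad, **kw)


class TestStage1:
    def test_maf_threshold_at_17_samples(self):
        # 17 diploid samples = 34 alleles; minor count 8 -> MAF .235 (drop),
        # minor count 9 -> MAF .2647 (keep)
        row8 = [1] * 8 + [0] * 9
        row9 = [1] * 9 + [0] * 8
        panel = hc_panel(np.array([row8, row9]))
        out, rep = stage1_filter(panel, panel.samples)
        steps = {s.name: s.removed for s in rep.steps}
        assert steps["MAF in 17 samples <25%"] == 1
        assert out.n_sites == 1

    def test_proximity_boundary(self):
        # pos 100/104 (distance 4) both removed; pos 200/206 (distance 6) kept
        gt = np.tile([0, 1, 1, 0], (4, 1)).astype(np.int8)
        panel = hc_panel(gt)
        panel.sites.loc[:, "pos"] = [100, 104, 200, 206]
        out, rep = stage1_filter(panel, panel.samples)
        assert list(out.sites["pos"]) == [200, 206]
        assert rep.steps[-1].removed == 2

    def test_planted_composition_bookkeeping(self):
        """Each filter removes exactly the sites planted to violate it."""
        n, m = 60, 17
        base = np.array(([0, 1, 2, 1] * 5)[:m], dtype=np.int8)  # MAF ~ .47
        gt = np.tile(base, (n, 1))
        dp = np.full((n, m), 30, dtype=np.int32)
        # plant: 4 low-MAF sites, 3 missing-call sites, 2 coverage outliers
        low_maf = [5, 15, 25, 35]
        for i in low_maf:
            gt[i] = 0
            gt[i, 0] = 1  # singleton het: MAF 1/34
        missing = [8, 18, 28]
        for i in missing:
            gt[i, 3] = MISSING
        outlier = [10, 40]
        dp[outlier[0]] = 200
        dp[outlier[1]] = 1
        ad = np.where(gt > 0, 15, 0).astype(np.int32)
        panel = make_panel(gt, dp=dp, ad=np.minimum(ad, dp), step=1000)
        decoyed = simulate.inject_decoys(panel, 5, 2, seed=62)
        out, rep = stage1_filter(decoyed, panel.samples)
        removed = {s.name: s.removed for s in rep.steps}
        assert removed["Multi-allelic or multi-nucleotide"] == 7
        assert removed[
            "Cumulative coverage outside of twofold range of global median coverage"
        ] == 2
        assert removed["MAF in 17 samples <25%"] == 4
        assert removed[">0 % missing data"] == 3
        assert rep.end_count == out.n_sites == 60 + 7 - 7 - 2 - 4 - 3 \
            - removed["Within 5 bp of another site"]

    def test_empty_hc_set_rejected(self):
        panel = hc_panel(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="non-empty"):
            stage1_filter(panel, [])


def family_units():
    ped = Pedigree([
        Individual("F", "M", 1980), Individual("M", "F", 1980),
        Individual("C1", "U", 1990, father="F", mother="M"),
        Individual("C2", "U", 1991, father="F", mother="M"),
    ])
    return [u for u in ped.decompose_units() if u.kind == "trio"]


class TestStage2:
    def test_het_fraction_boundary(self):
        # 10 samples: 6 het -> 0.6 retained; 7 het -> 0.7 removed
        gt6 = [1] * 6 + [0, 0, 2, 2]
        gt7 = [1] * 7 + [0, 0, 2]
        panel = make_panel(np.array([gt6, gt7]),
                          dp=np.full((2, 10), 10), ad=np.full((2, 10), 5))
        out, rep = stage2_filter(panel, [])
        removed = {s.name: s.removed for s in rep.steps}
        assert removed[">60% heterozygous calls"] == 1
        assert list(out.sites.index) == [0]

    def test_mendel_unit_boundary_at_five(self):
        # site 0: planted error in all 5 units (removed, >= 5);
        # site 1: error in 4 units (kept at this step)
        inds = [Individual("F", "M", 1980), Individual("M", "F", 1980)]
        inds += [Individual(f"C{k}", "U", 1990 + k, father="F", mother="M")
                 for k in range(5)]
        ped = Pedigree(inds)
        units = [u for u in ped.decompose_units() if u.kind == "trio"]
        samples = ["F", "M"] + [f"C{k}" for k in range(5)]
        gt = np.zeros((3, 7), dtype=np.int8)
        gt[0, 2:] = 2          # all five children impossible (hom_alt)
        gt[1, 2:6] = 2         # four children impossible
        gt[1, 6] = 0
        gt[2] = [0, 2, 1, 1, 1, 1, 1]  # clean site
        panel = make_panel(gt, dp=np.full((3, 7), 10),
                           ad=np.where(gt > 0, 5, 0), samples=samples)
        counts, _ = qc.mendel_unit_counts(panel, units)
        assert list(counts) == [5, 4, 0]
        out, rep = stage2_filter(panel, units)
        removed = {s.name: s.removed for s in rep.steps}
        assert removed[">=5 Mendel errors in parent-child comparisons"] == 1

    def test_sex_chromosome_exclusion(self):
        gt = np.tile([0, 1, 2, 1], (3, 1)).astype(np.int8)
        panel = make_panel(gt, chrom=["chr1", "chrX", "Y"],
                           dp=np.full((3, 4), 10), ad=np.where(gt > 0, 5, 0))
        out, rep = stage2_filter(panel, [])
        assert {s.name: s.removed for s in rep.steps}["Sex chromosome SNPs"] == 2
        assert list(out.sites["chrom"]) == ["chr1"]

    def test_missingness_boundary(self):
        gt = np.tile([0, 1, 2, 1, 0, 0, 1, 2, 1, 0], (2, 1)).astype(np.int8)
        gt[0, :5] = MISSING   # exactly 50 % missing: retained
        gt[1, :6] = MISSING   # 60 % missing: removed
        panel = make_panel(gt, dp=np.full((2, 10), 10), ad=np.full((2, 10), 5))
        out, rep = stage2_filter(panel, [])
        assert {s.name for s in rep.steps if s.removed} == {"Missing >50% of data"}
        assert out.n_sites == 1


class TestStage4:
    def test_masking_pushes_site_over_missing_ceiling(self):
        # 4 units with errors at site 0 (< 5, so not removed at step 1);
        # masking their 4 child calls makes missingness 4/20 = 20 % > 5 %
        inds = [Individual("F", "M", 1980), Individual("M", "F", 1980)]
        inds += [Individual(f"C{k}", "U", 1990 + k, father="F", mother="M")
                 for k in range(4)]
        extra = [Individual(f"X{k}", "M", 1980) for k in range(14)]
        ped = Pedigree(inds + extra)
        units = [u for u in ped.decompose_units() if u.kind == "trio"]
        samples = ["F", "M"] + [f"C{k}" for k in range(4)] + \
                  [f"X{k}" for k in range(14)]
        filler = np.array([0, 1, 2, 1, 0, 0, 1, 2, 1, 0, 0, 1, 2, 1],
                          dtype=np.int8)                 # het fraction < .6
        gt = np.zeros((2, 20), dtype=np.int8)
        gt[0] = np.concatenate([[0, 0, 2, 2, 2, 2], filler])
        gt[1] = np.concatenate([[0, 2, 1, 1, 1, 1], filler])  # clean site
        panel = make_panel(gt, dp=np.full((2, 20), 10),
                           ad=np.where(gt > 0, 5, 0), samples=samples)
        out, rep = stage4_final_filter(panel, units)
        removed = {s.name: s.removed for s in rep.steps}
        assert removed[">=5 Mendel errors between parents and offspring"] == 0
        assert removed["Missing rate >5%"] == 1
        assert out.n_sites == 1

    def test_clean_panel_untouched(self):
        units = family_units()
        gt = np.array([[0, 2, 1, 1], [1, 1, 0, 2]], dtype=np.int8)
        panel = make_panel(gt, dp=np.full((2, 4), 10),
                           ad=np.where(gt > 0, 5, 0),
                           samples=["F", "M", "C1", "C2"])
        out, rep = stage4_final_filter(panel, units)
        assert rep.total_removed == 0
        assert np.array_equal(out.gt, gt)

    def test_only_child_call_masked(self):
        units = family_units()
        gt = np.array([[0, 0, 1, 0]], dtype=np.int8)  # C1 impossible het
        panel = make_panel(gt, dp=np.full((1, 4), 10),
                           ad=np.where(gt > 0, 5, 0),
                           samples=["F", "M", "C1", "C2"])
        out, rep = stage4_final_filter(panel, units, missing_max=0.5)
        assert out.gt[0, 2] == MISSING
        assert out.gt[0, 0] == 0 and out.gt[0, 1] == 0 and out.gt[0, 3] == 0


class TestCascadeProperties:
    def test_idempotent(self, colony):
        ped, truth, reads, panel = colony
        hc = panel.samples[:6]
        once, rep1 = stage1_filter(panel, hc)
        twice, rep2 = stage1_filter(once, hc)
        assert rep2.end_count == rep1.end_count
        assert list(twice.sites["pos"]) == list(once.sites["pos"])

    def test_filter_order_not_commutative(self):
        # a missing-heavy site shields a neighbor from the proximity
        # filter when missingness runs first
        gt = np.array([[1, 1, 0, 0],      # clean site at pos 100
                       [MISSING, 1, 0, 1],  # missing site at pos 103
                       [0, 1, 1, 0]], dtype=np.int8)
        panel = make_panel(gt, dp=np.where(gt >= 0, 10, 0).astype(np.int32),
                           ad=np.where(gt > 0, 5, 0))
        panel.sites.loc[:, "pos"] = [100, 103, 5000]
        from pedpanel.qc import _proximity_mask

        # proximity first: both close sites die
        prox_first = set(panel.sites["pos"][~_proximity_mask(panel)])
        # missingness first: pos 103 dies, pos 100 then survives proximity
        clean = panel.subset_sites(panel.missing_rate() == 0)
        miss_first = set(clean.sites["pos"][~_proximity_mask(clean)])
        assert prox_first != miss_first
        assert 100 in miss_first and 100 not in prox_first
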