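"""Final panel construction: LD thinning, pedigree-wide Mendelian check,
genetic-map interpolation and per-chromosome panel summaries.

Two nested mapping sets are produced from the QC'd common-SNP panel: an
association set thinned at r² <= 0.9 and a linkage set obtained by
thinning the association set further at r² <= 0.4 (thinning the denser
set guarantees the linkage set is a subset of the association set).
Genetic positions are assigned to SNPs by piecewise-linear interpolation
between STR anchor markers of known physical and genetic position.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .ld import pairwise_r2, sliding_window_prune
from .panel import SitePanel
from .pedigree import Pedigree
from .qc import mendel_unit_counts

__all__ = [
    "ld_thin",
    "build_map_sets",
    "pedigree_mendel_check",
    "interpolate_map",
    "summarize_panel",
]


def ld_thin(
    panel: SitePanel,
    r2_max: float,
    window: int = 50,
    shift: int = 20,
) -> np.ndarray:
    """Retained site indices after sliding-window thinning at *r2_max*."""
    return sliding_window_prune(panel.dosage(), r2_max, window, shift)


def build_map_sets(
    panel: SitePanel,
    r2_association: float = 0.9,
    r2_linkage: float = 0.4,
    window: int = 50,
    shift: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """(association, linkage) retained index arrays, linkage ⊆ association."""
    assoc = ld_thin(panel, r2_association, window, shift)
    sub = panel.subset_sites(assoc)
    linkage_local = ld_thin(sub, r2_linkage, window, shift)
    return assoc, assoc[linkage_local]


def pedigree_mendel_check(
    panel: SitePanel,
    ped_or_units,
) -> np.ndarray:
    """Site indices with a Mendelian-impossible nuclear-family genotype
    configuration anywhere in the pedigree (level-1 check)."""
    if isinstance(ped_or_units, Pedigree):
        units = [u for u in ped_or_units.decompose_units(sequenced_only=True)
                 if u.kind != "singleton"]
    else:
        units = list(ped_or_units)
    counts, _ = mendel_unit_counts(panel, units)
    return np.flatnonzero(counts > 0)


def interpolate_map(anchors: pd.DataFrame, snps: pd.DataFrame) -> pd.DataFrame:
    """Genetic position (cM) for each SNP from STR anchor markers.

    Piecewise-linear bp→cM inside the anchor span; beyond the terminal
    anchors the terminal segment's slope is extended, floored at 0 cM.
    Output is monotone non-decreasing per chromosome and reproduces the
    anchors exactly.  ``snps`` needs columns chrom and pos.
    """
    out = np.full(len(snps), np.nan)
    chrom_col = snps["chrom"].to_numpy()
    pos_col = snps["pos"].to_numpy(dtype=float)
    for chrom in pd.unique(chrom_col):
        a = anchors[anchors["chrom"] == chrom].sort_values("pos_bp")
        if len(a) < 2:
            raise ValueError(
                f"chromosome {chrom!r} has {len(a)} genetic-map anchors; "
                "need at least 2"
            )
        bp = a["pos_bp"].to_numpy(dtype=float)
        cm = a["pos_cM"].to_numpy(dtype=float)
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"chromosome {chrom!r}: anchor cM not monotone")
        sel = chrom_col == chrom
        x = pos_col[sel]
        y = np.interp(x, bp, cm)
        # extend terminal slopes outside the anchor span
        left = x < bp[0]
        if left.any() and bp[1] > bp[0]:
            slope = (cm[1] - cm[0]) / (bp[1] - bp[0])
            y[left] = cm[0] + slope * (x[left] - bp[0])
        right = x > bp[-1]
        if right.any() and bp[-1] > bp[-2]:
            slope = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
            y[right] = cm[-1] + slope * (x[right] - bp[-1])
        y = np.maximum(y, 0.0)
        order = np.argsort(x, kind="stable")
        y[order] = np.maximum.accumulate(y[order])
        out[sel] = y
    return pd.DataFrame({"chrom": chrom_col, "pos_bp": snps["pos"].to_numpy(),
                         "pos_cM": out})


def summarize_panel(
    panel: SitePanel,
    retained: Optional[np.ndarray] = None,
    r2_window: int = 5,
) -> pd.DataFrame:
    """Per-chromosome summary of a (thinned) panel.

    Columns: n_snps, snps_per_mb (count over the retained span), max and
    mean gap between consecutive SNPs in bp, mean pairwise r² within
    consecutive windows of ``r2_window`` markers, mean heterozygosity.
    Chromosomes with a single SNP report NaN gaps.
    """
    sub = panel if retained is None else panel.subset_sites(retained)
    rows = []
    for chrom, grp in sub.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        n = len(idx)
        span_mb = (pos[-1] - pos[0]) / 1e6 if n > 1 else np.nan
        gaps = np.diff(pos) if n > 1 else np.array([])
        het = sub.het_fraction()[idx]
        het = het[~np.isnan(het)]
        r2_vals = []
        dos = sub.dosage()[idx]
        for start in range(0, n - 1, r2_window):
            block = dos[start:start + r2_window]
            if block.shape[0] >= 2:
                r2 = pairwise_r2(block)
                iu = np.triu_indices(block.shape[0], k=1)
                r2_vals.extend(r2[iu])
        rows.append({
            "chrom": chrom,
            "n_snps": n,
            "snps_per_mb": n / span_mb if span_mb and span_mb > 0 else np.nan,
            "max_gap_bp": float(gaps.max()) if gaps.size else np.nan,
            "mean_gap_bp": float(gaps.mean()) if gaps.size else np.nan,
            "mean_r2_5win": float(np.mean(r2_vals)) if r2_vals else np.nan,
            "mean_heterozygosity": float(het.mean()) if het.size else np.nan,
        })
    return pd.DataFrame(rows)
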