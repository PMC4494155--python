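"""SitePanel: ordered biallelic sites with per-sample reads and genotypes.

Genotypes are coded 0 (hom ref), 1 (het), 2 (hom alt), -1 (missing).
Read evidence is carried as total depth ``dp`` and alt-supporting reads
``ad_alt`` per sample per site.  The container is deliberately thin: a
pandas site table plus numpy matrices, with VCF import/export (GT, AD,
DP) for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class SitePanel:
    sites: pd.DataFrame            # columns chrom, pos, ref, alt
    samples: list[str]
    gt: np.ndarray                 # (n_sites, n_samples) int8
    dp: Optional[np.ndarray] = None  # (n_sites, n_samples) int32
    ad: Optional[np.ndarray] = None  # alt-read counts, (n_sites, n_samples)

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        n, m = len(self.sites), len(self.samples)
        if self.gt.shape != (n, m):
            raise ValueError(f"gt shape {self.gt.shape} != ({n}, {m})")
        for name in ("dp", "ad"):
            a = getattr(self, name)
            if a is not None and a.shape != (n, m):
                raise ValueError(f"{name} shape {a.shape} != ({n}, {m})")
        if self.ad is not None and self.dp is not None and np.any(self.ad > self.dp):
            raise ValueError("alt read count exceeds depth")

    # -- shape ---------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in panel") from None

    def subset_sites(self, index) -> "SitePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SitePanel(
            sites=self.sites.iloc[index],
            samples=list(self.samples),
            gt=self.gt[index],
            dp=None if self.dp is None else self.dp[index],
            ad=None if self.ad is None else self.ad[index],
        )

    def subset_samples(self, ids: Sequence[str]) -> "SitePanel":
        idx = self.sample_index(ids)
        return SitePanel(
            sites=self.sites,
            samples=list(ids),
            gt=self.gt[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
            ad=None if self.ad is None else self.ad[:, idx],
        )

    def copy(self) -> "SitePanel":
        return SitePanel(self.sites.copy(), list(self.samples), self.gt.copy(),
                         None if self.dp is None else self.dp.copy(),
                         None if self.ad is None else self.ad.copy())

    # -- per-site statistics -------------------------------------------

    def is_biallelic_snv(self) -> np.ndarray:
        ref = self.sites["ref"].str
        alt = self.sites["alt"].str
        return ((ref.len() == 1) & (alt.len() == 1)).to_numpy()

    def alt_frequency(self, sample_ids: Optional[Sequence[str]] = None) -> np.ndarray:
        """Alt allele frequency from called genotypes (missing excluded)."""
        gt = self.gt if sample_ids is None else self.gt[:, self.sample_index(sample_ids)]
        called = gt >= 0
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, gt, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def maf(self, sample_ids: Optional[Sequence[str]] = None) -> np.ndarray:
        f = self.alt_frequency(sample_ids)
        return np.minimum(f, 1.0 - f)

    def missing_rate(self, sample_ids: Optional[Sequence[str]] = None) -> np.ndarray:
        gt = self.gt if sample_ids is None else self.gt[:, self.sample_index(sample_ids)]
        if gt.shape[1] == 0:
            return np.zeros(gt.shape[0])
        return (gt < 0).mean(axis=1)

    def het_fraction(self) -> np.ndarray:
        """Fraction of heterozygous calls among non-missing calls."""
        called = self.gt >= 0
        n = called.sum(axis=1)
        het = (self.gt == 1).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, het / np.maximum(n, 1), np.nan)

    def cumulative_depth(self) -> np.ndarray:
        if self.dp is None:
            raise ValueError("panel carries no depth information")
        return self.dp.sum(axis=1)

    def dosage(self, impute_mean: bool = False) -> np.ndarray:
        """Genotype dosages (0/1/2) as float, missing as NaN (or site mean)."""
        d = self.gt.astype(float)
        d[self.gt < 0] = np.nan
        if impute_mean:
            mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=1)
            idx = np.where(np.isnan(d))
            d[idx] = np.take(np.nan_to_num(mean), idx[0])
        return d

    # -- VCF interoperability ------------------------------------------

    def to_vcf(self, path, phased: Optional[np.ndarray] = None) -> None:
        """Write as VCF 4.2 with GT, AD, DP.

        ``phased``: optional (n_sites, n_samples, 2) int8 haplotype array;
        where all alleles at a site/sample are >= 0 the genotype is
        written phased ('|').
        """
        chroms = self.sites["chrom"].astype(str)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic depths (ref,alt)">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            for c in dict.fromkeys(chroms):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for i in range(self.n_sites):
                row = self.sites.iloc[i]
                fields = [str(row["chrom"]), str(int(row["pos"])), ".",
                          row["ref"], row["alt"], ".", "PASS", ".", "GT:AD:DP"]
                cells = []
                for j in range(self.n_samples):
                    g = int(self.gt[i, j])
                    if phased is not None and phased[i, j, 0] >= 0 and phased[i, j, 1] >= 0:
                        gs = f"{phased[i, j, 0]}|{phased[i, j, 1]}"
                    else:
                        gs = gt_str.get(g, "./.")
                    dp = int(self.dp[i, j]) if self.dp is not None else 0
                    ad = int(self.ad[i, j]) if self.ad is not None else 0
                    cells.append(f"{gs}:{dp - ad},{ad}:{dp}")
                fh.write("\t".join(fields) + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_vcf(cls, path) -> "SitePanel":
        """Load a VCF (GT required; AD/DP used when present) via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        rows, gts, dps, ads = [], [], [], []
        for v in vcf:
            alt = ",".join(v.ALT) if v.ALT else "."
            rows.append((v.CHROM, v.POS, v.REF, alt))
            g = v.gt_types.astype(np.int8)  # 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
            g[g == 3] = MISSING
            gts.append(g)
            try:
                dp = v.format("DP")
                dps.append(dp[:, 0].astype(np.int32))
            except Exception:
                dps.append(np.zeros(len(samples), dtype=np.int32))
            try:
                ad = v.format("AD")
                ads.append(ad[:, 1].astype(np.int32).clip(min=0))
            except Exception:
                ads.append(np.zeros(len(samples), dtype=np.int32))
        sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
        return cls(sites, samples,
                   np.array(gts, dtype=np.int8).reshape(len(rows), len(samples)),
                   np.array(dps, dtype=np.int32).reshape(len(rows), len(samples)),
                   np.array(ads, dtype=np.int32).reshape(len(rows), len(samples)))
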