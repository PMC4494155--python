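"""Sliding-window LD pruning on genotype dosages.

r-squared is the squared Pearson correlation of genotype dosages
(composite LD) over pairwise-complete observations; monomorphic sites
have undefined correlation and are excluded from the comparison (their
r-squared is treated as 0, so they are never pruned for LD).

The pruning scheme is the classic SNP-count window: within each window
of ``window`` consecutive surviving SNPs, keep the earliest SNP of any
violating pair (a SNP is dropped when its r-squared with an
already-kept earlier SNP in the window exceeds the threshold); slide by
``shift`` SNPs; repeat full passes until a pass removes nothing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pairwise_r2", "sliding_window_prune", "find_window_violations"]


def pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """All-pairs r² for a (n_snps, n_samples) dosage block with NaNs.

    Pairwise-complete correlation; undefined entries (monomorphic or no
    overlap) are 0.
    """
    d = np.ma.masked_invalid(np.asarray(dosage, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.ma.corrcoef(d)
    r2 = np.asarray(np.ma.filled(corr, 0.0)) ** 2
    np.fill_diagonal(r2, 0.0)
    return r2


def sliding_window_prune(
    dosage: np.ndarray,
    r2_max: float,
    window: int = 50,
    shift: int = 20,
) -> np.ndarray:
    """Indices (into the input row order) of the retained SNPs."""
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2 threshold must be in (0, 1]")
    if window < 2 or shift < 1:
        raise ValueError("window must be >= 2 and shift >= 1")
    dosage = np.asarray(dosage, dtype=float)
    alive = np.arange(dosage.shape[0])
    while True:
        removed_any = False
        start = 0
        while start < len(alive):
            idx = alive[start:start + window]
            if len(idx) >= 2:
                r2 = pairwise_r2(dosage[idx])
                keep = np.ones(len(idx), dtype=bool)
                for j in range(1, len(idx)):
                    if np.any(r2[j, :j][keep[:j]] > r2_max):
                        keep[j] = False
                if not keep.all():
                    removed_any = True
                    drop = set(idx[~keep])
                    alive = np.array([a for a in alive if a not in drop])
            start += shift
        if not removed_any:
            return alive


def find_window_violations(
    dosage: np.ndarray,
    retained: np.ndarray,
    r2_max: float,
    window: int = 50,
    shift: int = 20,
) -> list[tuple[int, int, float]]:
    """Exhaustive post-check: violating pairs within any pruning window."""
    retained = np.asarray(retained)
    out = []
    start = 0
    while start < len(retained):
        idx = retained[start:start + window]
        if len(idx) >= 2:
            r2 = pairwise_r2(dosage[idx])
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    if r2[a, b] > r2_max:
                        out.append((int(idx[a]), int(idx[b]), float(r2[a, b])))
        start += shift
    return out
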