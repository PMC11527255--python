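"""Single-cell copy-number ratio profiles from genomic bin counts.

Low-pass single-cell whole-genome sequencing yields read counts per fixed
genomic bin.  After GC correction, counts are normalized to a genome mean
of 1 ("ratio space"), in which a whole-genome doubling (WGD) is invisible:
a cell that doubles its entire genome keeps the same ratio profile, so
clonal identity can be compared between diploid-range and polyploid cells.
This module implements GC correction, ratio conversion, recursive binary
segmentation of the ratio track, and profile comparison/clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "BinCounts",
    "RatioProfile",
    "gc_correct",
    "to_ratio",
    "segment_profile",
    "compare_profiles",
    "cluster_profiles",
    "read_bins_bed",
    "write_segments",
]

#: floor applied to ratios before log2, avoiding -inf on empty bins
LOG_RATIO_FLOOR = 1e-3


@dataclass
class BinCounts:
    """Shared bin definitions plus per-cell integer count vectors.

    ``bins`` is a DataFrame with columns ``chrom``, ``start``, ``end``,
    ``gc`` (0-based half-open coordinates, sorted, non-overlapping within
    each chromosome).  ``counts`` has shape (n_cells, n_bins).
    """

    bins: pd.DataFrame
    counts: np.ndarray
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        required = {"chrom", "start", "end", "gc"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"bins table missing columns: {sorted(missing)}")
        if self.counts.shape[1] != len(self.bins):
            raise ValueError(
                f"counts have {self.counts.shape[1]} bins, table has {len(self.bins)}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative bin counts")
        for _, grp in self.bins.groupby("chrom", sort=False):
            s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
            if (e <= s).any():
                raise ValueError("bins must be 0-based half-open with end > start")
            if (s[1:] < e[:-1]).any():
                raise ValueError("bins overlap or are unsorted within a chromosome")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.counts.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class RatioProfile:
    """GC-corrected, mean-normalized copy-number ratios for one cell.

    ``ratios`` average exactly 1 over the genome; a ratio of 1 marks a bin
    copy-number neutral relative to the genome mean.  After segmentation,
    ``segment_ids`` labels each bin and ``segment_means`` holds the mean
    ratio of each segment's member bins.
    """

    bins: pd.DataFrame
    ratios: np.ndarray
    cell_id: str = "cell"
    segment_ids: np.ndarray | None = None
    segment_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if len(self.ratios) != len(self.bins):
            raise ValueError("ratio vector and bin table length mismatch")

    @property
    def is_segmented(self) -> bool:
        return self.segment_ids is not None

    def segments_frame(self) -> pd.DataFrame:
        """Per-segment table: chrom, start, end, n_bins, seg_ratio."""
        if not self.is_segmented:
            raise ValueError("profile is not segmented")
        rows = []
        for seg in np.unique(self.segment_ids):
            idx = np.flatnonzero(self.segment_ids == seg)
            sub = self.bins.iloc[idx]
            rows.append(
                {
                    "chrom": sub["chrom"].iloc[0],
                    "start": int(sub["start"].iloc[0]),
                    "end": int(sub["end"].iloc[-1]),
                    "n_bins": len(idx),
                    "seg_ratio": float(self.segment_means[seg]),
                }
            )
        return pd.DataFrame(rows)


def gc_correct(bc: BinCounts, min_bins: int = 100) -> np.ndarray:
    """Remove the GC-content bias from bin counts.

    Fits, per cell, a quadratic least-squares trend of log counts against
    GC fraction and rescales each bin by ``global_median / trend(gc)`` so
    the corrected counts are flat in GC.  Returns a float array shaped
    like ``bc.counts``; corrected counts are non-negative.

    With fewer than ``min_bins`` bins or a degenerate (constant) GC
    vector the counts are returned unchanged with a warning.
    """
    counts = bc.counts.astype(float)
    gc = bc.bins["gc"].to_numpy(dtype=float)
    if bc.n_bins < min_bins:
        raise ValueError(f"need at least {min_bins} bins for GC correction, got {bc.n_bins}")
    if np.ptp(gc) < 1e-12:
        warnings.warn("degenerate GC vector (all equal); returning counts unchanged")
        return counts
    X = np.column_stack([np.ones_like(gc), gc, gc**2])
    corrected = np.empty_like(counts)
    for i in range(bc.n_cells):
        c = counts[i]
        logc = np.log(c + 0.5)
        beta, *_ = np.linalg.lstsq(X, logc, rcond=None)
        trend = np.exp(X @ beta)
        med = np.median(c)
        corrected[i] = c * (med / trend)
    return np.maximum(corrected, 0.0)


def to_ratio(bc_or_counts, bins: pd.DataFrame | None = None, cell_id: str = "cell") -> RatioProfile:
    """Convert one cell's corrected counts to a mean-1 ratio profile.

    ``ratio_i = corrected_i / mean(corrected)``, so the genome-wide mean is
    exactly 1 and the profile is invariant under global scaling of the
    counts — the property that makes ratio profiles blind to WGD.
    """
    if isinstance(bc_or_counts, BinCounts):
        if bc_or_counts.n_cells != 1:
            raise ValueError("to_ratio takes a single cell; index BinCounts.counts")
        counts = bc_or_counts.counts[0].astype(float)
        bins = bc_or_counts.bins
        cell_id = bc_or_counts.cell_ids[0]
    else:
        counts = np.asarray(bc_or_counts, dtype=float)
        if bins is None:
            raise ValueError("bins table required when passing a raw count vector")
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"cell {cell_id!r} has zero total count (fails QC)")
    ratios = counts / counts.mean()
    return RatioProfile(bins=bins, ratios=ratios, cell_id=cell_id)


def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Boundary maximizing the pooled two-sample t statistic on ``x``.

    Returns (split index k meaning x[:k] | x[k:], |t|); (-1, 0) if no
    admissible split. Vectorized over all boundaries via cumulative sums.
    """
    n = len(x)
    if n < 2 * min_bins:
        return -1, 0.0
    ks = np.arange(min_bins, n - min_bins + 1)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = csum[ks - 1]
    s2 = csum[-1] - s1
    m1, m2 = s1 / n1, s2 / n2
    ss1 = csq[ks - 1] - n1 * m1**2
    ss2 = (csq[-1] - csq[ks - 1]) - n2 * m2**2
    pooled = (ss1 + ss2) / np.maximum(n - 2, 1)
    se = np.sqrt(np.maximum(pooled, 1e-12) * (1 / n1 + 1 / n2))
    t = np.abs(m1 - m2) / se
    j = int(np.argmax(t))
    return int(ks[j]), float(t[j])


def segment_profile(rp: RatioProfile, penalty: float = 5.0, min_bins: int = 10) -> RatioProfile:
    """Segment a ratio profile by recursive binary splitting.

    Works per chromosome on log2 ratios (floored at ``LOG_RATIO_FLOOR``):
    the boundary maximizing the pooled two-sample t statistic is accepted
    when the statistic exceeds ``penalty`` and both sides keep at least
    ``min_bins`` bins, then each side is segmented recursively.  Segments
    never cross chromosome boundaries.  Segment means are means of the
    member bins' (untransformed) ratios.
    """
    logr = np.log2(np.maximum(rp.ratios, LOG_RATIO_FLOOR))
    seg_ids = np.full(len(rp.ratios), -1, dtype=int)
    next_id = 0

    def recurse(lo: int, hi: int) -> None:
        nonlocal next_id
        k, t = _best_split(logr[lo:hi], min_bins)
        if k >= 0 and t > penalty:
            recurse(lo, lo + k)
            recurse(lo + k, hi)
        else:
            seg_ids[lo:hi] = next_id
            next_id += 1

    chrom = rp.bins["chrom"].to_numpy()
    boundaries = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(chrom)]])
    for lo, hi in zip(starts, ends):
        recurse(int(lo), int(hi))

    means = np.array([rp.ratios[seg_ids == s].mean() for s in range(next_id)])
    return replace(rp, segment_ids=seg_ids, segment_means=means)


def compare_profiles(a: RatioProfile, b: RatioProfile) -> dict:
    """Similarity of two ratio profiles on a shared bin set.

    Returns ``{"r": Pearson correlation of bin ratios,
    "max_segment_diff": max |segment-mean difference| (None unless both
    profiles are segmented)}``.  Because ratio profiles are scale
    invariant, cells of one clone correlate highly regardless of WGD.
    """
    if len(a.ratios) != len(b.ratios) or not a.bins[["chrom", "start", "end"]].equals(
        b.bins[["chrom", "start", "end"]]
    ):
        raise ValueError("profiles must share the same bin set")
    r = float(np.corrcoef(a.ratios, b.ratios)[0, 1])
    max_diff = None
    if a.is_segmented and b.is_segmented:
        pa = a.segment_means[a.segment_ids]
        pb = b.segment_means[b.segment_ids]
        max_diff = float(np.max(np.abs(pa - pb)))
    return {"r": r, "max_segment_diff": max_diff}


def cluster_profiles(profiles: list[RatioProfile], n_clusters: int | None = None):
    """Hierarchically cluster profiles with distance 1 - Pearson r.

    Average linkage on the condensed ``1 - r`` distance matrix.  Returns
    ``(linkage_matrix, labels)``; ``labels`` is None unless ``n_clusters``
    is given, in which case flat clusters are cut from the tree.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    mat = np.vstack([p.ratios for p in profiles])
    corr = np.corrcoef(mat)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = None
    if n_clusters is not None:
        labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    return link, labels


def read_bins_bed(path) -> pd.DataFrame:
    """Read a BED-like TSV of bins: chrom, start, end, gc (no header)."""
    bins = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gc"])
    return bins


def write_segments(rp: RatioProfile, path) -> None:
    rp.segments_frame().to_csv(path, sep="\t", index=False)
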