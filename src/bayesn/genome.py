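"""Genotype/haplotype data model, window partitioning and panel summaries.

The genome coordinate backbone is a :class:`MarkerMap` (per-SNP chromosome
and physical bp position, 0-based). Non-overlapping fixed-width windows —
the unit of BayesN's outer variable selection — are half-open intervals
``[k*W, (k+1)*W)`` within each chromosome; windows that contain no SNP are
dropped, so the window count ``w`` counts only SNP-bearing windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkerMap",
    "HaplotypePanel",
    "GenotypeMatrix",
    "WindowPartition",
    "PanelSummary",
    "build_window_partition",
    "build_md_panel",
    "mask_qtl_from_panel",
    "allele_stats",
    "center_genotypes",
]


@dataclass
class MarkerMap:
    """Per-SNP identifiers and physical genome coordinates.

    Positions are 0-based bp; markers must be sorted by (chrom, pos_bp)
    with strictly increasing positions within each chromosome.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if not (len(self.snp_id) == len(self.chrom) == len(self.pos_bp)):
            raise ValueError("snp_id, chrom and pos_bp must have equal length")
        if np.any(self.pos_bp < 0):
            raise ValueError("positions must be non-negative")
        if len(self) > 1:
            dc = np.diff(self.chrom)
            if np.any(dc < 0):
                raise ValueError("chromosomes must be in ascending order")
            dp = np.diff(self.pos_bp)
            if np.any((dc == 0) & (dp <= 0)):
                raise ValueError(
                    "positions must be strictly increasing within a chromosome"
                )

    def __len__(self) -> int:
        return len(self.pos_bp)

    @property
    def n_snps(self) -> int:
        return len(self)

    def chrom_slices(self) -> list[tuple[int, slice]]:
        """(chromosome, slice-of-markers) pairs in map order."""
        out = []
        if len(self) == 0:
            return out
        chroms, starts = np.unique(self.chrom, return_index=True)
        bounds = list(starts) + [len(self)]
        for c, a, b in zip(chroms, bounds[:-1], bounds[1:]):
            out.append((int(c), slice(int(a), int(b))))
        return out

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx, dtype=np.int64)
        return MarkerMap(self.snp_id[idx], self.chrom[idx], self.pos_bp[idx])


@dataclass
class HaplotypePanel:
    """Phased binary alleles, rows 2i and 2i+1 are the gametes of individual i."""

    alleles: np.ndarray
    map: MarkerMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (gametes x loci)")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("gamete count must be even (two per individual)")
        if self.alleles.shape[1] != len(self.map):
            raise ValueError("column count must equal map length")
        bad = (self.alleles != 0) & (self.alleles != 1)
        if bad.any():
            raise ValueError("allele values must be 0/1")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate (coded-1) allele frequency per SNP over gametes."""
        return self.alleles.mean(axis=0)

    def genotypes(self) -> "GenotypeMatrix":
        """Collapse gamete pairs into 0/1/2 genotype scores."""
        g = self.alleles[0::2].astype(np.float64) + self.alleles[1::2]
        return GenotypeMatrix(scores=g, map=self.map)

    def subset_loci(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx, dtype=np.int64)
        return HaplotypePanel(self.alleles[:, idx], self.map.subset(idx))


@dataclass
class GenotypeMatrix:
    """n x m SNP genotype scores, {0,1,2} raw or real-valued once centered."""

    scores: np.ndarray
    map: MarkerMap | None = None
    centered: bool = False
    column_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D (individuals x loci)")
        if self.map is not None and self.scores.shape[1] != len(self.map):
            raise ValueError("column count must equal map length")
        if self.centered:
            n = self.scores.shape[0]
            if np.any(np.abs(self.scores.sum(axis=0)) > 1e-8 * max(n, 1)):
                raise ValueError("centered matrix must have zero column sums")

    @property
    def n_individuals(self) -> int:
        return self.scores.shape[0]

    @property
    def n_snps(self) -> int:
        return self.scores.shape[1]

    def subset_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.int64)
        return GenotypeMatrix(
            self.scores[:, idx],
            self.map.subset(idx) if self.map is not None else None,
            centered=self.centered,
            column_means=None if self.column_means is None else self.column_means[idx],
        )


@dataclass
class WindowPartition:
    """Assignment of every SNP to one non-overlapping fixed-width window.

    ``window_of_snp[j]`` indexes the SNP-bearing windows, numbered 0..w-1
    in genome order; windows never span chromosomes.
    """

    window_size_bp: int
    window_of_snp: np.ndarray
    w: int
    m_i: np.ndarray
    window_chrom: np.ndarray = field(default=None)
    window_start_bp: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.window_of_snp = np.asarray(self.window_of_snp, dtype=np.int64)
        self.m_i = np.asarray(self.m_i, dtype=np.int64)
        if self.m_i.sum() != len(self.window_of_snp):
            raise ValueError("sum of m_i must equal the SNP count")
        if len(self.m_i) != self.w:
            raise ValueError("m_i must have one entry per window")

    @property
    def n_snps(self) -> int:
        return len(self.window_of_snp)

    def snp_ranges(self) -> np.ndarray:
        """CSR-style offsets: window i holds SNPs offsets[i]:offsets[i+1]."""
        return np.concatenate([[0], np.cumsum(self.m_i)]).astype(np.int64)


@dataclass
class PanelSummary:
    """Per-SNP MAF, pairwise r² within a distance cutoff, and mean p*q."""

    maf: np.ndarray
    pair_index: np.ndarray  # (n_pairs, 2) SNP indices
    pair_dist_bp: np.ndarray
    pair_r2: np.ndarray  # NaN where a locus is monomorphic
    pq_bar: float

    @property
    def adjacent_r2(self) -> np.ndarray:
        """r² of physically adjacent pairs (those one index apart)."""
        adj = (self.pair_index[:, 1] - self.pair_index[:, 0]) == 1
        return self.pair_r2[adj]


def build_window_partition(map: MarkerMap, window_size_bp: int) -> WindowPartition:
    """Assign every SNP to the half-open window floor(pos/W) on its chromosome.

    Windows with no SNPs are dropped; ``w`` counts SNP-bearing windows only.
    """
    if window_size_bp <= 0:
        raise ValueError("window_size_bp must be positive")
    if len(map) == 0:
        raise ValueError("empty marker map")
    raw_bin = map.pos_bp // window_size_bp
    # unique (chrom, bin) in map order = genome order
    key = np.stack([map.chrom, raw_bin], axis=1)
    change = np.ones(len(map), dtype=bool)
    change[1:] = np.any(key[1:] != key[:-1], axis=1)
    window_of_snp = np.cumsum(change) - 1
    w = int(window_of_snp[-1]) + 1
    m_i = np.bincount(window_of_snp, minlength=w)
    starts = np.flatnonzero(change)
    return WindowPartition(
        window_size_bp=int(window_size_bp),
        window_of_snp=window_of_snp,
        w=w,
        m_i=m_i,
        window_chrom=map.chrom[starts],
        window_start_bp=raw_bin[starts] * window_size_bp,
    )


def build_md_panel(map: MarkerMap, stride: int) -> np.ndarray:
    """Every ``stride``-th SNP, restarting the count at each chromosome."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if len(map) == 0:
        raise ValueError("empty marker map")
    keep = []
    for _, sl in map.chrom_slices():
        keep.append(np.arange(sl.start, sl.stop, stride, dtype=np.int64))
    return np.concatenate(keep)


def mask_qtl_from_panel(panel: np.ndarray, qtl: np.ndarray) -> np.ndarray:
    """Remove QTL indices from a marker panel, preserving order."""
    panel = np.asarray(panel, dtype=np.int64)
    qtl = np.asarray(qtl, dtype=np.int64)
    return panel[~np.isin(panel, qtl)]


def _r2_from_haplotypes(a: np.ndarray, b: np.ndarray) -> float:
    """Standard LD r² = D²/(pA qA pB qB) from gamete allele columns."""
    pa = a.mean()
    pb = b.mean()
    va = pa * (1.0 - pa)
    vb = pb * (1.0 - pb)
    if va <= 0.0 or vb <= 0.0:
        return np.nan
    d = (a * b).mean() - pa * pb
    return float(d * d / (va * vb))


def allele_stats(
    panel: HaplotypePanel | GenotypeMatrix, max_dist_bp: int
) -> PanelSummary:
    """MAF, pairwise r² within ``max_dist_bp`` on the same chromosome, pq_bar.

    For haplotype input r² is the gametic D²/(pA qA pB qB); for (unphased)
    genotype input the squared Pearson correlation of scores is used as the
    composite-LD analogue. Pairs involving a monomorphic locus get NaN;
    monomorphic loci are excluded from pq_bar.
    """
    if isinstance(panel, HaplotypePanel):
        if panel.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        data = panel.alleles.astype(np.float64)
        freq = data.mean(axis=0)
        mp = panel.map
        phased = True
    else:
        if panel.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if panel.map is None:
            raise ValueError("genotype matrix needs a marker map for distances")
        if panel.centered:
            data = panel.scores + panel.column_means
        else:
            data = panel.scores
        freq = data.mean(axis=0) / 2.0
        mp = panel.map
        phased = False

    maf = np.minimum(freq, 1.0 - freq)
    poly = (freq > 0.0) & (freq < 1.0)
    pq = freq * (1.0 - freq)
    pq_bar = float(pq[poly].mean()) if poly.any() else np.nan

    idx_a, idx_b, dists, r2s = [], [], [], []
    for _, sl in mp.chrom_slices():
        pos = mp.pos_bp[sl]
        for u in range(sl.start, sl.stop):
            for v in range(u + 1, sl.stop):
                d = pos[v - sl.start] - pos[u - sl.start]
                if d > max_dist_bp:
                    break
                if phased:
                    r2 = _r2_from_haplotypes(data[:, u], data[:, v])
                else:
                    su = data[:, u]
                    sv = data[:, v]
                    if su.std() <= 0 or sv.std() <= 0:
                        r2 = np.nan
                    else:
                        r2 = float(np.corrcoef(su, sv)[0, 1] ** 2)
                idx_a.append(u)
                idx_b.append(v)
                dists.append(d)
                r2s.append(r2)
    pair_index = (
        np.array([idx_a, idx_b], dtype=np.int64).T
        if idx_a
        else np.empty((0, 2), dtype=np.int64)
    )
    return PanelSummary(
        maf=maf,
        pair_index=pair_index,
        pair_dist_bp=np.asarray(dists, dtype=np.int64),
        pair_r2=np.asarray(r2s, dtype=np.float64),
        pq_bar=pq_bar,
    )


def center_genotypes(Z: GenotypeMatrix) -> GenotypeMatrix:
    """Subtract column means so Z'1 = 0; means retained for back-transform."""
    if Z.centered:
        warnings.warn("genotype matrix already centered; returning as-is")
        return Z
    means = Z.scores.mean(axis=0)
    return GenotypeMatrix(
        scores=Z.scores - means, map=Z.map, centered=True, column_means=means
    )
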