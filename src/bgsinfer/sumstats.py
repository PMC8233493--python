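"""Site-frequency spectra, diversity and LD statistics, SNP thinning.

All estimators are the standard ones: pi is mean pairwise diversity,
Watterson's theta is S / a_{n-1}, Tajima's D and the normalized Fay & Wu
H use their published variance normalizations, and LD statistics (r^2,
D, D') are averaged over SNP pairs within a window. The 22-element
summary vector used by the ABC method is the mean and between-window
variance of eleven per-window statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .masks import MaskSet
from .samples import HaplotypeSample

__all__ = [
    "SFS",
    "WindowStats",
    "STAT_FIELDS",
    "compute_sfs",
    "thin_snps",
    "scale_zero_class",
    "window_stats",
    "abc_stat_vector",
    "nucleotide_diversity",
]


@dataclass
class SFS:
    """Site frequency spectrum with an explicit monomorphic (zero) class.

    ``counts[b]`` is the number of sites with b derived copies among
    ``n_hap`` sampled haplotypes; ``counts[0]`` is the monomorphic class
    (unmasked length minus segregating sites). When ``folded``, classes
    above n_hap/2 are empty and counts[b] tallies minor-allele counts.
    """

    counts: np.ndarray
    n_hap: int
    folded: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.n_hap + 1,):
            raise ValueError("counts must have n_hap + 1 classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.folded and np.any(self.counts[self.n_hap // 2 + 1 :] != 0):
            raise ValueError("folded SFS has classes above n/2")

    @property
    def total_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def n_segregating(self) -> int:
        return int(self.counts[1:].sum())

    def polymorphic(self) -> np.ndarray:
        """Counts for derived classes 1..n_hap-1 (unfolded) or 1..n/2."""
        return self.counts[1:] if not self.folded else self.counts[1 : self.n_hap // 2 + 1]

    def fold(self) -> "SFS":
        if self.folded:
            return self
        n = self.n_hap
        c = self.counts.copy()
        out = np.zeros_like(c)
        out[0] = c[0] + c[n]
        for b in range(1, n // 2 + 1):
            out[b] = c[b] + (c[n - b] if b != n - b else 0)
        return SFS(counts=out, n_hap=n, folded=True)


def compute_sfs(
    sample: HaplotypeSample, mask: MaskSet | None = None, fold: bool = False
) -> SFS:
    """Tally derived-allele counts over unmasked positions, all chromosomes pooled.

    The monomorphic class is the unmasked genome length minus the number
    of segregating (unmasked) sites.
    """
    keep = np.ones(sample.n_sites, dtype=bool)
    masked_bp = 0
    if mask is not None:
        for c in range(len(sample.chrom_lengths)):
            sel = sample.chrom == c
            keep[sel] = ~mask.is_masked(c, sample.positions[sel])
            masked_bp += min(mask.masked_bp(c), sample.chrom_lengths[c])
    unmasked_len = sample.total_length - masked_bp
    if unmasked_len <= 0:
        raise ValueError("mask covers the whole genome; empty SFS")
    counts = sample.derived_counts()[keep]
    n = sample.n_hap
    sfs = np.zeros(n + 1, dtype=np.int64)
    np.add.at(sfs, counts, 1)
    sfs[0] = unmasked_len - counts.size
    out = SFS(counts=sfs, n_hap=n, folded=False)
    return out.fold() if fold else out


def thin_snps(positions: np.ndarray, min_gap: float) -> np.ndarray:
    """Greedy left-to-right thinning: kept SNPs are >= min_gap apart.

    The first SNP is always kept; each subsequent SNP is kept iff its
    distance to the last kept SNP is at least ``min_gap``. Returns kept
    indices. Apply per chromosome. Idempotent.
    """
    positions = np.asarray(positions)
    if positions.size == 0:
        return np.empty(0, dtype=np.int64)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    kept = [0]
    last = positions[0]
    for i in range(1, positions.size):
        if positions[i] - last >= min_gap:
            kept.append(i)
            last = positions[i]
    return np.asarray(kept, dtype=np.int64)


def thin_sample(sample: HaplotypeSample, min_gap: float) -> tuple[HaplotypeSample, float]:
    """Thin per chromosome; returns (thinned sample, kept fraction)."""
    keep_idx = []
    for c in range(len(sample.chrom_lengths)):
        idx = np.flatnonzero(sample.chrom == c)
        if idx.size:
            keep_idx.append(idx[thin_snps(sample.positions[idx], min_gap)])
    keep = np.concatenate(keep_idx) if keep_idx else np.empty(0, np.int64)
    keep.sort()
    frac = keep.size / max(sample.n_sites, 1)
    return sample.subset_sites(keep), frac


def scale_zero_class(sfs: SFS, kept_fraction: float) -> SFS:
    """Scale the monomorphic class by the SNP-thinning survival fraction.

    After thinning to 1 SNP per X kb, the zero class is scaled down by the
    same factor as the decrease in the total SNP count, keeping the SFS
    internally consistent for likelihood fitting.
    """
    if not (0 < kept_fraction <= 1):
        raise ValueError("kept_fraction must lie in (0, 1]")
    c = sfs.counts.copy()
    c[0] = int(round(c[0] * kept_fraction))
    return SFS(counts=c, n_hap=sfs.n_hap, folded=sfs.folded)


# ---------------------------------------------------------------------------
# Per-window statistics
# ---------------------------------------------------------------------------

#: The eleven per-window statistics, in the fixed order used everywhere.
STAT_FIELDS = (
    "pi",
    "theta_w",
    "tajima_d",
    "fay_wu_h",
    "fay_wu_h_norm",
    "n_singletons",
    "hap_diversity",
    "mean_r2",
    "mean_d",
    "mean_dprime",
    "divergence",
)


@dataclass
class WindowStats:
    """Statistics for one genomic window (nan = undefined for this window)."""

    chrom: int
    start: int
    end: int
    n_snps: int
    pi: float
    theta_w: float
    tajima_d: float
    fay_wu_h: float
    fay_wu_h_norm: float
    n_singletons: float
    hap_diversity: float
    mean_r2: float
    mean_d: float
    mean_dprime: float
    divergence: float


def _harmonics(n: int) -> tuple[float, float]:
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    return a1, a2


def nucleotide_diversity(counts: np.ndarray, n: int) -> float:
    """Sum over sites of 2*b*(n-b)/(n*(n-1)) — total, not per site."""
    b = counts.astype(float)
    return float(np.sum(2.0 * b * (n - b) / (n * (n - 1.0))))


def _tajima_d(S: int, pi: float, n: int) -> float:
    if S == 0:
        return math.nan
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi - S / a1) / math.sqrt(var)


def _fay_wu(counts: np.ndarray, n: int, pi: float) -> tuple[float, float]:
    """(absolute H = pi - theta_H, normalized H) per Zeng et al.'s variance."""
    S = counts.size
    if S == 0:
        return math.nan, math.nan
    b = counts.astype(float)
    theta_h = float(np.sum(2.0 * b * b / (n * (n - 1.0))))
    theta_l = float(np.sum(b / (n - 1.0)))
    h_abs = pi - theta_h
    a1, a2 = _harmonics(n)
    bn1 = a2 + 1.0 / (n * n)  # sum_{i=1}^{n} 1/i^2
    theta_w = S / a1
    theta_sq = S * (S - 1.0) / (a1**2 + a2)
    var = (
        theta_w * (n - 2.0) / (6.0 * (n - 1.0))
        + theta_sq
        * (
            18.0 * n * n * (3.0 * n + 2.0) * bn1
            - (88.0 * n**3 + 9.0 * n * n - 13.0 * n + 6.0)
        )
        / (9.0 * n * (n - 1.0) ** 2)
    )
    if var <= 0:
        return h_abs, math.nan
    return h_abs, (pi - theta_l) / math.sqrt(var)


def _haplotype_diversity(H: np.ndarray) -> float:
    n = H.shape[0]
    _, counts = np.unique(H, axis=0, return_counts=True)
    p = counts / n
    return float((1.0 - np.sum(p * p)) * n / (n - 1.0))


def _ld_stats(
    H: np.ndarray, pair_cap: int = 5000, rng: np.random.Generator | None = None
) -> tuple[float, float, float]:
    """Mean r^2, D, D' over SNP pairs (seeded subsample above pair_cap)."""
    n, S = H.shape
    if S < 2:
        return math.nan, math.nan, math.nan
    iu, ju = np.triu_indices(S, k=1)
    if iu.size > pair_cap:
        rng = rng or np.random.default_rng(0)
        pick = rng.choice(iu.size, size=pair_cap, replace=False)
        iu, ju = iu[pick], ju[pick]
    X = H.astype(float)
    p = X.mean(axis=0)
    pab = np.einsum("ni,ni->i", X[:, iu], X[:, ju]) / n
    D = pab - p[iu] * p[ju]
    va = p * (1.0 - p)
    r2 = D * D / (va[iu] * va[ju])
    dmax = np.where(
        D >= 0,
        np.minimum(p[iu] * (1 - p[ju]), (1 - p[iu]) * p[ju]),
        np.minimum(p[iu] * p[ju], (1 - p[iu]) * (1 - p[ju])),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        dprime = np.abs(D) / dmax
    return float(r2.mean()), float(D.mean()), float(np.nanmean(dprime))


def window_stats(
    sample: HaplotypeSample,
    windows: list[tuple[int, int, int]],
    pair_cap: int = 5000,
    ld_seed: int = 0,
) -> list[WindowStats]:
    """Compute the eleven per-window statistics for (chrom, start, end) windows.

    pi and Watterson's theta are per site; divergence is fixations per
    site per generation after the burn-in (nan when the sample carries no
    post-burn-in generation span); LD means are over within-window SNP
    pairs, capped at ``pair_cap`` pairs with seeded subsampling.
    """
    n = sample.n_hap
    if n < 4:
        raise ValueError("window statistics need at least 4 haplotypes")
    rng = np.random.default_rng(ld_seed)
    gens = sample.generation
    out = []
    for chrom, start, end in windows:
        if end <= start:
            raise ValueError("empty window")
        length = end - start
        sel = (sample.chrom == chrom) & (sample.positions >= start) & (
            sample.positions < end
        )
        H = sample.haplotypes[:, sel]
        counts = H.sum(axis=0).astype(np.int64)
        S = counts.size
        pi_tot = nucleotide_diversity(counts, n)
        a1, _ = _harmonics(n)
        h_abs, h_norm = _fay_wu(counts, n, pi_tot)
        n_fix = sum(
            1 for f in sample.fixations
            if f.chrom == chrom and start <= f.position < end and f.generation > 0
        )
        div = n_fix / (length * gens) if gens > 0 else math.nan
        r2, d, dp = _ld_stats(H, pair_cap=pair_cap, rng=rng)
        out.append(
            WindowStats(
                chrom=chrom,
                start=start,
                end=end,
                n_snps=S,
                pi=pi_tot / length,
                theta_w=S / a1 / length,
                tajima_d=_tajima_d(S, pi_tot, n),
                fay_wu_h=h_abs,
                fay_wu_h_norm=h_norm,
                n_singletons=float(np.sum(counts == 1)),
                hap_diversity=_haplotype_diversity(H) if S else 0.0,
                mean_r2=r2,
                mean_d=d,
                mean_dprime=dp,
                divergence=div,
            )
        )
    return out


def mean_r2_between_chromosomes(
    sample: HaplotypeSample, max_pairs: int = 20_000, seed: int = 0
) -> tuple[float, int]:
    """Mean r^2 over SNP pairs drawn from different chromosomes.

    With free recombination between chromosomes this estimates the
    unlinked-SNP LD baseline (E[r^2] ~ 1/n_hap for a neutral equilibrium
    sample, no frequency filtering). Returns (mean, number of pairs).
    """
    S = sample.n_sites
    if S < 2:
        raise ValueError("need at least two SNPs")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, S, size=2 * max_pairs)
    j = rng.integers(0, S, size=2 * max_pairs)
    keep = sample.chrom[i] != sample.chrom[j]
    i, j = i[keep][:max_pairs], j[keep][:max_pairs]
    if i.size == 0:
        raise ValueError("no cross-chromosome SNP pairs available")
    X = sample.haplotypes.astype(float)
    n = sample.n_hap
    p = X.mean(axis=0)
    pab = np.einsum("ni,ni->i", X[:, i], X[:, j]) / n
    D = pab - p[i] * p[j]
    va = p * (1 - p)
    r2 = D * D / (va[i] * va[j])
    return float(r2.mean()), int(i.size)


def abc_stat_vector(per_window: list[WindowStats]) -> np.ndarray:
    """The 22-element summary vector: means then variances of the 11 stats.

    Order: mean(pi), mean(theta_w), ..., mean(divergence), then the
    between-window variances in the same statistic order. Windows where a
    statistic is undefined (nan) are excluded from that statistic's mean
    and variance; at least two defined windows are required.
    """
    if len(per_window) < 2:
        raise ValueError("need at least two windows for between-window variances")
    means, variances = [], []
    for f in STAT_FIELDS:
        v = np.array([getattr(w, f) for w in per_window], dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            means.append(0.0)
            variances.append(0.0)
        else:
            means.append(float(v.mean()))
            variances.append(float(v.var(ddof=1)))
    return np.array(means + variances)
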