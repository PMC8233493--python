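"""The haplotype-sample container shared by both simulation engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypeSample", "concat_samples"]


@dataclass
class Fixation:
    """A derived allele fixed after the burn-in (used for divergence)."""

    chrom: int
    position: int
    generation: int
    s: float = 0.0


@dataclass
class HaplotypeSample:
    """A haplotype-by-variant 0/1 matrix with positions and metadata.

    ``haplotypes`` has shape (n_hap, n_sites) with 1 = derived allele; only
    polymorphic columns are stored (derived count in [1, n_hap-1]);
    monomorphic sites are implied by ``chrom_lengths``. ``chrom`` maps each
    column to a chromosome index, and positions are 0-based bp, strictly
    increasing within a chromosome.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    chrom: np.ndarray
    chrom_lengths: tuple[int, ...]
    n_diploids: int
    generation: int = 0
    burnin_generations: int = 0
    fixations: list[Fixation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (n_hap, n_sites)")
        n_hap, n_sites = self.haplotypes.shape
        if n_hap != 2 * self.n_diploids:
            raise ValueError("row count must equal 2 * n_diploids")
        if self.positions.shape != (n_sites,) or self.chrom.shape != (n_sites,):
            raise ValueError("positions/chrom must have one entry per site")
        counts = self.haplotypes.sum(axis=0)
        if n_sites and (counts.min() < 1 or counts.max() > n_hap - 1):
            raise ValueError("every stored column must be polymorphic in the sample")
        for c in range(len(self.chrom_lengths)):
            p = self.positions[self.chrom == c]
            if p.size and np.any(np.diff(p) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def derived_counts(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int64)

    def subset_sites(self, index: np.ndarray) -> "HaplotypeSample":
        return HaplotypeSample(
            haplotypes=self.haplotypes[:, index],
            positions=self.positions[index],
            chrom=self.chrom[index],
            chrom_lengths=self.chrom_lengths,
            n_diploids=self.n_diploids,
            generation=self.generation,
            burnin_generations=self.burnin_generations,
            fixations=self.fixations,
        )


def concat_samples(samples: list[HaplotypeSample]) -> HaplotypeSample:
    """Stack samples of the same individuals as successive chromosomes."""
    if not samples:
        raise ValueError("no samples to concatenate")
    n_hap = samples[0].n_hap
    if any(s.n_hap != n_hap for s in samples):
        raise ValueError("all samples must have the same haplotype count")
    chrom_lengths: list[int] = []
    chrom_parts, fixations = [], []
    offset = 0
    for s in samples:
        chrom_parts.append(s.chrom + offset)
        for f in s.fixations:
            fixations.append(
                Fixation(f.chrom + offset, f.position, f.generation, f.s)
            )
        chrom_lengths.extend(s.chrom_lengths)
        offset += len(s.chrom_lengths)
    return HaplotypeSample(
        haplotypes=np.concatenate([s.haplotypes for s in samples], axis=1),
        positions=np.concatenate([s.positions for s in samples]),
        chrom=np.concatenate(chrom_parts),
        chrom_lengths=tuple(chrom_lengths),
        n_diploids=samples[0].n_diploids,
        generation=samples[0].generation,
        burnin_generations=samples[0].burnin_generations,
        fixations=fixations,
    )
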