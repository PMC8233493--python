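"""Neutral coalescent engine (msprime) for calibration experiments.

Used for all purely neutral computations — segregating-site calibrations,
expected-SFS cross-checks, unlinked-LD baselines — where a forward
simulation would be needlessly slow. The forward engine is authoritative
whenever selection is present.
"""

from __future__ import annotations

import numpy as np

from .genomes import Demography
from .samples import HaplotypeSample, concat_samples

__all__ = [
    "run_neutral_coalescent",
    "segregating_sites_replicates",
    "sfs_counts_replicates",
    "unlinked_loci_sample",
]

_DEFAULT_CHUNK = 100_000_000


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(n)]


def _simulate_chunk(demography: Demography, L: float, n_hap: int, mu: float,
                    rec: float, seed: int):
    import msprime

    if n_hap % 2:
        raise ValueError("n_hap must be even (phased diploids)")
    s1, s2 = _child_seeds(seed, 2)
    ts = msprime.sim_ancestry(
        samples=n_hap // 2,
        demography=demography.to_msprime(),
        sequence_length=L,
        recombination_rate=rec,
        random_seed=s1,
    )
    return msprime.sim_mutations(ts, rate=mu, random_seed=s2, model="binary")


def run_neutral_coalescent(
    demography: Demography,
    L: float,
    n_hap: int,
    mu: float,
    rec: float,
    seed: int,
    chunk_bp: float = _DEFAULT_CHUNK,
) -> HaplotypeSample:
    """Sample haplotypes from the neutral coalescent with recombination.

    Regions longer than ``chunk_bp`` are simulated as independent chunks
    (returned as successive chromosomes), which bounds the ancestral
    recombination graph size for Gb-scale regions.
    """
    if n_hap < 2:
        raise ValueError("need at least two haplotypes")
    if mu < 0 or rec < 0:
        raise ValueError("rates must be non-negative")
    n_chunks = max(1, int(np.ceil(L / chunk_bp)))
    sizes = [L / n_chunks] * n_chunks
    seeds = _child_seeds(seed, n_chunks)
    parts = []
    for sz, sd in zip(sizes, seeds):
        ts = _simulate_chunk(demography, sz, n_hap, mu, rec, sd)
        gm = ts.genotype_matrix()  # (S, n_hap)
        derived = (gm != 0)
        counts = derived.sum(axis=1)
        keep = (counts > 0) & (counts < n_hap)
        hap = derived[keep].T.astype(np.uint8)
        pos = np.array([ts.site(i).position for i in np.flatnonzero(keep)],
                       dtype=np.int64) if keep.any() else np.empty(0, np.int64)
        parts.append(
            HaplotypeSample(
                haplotypes=hap,
                positions=pos,
                chrom=np.zeros(hap.shape[1], dtype=np.int32),
                chrom_lengths=(int(sz),),
                n_diploids=n_hap // 2,
            )
        )
    return parts[0] if len(parts) == 1 else concat_samples(parts)


def segregating_sites_replicates(
    demography: Demography,
    L: float,
    n_hap: int,
    mu: float,
    rec: float,
    n_reps: int,
    seed: int,
    chunk_bp: float = _DEFAULT_CHUNK,
) -> np.ndarray:
    """Per-replicate segregating-site counts (fast path; no genotype matrix)."""
    rep_seeds = _child_seeds(seed, n_reps)
    n_chunks = max(1, int(np.ceil(L / chunk_bp)))
    out = np.zeros(n_reps, dtype=np.int64)
    for i, sd in enumerate(rep_seeds):
        total = 0
        for csd in _child_seeds(sd, n_chunks):
            ts = _simulate_chunk(demography, L / n_chunks, n_hap, mu, rec, csd)
            afs = ts.allele_frequency_spectrum(
                polarised=True, span_normalise=False
            )
            total += int(afs[1:n_hap].sum())
        out[i] = total
    return out


def sfs_counts_replicates(
    demography: Demography,
    L: float,
    n_hap: int,
    mu: float,
    rec: float,
    n_reps: int,
    seed: int,
) -> np.ndarray:
    """(n_reps, n_hap-1) derived-allele SFS counts per replicate."""
    rep_seeds = _child_seeds(seed, n_reps)
    out = np.zeros((n_reps, n_hap - 1), dtype=np.int64)
    for i, sd in enumerate(rep_seeds):
        ts = _simulate_chunk(demography, L, n_hap, mu, rec, sd)
        afs = ts.allele_frequency_spectrum(polarised=True, span_normalise=False)
        out[i] = afs[1:n_hap].astype(np.int64)
    return out


def unlinked_loci_sample(
    demography: Demography,
    n_loci: int,
    locus_bp: float,
    n_hap: int,
    mu: float,
    seed: int,
) -> HaplotypeSample:
    """Many freely recombining loci for the same sample (for unlinked-LD baselines).

    Each locus has an independent genealogy (free recombination between
    loci, none within), mimicking completely unlinked SNPs.
    """
    seeds = _child_seeds(seed, n_loci)
    parts = [
        run_neutral_coalescent(demography, locus_bp, n_hap, mu, 0.0, sd)
        for sd in seeds
    ]
    return concat_samples(parts)
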