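"""Forward Wright-Fisher simulation with purifying selection.

Diploid, randomly mating population with multiplicative fitness across
sites and semidominance within sites (genotype fitnesses 1, 1-s/2, 1-s).
Mutations arise per base pair at rate mu; mutations landing in exonic
(selected) regions draw a selection coefficient from the discrete DFE,
all other mutations are neutral. The simulation runs a burn-in of
10*Nanc generations at the ancestral size, then plays the demographic
epochs forward in time; fixations after the burn-in are recorded for
divergence estimates.

The mutation model is finite-sites with at most one segregating mutation
per site at a time: a new mutation proposed at a currently segregating
site is rejected and redrawn. Once an allele fixes or is lost the site
becomes available again; back mutation is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import (
    Demography,
    DiscreteDFE,
    GenomeLayout,
    SimParams,
    rescale,
    sample_selection_coefficients,
)
from .ratemaps import RateMaps
from .samples import Fixation, HaplotypeSample

__all__ = ["Locus", "run_forward", "loci_from_layout"]


@dataclass(frozen=True)
class Locus:
    """One independently assorting stretch of sequence.

    ``selected`` marks which bp draw selection coefficients from the DFE:
    True/False for the whole locus, or a per-bp boolean array. ``rec`` is
    the per-bp crossover rate within the locus; loci assort freely.
    """

    length: int
    rec: float
    selected: bool | np.ndarray = False

    def selected_mask(self) -> np.ndarray:
        if isinstance(self.selected, np.ndarray):
            if self.selected.shape != (self.length,):
                raise ValueError("selected mask must have one entry per bp")
            return self.selected.astype(bool)
        return np.full(self.length, bool(self.selected))


def loci_from_layout(layout: GenomeLayout, rec: float) -> list[Locus]:
    """A single locus spanning the layout, selected at exonic positions."""
    return [Locus(length=layout.chrom_length, rec=rec, selected=layout.exon_mask())]


def _forward_sizes(demography: Demography) -> np.ndarray:
    """Diploid size at each post-burn-in generation, oldest first."""
    span = int(round(demography.change_time))
    if span == 0:
        return np.empty(0, dtype=np.int64)
    t_ago = span - 1 - np.arange(span)  # size during each forward generation
    return np.array(
        [max(2, int(round(demography.size_at(t)))) for t in t_ago], dtype=np.int64
    )


class _Population:
    """Mutable simulation state: haplotypes x sorted segregating sites."""

    def __init__(self, n_diploids: int, rng: np.random.Generator):
        self.G = np.empty((2 * n_diploids, 0), dtype=np.uint8)
        self.pos = np.empty(0, dtype=np.int64)  # global (concatenated-loci) coords
        self.s = np.empty(0, dtype=np.float64)
        self.rng = rng

    @property
    def n_hap(self) -> int:
        return self.G.shape[0]


def run_forward(
    loci: list[Locus] | GenomeLayout,
    dfe: DiscreteDFE | None,
    demography: Demography,
    mu: float,
    rec: float | None = None,
    *,
    Q: float = 1.0,
    n_sample: int,
    seed: int,
    sample_times: list[int] | None = None,
    burnin_factor: float = 10.0,
    rate_maps: RateMaps | None = None,
) -> HaplotypeSample | list[HaplotypeSample]:
    """Run the forward simulation and sample diploids without replacement.

    Parameters are given on the natural scale and rescaled internally by
    ``Q`` (sizes and times divided, rates and selection coefficients
    multiplied, leaving 4*N*mu, 4*N*r, 2*N*s invariant). ``sample_times``
    are generations after the end of the burn-in at which to draw samples
    (default: only at the present, i.e. after all epochs have elapsed);
    with several times a list of samples is returned.

    If ``rate_maps`` is given (single-locus case only), crossover and
    mutation positions follow the step maps instead of uniform rates.
    """
    if isinstance(loci, GenomeLayout):
        if rec is None:
            raise ValueError("rec is required when passing a GenomeLayout")
        loci = loci_from_layout(loci, rec)
    if not loci:
        raise ValueError("need at least one locus")
    if mu < 0:
        raise ValueError("mu must be non-negative")

    scaled = rescale(SimParams(demography=demography, mu=mu, rec=0.0), Q)
    dem = scaled.demography
    mu_s = scaled.mu
    Nanc = max(2, int(round(dem.Nanc)))
    if dfe is not None:
        # bins are in 2*Nanc*s, which Q leaves invariant: re-anchor to the
        # scaled ancestral size so drawn s values are already on the Q scale
        dfe = dfe.with_nanc(Nanc)

    # per-locus geometry in a concatenated global coordinate system
    lengths = np.array([lc.length for lc in loci], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    L_total = int(offsets[-1])
    sel_lookup = np.concatenate([lc.selected_mask() for lc in loci])
    if sel_lookup.any() and dfe is None:
        raise ValueError("selected sites present but no DFE given")
    rec_rates = np.array([lc.rec * Q for lc in loci], dtype=float)
    xover_mean = rec_rates * np.maximum(lengths - 1, 0)
    if rate_maps is not None:
        if len(loci) != 1:
            raise ValueError("rate_maps supported only for a single locus")
        rmap = rate_maps.recombination
        mmap = rate_maps.mutation
        xover_mean = np.array([rmap.total_mass * Q])
        mu_total = mmap.total_mass * Q
    else:
        rmap = mmap = None
        mu_total = mu_s * L_total

    rng = np.random.default_rng(seed)
    burn_gens = int(round(burnin_factor * Nanc))
    sizes_fwd = _forward_sizes(dem)
    span = sizes_fwd.size
    if sample_times is None:
        times = [span]
    else:
        times = sorted(set(int(t) for t in sample_times))
        if any(t < 0 or t > span for t in times):
            raise ValueError(f"sample_times must lie in [0, {span}]")
    single = sample_times is None

    pop = _Population(Nanc, rng)
    fixations: list[Fixation] = []
    samples: list[HaplotypeSample] = []

    def locus_of(global_pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(offsets, global_pos, side="right") - 1

    def take_sample(gen: int) -> HaplotypeSample:
        n_dip = pop.n_hap // 2
        if n_sample > n_dip:
            raise ValueError(f"cannot sample {n_sample} diploids from {n_dip}")
        chosen = rng.choice(n_dip, size=n_sample, replace=False)
        rows = np.sort(np.concatenate([2 * chosen, 2 * chosen + 1]))
        H = pop.G[rows]
        cnt = H.sum(axis=0, dtype=np.int64)
        keep = (cnt > 0) & (cnt < rows.size)
        H = H[:, keep]
        gpos = pop.pos[keep]
        loc = locus_of(gpos)
        return HaplotypeSample(
            haplotypes=H,
            positions=gpos - offsets[loc],
            chrom=loc.astype(np.int32),
            chrom_lengths=tuple(int(x) for x in lengths),
            n_diploids=n_sample,
            generation=gen,
            burnin_generations=burn_gens,
            fixations=list(fixations),
        )

    if rmap is None:
        # compiled kernel path (uniform per-locus rates)
        from ._wf_kernel import wf_span

        if dfe is not None:
            dfe_cdf = np.cumsum(dfe.f)
            bounds = np.array(dfe.bin_bounds)
            bin_lo, bin_hi = bounds[:, 0].copy(), bounds[:, 1].copy()
            neutral0 = bool(dfe.strictly_neutral_class0)
        else:
            dfe_cdf = np.array([1.0, 1.0, 1.0, 1.0])
            bin_lo = np.zeros(4)
            bin_hi = np.ones(4)
            neutral0 = True
        inv_two_nanc = 1.0 / (2.0 * Nanc)

        all_sizes = np.concatenate(
            [np.full(burn_gens, Nanc, dtype=np.int64), sizes_fwd]
        )
        labels_start = -burn_gens + 1  # forward generations are labeled 1..span
        # segment boundaries at each requested sampling time
        bounds_g = [0] + [burn_gens + t for t in times]
        fix_cap = int(10 * mu_total * (span + 1)) + 500
        fix_pos = np.empty(fix_cap, dtype=np.int64)
        fix_gen = np.empty(fix_cap, dtype=np.int64)
        fix_s = np.empty(fix_cap)
        prev = 0
        for b_end, t_label in zip(bounds_g[1:], times):
            seg_sizes = all_sizes[prev:b_end]
            if seg_sizes.size:
                ks = int(rng.integers(1, 2**31 - 1))
                G2, pos2, s2, n_fix = wf_span(
                    pop.G, pop.pos, pop.s, seg_sizes,
                    offsets.astype(np.int64), xover_mean.astype(np.float64),
                    sel_lookup, float(mu_total), np.int64(L_total),
                    dfe_cdf, bin_lo, bin_hi, float(inv_two_nanc), neutral0,
                    np.int64(0), np.int64(labels_start + prev),
                    fix_pos, fix_gen, fix_s, ks,
                )
                pop.G, pop.pos, pop.s = G2, pos2, s2
                for i in range(n_fix):
                    l = int(locus_of(fix_pos[i : i + 1])[0])
                    fixations.append(
                        Fixation(l, int(fix_pos[i] - offsets[l]),
                                 int(fix_gen[i]), float(fix_s[i]))
                    )
            samples.append(take_sample(t_label))
            prev = b_end
        return samples[0] if single else samples

    def step(N_next: int, record_fix: bool, gen_label: int) -> None:
        G, pos, s_arr = pop.G, pop.pos, pop.s
        n_par = G.shape[0] // 2
        # --- fitness and parent sampling -------------------------------
        sel = np.flatnonzero(s_arr > 0)
        if sel.size:
            if sel.size == s_arr.size:
                A = G[0::2] + G[1::2]
            else:
                A = G[0::2][:, sel] + G[1::2][:, sel]
            sv = s_arr[sel]
            c_het = np.log1p(-0.5 * sv)
            c_hom = np.log1p(-sv)
            Af = A.astype(np.float64)
            logw = Af @ c_het + (A == 2) @ (c_hom - 2.0 * c_het)
            logw -= logw.max()
            w = np.exp(logw)
            cum = np.cumsum(w)
            parents = np.searchsorted(cum, rng.random(2 * N_next) * cum[-1])
            np.minimum(parents, n_par - 1, out=parents)
        else:
            parents = rng.integers(0, n_par, size=2 * N_next)
        n_g = 2 * N_next

        # --- gamete formation: free assortment between loci ------------
        S = pos.size
        n_loci = len(loci)
        phase = rng.integers(0, 2, size=(n_g, n_loci), dtype=np.int64)
        col_hi = np.searchsorted(pos, offsets[1:], side="left")
        if S:
            if n_loci == 1:
                child = G[2 * parents + phase[:, 0]]
            else:
                child = np.empty((n_g, S), dtype=np.uint8)
                col_lo = np.concatenate([[0], col_hi[:-1]])
                for l in range(n_loci):
                    a, b = col_lo[l], col_hi[l]
                    if b > a:
                        np.take(G[:, a:b], 2 * parents + phase[:, l], axis=0,
                                out=child[:, a:b])
            # within-locus crossovers: each crossover XOR-flips the suffix
            # of its locus between the two parental haplotypes, so cuts can
            # be applied independently in any order
            total_rate = float(xover_mean.sum())
            n_xo = rng.poisson(n_g * total_rate) if total_rate > 0 else 0
            if n_xo:
                gam = rng.integers(0, n_g, size=n_xo)
                if rmap is not None:
                    cuts = rmap.sample_positions(n_xo, rng)
                    loc = np.zeros(n_xo, dtype=np.int64)
                else:
                    loc = rng.choice(len(loci), size=n_xo, p=xover_mean / total_rate)
                    lo_bp = offsets[loc] + 1
                    hi_bp = offsets[loc + 1]
                    cuts = lo_bp + (rng.random(n_xo) * (hi_bp - lo_bp)).astype(np.int64)
                ci = np.searchsorted(pos, cuts)
                for g, l, a in zip(gam, loc, ci):
                    b = col_hi[l]
                    if b > a:
                        p2 = 2 * parents[g]
                        child[g, a:b] = G[p2, a:b] + G[p2 + 1, a:b] - child[g, a:b]
        else:
            child = np.empty((n_g, 0), dtype=np.uint8)

        # --- new mutations ---------------------------------------------
        n_mut = rng.poisson(n_g * mu_total)
        if n_mut:
            newpos = np.empty(0, dtype=np.int64)
            need = n_mut
            while need:
                if mmap is not None:
                    cand = mmap.sample_positions(need, rng)
                else:
                    cand = rng.integers(0, L_total, size=need)
                # reject candidates at currently segregating sites (pos sorted)
                if pos.size:
                    j = np.searchsorted(pos, cand)
                    occupied = (j < pos.size) & (pos[np.minimum(j, pos.size - 1)] == cand)
                    cand = cand[~occupied]
                cand = np.unique(cand)
                if newpos.size:
                    k = np.searchsorted(newpos, cand)
                    dup = (k < newpos.size) & (newpos[np.minimum(k, newpos.size - 1)] == cand)
                    cand = cand[~dup]
                newpos = np.sort(np.concatenate([newpos, cand[:need]]))
                need = n_mut - newpos.size
            carriers = rng.integers(0, n_g, size=n_mut)
            new_s = np.zeros(n_mut)
            in_exon = sel_lookup[newpos]
            if in_exon.any():
                _, svals = sample_selection_coefficients(dfe, int(in_exon.sum()), rng)
                new_s[in_exon] = svals
            # single-pass sorted insertion of the new columns
            ins = np.searchsorted(pos, newpos)
            new_idx = ins + np.arange(n_mut)
            S2 = S + n_mut
            old_mask = np.ones(S2, dtype=bool)
            old_mask[new_idx] = False
            child2 = np.zeros((n_g, S2), dtype=np.uint8)
            child2[:, old_mask] = child
            child2[carriers, new_idx] = 1
            pos2 = np.empty(S2, dtype=np.int64)
            pos2[old_mask], pos2[new_idx] = pos, newpos
            s2 = np.empty(S2)
            s2[old_mask], s2[new_idx] = s_arr, new_s
            child, pos, s_arr = child2, pos2, s2

        # --- loss / fixation -------------------------------------------
        cnt = child.sum(axis=0, dtype=np.int64)
        fixed = cnt == n_g
        if record_fix and fixed.any():
            for j in np.flatnonzero(fixed):
                l = int(locus_of(pos[j : j + 1])[0])
                fixations.append(
                    Fixation(l, int(pos[j] - offsets[l]), gen_label, float(s_arr[j]))
                )
        keep = (cnt > 0) & ~fixed
        pop.G = np.ascontiguousarray(child[:, keep])
        pop.pos = pos[keep]
        pop.s = s_arr[keep]

    # --- main loop (rate-map path) --------------------------------------
    for _ in range(burn_gens):
        step(Nanc, record_fix=False, gen_label=0)
    t = 0
    pending = list(times)
    while pending and pending[0] == t:
        samples.append(take_sample(t))
        pending.pop(0)
    for g in range(span):
        step(int(sizes_fwd[g]), record_fix=True, gen_label=g + 1)
        t = g + 1
        while pending and pending[0] == t:
            samples.append(take_sample(t))
            pending.pop(0)

    return samples[0] if single else samples
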