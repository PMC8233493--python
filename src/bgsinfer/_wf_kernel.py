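"""Compiled inner loop of the forward Wright-Fisher engine.

One generation = fitness evaluation, parent sampling, gamete formation
with free assortment between loci and Poisson crossovers within them,
finite-sites mutation (occupied sites rejected), and loss/fixation
bookkeeping. The matrix of haplotypes is rebuilt once per generation in a
single pass that simultaneously drops lost/fixed columns and inserts new
mutations at their position-sorted slots.

Only uniform per-locus rates are handled here; heterogeneous rate maps
take the (slower) numpy path in :mod:`bgsinfer.forward`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["wf_span"]


@njit(cache=True, fastmath=False)
def _searchsorted_right(a, v):
    lo, hi = 0, a.size
    while lo < hi:
        mid = (lo + hi) // 2
        if v < a[mid]:
            hi = mid
        else:
            lo = mid + 1
    return lo


@njit(cache=True)
def wf_span(
    G,            # (2*N_cur, S) uint8 haplotype matrix, columns position-sorted
    pos,          # (S,) int64 global bp positions
    sarr,         # (S,) float64 selection coefficients (0 = neutral)
    sizes,        # (n_gen,) int64 diploid size of each offspring generation
    offsets,      # (n_loci+1,) int64 locus bp offsets in global coordinates
    xover_mean,   # (n_loci,) float64 expected crossovers per gamete per locus
    sel_lookup,   # (L_total,) bool: does this bp draw s from the DFE
    mu_total,     # float64 expected mutations per haplotype per generation
    L_total,      # int64
    dfe_cdf,      # (4,) float64 cumulative class probabilities
    bin_lo,       # (4,) float64 bin bounds on 2*Nanc*s
    bin_hi,
    inv_two_nanc,  # 1 / (2*Nanc_scaled)
    neutral_class0,  # bool: class-0 draws get s = 0 exactly
    record_from,  # int64: record fixations for generations > this label
    gen0,         # int64 label of the first generation in this span
    fix_pos,      # preallocated int64 output buffers for fixations
    fix_gen,
    fix_s,
    seed,
):
    np.random.seed(seed)
    n_loci = offsets.size - 1
    n_fix = 0
    S = pos.size

    for t in range(sizes.size):
        n_par = G.shape[0] // 2
        n_g = 2 * int(sizes[t])
        gen_label = gen0 + t

        # --- fitness ---------------------------------------------------
        n_sel = 0
        for j in range(S):
            if sarr[j] > 0.0:
                n_sel += 1
        cum = np.empty(n_par)
        if n_sel > 0:
            logw = np.zeros(n_par)
            c_het = np.empty(S)
            c_hom = np.empty(S)
            for j in range(S):
                if sarr[j] > 0.0:
                    c_het[j] = np.log1p(-0.5 * sarr[j])
                    c_hom[j] = np.log1p(-sarr[j])
            mx = -1e300
            for i in range(n_par):
                lw = 0.0
                for j in range(S):
                    if sarr[j] > 0.0:
                        a = G[2 * i, j] + G[2 * i + 1, j]
                        if a == 1:
                            lw += c_het[j]
                        elif a == 2:
                            lw += c_hom[j]
                logw[i] = lw
                if lw > mx:
                    mx = lw
            tot = 0.0
            for i in range(n_par):
                tot += np.exp(logw[i] - mx)
                cum[i] = tot
        else:
            for i in range(n_par):
                cum[i] = float(i + 1)

        # --- parents ---------------------------------------------------
        parents = np.empty(n_g, dtype=np.int64)
        wtot = cum[n_par - 1]
        for g in range(n_g):
            u = np.random.random() * wtot
            p = _searchsorted_right(cum[:n_par], u)
            if p >= n_par:
                p = n_par - 1
            parents[g] = p

        # --- locus column ranges --------------------------------------
        col_lo = np.empty(n_loci, dtype=np.int64)
        col_hi = np.empty(n_loci, dtype=np.int64)
        for l in range(n_loci):
            col_lo[l] = np.searchsorted(pos[:S], offsets[l])
            col_hi[l] = np.searchsorted(pos[:S], offsets[l + 1])

        # --- gametes ---------------------------------------------------
        child = np.empty((n_g, S), dtype=np.uint8)
        for g in range(n_g):
            p2 = 2 * parents[g]
            for l in range(n_loci):
                ph = np.random.randint(0, 2)
                row = p2 + ph
                for j in range(col_lo[l], col_hi[l]):
                    child[g, j] = G[row, j]
                if xover_mean[l] > 0.0 and col_hi[l] > col_lo[l]:
                    k = np.random.poisson(xover_mean[l])
                    for _ in range(k):
                        cut = offsets[l] + 1 + np.random.randint(
                            0, offsets[l + 1] - offsets[l] - 1
                        )
                        ci = np.searchsorted(pos[:S], cut)
                        # XOR-flip the suffix of this locus
                        for j in range(ci, col_hi[l]):
                            child[g, j] = G[p2, j] + G[p2 + 1, j] - child[g, j]

        # --- new mutations --------------------------------------------
        n_mut = np.random.poisson(n_g * mu_total)
        newpos = np.empty(n_mut, dtype=np.int64)
        n_new = 0
        for _ in range(n_mut):
            for _try in range(10_000):
                cand = np.random.randint(0, L_total)
                j = np.searchsorted(pos[:S], cand)
                if j < S and pos[j] == cand:
                    continue
                dup = False
                ins = n_new
                for m in range(n_new):
                    if newpos[m] == cand:
                        dup = True
                        break
                    if newpos[m] > cand:
                        ins = m
                        break
                if dup:
                    continue
                for m in range(n_new, ins, -1):
                    newpos[m] = newpos[m - 1]
                newpos[ins] = cand
                n_new += 1
                break

        new_s = np.zeros(n_new)
        carriers = np.empty(n_new, dtype=np.int64)
        for m in range(n_new):
            carriers[m] = np.random.randint(0, n_g)
            if sel_lookup[newpos[m]]:
                u = np.random.random()
                cls = 0
                while cls < 3 and u > dfe_cdf[cls]:
                    cls += 1
                if cls == 0 and neutral_class0:
                    new_s[m] = 0.0
                else:
                    two_ns = bin_lo[cls] + np.random.random() * (
                        bin_hi[cls] - bin_lo[cls]
                    )
                    new_s[m] = two_ns * inv_two_nanc

        # --- count, classify, rebuild in one pass ----------------------
        keep = np.empty(S, dtype=np.bool_)
        n_keep = 0
        for j in range(S):
            c = 0
            for g in range(n_g):
                c += child[g, j]
            if c == 0:
                keep[j] = False
            elif c == n_g:
                keep[j] = False
                if gen_label > record_from and n_fix < fix_pos.size:
                    fix_pos[n_fix] = pos[j]
                    fix_gen[n_fix] = gen_label
                    fix_s[n_fix] = sarr[j]
                    n_fix += 1
            else:
                keep[j] = True
                n_keep += 1

        S2 = n_keep + n_new
        # source map: old column index, or -(m+1) for new mutation m
        src = np.empty(S2, dtype=np.int64)
        pos2 = np.empty(S2, dtype=np.int64)
        s2 = np.empty(S2)
        oi = 0  # next kept old column
        mi = 0  # next new mutation
        k = 0
        while oi < S or mi < n_new:
            if oi < S and not keep[oi]:
                oi += 1
                continue
            take_old = oi < S and (mi >= n_new or pos[oi] < newpos[mi])
            if take_old:
                src[k] = oi
                pos2[k] = pos[oi]
                s2[k] = sarr[oi]
                oi += 1
            else:
                src[k] = -(mi + 1)
                pos2[k] = newpos[mi]
                s2[k] = new_s[mi]
                mi += 1
            k += 1

        G2 = np.empty((n_g, S2), dtype=np.uint8)
        for g in range(n_g):
            for j in range(S2):
                sj = src[j]
                G2[g, j] = child[g, sj] if sj >= 0 else 0
        for m in range(n_new):
            # locate the column of mutation m
            j = np.searchsorted(pos2, newpos[m])
            G2[carriers[m], j] = 1

        G = G2
        pos = pos2
        sarr = s2
        S = S2

    return G, pos, sarr, n_fix
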