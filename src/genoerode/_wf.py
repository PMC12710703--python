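"""Numba kernels for the forward Wright-Fisher simulator.

The population is a pair of ragged arrays (CSR layout) of mutation entries
per haplotype: one structure for neutral mutations and one for selected
mutations, sharing a single mutation table (``mut_pos``, ``mut_s``,
``mut_gene`` plus precomputed per-mutation log-fitness terms).  Haplotypes
``2i`` and ``2i+1`` belong to diploid individual ``i``.  Each carried
entry is a composite ``(gene << 32) | id`` so the transmission inner loop
never dereferences the mutation table; lists are not kept sorted, and
genotype state is recovered with a stamped scratch array.

Per generation the kernel

1. computes multiplicative log fitness per individual from the selected
   structure only (shared id in both haplotypes = homozygote, ``1+s``;
   single copy = heterozygote, ``1+h*s``; fitness floored at zero by
   clipping ``s`` at -1, encoded as a large negative log term),
2. samples two parents per offspring with probability proportional to
   fitness (selfing permitted, canonical Wright-Fisher),
3. transmits one gamete per parent with free recombination between genes
   and none within a gene: one random bit per gene selects the parental
   haplotype, and a mutation is copied from haplotype 0 (1) iff its gene's
   bit is 0 (1) - a mutation carried homozygously is transmitted exactly
   once either way,
4. adds Poisson-distributed new mutations, each on a random gamete at a
   random genomic position, neutral with probability ``p_neutral``,
   otherwise with ``s`` drawn from a negated gamma distribution.

Offspring are written into ping-pong buffers grown geometrically, so the
steady-state generation loop performs no large allocations.  The kernel
runs a bounded chunk of generations; the Python wrapper prunes fixed/lost
mutations and compacts the table between chunks and refreshes the
log-fitness terms when the epoch-level scaling of ``s`` changes.
Randomness uses numba's internal ``np.random`` state, seeded per chunk.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: log-fitness stand-in for "fitness is zero" (homozygote for s <= -1)
NEG_INF = -1.0e30

#: low half of a composite haplotype entry = mutation id
ID_MASK = np.int64((1 << 32) - 1)


@njit(cache=True)
def _log_fitness(sel_data, sel_ptr, n_ind, lw_het, lw_hom, stamp, tag0, logw, id_mask):
    """Per-individual log fitness from the selected-mutation structure.

    ``stamp`` is an int64 scratch indexed by mutation id holding the tag of
    the individual that last touched the entry; a repeated id within one
    individual is the homozygous second copy.  Returns the next free tag.
    """
    tag = tag0
    for i in range(n_ind):
        tag += 1
        acc = 0.0
        for idx in range(sel_ptr[2 * i], sel_ptr[2 * i + 2]):
            mid = sel_data[idx] & id_mask
            if stamp[mid] == tag:
                acc += lw_hom[mid] - lw_het[mid]
            else:
                stamp[mid] = tag
                acc += lw_het[mid]
        logw[i] = acc
    return tag


@njit(cache=True, inline="always")
def _transmit_gamete(data, ptr, p, words, row, out, pos, gene_shift):
    """Copy one gamete of parent ``p`` into ``out`` starting at ``pos``."""
    for idx in range(ptr[2 * p], ptr[2 * p + 1]):
        mid = data[idx]
        g = np.int64(mid) >> gene_shift
        bit = (words[row + (g >> 6)] >> (g & 63)) & 1
        out[pos] = mid
        pos += 1 - bit
    for idx in range(ptr[2 * p + 1], ptr[2 * p + 2]):
        mid = data[idx]
        g = np.int64(mid) >> gene_shift
        bit = (words[row + (g >> 6)] >> (g & 63)) & 1
        out[pos] = mid
        pos += bit
    return pos


@njit(cache=True)
def _run_generations(
    neu_data,
    neu_ptr,
    sel_data,
    sel_ptr,
    sizes,          # int64[:] diploid size of each offspring generation
    mut_pos,        # int64[cap] mutation table: genomic position
    mut_s,          # float64[cap] natural-scale selection coefficient
    mut_gene,       # int32[cap] gene index
    lw_het,         # float64[cap] log(1 + h * s_eff)
    lw_hom,         # float64[cap] log(1 + s_eff) or NEG_INF
    stamp,          # int64[cap] zeroed scratch for genotype recovery
    n_mut,
    mu_per_gamete,  # expected new mutations per gamete (mu_eff * L)
    s_mult,
    h,
    p_neutral,
    gamma_shape,
    gamma_scale,
    L_total,
    gene_length,
    n_genes,
    gene_shift,     # bits reserved for the id half of a composite entry
    seed,
):
    """Advance the population over ``len(sizes)`` generations.

    Returns the four CSR arrays (tight copies) plus the new table fill;
    the table arrays are written in place and must have capacity for the
    whole chunk (the wrapper guarantees this; the kernel raises otherwise).
    """
    np.random.seed(seed)
    id_mask = (np.int64(1) << gene_shift) - 1
    n_words = (n_genes + 63) // 64
    cap = mut_pos.shape[0]
    n_cur = (neu_ptr.shape[0] - 1) // 2
    max_n = np.int64(sizes.max())
    if n_cur > max_n:
        max_n = np.int64(n_cur)

    # hoisted per-generation scratch, sized for the largest generation
    words = np.empty(2 * max_n * n_words, dtype=np.int64)
    parents = np.empty(2 * max_n, dtype=np.int64)
    logw = np.empty(max_n, dtype=np.float64)
    cw = np.empty(max_n, dtype=np.float64)
    new_cap = int(8.0 * mu_per_gamete * max_n) + 64
    gam_of_new = np.empty(new_cap, dtype=np.int64)
    neu_grp = np.empty(new_cap, dtype=neu_data.dtype)  # new mutations grouped
    sel_grp = np.empty(new_cap, dtype=sel_data.dtype)  # per gamete, per class
    neu_start = np.zeros(2 * max_n + 1, dtype=np.int64)
    sel_start = np.zeros(2 * max_n + 1, dtype=np.int64)
    tag = np.int64(0)

    # ping-pong output buffers per mutation class; the inputs may be
    # caller-owned, so the first swap targets fresh arrays
    neu_out = np.empty(max(64, 2 * neu_data.shape[0]), dtype=neu_data.dtype)
    sel_out = np.empty(max(64, 2 * sel_data.shape[0]), dtype=sel_data.dtype)
    neu_optr = np.empty(4 * max_n + 2, dtype=np.int64)
    sel_optr = np.empty(4 * max_n + 2, dtype=np.int64)
    neu_back = np.empty(0, dtype=neu_data.dtype)  # becomes the spare after swap 1
    sel_back = np.empty(0, dtype=sel_data.dtype)
    neu_bptr = np.empty(4 * max_n + 2, dtype=np.int64)
    sel_bptr = np.empty(4 * max_n + 2, dtype=np.int64)

    for t in range(sizes.shape[0]):
        n_next = sizes[t]
        n_gam = 2 * n_next

        # --- fitness-weighted parent sampling ---
        tag = _log_fitness(
            sel_data, sel_ptr, n_cur, lw_het, lw_hom, stamp, tag, logw, id_mask
        )
        wmax = logw[0]
        for i in range(1, n_cur):
            if logw[i] > wmax:
                wmax = logw[i]
        total = 0.0
        if wmax <= NEG_INF:
            for i in range(n_cur):
                total += 1.0
                cw[i] = total
        else:
            for i in range(n_cur):
                total += np.exp(logw[i] - wmax)
                cw[i] = total
        for k in range(n_gam):
            u = np.random.random() * total
            parents[k] = min(
                np.searchsorted(cw[:n_cur], u, side="right"), n_cur - 1
            )

        # --- new mutations: draw, classify, group per gamete ---
        n_new = np.random.poisson(n_gam * mu_per_gamete)
        if n_mut + n_new > cap:
            raise ValueError("mutation table capacity exceeded")
        while n_new > gam_of_new.shape[0]:
            gam_of_new = np.empty(2 * gam_of_new.shape[0], dtype=np.int64)
            neu_grp = np.empty(gam_of_new.shape[0], dtype=neu_data.dtype)
            sel_grp = np.empty(gam_of_new.shape[0], dtype=sel_data.dtype)
        for k in range(n_gam + 1):
            neu_start[k] = 0
            sel_start[k] = 0
        for m in range(n_new):
            mid = n_mut + m
            pos = np.random.randint(0, L_total)
            mut_pos[mid] = pos
            mut_gene[mid] = np.int32(pos // gene_length)
            gam = np.random.randint(0, n_gam)
            gam_of_new[m] = gam
            if np.random.random() < p_neutral:
                mut_s[mid] = 0.0
                lw_het[mid] = 0.0
                lw_hom[mid] = 0.0
                neu_start[gam + 1] += 1
            else:
                s = -np.random.gamma(gamma_shape, gamma_scale)
                mut_s[mid] = s
                se = s * s_mult
                if se < -1.0:
                    se = -1.0
                lw_het[mid] = np.log(1.0 + h * se)
                lw_hom[mid] = NEG_INF if se <= -1.0 else np.log(1.0 + se)
                sel_start[gam + 1] += 1
        for k in range(n_gam):
            neu_start[k + 1] += neu_start[k]
            sel_start[k + 1] += sel_start[k]
        if n_new > 0:
            neu_fill = neu_start.copy()
            sel_fill = sel_start.copy()
            for m in range(n_new):
                mid = n_mut + m
                gam = gam_of_new[m]
                comp = (np.int64(mut_gene[mid]) << gene_shift) | np.int64(mid)
                if mut_s[mid] == 0.0:
                    neu_grp[neu_fill[gam]] = comp
                    neu_fill[gam] += 1
                else:
                    sel_grp[sel_fill[gam]] = comp
                    sel_fill[gam] += 1
        n_mut += n_new

        # --- per-gamete, per-gene inheritance bits ---
        for k in range(n_gam * n_words):
            lo = np.random.randint(0, 1 << 32)
            hi = np.random.randint(0, 1 << 32)
            words[k] = (hi << 32) | lo

        # --- transmission (both classes share parents and words) ---
        bound_n = np.int64(n_new)
        bound_s = np.int64(n_new)
        for k in range(n_gam):
            p = parents[k]
            bound_n += neu_ptr[2 * p + 2] - neu_ptr[2 * p]
            bound_s += sel_ptr[2 * p + 2] - sel_ptr[2 * p]
        while bound_n > neu_out.shape[0]:
            neu_out = np.empty(2 * bound_n, dtype=neu_data.dtype)
        while bound_s > sel_out.shape[0]:
            sel_out = np.empty(2 * bound_s, dtype=sel_data.dtype)

        pos_n = np.int64(0)
        pos_s = np.int64(0)
        neu_optr[0] = 0
        sel_optr[0] = 0
        for k in range(n_gam):
            p = parents[k]
            row = k * n_words
            pos_n = _transmit_gamete(
                neu_data, neu_ptr, p, words, row, neu_out, pos_n, gene_shift
            )
            pos_s = _transmit_gamete(
                sel_data, sel_ptr, p, words, row, sel_out, pos_s, gene_shift
            )
            for m in range(neu_start[k], neu_start[k + 1]):
                neu_out[pos_n] = neu_grp[m]
                pos_n += 1
            for m in range(sel_start[k], sel_start[k + 1]):
                sel_out[pos_s] = sel_grp[m]
                pos_s += 1
            neu_optr[k + 1] = pos_n
            sel_optr[k + 1] = pos_s

        # --- ping-pong swap: outputs become inputs, spares become outputs ---
        tmp = neu_back if t > 0 else np.empty(neu_out.shape[0], dtype=neu_data.dtype)
        neu_back = neu_data
        neu_data = neu_out
        neu_out = tmp
        tmp = sel_back if t > 0 else np.empty(sel_out.shape[0], dtype=sel_data.dtype)
        sel_back = sel_data
        sel_data = sel_out
        sel_out = tmp
        tmp_p = neu_bptr
        neu_bptr = neu_ptr if t > 0 else neu_bptr
        neu_ptr = neu_optr
        neu_optr = tmp_p if t > 0 else np.empty(4 * max_n + 2, dtype=np.int64)
        tmp_p = sel_bptr
        sel_bptr = sel_ptr if t > 0 else sel_bptr
        sel_ptr = sel_optr
        sel_optr = tmp_p if t > 0 else np.empty(4 * max_n + 2, dtype=np.int64)
        n_cur = n_next

    # tight copies so the oversized buffers do not escape the kernel
    out_neu = neu_data[: neu_ptr[2 * n_cur]].copy()
    out_sel = sel_data[: sel_ptr[2 * n_cur]].copy()
    return out_neu, neu_ptr[: 2 * n_cur + 1].copy(), out_sel, sel_ptr[: 2 * n_cur + 1].copy(), n_mut


def refresh_log_terms(mut_s, lw_het, lw_hom, n_mut, s_mult, h):
    """Recompute the per-mutation log-fitness terms for a new epoch scale."""
    s = mut_s[:n_mut]
    se = np.clip(s * s_mult, -1.0, 0.0)
    lw_het[:n_mut] = np.log1p(h * se)
    with np.errstate(divide="ignore"):
        lw_hom[:n_mut] = np.where(se <= -1.0, NEG_INF, np.log1p(se))
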