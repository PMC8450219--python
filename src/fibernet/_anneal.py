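"""Compiled inner loop of the network annealing.

Same algorithm as the pure-Python reference path in
:mod:`fibernet.network` (single-node Metropolis displacements against
binned descriptor targets); maintained separately so the hot loop can be
JIT-compiled with numba.  Histogram grids must be uniform here — the
public API validates this before dispatching.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _bin_index(x, lo, width, nbins):
    b = int((x - lo) / width)
    if b < 0:
        b = 0
    elif b >= nbins:
        b = nbins - 1
    return b


@njit(cache=True)
def _node_cosines(u, inc_ptr, inc_idx, segs, vec, lengths, out):
    """Cosines of all unordered tangent pairs at node u; returns count."""
    lo, hi = inc_ptr[u], inc_ptr[u + 1]
    deg = hi - lo
    c = 0
    for p in range(deg):
        k1 = inc_idx[lo + p]
        s1 = 1.0 if segs[k1, 0] == u else -1.0
        for q in range(p + 1, deg):
            k2 = inc_idx[lo + q]
            s2 = 1.0 if segs[k2, 0] == u else -1.0
            dot = (
                vec[k1, 0] * vec[k2, 0] + vec[k1, 1] * vec[k2, 1] + vec[k1, 2] * vec[k2, 2]
            ) * s1 * s2 / (lengths[k1] * lengths[k2])
            if dot > 1.0:
                dot = 1.0
            elif dot < -1.0:
                dot = -1.0
            out[c] = dot
            c += 1
    return c


@njit(cache=True)
def anneal_kernel(
    pos,
    segs,
    shifts,
    L,
    inc_ptr,
    inc_idx,
    len_target,
    cos_target,
    w_len,
    w_cos,
    e_valency,
    len_lo,
    len_w,
    cos_lo,
    cos_w,
    len_counts,
    cos_counts,
    w_conc,
    T0,
    cooling,
    moves_per_sweep,
    max_sweeps,
    amp0,
    amp1,
    min_len,
    seed,
    energy_tol,
):
    """Run the Metropolis annealing loop in place; returns the energy trace.

    Mutates ``pos``, ``shifts``, ``len_counts`` and ``cos_counts``.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    m = segs.shape[0]
    nlen = len_counts.shape[0]
    ncos = cos_counts.shape[0]
    len_total = 0.0
    for b in range(nlen):
        len_total += len_counts[b]
    cos_total = 0.0
    for b in range(ncos):
        cos_total += cos_counts[b]

    vec = np.empty((m, 3))
    lengths = np.empty(m)
    for k in range(m):
        a, b2 = segs[k, 0], segs[k, 1]
        for d in range(3):
            vec[k, d] = pos[b2, d] + shifts[k, d] * L[d] - pos[a, d]
        lengths[k] = np.sqrt(vec[k, 0] ** 2 + vec[k, 1] ** 2 + vec[k, 2] ** 2)
    L_tot = lengths.sum()
    L_ref = L_tot

    def full_energy(len_counts, cos_counts, L_tot):
        e = e_valency
        for b in range(nlen):
            diff = len_counts[b] / len_total - len_target[b]
            e += w_len * diff * diff
        for b in range(ncos):
            diff = cos_counts[b] / cos_total - cos_target[b]
            e += w_cos * diff * diff
        rel = L_tot / L_ref - 1.0
        e += w_conc * rel * rel
        return e

    E = full_energy(len_counts, cos_counts, L_tot)
    trace = np.empty(max_sweeps + 1)
    trace[0] = E
    T = T0
    n_sweeps_done = 0
    n_acc = 0
    n_prop = 0

    max_deg = 0
    for u in range(n):
        deg = inc_ptr[u + 1] - inc_ptr[u]
        if deg > max_deg:
            max_deg = deg
    max_pairs = max_deg * (max_deg - 1) // 2
    max_aff = max_deg + 1

    old_vec = np.empty((max_deg, 3))
    old_len = np.empty(max_deg)
    cos_buf = np.empty(max_pairs)
    old_bins = np.empty(max_aff * max_pairs + max_deg, np.int64)
    new_bins = np.empty(max_aff * max_pairs + max_deg, np.int64)
    affected = np.empty(max_aff, np.int64)

    if max_sweeps > 0:
        amp_ratio = (amp1 / amp0) ** (1.0 / max(max_sweeps - 1, 1))
    else:
        amp_ratio = 1.0
    amp = amp0

    for sweep in range(max_sweeps):
        for _ in range(moves_per_sweep):
            n_prop += 1
            i = np.random.randint(0, n)
            dx = np.random.uniform(-amp, amp)
            dy = np.random.uniform(-amp, amp)
            dz = np.random.uniform(-amp, amp)

            lo_i, hi_i = inc_ptr[i], inc_ptr[i + 1]
            deg = hi_i - lo_i
            ok = True
            for p in range(deg):
                k = inc_idx[lo_i + p]
                sgn = 1.0 if segs[k, 0] == i else -1.0
                nv0 = vec[k, 0] - sgn * dx
                nv1 = vec[k, 1] - sgn * dy
                nv2 = vec[k, 2] - sgn * dz
                nl = np.sqrt(nv0 * nv0 + nv1 * nv1 + nv2 * nv2)
                if nl < min_len:
                    ok = False
                    break
                old_vec[p, 0] = vec[k, 0]
                old_vec[p, 1] = vec[k, 1]
                old_vec[p, 2] = vec[k, 2]
                old_len[p] = lengths[k]
                # stage: write tentative values later, after old cosines are read
            if not ok:
                continue

            # affected nodes: i plus distinct other endpoints
            n_aff = 1
            affected[0] = i
            for p in range(deg):
                k = inc_idx[lo_i + p]
                other = segs[k, 0] + segs[k, 1] - i
                seen = False
                for q in range(n_aff):
                    if affected[q] == other:
                        seen = True
                        break
                if not seen:
                    affected[n_aff] = other
                    n_aff += 1

            n_old = 0
            for q in range(n_aff):
                cnum = _node_cosines(affected[q], inc_ptr, inc_idx, segs, vec, lengths, cos_buf)
                for c in range(cnum):
                    old_bins[n_old] = _bin_index(cos_buf[c], cos_lo, cos_w, ncos)
                    n_old += 1
            n_old_len = 0
            for p in range(deg):
                old_bins[n_old + n_old_len] = -1  # sentinel unused; lengths handled below
                n_old_len += 1

            # apply tentative geometry
            for p in range(deg):
                k = inc_idx[lo_i + p]
                sgn = 1.0 if segs[k, 0] == i else -1.0
                vec[k, 0] -= sgn * dx
                vec[k, 1] -= sgn * dy
                vec[k, 2] -= sgn * dz
                lengths[k] = np.sqrt(vec[k, 0] ** 2 + vec[k, 1] ** 2 + vec[k, 2] ** 2)

            n_new = 0
            for q in range(n_aff):
                cnum = _node_cosines(affected[q], inc_ptr, inc_idx, segs, vec, lengths, cos_buf)
                for c in range(cnum):
                    new_bins[n_new] = _bin_index(cos_buf[c], cos_lo, cos_w, ncos)
                    n_new += 1

            # energy change: remove old bins, add new bins, one at a time
            dE = 0.0
            dL = 0.0
            for p in range(deg):
                k = inc_idx[lo_i + p]
                dL += lengths[k] - old_len[p]
            rel_new = (L_tot + dL) / L_ref - 1.0
            rel_old = L_tot / L_ref - 1.0
            dE += w_conc * (rel_new * rel_new - rel_old * rel_old)
            for c in range(n_old):
                b = old_bins[c]
                pcur = cos_counts[b] / cos_total
                t = cos_target[b]
                dE += w_cos * (((pcur - 1.0 / cos_total) - t) ** 2 - (pcur - t) ** 2)
                cos_counts[b] -= 1.0
            for c in range(n_new):
                b = new_bins[c]
                pcur = cos_counts[b] / cos_total
                t = cos_target[b]
                dE += w_cos * (((pcur + 1.0 / cos_total) - t) ** 2 - (pcur - t) ** 2)
                cos_counts[b] += 1.0
            for p in range(deg):
                k = inc_idx[lo_i + p]
                b = _bin_index(old_len[p], len_lo, len_w, nlen)
                pcur = len_counts[b] / len_total
                t = len_target[b]
                dE += w_len * (((pcur - 1.0 / len_total) - t) ** 2 - (pcur - t) ** 2)
                len_counts[b] -= 1.0
                b = _bin_index(lengths[k], len_lo, len_w, nlen)
                pcur = len_counts[b] / len_total
                t = len_target[b]
                dE += w_len * (((pcur + 1.0 / len_total) - t) ** 2 - (pcur - t) ** 2)
                len_counts[b] += 1.0

            accept = dE <= 0.0 or np.random.random() < np.exp(-dE / T)
            if accept:
                n_acc += 1
                E += dE
                L_tot += dL
                # commit position with wrapping
                px = pos[i, 0] + dx
                py = pos[i, 1] + dy
                pz = pos[i, 2] + dz
                sx = int(np.floor(px / L[0]))
                sy = int(np.floor(py / L[1]))
                sz = int(np.floor(pz / L[2]))
                pos[i, 0] = px - sx * L[0]
                pos[i, 1] = py - sy * L[1]
                pos[i, 2] = pz - sz * L[2]
                if sx != 0 or sy != 0 or sz != 0:
                    for p in range(deg):
                        k = inc_idx[lo_i + p]
                        if segs[k, 0] == i:
                            shifts[k, 0] -= sx
                            shifts[k, 1] -= sy
                            shifts[k, 2] -= sz
                        else:
                            shifts[k, 0] += sx
                            shifts[k, 1] += sy
                            shifts[k, 2] += sz
            else:
                # revert counts and geometry
                for c in range(n_new):
                    cos_counts[new_bins[c]] -= 1.0
                for c in range(n_old):
                    cos_counts[old_bins[c]] += 1.0
                for p in range(deg):
                    k = inc_idx[lo_i + p]
                    len_counts[_bin_index(lengths[k], len_lo, len_w, nlen)] -= 1.0
                    len_counts[_bin_index(old_len[p], len_lo, len_w, nlen)] += 1.0
                    vec[k, 0] = old_vec[p, 0]
                    vec[k, 1] = old_vec[p, 1]
                    vec[k, 2] = old_vec[p, 2]
                    lengths[k] = old_len[p]

        trace[sweep + 1] = E
        n_sweeps_done = sweep + 1
        T *= cooling
        amp *= amp_ratio
        if E <= energy_tol:
            break

    return trace[: n_sweeps_done + 1], n_acc, n_prop
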