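"""Compiled inner loop for the Metropolis chain over (type, rotamer) space.

The sampler packs a design system into dense arrays — one (type, rotamer)
"combo" index per position, a diagonal energy table and a symmetric dense
pair table — and hands chunks of pre-drawn uniforms to :func:`run_chain`.
Keeping all randomness outside the kernel makes runs reproducible from a
single seed and keeps the kernel a pure function of its inputs.

Array layout (positions ordered mutable-first):

- ``comb[i]``       current combo index at position ``i`` (mutated in place)
- ``cur_type[k]``   current local type index at mutable position ``k``
- ``diag[i, c]``    self energy of combo ``c`` at position ``i``
- ``pairm[i, j, c, d]``  interaction energy, stored symmetrically
- ``comb_type[i, c]``    local type index of combo ``c``
- ``bsingle[k, a]`` / ``bpair[k, l, a, b]``  bias terms over types
"""

import numpy as np
from numba import njit


@njit(cache=True)
def total_energy_arrays(comb, diag, pairm):
    n = comb.shape[0]
    e = 0.0
    for i in range(n):
        e += diag[i, comb[i]]
        for j in range(i + 1, n):
            e += pairm[i, j, comb[i], comb[j]]
    return e


@njit(cache=True)
def _pair_bias_total(cur_type, bpair):
    n = cur_type.shape[0]
    e = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            e += bpair[a, b, cur_type[a], cur_type[b]]
    return e


@njit(cache=True)
def run_chain(
    comb,
    cur_type,
    diag,
    pairm,
    comb_type,
    ncomb,
    n_mut,
    bsingle,
    bpair,
    pair_bias_on,
    kT,
    move_mix,
    rand,
    step_offset,
    record_interval,
    counts,
    strides,
    adapt,
    update_period,
    e0,
    E0,
    tail_start,
    bsingle_sum,
    bpair_sum,
):
    """Advance the chain by ``rand.shape[0]`` steps; mutates ``comb``,
    ``cur_type``, ``counts`` and (when adapting) the bias arrays in place.

    During adaptation, snapshots of the bias taken at every update event
    with global step >= ``tail_start`` are accumulated into
    ``bsingle_sum``/``bpair_sum`` (for tail averaging by the caller).
    Returns the number of accumulated snapshots.
    """
    n_steps = rand.shape[0]
    n_pos = comb.shape[0]
    n_acc = 0
    for step in range(n_steps):
        g = step_offset + step + 1
        two = (rand[step, 0] < move_mix) and (n_pos >= 2)
        i = int(rand[step, 1] * n_pos)
        if i >= n_pos:
            i = n_pos - 1
        ci_old = comb[i]
        ci_new = int(rand[step, 3] * ncomb[i])
        if ci_new >= ncomb[i]:
            ci_new = ncomb[i] - 1
        j = -1
        cj_old = -1
        cj_new = -1
        if two:
            j = int(rand[step, 2] * (n_pos - 1))
            if j >= n_pos - 1:
                j = n_pos - 2
            if j >= i:
                j += 1
            cj_old = comb[j]
            cj_new = int(rand[step, 4] * ncomb[j])
            if cj_new >= ncomb[j]:
                cj_new = ncomb[j] - 1

        # matrix energy delta
        dE = diag[i, ci_new] - diag[i, ci_old]
        for k in range(n_pos):
            if k == i or k == j:
                continue
            dE += pairm[i, k, ci_new, comb[k]] - pairm[i, k, ci_old, comb[k]]
        if two:
            dE += diag[j, cj_new] - diag[j, cj_old]
            for k in range(n_pos):
                if k == i or k == j:
                    continue
                dE += pairm[j, k, cj_new, comb[k]] - pairm[j, k, cj_old, comb[k]]
            dE += pairm[i, j, ci_new, cj_new] - pairm[i, j, ci_old, cj_old]

        # bias delta (sequence types only)
        ti_new = -1
        tj_new = -1
        changed = False
        if i < n_mut:
            ti_new = comb_type[i, ci_new]
            if ti_new != cur_type[i]:
                changed = True
                dE += bsingle[i, ti_new] - bsingle[i, cur_type[i]]
        if two and j < n_mut:
            tj_new = comb_type[j, cj_new]
            if tj_new != cur_type[j]:
                changed = True
                dE += bsingle[j, tj_new] - bsingle[j, cur_type[j]]
        if pair_bias_on and changed:
            old_e = 0.0
            new_e = 0.0
            for a in range(n_mut):
                ta = cur_type[a]
                na = ta
                if a == i and ti_new >= 0:
                    na = ti_new
                if two and a == j and tj_new >= 0:
                    na = tj_new
                for b in range(a + 1, n_mut):
                    tb = cur_type[b]
                    nb = tb
                    if b == i and ti_new >= 0:
                        nb = ti_new
                    if two and b == j and tj_new >= 0:
                        nb = tj_new
                    old_e += bpair[a, b, ta, tb]
                    new_e += bpair[a, b, na, nb]
            dE += new_e - old_e

        if dE <= 0.0 or rand[step, 5] < np.exp(-dE / kT):
            comb[i] = ci_new
            if i < n_mut:
                cur_type[i] = comb_type[i, ci_new]
            if two:
                comb[j] = cj_new
                if j < n_mut:
                    cur_type[j] = comb_type[j, cj_new]

        if adapt and g % update_period == 0:
            # increments from pre-update values
            for a in range(n_mut):
                inc = e0 * np.exp(-bsingle[a, cur_type[a]] / E0)
                bsingle[a, cur_type[a]] += inc
            if pair_bias_on:
                for a in range(n_mut):
                    for b in range(a + 1, n_mut):
                        incp = e0 * np.exp(-bpair[a, b, cur_type[a], cur_type[b]] / E0)
                        bpair[a, b, cur_type[a], cur_type[b]] += incp
            if g >= tail_start:
                n_acc += 1
                for a in range(n_mut):
                    for t in range(bsingle.shape[1]):
                        bsingle_sum[a, t] += bsingle[a, t]
                if pair_bias_on:
                    for a in range(n_mut):
                        for b in range(a + 1, n_mut):
                            for x in range(bpair.shape[2]):
                                for y in range(bpair.shape[3]):
                                    bpair_sum[a, b, x, y] += bpair[a, b, x, y]

        if g % record_interval == 0:
            s = 0
            for a in range(n_mut):
                s += cur_type[a] * strides[a]
            counts[s] += 1
    return n_acc
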