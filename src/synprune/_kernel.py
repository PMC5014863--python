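"""Fused per-example simulation kernel (numba).

One call advances the whole network by one stimulus presentation
(``n_steps`` global steps) on pre-sampled input spike trains.  The loop
implements exactly the update order documented in :mod:`synprune.lif`
and :mod:`synprune.stdp`: decay conductances and traces, integrate the
membranes (forward Euler), detect and reset spikes, then deliver the
spikes (conductance increments, pre-side depression, post-side
potentiation, traces set to one last).  A pure-numpy reference
implementation composed from the module-level operations lives in
:mod:`synprune.experiments`; the two are tested to agree bit for bit.

All populations share one size per kind so their states are stacked
into 2-D arrays; connection matrices, masks and traces are passed as
numba typed lists.  Array kinds: 0 = input population, 1 = excitatory
group, 2 = inhibitory group.
"""

from __future__ import annotations

import numpy as np
from numba import njit

E_INH = -85.0


@njit(cache=True)
def run_example(  # noqa: PLR0913 - flat argument list keeps numba happy
    n_steps,
    dt,
    # excitatory groups, stacked (P, n_exc)
    v_e, ge_e, gi_e,
    e_rest, e_reset, e_th, e_tau, dge, dgi,
    # inhibitory groups, stacked (P, n_inh)
    v_i, ge_i, gi_i,
    i_rest, i_reset, i_th, i_tau,
    # input spikes (K, n_steps, n_in) uint8
    inp,
    # connections
    ws, masks,                       # typed lists of 2-D arrays
    src_kind, src_pop, tgt_kind, tgt_pop,   # int32 per connection
    is_plastic,                      # uint8 per connection
    rs, os,                          # typed lists of 1-D trace arrays
    fr, fo,                          # per-step trace decay factors
    nu_pre, nu_post, eta_pre, eta_post, w_maxs,
    plastic_on,
    counts_e,                        # (P, n_exc) int64, accumulated in place
):
    n_pop, n_exc = v_e.shape
    n_inh = v_i.shape[1]
    n_conn = len(ws)
    spk_e = np.zeros((n_pop, n_exc), np.uint8)
    spk_i = np.zeros((n_pop, n_inh), np.uint8)
    total_e = 0
    total_i = 0

    for t in range(n_steps):
        # (1) decay conductances and traces
        for p in range(n_pop):
            for j in range(n_exc):
                ge_e[p, j] *= dge
                gi_e[p, j] *= dgi
            for j in range(n_inh):
                ge_i[p, j] *= dge
                gi_i[p, j] *= dgi
        if plastic_on:
            for c in range(n_conn):
                if is_plastic[c]:
                    r = rs[c]
                    o = os[c]
                    for s in range(r.shape[0]):
                        r[s] *= fr[c]
                    for j in range(o.shape[0]):
                        o[j] *= fo[c]

        # (2) integrate membranes, (3) detect spikes and reset
        for p in range(n_pop):
            for j in range(n_exc):
                v = v_e[p, j]
                v += dt * ((e_rest - v) - v * ge_e[p, j]
                           + (E_INH - v) * gi_e[p, j]) / e_tau
                if v >= e_th:
                    spk_e[p, j] = 1
                    v_e[p, j] = e_reset
                    counts_e[p, j] += 1
                    total_e += 1
                else:
                    spk_e[p, j] = 0
                    v_e[p, j] = v
            for j in range(n_inh):
                v = v_i[p, j]
                v += dt * ((i_rest - v) - v * ge_i[p, j]
                           + (E_INH - v) * gi_i[p, j]) / i_tau
                if v >= i_th:
                    spk_i[p, j] = 1
                    v_i[p, j] = i_reset
                    total_i += 1
                else:
                    spk_i[p, j] = 0
                    v_i[p, j] = v

        # (4) deliver spikes: conductances, then pre-side depression
        for c in range(n_conn):
            w = ws[c]
            m = masks[c]
            n_src = w.shape[0]
            n_tgt = w.shape[1]
            sk = src_kind[c]
            sp = src_pop[c]
            tk = tgt_kind[c]
            tp = tgt_pop[c]
            plast = plastic_on and is_plastic[c]
            for s in range(n_src):
                if sk == 0:
                    fired = inp[sp, t, s]
                elif sk == 1:
                    fired = spk_e[sp, s]
                else:
                    fired = spk_i[sp, s]
                if fired == 0:
                    continue
                # conductance increments (weight value at spike arrival)
                if sk == 2:  # inhibitory source
                    if tk == 1:
                        for j in range(n_tgt):
                            if w[s, j] > 0.0:
                                gi_e[tp, j] += w[s, j]
                    else:
                        for j in range(n_tgt):
                            if w[s, j] > 0.0:
                                gi_i[tp, j] += w[s, j]
                else:
                    if tk == 1:
                        for j in range(n_tgt):
                            if w[s, j] > 0.0:
                                ge_e[tp, j] += w[s, j]
                    else:
                        for j in range(n_tgt):
                            if w[s, j] > 0.0:
                                ge_i[tp, j] += w[s, j]
                if plast:
                    o = os[c]
                    for j in range(n_tgt):
                        if m[s, j]:
                            nw = w[s, j] - o[j] * nu_pre[c] * w[s, j] ** eta_pre[c]
                            w[s, j] = nw if nw > 0.0 else 0.0

            # post-side potentiation (plastic targets are excitatory groups)
            if plast:
                r = rs[c]
                o = os[c]
                for j in range(n_tgt):
                    if spk_e[tp, j]:
                        oj = o[j]
                        if oj > 0.0:
                            for s in range(n_src):
                                if m[s, j] and r[s] > 0.0:
                                    head = w_maxs[c] - w[s, j]
                                    if head > 0.0:
                                        nw = w[s, j] + (r[s] * nu_post[c] * oj
                                                        * head ** eta_post[c])
                                        w[s, j] = nw if nw < w_maxs[c] else w_maxs[c]

        # traces are set to one only after all updates of the step
        if plastic_on:
            for c in range(n_conn):
                if is_plastic[c]:
                    r = rs[c]
                    o = os[c]
                    sk = src_kind[c]
                    sp = src_pop[c]
                    tp = tgt_pop[c]
                    for s in range(r.shape[0]):
                        if sk == 0:
                            fired = inp[sp, t, s]
                        elif sk == 1:
                            fired = spk_e[sp, s]
                        else:
                            fired = spk_i[sp, s]
                        if fired:
                            r[s] = 1.0
                    for j in range(o.shape[0]):
                        if spk_e[tp, j]:
                            o[j] = 1.0

    return total_e, total_i
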