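"""Compiled event loop for the delay stochastic simulation algorithm.

This module contains a single numba-jitted kernel implementing the
direct-method dSSA with interruption:

* between events, an exponential waiting time at rate ``a0`` (total
  propensity) selects the next putative firing;
* if a queued delayed completion (or a background mode switch) precedes the
  putative firing, time advances to that event instead and the exponential
  clock is redrawn — exact by memorylessness;
* delayed reactions are non-consuming: at firing a delay is drawn and a
  completion is scheduled, the full state change being applied at completion;
* ties between a putative firing and a queued completion are resolved in
  favor of the completion (completions are pre-committed events).

The pending-completion queue is a binary min-heap keyed on
``(completion_time, insertion_sequence)`` so that simultaneous completions
pop in FIFO order.

The optional hybrid mode is a background two-state continuous-time Markov
chain with symmetric switching rate ``r``; the chain's state at *initiation*
time selects which of two fixed delays an initiating delayed reaction uses.
Mode switches are first-class events in the same loop; they do not change
propensities, so the reaction clock is not redrawn when one occurs.

Because metastable-state residence times can span >1e8 events, the kernel
can classify the state online through a linear projection and log only the
times at which the region label (H / L / I / gap) changes.  All randomness
flows through numba's per-run global PRNG, seeded once at entry, so a whole
run replays from a single integer seed.
"""

import numpy as np
from numba import njit

from .network import (
    PROP_BIMOLECULAR,
    PROP_CONSTANT,
    PROP_DIMERIZE,
    PROP_HILL_ACTIVATE,
    PROP_HILL_REPRESS,
    PROP_LINEAR,
)
from .kernels import KERNEL_BERNOULLI, KERNEL_FIXED, KERNEL_GAMMA

# event kinds in the full event log
EV_INSTANT = 0
EV_INITIATION = 1
EV_COMPLETION = 2
EV_MODE = 3

# region symbols
SYM_H = 0
SYM_L = 1
SYM_I = 2
SYM_GAP = 3


@njit(cache=True)
def _props(kinds, params, spvec, x, out):
    a0 = 0.0
    for i in range(kinds.shape[0]):
        k = kinds[i]
        if k == PROP_CONSTANT:
            a = params[i, 0]
        elif k == PROP_LINEAR:
            a = params[i, 0] * x[spvec[i, 0]]
        elif k == PROP_DIMERIZE:
            n = x[spvec[i, 0]]
            a = params[i, 0] * n * (n - 1) * 0.5
        elif k == PROP_BIMOLECULAR:
            a = params[i, 0] * x[spvec[i, 0]] * x[spvec[i, 1]]
        elif k == PROP_HILL_REPRESS:
            q = x[spvec[i, 0]]
            a = params[i, 0] * params[i, 1] / (params[i, 1] + q * q)
        else:  # PROP_HILL_ACTIVATE
            q = x[spvec[i, 0]]
            if q <= 0:
                a = params[i, 0]
            else:
                u = (q / params[i, 3]) ** params[i, 2]
                a = params[i, 0] + params[i, 1] * u / (1.0 + u)
        if a < 0.0:
            a = 0.0
        out[i] = a
        a0 += a
    return a0


@njit(cache=True)
def _classify(p, th_pos, th_neg, w_pos, w_neg):
    if p >= th_pos:
        return SYM_H
    if p <= -th_neg:
        return SYM_L
    if -w_neg <= p <= w_pos:
        return SYM_I
    return SYM_GAP


@njit(cache=True)
def run_dssa(
    x0,
    kinds,
    params,
    spvec,
    changes,
    delayed,
    kern_kind,
    kern_params,
    hybrid_on,
    hyb_lo,
    hyb_hi,
    hyb_r,
    mode0,
    t_max,
    max_events,
    seed,
    have_regions,
    weights,
    offset,
    th_pos,
    th_neg,
    w_pos,
    w_neg,
    stop_entries,
    rec_events,
    rec_symbols,
    rec_inits,
    rec_modes,
):
    np.random.seed(seed)
    n_rx = kinds.shape[0]
    n_sp = x0.shape[0]
    x = x0.copy()

    props = np.empty(n_rx)
    a0 = _props(kinds, params, spvec, x, props)

    # projection increments per reaction (region bookkeeping)
    proj = offset
    proj_delta = np.zeros(n_rx)
    if have_regions:
        for i in range(n_sp):
            proj += weights[i] * x[i]
        for r in range(n_rx):
            d = 0.0
            for i in range(n_sp):
                d += weights[i] * changes[r, i]
            proj_delta[r] = d

    # pending-completion heap keyed on (time, sequence)
    heap_cap = 256
    heap_t = np.empty(heap_cap)
    heap_q = np.empty(heap_cap, dtype=np.int64)
    heap_r = np.empty(heap_cap, dtype=np.int64)
    heap_n = 0
    seq = 0

    # growable logs
    ev_cap = 1024 if rec_events else 1
    ev_t = np.empty(ev_cap)
    ev_k = np.empty(ev_cap, dtype=np.int8)
    ev_r = np.empty(ev_cap, dtype=np.int64)
    n_ev = 0

    sym_cap = 1024 if rec_symbols else 1
    sym_t = np.empty(sym_cap)
    sym_c = np.empty(sym_cap, dtype=np.int8)
    n_sym = 0

    init_cap = 1024 if rec_inits else 1
    init_t = np.empty(init_cap)
    init_tau = np.empty(init_cap)
    init_r = np.empty(init_cap, dtype=np.int64)
    n_init = 0

    mode_cap = 1024 if rec_modes else 1
    mode_t = np.empty(mode_cap)
    n_mode = 0

    t = 0.0
    mode = mode0
    n_events = 0
    n_entries = 0
    last_meta = -1

    cur_sym = SYM_GAP
    if have_regions:
        cur_sym = _classify(proj, th_pos, th_neg, w_pos, w_neg)
        if rec_symbols:
            sym_t[0] = 0.0
            sym_c[0] = cur_sym
            n_sym = 1
        if cur_sym == SYM_H or cur_sym == SYM_L:
            last_meta = cur_sym

    inf = np.inf
    t_rx = t + np.random.exponential(1.0 / a0) if a0 > 0.0 else inf
    t_mode = t + np.random.exponential(1.0 / hyb_r) if (hybrid_on and hyb_r > 0.0) else inf

    while True:
        t_comp = heap_t[0] if heap_n > 0 else inf
        # earliest of completion / mode switch / putative firing;
        # completion wins ties against the putative firing
        if t_comp <= t_rx and t_comp <= t_mode:
            if t_comp > t_max:
                t = t_max
                break
            # pop min
            t = t_comp
            rx = heap_r[0]
            heap_n -= 1
            if heap_n > 0:
                lt = heap_t[heap_n]
                lq = heap_q[heap_n]
                lr = heap_r[heap_n]
                i = 0
                while True:
                    c1 = 2 * i + 1
                    if c1 >= heap_n:
                        break
                    c2 = c1 + 1
                    c = c1
                    if c2 < heap_n and (
                        heap_t[c2] < heap_t[c1]
                        or (heap_t[c2] == heap_t[c1] and heap_q[c2] < heap_q[c1])
                    ):
                        c = c2
                    if heap_t[c] < lt or (heap_t[c] == lt and heap_q[c] < lq):
                        heap_t[i] = heap_t[c]
                        heap_q[i] = heap_q[c]
                        heap_r[i] = heap_r[c]
                        i = c
                    else:
                        break
                heap_t[i] = lt
                heap_q[i] = lq
                heap_r[i] = lr
            changed = True
            for i in range(n_sp):
                x[i] += changes[rx, i]
            proj += proj_delta[rx]
            a0 = _props(kinds, params, spvec, x, props)
            t_rx = t + np.random.exponential(1.0 / a0) if a0 > 0.0 else inf
            if rec_events:
                if n_ev >= ev_cap:
                    ev_cap *= 2
                    tmp_t = np.empty(ev_cap)
                    tmp_t[:n_ev] = ev_t[:n_ev]
                    ev_t = tmp_t
                    tmp_k = np.empty(ev_cap, dtype=np.int8)
                    tmp_k[:n_ev] = ev_k[:n_ev]
                    ev_k = tmp_k
                    tmp_r = np.empty(ev_cap, dtype=np.int64)
                    tmp_r[:n_ev] = ev_r[:n_ev]
                    ev_r = tmp_r
                ev_t[n_ev] = t
                ev_k[n_ev] = EV_COMPLETION
                ev_r[n_ev] = rx
                n_ev += 1
        elif t_mode < t_rx:
            if t_mode > t_max:
                t = t_max
                break
            t = t_mode
            mode = 1 - mode
            t_mode = t + np.random.exponential(1.0 / hyb_r)
            changed = False
            if rec_modes:
                if n_mode >= mode_cap:
                    mode_cap *= 2
                    tmp = np.empty(mode_cap)
                    tmp[:n_mode] = mode_t[:n_mode]
                    mode_t = tmp
                mode_t[n_mode] = t
                n_mode += 1
            if rec_events:
                if n_ev >= ev_cap:
                    ev_cap *= 2
                    tmp_t = np.empty(ev_cap)
                    tmp_t[:n_ev] = ev_t[:n_ev]
                    ev_t = tmp_t
                    tmp_k = np.empty(ev_cap, dtype=np.int8)
                    tmp_k[:n_ev] = ev_k[:n_ev]
                    ev_k = tmp_k
                    tmp_r = np.empty(ev_cap, dtype=np.int64)
                    tmp_r[:n_ev] = ev_r[:n_ev]
                    ev_r = tmp_r
                ev_t[n_ev] = t
                ev_k[n_ev] = EV_MODE
                ev_r[n_ev] = mode
                n_ev += 1
        else:
            if t_rx > t_max or not np.isfinite(t_rx):
                t = t_max
                break
            t = t_rx
            # select reaction proportionally to propensity
            u = np.random.random() * a0
            rx = 0
            acc = props[0]
            while acc < u and rx < n_rx - 1:
                rx += 1
                acc += props[rx]
            if delayed[rx]:
                changed = False
                if hybrid_on:
                    tau = hyb_lo if mode == 0 else hyb_hi
                else:
                    kk = kern_kind[rx]
                    if kk == KERNEL_FIXED:
                        tau = kern_params[rx, 0]
                    elif kk == KERNEL_GAMMA:
                        tau = np.random.gamma(kern_params[rx, 0]) * kern_params[rx, 1]
                        while tau <= 0.0:
                            tau = np.random.gamma(kern_params[rx, 0]) * kern_params[rx, 1]
                    else:  # KERNEL_BERNOULLI
                        tau = (
                            kern_params[rx, 0]
                            if np.random.random() < 0.5
                            else kern_params[rx, 1]
                        )
                # push (t + tau, seq, rx)
                if heap_n >= heap_cap:
                    heap_cap *= 2
                    tmp_t = np.empty(heap_cap)
                    tmp_t[:heap_n] = heap_t[:heap_n]
                    heap_t = tmp_t
                    tmp_q = np.empty(heap_cap, dtype=np.int64)
                    tmp_q[:heap_n] = heap_q[:heap_n]
                    heap_q = tmp_q
                    tmp_r = np.empty(heap_cap, dtype=np.int64)
                    tmp_r[:heap_n] = heap_r[:heap_n]
                    heap_r = tmp_r
                i = heap_n
                heap_n += 1
                tc = t + tau
                while i > 0:
                    p = (i - 1) // 2
                    if heap_t[p] > tc or (heap_t[p] == tc and heap_q[p] > seq):
                        heap_t[i] = heap_t[p]
                        heap_q[i] = heap_q[p]
                        heap_r[i] = heap_r[p]
                        i = p
                    else:
                        break
                heap_t[i] = tc
                heap_q[i] = seq
                heap_r[i] = rx
                seq += 1
                if rec_inits:
                    if n_init >= init_cap:
                        init_cap *= 2
                        tmp_t = np.empty(init_cap)
                        tmp_t[:n_init] = init_t[:n_init]
                        init_t = tmp_t
                        tmp_d = np.empty(init_cap)
                        tmp_d[:n_init] = init_tau[:n_init]
                        init_tau = tmp_d
                        tmp_r = np.empty(init_cap, dtype=np.int64)
                        tmp_r[:n_init] = init_r[:n_init]
                        init_r = tmp_r
                    init_t[n_init] = t
                    init_tau[n_init] = tau
                    init_r[n_init] = rx
                    n_init += 1
                ev_kind = EV_INITIATION
            else:
                changed = True
                for i in range(n_sp):
                    x[i] += changes[rx, i]
                proj += proj_delta[rx]
                a0 = _props(kinds, params, spvec, x, props)
                ev_kind = EV_INSTANT
            t_rx = t + np.random.exponential(1.0 / a0) if a0 > 0.0 else inf
            if rec_events:
                if n_ev >= ev_cap:
                    ev_cap *= 2
                    tmp_t = np.empty(ev_cap)
                    tmp_t[:n_ev] = ev_t[:n_ev]
                    ev_t = tmp_t
                    tmp_k = np.empty(ev_cap, dtype=np.int8)
                    tmp_k[:n_ev] = ev_k[:n_ev]
                    ev_k = tmp_k
                    tmp_r = np.empty(ev_cap, dtype=np.int64)
                    tmp_r[:n_ev] = ev_r[:n_ev]
                    ev_r = tmp_r
                ev_t[n_ev] = t
                ev_k[n_ev] = ev_kind
                ev_r[n_ev] = rx
                n_ev += 1

        # region bookkeeping after any state change
        if changed and have_regions:
            s = _classify(proj, th_pos, th_neg, w_pos, w_neg)
            if s != cur_sym:
                cur_sym = s
                if rec_symbols:
                    if n_sym >= sym_cap:
                        sym_cap *= 2
                        tmp_t = np.empty(sym_cap)
                        tmp_t[:n_sym] = sym_t[:n_sym]
                        sym_t = tmp_t
                        tmp_c = np.empty(sym_cap, dtype=np.int8)
                        tmp_c[:n_sym] = sym_c[:n_sym]
                        sym_c = tmp_c
                    sym_t[n_sym] = t
                    sym_c[n_sym] = s
                    n_sym += 1
                if (s == SYM_H or s == SYM_L) and s != last_meta:
                    last_meta = s
                    n_entries += 1
                    if stop_entries > 0 and n_entries >= stop_entries:
                        break

        n_events += 1
        if n_events >= max_events:
            break

    return (
        t,
        x,
        n_events,
        n_entries,
        mode,
        ev_t[:n_ev].copy(),
        ev_k[:n_ev].copy(),
        ev_r[:n_ev].copy(),
        sym_t[:n_sym].copy(),
        sym_c[:n_sym].copy(),
        init_t[:n_init].copy(),
        init_tau[:n_init].copy(),
        init_r[:n_init].copy(),
        mode_t[:n_mode].copy(),
    )
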