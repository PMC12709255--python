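"""Compiled event loop for the next-subvolume-method simulator.

The lattice state lives in flat arrays over *accessible* voxels only.  Each
voxel carries counts of four species (free/bound x unbleached/bleached) and
a slot in an indexed binary min-heap keyed by its next-event time.  One
event is: pop the voxel with the minimal time, pick hop/bind/unbind by the
direct method, apply it, and resample fresh exponential waiting times for
the one or two voxels whose propensity changed (exact by memorylessness).

Species indices: 0 FREE_UNBLEACHED, 1 FREE_BLEACHED,
                 2 BOUND_UNBLEACHED, 3 BOUND_BLEACHED.
Counts are laid out (n_voxels, 4) so one voxel's species share a cache
line; the heap stores (time, voxel) pairs in parallel arrays so sift
comparisons read contiguous memory.
"""

import numpy as np
from numba import njit

INF = np.inf


# ---------------------------------------------------------------------------
# RNG: xorshift128+ with 53-bit uniform output; state is a uint64[2] array
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rand(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 = s1 ^ s0 ^ (s1 >> np.uint64(18)) ^ (s0 >> np.uint64(5))
    state[1] = s1
    x = s1 + s0
    return ((x >> np.uint64(11)) + np.uint64(1)) * 1.1102230246251564e-16  # (0,1]


@njit(cache=True, inline="always")
def _exp_rand(state, rate):
    if rate <= 0.0:
        return INF
    return -np.log(_rand(state)) / rate


# ---------------------------------------------------------------------------
# indexed binary min-heap: heap_t (keys), heap_v (voxel ids), pos (voxel->slot)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _sift_up(heap_t, heap_v, pos, i, tv, v):
    while i > 0:
        p = (i - 1) >> 2
        tp = heap_t[p]
        if tv < tp:
            vp = heap_v[p]
            heap_t[i] = tp
            heap_v[i] = vp
            pos[vp] = i
            i = p
        else:
            break
    heap_t[i] = tv
    heap_v[i] = v
    pos[v] = i


@njit(cache=True, inline="always")
def _sift_down(heap_t, heap_v, pos, i, n, tv, v):
    # 4-ary heap: children of i are 4i+1 .. 4i+4
    while True:
        base = 4 * i + 1
        if base >= n:
            break
        end = base + 4
        if end > n:
            end = n
        c = base
        tc = heap_t[base]
        for j in range(base + 1, end):
            tj = heap_t[j]
            if tj < tc:
                c = j
                tc = tj
        if tc < tv:
            vc = heap_v[c]
            heap_t[i] = tc
            heap_v[i] = vc
            pos[vc] = i
            i = c
        else:
            break
    heap_t[i] = tv
    heap_v[i] = v
    pos[v] = i


@njit(cache=True, inline="always")
def _update_time(heap_t, heap_v, pos, v, t, n):
    i = pos[v]
    if t < heap_t[i]:
        _sift_up(heap_t, heap_v, pos, i, t, v)
    else:
        _sift_down(heap_t, heap_v, pos, i, n, t, v)


@njit(cache=True)
def _heapify(heap_t, heap_v, pos):
    n = heap_t.shape[0]
    for i in range((n - 2) // 4, -1, -1):
        _sift_down(heap_t, heap_v, pos, i, n, heap_t[i], heap_v[i])


@njit(cache=True, inline="always")
def _propensity(counts, v, hop, n_open, kb_ves, ku):
    free = counts[v, 0] + counts[v, 1]
    bound = counts[v, 2] + counts[v, 3]
    return free * (hop * n_open[v] + kb_ves[v]) + bound * ku


@njit(cache=True)
def init_queue(counts, n_open, kb_ves, ku, hop, heap_t, heap_v, pos, t0, rng):
    n = heap_t.shape[0]
    for v in range(n):
        a = _propensity(counts, v, hop, n_open, kb_ves, ku)
        heap_t[v] = t0 + _exp_rand(rng, a)
        heap_v[v] = v
        pos[v] = v
    _heapify(heap_t, heap_v, pos)


@njit(cache=True)
def advance(counts, nb, wrapf, n_open, kb_ves, ku, hop,
            heap_t, heap_v, pos, rng,
            t_stop, bleach_mask, bleach_active, max_events):
    """Run events until the next event time exceeds ``t_stop``.

    Returns (current time clamped to t_stop, number of events executed).
    With ``bleach_active`` every unbleached free protein hopping onto a
    voxel with ``bleach_mask`` set is converted to its bleached species.
    Hops across the periodic axon boundary (wrap flag) convert bleached
    movers back to unbleached, mimicking exchange with a fresh reservoir.
    """
    nvox = heap_t.shape[0]
    t = t_stop
    n_events = 0
    while n_events < max_events:
        tv = heap_t[0]
        if tv > t_stop:
            return t_stop, n_events
        v = heap_v[0]
        t = tv
        # channel propensities in voxel v
        hr = hop * n_open[v]
        kv = kb_ves[v]
        fr = hr + kv
        a_free_u = counts[v, 0] * fr
        a_free_b = counts[v, 1] * fr
        a_unb_u = counts[v, 2] * ku
        a_unb_b = counts[v, 3] * ku
        atot = a_free_u + a_free_b + a_unb_u + a_unb_b
        if atot <= 0.0:
            _update_time(heap_t, heap_v, pos, v, INF, nvox)  # stale entry
            continue
        r = _rand(rng) * atot
        w = -1
        if r < a_free_u + a_free_b:
            s = 0
            if r >= a_free_u:
                s = 1
                r -= a_free_u
            # within-species split: hop with weight hr, bind with weight kv
            cnt = counts[v, s]
            if r < cnt * hr:
                # hop: reuse the uniform remainder to pick the open face
                u = r / (cnt * hr)
                j = int(u * n_open[v])
                if j >= n_open[v]:
                    j = n_open[v] - 1
                w = nb[v, j]
                s2 = s
                if wrapf[v, j] == 1 and s2 == 1:
                    s2 = 0  # reservoir exchange: bleached re-enters unbleached
                if bleach_active and bleach_mask[w] == 1 and s2 == 0:
                    s2 = 1  # enters the active laser spot
                counts[v, s] -= 1
                counts[w, s2] += 1
                a_v = atot - fr
            else:
                counts[v, s] -= 1
                counts[v, s + 2] += 1
                a_v = atot - fr + ku
        else:
            r -= a_free_u + a_free_b
            s = 2
            if r >= a_unb_u:
                s = 3
            counts[v, s] -= 1
            counts[v, s - 2] += 1
            a_v = atot - ku + fr
        # resample waiting times of affected voxels
        _update_time(heap_t, heap_v, pos, v, t + _exp_rand(rng, a_v), nvox)
        if w >= 0:
            a_w = _propensity(counts, w, hop, n_open, kb_ves, ku)
            _update_time(heap_t, heap_v, pos, w, t + _exp_rand(rng, a_w), nvox)
        n_events += 1
    return t, n_events
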