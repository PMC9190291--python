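"""Compiled inner loops for the approximate-majority network.

The batch resolver is the hot path of the agent-based model: every cell
division triggers two network resolutions, each a few hundred to a few
thousand reaction events. A numba-jitted kernel runs these event loops in
machine code; when numba is unavailable the module falls back to a
vectorised numpy engine that advances all unresolved replicates in
lockstep. Both engines simulate the embedded jump chain of the exact
stochastic simulation algorithm (reaction choice proportional to
mass-action propensity), which fully determines the absorption outcome
and event count; waiting times are irrelevant to either.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    numba = None
    HAVE_NUMBA = False


def _resolve_batch_py(ns, nr, nb, k_ds, k_dr, k_db, k_rs, k_rr, max_events, seed):
    np.random.seed(seed)
    n = ns.shape[0]
    winner_s = np.zeros(n, dtype=np.uint8)
    n_events = np.zeros(n, dtype=np.int64)
    for i in range(n):
        s = ns[i]
        r = nr[i]
        b = nb[i]
        ev = 0
        ok = True
        tie = False
        while not ((b == 0) and (s == 0 or r == 0)):
            a1 = k_ds * s * r
            a2 = k_dr * s * r
            a3 = k_db * s * r
            a4 = k_rs * b * s
            a5 = k_rr * b * r
            tot = a1 + a2 + a3 + a4 + a5
            if tot <= 0.0:
                tie = True  # all-b deadlock: a perfectly symmetric tie
                break
            u = np.random.random() * tot
            if u < a1:
                s -= 1
                b += 1
            elif u < a1 + a2:
                r -= 1
                b += 1
            elif u < a1 + a2 + a3:
                s -= 1
                r -= 1
                b += 2
            elif u < a1 + a2 + a3 + a4:
                b -= 1
                s += 1
            else:
                b -= 1
                r += 1
            ev += 1
            if ev >= max_events:
                ok = False
                break
        if not ok:
            n_events[i] = -1
        elif tie:
            n_events[i] = ev
            winner_s[i] = 1 if np.random.random() < 0.5 else 0
        else:
            n_events[i] = ev
            winner_s[i] = 1 if (r == 0 and b == 0 and s > 0) else 0
    return winner_s, n_events


if HAVE_NUMBA:
    _resolve_batch_jit = numba.njit(cache=True)(_resolve_batch_py)


def _resolve_batch_numpy(ns, nr, nb, k_ds, k_dr, k_db, k_rs, k_rr, max_events, rng):
    """Lockstep vectorised fallback: one reaction per active replicate per pass."""
    s = ns.astype(np.int64).copy()
    r = nr.astype(np.int64).copy()
    b = nb.astype(np.int64).copy()
    n = s.shape[0]
    n_events = np.zeros(n, dtype=np.int64)
    active = ~((b == 0) & ((s == 0) | (r == 0)))
    idx = np.nonzero(active)[0]
    ev = 0
    while idx.size:
        ev += 1
        if ev > max_events:
            n_events[idx] = -1
            break
        si, ri, bi = s[idx], r[idx], b[idx]
        cross = (si * ri).astype(np.float64)
        a = np.empty((5, idx.size))
        a[0] = k_ds * cross
        a[1] = k_dr * cross
        a[2] = k_db * cross
        a[3] = k_rs * bi * si
        a[4] = k_rr * bi * ri
        cum = np.cumsum(a, axis=0)
        tot = cum[-1]
        stuck = tot <= 0.0
        if stuck.any():
            # all-b deadlock: symmetric tie, resolved by a fair coin
            tied = idx[stuck]
            s[tied] = (rng.random(tied.size) < 0.5).astype(np.int64)
            r[tied] = 1 - s[tied]
            b[tied] = 0
            keep = ~stuck
            idx = idx[keep]
            if not idx.size:
                break
            cum = cum[:, keep]
            tot = tot[keep]
        u = rng.random(idx.size) * tot
        choice = (u[None, :] >= cum).sum(axis=0)
        s[idx] -= (choice == 0) | (choice == 2)
        r[idx] -= (choice == 1) | (choice == 2)
        b[idx] += np.select([choice <= 1, choice == 2], [1, 2], default=-1)
        s[idx] += choice == 3
        r[idx] += choice == 4
        n_events[idx] += 1
        done = (b[idx] == 0) & ((s[idx] == 0) | (r[idx] == 0))
        idx = idx[~done]
    winner_s = ((r == 0) & (b == 0) & (s > 0)).astype(np.uint8)
    winner_s[n_events < 0] = 0
    return winner_s, n_events


def resolve_batch(ns, nr, nb, rates_tuple, max_events, rng):
    """Resolve many network instances to absorption.

    Parameters are integer arrays of initial counts (one entry per
    replicate), the five mass-action rate constants, an event guard and a
    ``numpy.random.Generator`` supplying the randomness (a derived integer
    seed is handed to the compiled kernel).

    Returns ``(winner_s, n_events)``; ``n_events`` is -1 where the guard
    tripped.
    """
    ns = np.ascontiguousarray(ns, dtype=np.int64)
    nr = np.ascontiguousarray(nr, dtype=np.int64)
    nb = np.ascontiguousarray(nb, dtype=np.int64)
    k_ds, k_dr, k_db, k_rs, k_rr = (float(k) for k in rates_tuple)
    if HAVE_NUMBA:
        seed = int(rng.integers(0, 2**31 - 1))
        return _resolve_batch_jit(
            ns, nr, nb, k_ds, k_dr, k_db, k_rs, k_rr, int(max_events), seed
        )
    return _resolve_batch_numpy(
        ns, nr, nb, k_ds, k_dr, k_db, k_rs, k_rr, int(max_events), rng
    )
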