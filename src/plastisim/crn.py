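"""Approximate-majority chemical reaction network.

The network is the phenotype-decision switch of the bet-hedging model: a
cell division initialises it with ``s`` and ``r`` molecules (the two
phenotype "votes") and lets it run to absorption. The network amplifies
the initial majority into a consensus — all molecules end up as the
majority species — through a transient facilitating species ``b`` that
starts and ends at zero.

Five symmetric mass-action reactions are used, covering both canonical
demotion channels of the approximate-majority family:

    s + r -> r + b      (rate demote_s)
    s + r -> s + b      (rate demote_r)
    s + r -> b + b      (rate demote_both)
    b + s -> s + s      (rate recruit_s)
    b + r -> r + r      (rate recruit_r)

Every reaction conserves the total molecule count. Absorption is almost
always at one of the two consensus states; the one other dead state, an
all-b pool (reachable only through the both-demotion channel when the
network has drained to one molecule of each species), is perfectly
symmetric between s and r and is resolved as a fair-coin tie. The
default rates (1, 1, 0.5, 1, 1) are s<->r
symmetric — forcing an exact 50 % split for equal initial counts — and
were calibrated so the 100-molecule switch reproduces the reference
operating points of the bet-hedging model: a 53s/47r start resolves to
all-s with probability 0.753 and a 46s/54r start to all-r with
probability 0.819 (exact values from the embedded-chain linear solve,
see :func:`exact_phenotype_probability`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from ._kernels import resolve_batch

DEFAULT_MAX_EVENTS = 10**7


@dataclass(frozen=True)
class CRNRates:
    """Mass-action rate constants of the five reactions."""

    demote_s: float = 1.0
    demote_r: float = 1.0
    demote_both: float = 0.5
    recruit_s: float = 1.0
    recruit_r: float = 1.0

    def __post_init__(self) -> None:
        for name in ("demote_s", "demote_r", "demote_both", "recruit_s", "recruit_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name!r} must be non-negative")
        if self.recruit_s <= 0 or self.recruit_r <= 0:
            raise ValueError("recruitment rates must be positive (b must drain)")
        if self.demote_s + self.demote_r + self.demote_both <= 0:
            raise ValueError("at least one demotion channel must have positive rate")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.demote_s, self.demote_r, self.demote_both,
                self.recruit_s, self.recruit_r)


@dataclass(frozen=True)
class CRNState:
    """Molecule counts (s, r, b). Total count is conserved by every reaction."""

    n_s: int
    n_r: int
    n_b: int = 0

    def __post_init__(self) -> None:
        if min(self.n_s, self.n_r, self.n_b) < 0:
            raise ValueError("molecule counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_s + self.n_r + self.n_b

    @property
    def is_absorbing(self) -> bool:
        return self.n_b == 0 and (self.n_s == 0 or self.n_r == 0)


@dataclass(frozen=True)
class CRNOutcome:
    """Resolved absorbing state: winning phenotype, conserved total, event count."""

    winner: str  # "S" or "R"
    final_count: int
    n_events: int


@dataclass(frozen=True)
class ProbabilityEstimate:
    """Monte-Carlo estimate of the S-consensus probability with a Wilson CI."""

    p_s: float
    ci_low: float
    ci_high: float
    n_reps: int
    n_s_wins: int

    @property
    def p_r(self) -> float:
        return 1.0 - self.p_s


def _wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2.0)
    p = k / n
    denom = 1.0 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def resolve_crn(
    init: CRNState,
    rates: CRNRates | None = None,
    rng: np.random.Generator | None = None,
    max_events: int = DEFAULT_MAX_EVENTS,
    record_trajectory: bool = False,
):
    """Run one exact stochastic simulation to absorption.

    Event-by-event Gillespie direct method: exponential waiting times from
    the total propensity, reaction choice proportional to mass-action
    propensities. Returns a :class:`CRNOutcome`, or ``(outcome,
    trajectory)`` with the trajectory as an ``(n_events + 1, 3)`` integer
    array of (s, r, b) counts when ``record_trajectory`` is set.
    """
    rates = rates or CRNRates()
    rng = rng if rng is not None else np.random.default_rng()
    if init.total == 0:
        raise ValueError("empty molecular pool: total molecule count is zero")
    k_ds, k_dr, k_db, k_rs, k_rr = rates.as_tuple()
    s, r, b = init.n_s, init.n_r, init.n_b
    traj = [(s, r, b)] if record_trajectory else None
    ev = 0
    while not (b == 0 and (s == 0 or r == 0)):
        cross = s * r
        a = (k_ds * cross, k_dr * cross, k_db * cross, k_rs * b * s, k_rr * b * r)
        tot = sum(a)
        if tot <= 0.0:
            # all-b deadlock (reachable from s = r = 1 via the
            # both-demotion channel): a perfectly symmetric tie,
            # resolved by a fair coin
            winner = "S" if rng.random() < 0.5 else "R"
            outcome = CRNOutcome(winner=winner, final_count=init.total,
                                 n_events=ev)
            if record_trajectory:
                return outcome, np.asarray(traj, dtype=np.int64)
            return outcome
        rng.exponential(1.0 / tot)  # waiting time; drawn to keep the SSA exact
        u = rng.random() * tot
        if u < a[0]:
            s, b = s - 1, b + 1
        elif u < a[0] + a[1]:
            r, b = r - 1, b + 1
        elif u < a[0] + a[1] + a[2]:
            s, r, b = s - 1, r - 1, b + 2
        elif u < a[0] + a[1] + a[2] + a[3]:
            s, b = s + 1, b - 1
        else:
            r, b = r + 1, b - 1
        ev += 1
        if traj is not None:
            traj.append((s, r, b))
        if ev >= max_events:
            raise RuntimeError(f"network did not absorb within {max_events} events")
    outcome = CRNOutcome(winner="S" if s > 0 else "R",
                         final_count=s + r, n_events=ev)
    if record_trajectory:
        return outcome, np.asarray(traj, dtype=np.int64)
    return outcome


def resolve_crn_batch(
    n_s: np.ndarray,
    n_r: np.ndarray,
    n_b: np.ndarray | None = None,
    rates: CRNRates | None = None,
    rng: np.random.Generator | None = None,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> np.ndarray:
    """Resolve many network instances at once; returns a boolean all-s array."""
    rates = rates or CRNRates()
    rng = rng if rng is not None else np.random.default_rng()
    n_s = np.asarray(n_s, dtype=np.int64)
    n_r = np.asarray(n_r, dtype=np.int64)
    if n_b is None:
        n_b = np.zeros_like(n_s)
    n_b = np.asarray(n_b, dtype=np.int64)
    if (n_s + n_r + n_b <= 0).any():
        raise ValueError("every replicate needs at least one molecule")
    winner_s, n_events = resolve_batch(n_s, n_r, n_b, rates.as_tuple(),
                                       max_events, rng)
    if (n_events < 0).any():
        raise RuntimeError(f"a replicate did not absorb within {max_events} events")
    return winner_s.astype(bool)


def phenotype_probability(
    init: CRNState,
    rates: CRNRates | None = None,
    n_reps: int = 20_000,
    rng: np.random.Generator | None = None,
    confidence: float = 0.95,
) -> ProbabilityEstimate:
    """Monte-Carlo estimate of P(S consensus) from ``n_reps`` resolutions."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if init.total == 0:
        raise ValueError("empty molecular pool: total molecule count is zero")
    rng = rng if rng is not None else np.random.default_rng()
    ones = np.ones(n_reps, dtype=np.int64)
    wins = resolve_crn_batch(init.n_s * ones, init.n_r * ones, init.n_b * ones,
                             rates, rng)
    k = int(wins.sum())
    lo, hi = _wilson_interval(k, n_reps, confidence)
    return ProbabilityEstimate(p_s=k / n_reps, ci_low=lo, ci_high=hi,
                               n_reps=n_reps, n_s_wins=k)


def _fraction_to_count(fraction: float, total: int) -> int:
    # round half away from zero
    return int(math.floor(fraction * total + 0.5))


def probability_curve(
    total: int,
    fraction_grid: Sequence[float],
    rates: CRNRates | None = None,
    n_reps: int = 20_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """P(S consensus) as a function of the initial s-molecule fraction.

    Returns a DataFrame sorted by fraction with columns ``s_fraction,
    s_count, r_count, p_S, ci_low, ci_high, n_reps``. The endpoints 0 and
    1 are consensus states already, so their probabilities are exact.
    """
    if total < 2:
        raise ValueError("total must be at least 2")
    fractions = sorted(float(f) for f in fraction_grid)
    if not fractions:
        raise ValueError("fraction_grid is empty")
    if fractions[0] < 0.0 or fractions[-1] > 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    for f in fractions:
        n_s = _fraction_to_count(f, total)
        n_r = total - n_s
        if n_s == 0 or n_r == 0:
            p, lo, hi = (float(n_s > 0),) * 3
        else:
            est = phenotype_probability(CRNState(n_s, n_r, 0), rates, n_reps, rng)
            p, lo, hi = est.p_s, est.ci_low, est.ci_high
        rows.append((f, n_s, n_r, p, lo, hi, n_reps))
    return pd.DataFrame(rows, columns=["s_fraction", "s_count", "r_count",
                                       "p_S", "ci_low", "ci_high", "n_reps"])


def exact_phenotype_probability(init: CRNState, rates: CRNRates | None = None) -> float:
    """Exact P(S consensus) by linear solve over the embedded Markov chain.

    Enumerates all states of the conserved-total lattice and solves the
    first-step equations with a sparse direct solver. Practical up to a
    few hundred molecules; independent of the stochastic engines.
    """
    rates = rates or CRNRates()
    if init.total == 0:
        raise ValueError("empty molecular pool: total molecule count is zero")
    k_ds, k_dr, k_db, k_rs, k_rr = rates.as_tuple()
    n = init.total
    index: dict[tuple[int, int], int] = {}
    for s in range(n + 1):
        for r in range(n + 1 - s):
            index[(s, r)] = len(index)
    size = len(index)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros(size)
    for (s, r), i in index.items():
        b = n - s - r
        cross = s * r
        channels = (
            (k_ds * cross, (-1, 0)),
            (k_dr * cross, (0, -1)),
            (k_db * cross, (-1, -1)),
            (k_rs * b * s, (1, 0)),
            (k_rr * b * r, (0, 1)),
        )
        tot = sum(a for a, _ in channels)
        rows.append(i)
        cols.append(i)
        vals.append(1.0)
        if tot <= 0.0:
            if b > 0:  # all-b deadlock: fair-coin tie
                rhs[i] = 0.5
            else:
                rhs[i] = 1.0 if (r == 0 and s > 0) else 0.0
            continue
        for a, (ds, dr) in channels:
            if a > 0:
                rows.append(i)
                cols.append(index[(s + ds, r + dr)])
                vals.append(-a / tot)
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(size, size))
    solution = spsolve(mat, rhs)
    return float(solution[index[(init.n_s, init.n_r)]])
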