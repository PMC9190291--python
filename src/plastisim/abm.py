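"""Agent-based bet-hedging population model under pulsed therapy.

An isogenic population of cells carries one of two phenotypes: fast-growing
drug-sensitive ``S`` or slow-growing drug-resistant ``R``. At every division
each daughter's phenotype is decided independently by running the
approximate-majority network (:mod:`plastisim.crn`) seeded with the cell
line's fixed *genotype* molecules — g_s copies of s and g_r copies of r —
plus, when phenotypic memory is enabled, the molecules inherited from the
parent.

Memory works as follows: after a daughter's network resolves, the absorbed
molecule pool (all of the winning species) is retained as the daughter's
molecular store. The store decays exponentially over the cell's lifetime
(binomial thinning at division time), is split in half between the two
daughters, and each half is added to the genotype molecules before the
daughters' networks are run. Fast-dividing cells therefore pass on large
stores and tend to reproduce their parent's phenotype; slow-dividing cells
revert toward the genotype-only baseline.

Therapy is a train of drug pulses that kill only S cells. The discrete-time
scheduler applies, per step and per cell: therapy kill, baseline death,
then logistic-gated division.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import math

import numpy as np
import pandas as pd

from .crn import CRNRates, CRNState, resolve_crn, resolve_crn_batch

__all__ = [
    "Genotype", "Cell", "TherapySchedule", "ABMConfig", "PopulationTrace",
    "RegimeThresholds", "decide_daughter_phenotype", "decay_store",
    "split_store", "step_population", "run_abm", "classify_regime",
]

REGIMES = ("persister", "tissue_preservation", "hybrid_growth", "extinct")


@dataclass(frozen=True)
class Genotype:
    """Fixed s/r molecule counts contributed to the decision network per division."""

    g_s: int
    g_r: int

    def __post_init__(self) -> None:
        if self.g_s < 0 or self.g_r < 0:
            raise ValueError("genotype molecule counts must be non-negative")
        if self.g_s + self.g_r < 1:
            raise ValueError("genotype must contribute at least one molecule")


@dataclass
class Cell:
    """Agent state. The store always holds the phenotype's own species,
    because the decision network absorbs to an all-winner pool."""

    phenotype: str  # "S" or "R"
    store_count: int
    birth_time: float

    @property
    def store_species(self) -> str:
        return "s" if self.phenotype == "S" else "r"


@dataclass(frozen=True)
class TherapySchedule:
    """Pulsed drug schedule; the drug kills only S cells while on."""

    n_pulses: int = 6
    pulse_duration: float = 10.0
    inter_pulse_gap: float = 20.0
    start_time: float = 50.0
    kill_probability_S: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.kill_probability_S <= 1.0:
            raise ValueError("kill_probability_S must be in [0, 1]")
        if self.n_pulses < 0 or self.pulse_duration < 0 or self.inter_pulse_gap < 0:
            raise ValueError("schedule durations must be non-negative")

    def drug_on(self, t: float) -> bool:
        if self.n_pulses == 0 or t < self.start_time:
            return False
        period = self.pulse_duration + self.inter_pulse_gap
        elapsed = t - self.start_time
        pulse_index = int(elapsed // period) if period > 0 else 0
        if pulse_index >= self.n_pulses:
            return False
        return (elapsed - pulse_index * period) < self.pulse_duration

    @property
    def end_time(self) -> float:
        if self.n_pulses == 0:
            return self.start_time
        period = self.pulse_duration + self.inter_pulse_gap
        return self.start_time + (self.n_pulses - 1) * period + self.pulse_duration


@dataclass(frozen=True)
class ABMConfig:
    genotype: Genotype = field(default_factory=lambda: Genotype(53, 47))
    memory_enabled: bool = False
    decay_rate_s: float = 0.0
    decay_rate_r: float = 0.0
    division_probability_S: float = 0.3
    division_probability_R: float = 0.1
    carrying_capacity: int = 5_000
    baseline_death_probability: float = 0.01
    initial_population: int = 500
    time_step: float = 1.0
    horizon: float = 260.0
    seed: int = 0
    crn_rates: CRNRates = field(default_factory=CRNRates)

    def __post_init__(self) -> None:
        for name in ("division_probability_S", "division_probability_R",
                     "baseline_death_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.division_probability_S <= self.division_probability_R:
            raise ValueError("S must divide faster than R "
                             "(division_probability_S > division_probability_R)")
        for name in ("decay_rate_s", "decay_rate_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.carrying_capacity < 1 or self.initial_population < 1:
            raise ValueError("population sizes must be positive")
        if self.time_step <= 0 or self.horizon <= 0:
            raise ValueError("time_step and horizon must be positive")


@dataclass
class PopulationTrace:
    """Recorded population time series plus outcome annotations."""

    frame: pd.DataFrame  # columns: t, n_S, n_R, n_total, drug_on
    extinction_time: float | None = None
    regime: str | None = None

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def extinct(self) -> bool:
        return self.extinction_time is not None


def decay_store(count: int, elapsed: float, rate: float,
                rng: np.random.Generator) -> int:
    """Binomial thinning: each molecule survives with probability exp(-rate*elapsed)."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if rate < 0 or elapsed < 0:
        raise ValueError("rate and elapsed must be non-negative")
    if count == 0:
        return 0
    p = math.exp(-rate * elapsed)
    if p >= 1.0:
        return int(count)
    return int(rng.binomial(count, p))


def split_store(count: int, rng: np.random.Generator) -> tuple[int, int]:
    """Halve a parent's store; an odd molecule goes to a random daughter."""
    if count < 0:
        raise ValueError("count must be non-negative")
    low, high = count // 2, count - count // 2
    if low != high and rng.random() < 0.5:
        return high, low
    return low, high


def decide_daughter_phenotype(
    inherited: tuple[str | None, int],
    genotype: Genotype,
    rates: CRNRates | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, int]:
    """Resolve one daughter's phenotype from genotype plus inherited molecules.

    ``inherited`` is ``(species, count)`` with species ``"s"``, ``"r"`` or
    ``None``. Returns ``(phenotype, store_count)`` where the store is the
    absorbed total (= g_s + g_r + inherited count).
    """
    species, count = inherited
    if count < 0:
        raise ValueError("inherited count must be non-negative")
    if species not in (None, "s", "r"):
        raise ValueError("inherited species must be 's', 'r' or None")
    n_s = genotype.g_s + (count if species == "s" else 0)
    n_r = genotype.g_r + (count if species == "r" else 0)
    outcome = resolve_crn(CRNState(n_s, n_r, 0), rates, rng)
    return outcome.winner, outcome.final_count


# ---------------------------------------------------------------------------
# scheduler internals: arrays of (is_s, store, birth_time) for speed
# ---------------------------------------------------------------------------

def _seed_population(config: ABMConfig, rng: np.random.Generator):
    n = config.initial_population
    g = config.genotype
    wins = resolve_crn_batch(np.full(n, g.g_s), np.full(n, g.g_r),
                             rates=config.crn_rates, rng=rng)
    store = np.full(n, g.g_s + g.g_r, dtype=np.int64)
    birth = np.zeros(n)
    return wins.copy(), store, birth


def _step_arrays(is_s, store, birth, config: ABMConfig,
                 schedule: TherapySchedule, t: float, rng: np.random.Generator):
    dt = config.time_step
    n = is_s.size
    if n == 0:
        return is_s, store, birth
    alive = np.ones(n, dtype=bool)
    # 1) therapy kill (S cells only)
    if schedule.drug_on(t):
        doomed = is_s & (rng.random(n) < schedule.kill_probability_S)
        alive &= ~doomed
    # 2) baseline death
    alive &= rng.random(n) >= config.baseline_death_probability
    is_s, store, birth = is_s[alive], store[alive], birth[alive]
    n = is_s.size
    if n == 0:
        return is_s, store, birth
    # 3) logistic-gated division
    crowding = max(0.0, 1.0 - n / config.carrying_capacity)
    p_div = np.where(is_s, config.division_probability_S,
                     config.division_probability_R) * crowding
    divides = rng.random(n) < p_div
    n_div = int(divides.sum())
    if n_div == 0:
        return is_s, store, birth
    g = config.genotype
    t_next = t + dt
    if config.memory_enabled:
        parent_is_s = is_s[divides]
        elapsed = t_next - birth[divides]
        rate = np.where(parent_is_s, config.decay_rate_s, config.decay_rate_r)
        surviving = rng.binomial(store[divides],
                                 np.exp(-rate * elapsed)).astype(np.int64)
        half_a = surviving // 2
        odd = surviving - 2 * half_a
        extra = odd * (rng.random(n_div) < 0.5)
        half_a = half_a + extra
        half_b = surviving - half_a
        halves = np.concatenate([half_a, half_b])
        daughters_parent_s = np.concatenate([parent_is_s, parent_is_s])
        ns0 = g.g_s + np.where(daughters_parent_s, halves, 0)
        nr0 = g.g_r + np.where(daughters_parent_s, 0, halves)
    else:
        ns0 = np.full(2 * n_div, g.g_s, dtype=np.int64)
        nr0 = np.full(2 * n_div, g.g_r, dtype=np.int64)
    wins = resolve_crn_batch(ns0, nr0, rates=config.crn_rates, rng=rng)
    keep = ~divides
    new_is_s = np.concatenate([is_s[keep], wins])
    new_store = np.concatenate([store[keep], ns0 + nr0])
    new_birth = np.concatenate([birth[keep], np.full(2 * n_div, t_next)])
    return new_is_s, new_store, new_birth


def step_population(
    population: Sequence[Cell],
    config: ABMConfig,
    schedule: TherapySchedule,
    t: float,
    rng: np.random.Generator,
) -> tuple[list[Cell], dict]:
    """Advance the population one step; returns (new population, step record)."""
    is_s = np.array([c.phenotype == "S" for c in population], dtype=bool)
    store = np.array([c.store_count for c in population], dtype=np.int64)
    birth = np.array([c.birth_time for c in population], dtype=float)
    is_s, store, birth = _step_arrays(is_s, store, birth, config, schedule, t, rng)
    cells = [Cell("S" if s else "R", int(c), float(b))
             for s, c, b in zip(is_s, store, birth)]
    record = {
        "t": t + config.time_step,
        "n_S": int(is_s.sum()),
        "n_R": int(is_s.size - is_s.sum()),
        "n_total": int(is_s.size),
        "drug_on": schedule.drug_on(t),
    }
    return cells, record


def run_abm(
    config: ABMConfig,
    schedule: TherapySchedule | None = None,
    rng: np.random.Generator | None = None,
) -> PopulationTrace:
    """Run the full simulation and record the population time series.

    The trace has one row per recorded time (0, dt, 2dt, ...); ``drug_on``
    on a row states whether the drug acted during the step *ending* at
    that row's time. The run stops early at extinction.
    """
    schedule = schedule or TherapySchedule()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    is_s, store, birth = _seed_population(config, rng)
    dt = config.time_step
    n_steps = int(round(config.horizon / dt))
    rows = [(0.0, int(is_s.sum()), int(is_s.size - is_s.sum()),
             int(is_s.size), False)]
    extinction_time = None
    for k in range(n_steps):
        t = k * dt
        is_s, store, birth = _step_arrays(is_s, store, birth, config,
                                          schedule, t, rng)
        total = int(is_s.size)
        rows.append((t + dt, int(is_s.sum()), total - int(is_s.sum()),
                     total, schedule.drug_on(t)))
        if total == 0:
            extinction_time = t + dt
            break
    frame = pd.DataFrame(rows, columns=["t", "n_S", "n_R", "n_total", "drug_on"])
    return PopulationTrace(frame=frame, extinction_time=extinction_time)


@dataclass(frozen=True)
class RegimeThresholds:
    """Decision thresholds for the qualitative regime taxonomy."""

    tissue_min_fraction: float = 0.5   # on-treatment minimum vs pre-treatment level
    hybrid_growth_factor: float = 1.5  # net growth across the treatment window
    hybrid_peak_tolerance: float = 0.05  # slack on inter-pulse peak growth


def classify_regime(trace: PopulationTrace,
                    thresholds: RegimeThresholds | None = None) -> str:
    """Label a trace as persister / tissue_preservation / hybrid_growth / extinct.

    Deterministic rules, applied in order: *extinct* if the population hits
    zero; *hybrid_growth* if the population grows monotonically through the
    pulse train — successive inter-pulse recovery peaks are non-decreasing
    within tolerance and the treatment window ends above the pre-treatment
    level by the growth factor (the within-pulse transient is not held
    against monotone growth); *tissue_preservation* if the on-treatment
    minimum stays above half the pre-treatment level; *persister*
    otherwise (deep on-treatment kills with off-treatment recovery).
    """
    th = thresholds or RegimeThresholds()
    frame = trace.frame
    if frame.empty:
        raise ValueError("empty trace")
    total = frame["n_total"].to_numpy()
    if trace.extinct or (total == 0).any():
        return "extinct"
    on = frame["drug_on"].to_numpy()
    if not on.any():
        # never treated: flat-at-capacity traces read as preserved tissue
        return "tissue_preservation"
    first_on = int(np.argmax(on))
    last_on = len(on) - 1 - int(np.argmax(on[::-1]))
    pre_level = float(total[max(0, first_on - 1)])
    window = total[first_on:last_on + 1].astype(float)
    # recovery peaks: max census in each off-drug stretch between pulses
    # (the first-pulse transient and the mid-pulse window end are not
    # peaks; the net-growth condition handles the endpoint level)
    off = ~on[first_on:last_on + 1]
    fence = np.diff(np.concatenate([[0], off.astype(int), [0]]))
    run_starts = np.flatnonzero(fence == 1)
    run_ends = np.flatnonzero(fence == -1) - 1
    peaks_arr = np.asarray([float(window[a:b + 1].max())
                            for a, b in zip(run_starts, run_ends)])
    growing = bool(peaks_arr.size < 2 or
                   (peaks_arr[1:] >= (1.0 - th.hybrid_peak_tolerance)
                    * np.maximum.accumulate(peaks_arr)[:-1]).all())
    net_growth = window[-1] / max(pre_level, 1.0)
    if growing and net_growth >= th.hybrid_growth_factor:
        return "hybrid_growth"
    if window.min() > th.tissue_min_fraction * pre_level:
        return "tissue_preservation"
    return "persister"
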