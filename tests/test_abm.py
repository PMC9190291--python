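"""Tests for the bet-hedging agent-based model and its building blocks."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastisim.abm import (ABMConfig, Cell, Genotype, PopulationTrace,
                           RegimeThresholds, TherapySchedule, classify_regime,
                           decay_store, decide_daughter_phenotype, run_abm,
                           split_store, step_population)
from plastisim.crn import CRNState, phenotype_probability


class TestDecayStore:
    def test_zero_rate_preserves_all_molecules(self, rng):
        assert decay_store(100, elapsed=37.0, rate=0.0, rng=rng) == 100

    def test_huge_rate_reduces_to_memoryless_limit(self, rng):
        assert decay_store(100, elapsed=1.0, rate=1e6, rng=rng) == 0

    def test_binomial_moments(self, rng):
        # survival probability p = exp(-r t); mean 100 p, variance 100 p(1-p)
        r, t, n0, reps = 0.05, 10.0, 100, 4_000
        p = math.exp(-r * t)
        draws = np.array([decay_store(n0, t, r, rng) for _ in range(reps)])
        se_mean = math.sqrt(n0 * p * (1 - p) / reps)
        assert abs(draws.mean() - n0 * p) < 4 * se_mean
        assert draws.var() == pytest.approx(n0 * p * (1 - p), rel=0.2)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            decay_store(-1, 1.0, 0.1, rng)
        with pytest.raises(ValueError):
            decay_store(10, -1.0, 0.1, rng)
        with pytest.raises(ValueError):
            decay_store(10, 1.0, -0.1, rng)


class TestSplitStore:
    def test_even_count_splits_exactly(self, rng):
        assert split_store(20, rng) == (10, 10)
        assert split_store(0, rng) == (0, 0)

    def test_odd_remainder_assigned_randomly_and_sum_conserved(self, rng):
        firsts = [split_store(21, rng) for _ in range(2_000)]
        assert all(a + b == 21 and {a, b} == {10, 11} for a, b in firsts)
        mean_first = np.mean([a for a, _ in firsts])
        assert mean_first == pytest.approx(10.5, abs=0.05)

    def test_negative_rejected(self, rng):
        with pytest.raises(ValueError):
            split_store(-1, rng)


class TestDaughterDecision:
    def test_store_is_absorbed_total(self, rng):
        phen, store = decide_daughter_phenotype(("s", 10), Genotype(53, 47),
                                                rng=rng)
        assert store == 53 + 47 + 10
        assert phen in ("S", "R")

    def test_inherited_s_molecules_bias_toward_s(self, rng):
        # (53+10)s / 47r must beat the genotype-only baseline
        n = 8_000
        biased = phenotype_probability(CRNState(63, 47), n_reps=n, rng=rng)
        base = phenotype_probability(CRNState(53, 47), n_reps=n, rng=rng)
        assert biased.ci_low > base.ci_high

    def test_inherited_r_molecules_bias_toward_r(self, rng):
        n = 8_000
        biased = phenotype_probability(CRNState(53, 57), n_reps=n, rng=rng)
        base = phenotype_probability(CRNState(53, 47), n_reps=n, rng=rng)
        assert 1 - biased.ci_high > 1 - base.ci_low  # p_R above baseline

    def test_invalid_inherited_rejected(self, rng):
        with pytest.raises(ValueError):
            decide_daughter_phenotype(("s", -1), Genotype(53, 47), rng=rng)
        with pytest.raises(ValueError):
            decide_daughter_phenotype(("x", 1), Genotype(53, 47), rng=rng)


class TestTherapySchedule:
    def test_pulse_train_timing(self):
        sch = TherapySchedule(n_pulses=2, pulse_duration=10, inter_pulse_gap=20,
                              start_time=50)
        assert not sch.drug_on(49.9)
        assert sch.drug_on(50.0) and sch.drug_on(59.9)
        assert not sch.drug_on(60.0) and not sch.drug_on(79.9)
        assert sch.drug_on(80.0) and not sch.drug_on(90.0)
        assert sch.end_time == 90.0

    def test_no_pulses_means_never_on(self):
        sch = TherapySchedule(n_pulses=0)
        assert not any(sch.drug_on(t) for t in np.arange(0, 300, 7.0))


class TestStepPopulation:
    def test_certain_kill_extinguishes_sensitive_only_population(self, rng):
        cfg = ABMConfig(initial_population=1, baseline_death_probability=0.0)
        sch = TherapySchedule(start_time=0.0, kill_probability_S=1.0)
        pop = [Cell("S", 100, 0.0)]
        new, record = step_population(pop, cfg, sch, t=0.0, rng=rng)
        assert new == [] and record["n_total"] == 0

    def test_division_blocked_at_carrying_capacity(self, rng):
        cfg = ABMConfig(carrying_capacity=3, initial_population=3,
                        baseline_death_probability=0.0,
                        division_probability_S=1.0, division_probability_R=0.5)
        sch = TherapySchedule(n_pulses=0)
        pop = [Cell("S", 100, 0.0)] * 3
        new, record = step_population(pop, cfg, sch, t=0.0, rng=rng)
        assert record["n_total"] == 3

    def test_memoryless_daughters_follow_genotype_distribution(self, rng):
        # all cells divide once; daughter S fraction must match the
        # genotype-only network probability
        cfg = ABMConfig(genotype=Genotype(53, 47), memory_enabled=False,
                        carrying_capacity=10**9, initial_population=1,
                        baseline_death_probability=0.0,
                        division_probability_S=1.0,
                        division_probability_R=0.999)
        sch = TherapySchedule(n_pulses=0)
        pop = [Cell("S", 100, 0.0)] * 2_000 + [Cell("R", 100, 0.0)] * 2_000
        new, record = step_population(pop, cfg, sch, t=0.0, rng=rng)
        assert record["n_total"] >= 7_900  # p_R < 1, so a few parents persist
        frac_s = record["n_S"] / record["n_total"]
        expected = phenotype_probability(CRNState(53, 47), n_reps=20_000,
                                         rng=rng).p_s
        assert abs(frac_s - expected) < 4 * math.sqrt(0.25 / 8_000) + 0.01


class TestRunABM:
    def test_same_seed_gives_bit_identical_trace(self):
        cfg = ABMConfig(initial_population=100, carrying_capacity=500,
                        horizon=40.0, seed=7)
        sch = TherapySchedule(start_time=10.0, n_pulses=2)
        a = run_abm(cfg, sch, np.random.default_rng(7))
        b = run_abm(cfg, sch, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_trace_invariants(self):
        cfg = ABMConfig(initial_population=100, carrying_capacity=500,
                        horizon=40.0)
        trace = run_abm(cfg, TherapySchedule(start_time=10.0),
                        np.random.default_rng(3))
        f = trace.frame
        assert (f["n_total"] == f["n_S"] + f["n_R"]).all()
        assert (f["n_total"] >= 0).all()
        assert f["t"].iloc[-1] == 40.0 or trace.extinct

    def test_fast_decay_matches_memoryless_model(self):
        # decay >> 1/lifetime leaves no inherited molecules, so the
        # memory model must collapse onto the memoryless one
        def s_fraction(memory, decay, seed):
            cfg = ABMConfig(genotype=Genotype(53, 47), memory_enabled=memory,
                            decay_rate_s=decay, decay_rate_r=decay,
                            initial_population=200, carrying_capacity=1_000,
                            horizon=50.0)
            tr = run_abm(cfg, TherapySchedule(n_pulses=0),
                         np.random.default_rng(seed))
            f = tr.frame
            return (f["n_S"] / f["n_total"]).tail(20).mean()

        a = np.array([s_fraction(True, 1e3, s) for s in range(8)])
        b = np.array([s_fraction(False, 0.0, 100 + s) for s in range(8)])
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_daughter_store_species_matches_phenotype(self, rng):
        # invariant by construction: the network absorbs to an all-winner
        # pool, so a daughter's store is always its own species
        phen, store = decide_daughter_phenotype(("r", 12), Genotype(53, 47),
                                                rng=rng)
        cell = Cell(phen, store, 0.0)
        assert cell.store_species == ("s" if phen == "S" else "r")


def _trace(rows):
    frame = pd.DataFrame(rows, columns=["t", "n_S", "n_R", "n_total", "drug_on"])
    return PopulationTrace(frame=frame)


class TestClassifyRegime:
    def test_population_hitting_zero_is_extinct(self):
        tr = _trace([(0, 5, 5, 10, False), (1, 0, 0, 0, True)])
        tr.extinction_time = 1.0
        assert classify_regime(tr) == "extinct"

    def test_constant_trace_at_capacity_is_tissue_preservation(self):
        rows = [(t, 500, 500, 1000, 10 <= t < 20) for t in range(30)]
        assert classify_regime(_trace(rows)) == "tissue_preservation"

    def test_deep_kill_with_recovery_is_persister(self):
        rows = ([(t, 900, 100, 1000, False) for t in range(10)]
                + [(10 + t, 20, 100, 120, True) for t in range(5)]
                + [(15 + t, 800, 100, 900, False) for t in range(10)])
        assert classify_regime(_trace(rows)) == "persister"

    def test_growth_through_pulses_is_hybrid(self):
        rows = [(0, 90, 10, 100, False)]
        n = 100
        for t in range(1, 40):
            on = (t // 5) % 2 == 1
            n = int(n * (0.95 if on else 1.25))
            rows.append((t, 0, n, n, on))
        assert classify_regime(_trace(rows)) == "hybrid_growth"

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            classify_regime(PopulationTrace(frame=pd.DataFrame(
                columns=["t", "n_S", "n_R", "n_total", "drug_on"])))


class TestConfigValidation:
    def test_slow_growing_resistant_enforced(self):
        with pytest.raises(ValueError):
            ABMConfig(division_probability_S=0.1, division_probability_R=0.3)

    def test_genotype_needs_molecules(self):
        with pytest.raises(ValueError):
            Genotype(0, 0)


@given(st.integers(0, 10_000))
def test_split_store_partitions_any_count(count):
    rng = np.random.default_rng(count)
    a, b = split_store(count, rng)
    assert a + b == count and abs(a - b) <= 1 and a >= 0
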