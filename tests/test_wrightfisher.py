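"""Wright-Fisher dilution model: closed forms, drift theory, determinism."""

import numpy as np
import pytest

from mitobottleneck import (
    ExtinctionError,
    LineageState,
    SimParams,
    bottleneck_size,
    copy_number_schedule,
    evolve_generation,
    mutation_pmf,
    nk_baseline,
    nk_params,
    simulate_cellset,
    simulate_lineage,
)
from mitobottleneck.wrightfisher import drift_replicates

U_DEFAULT = 1e-7 * 16_569


class TestBottleneckSize:
    @pytest.mark.parametrize(
        "N0,alpha,Td,expected",
        [
            (500, 1.0, 30, 500.0),  # alpha = 1 identity
            (500, 0.37, 0, 500.0),  # no dilution divisions
            (500, 0.9, 10, 174.34),  # closed form N0 * alpha**Td
            (300, 0.9, 10, 104.60),
        ],
    )
    def test_closed_form(self, N0, alpha, Td, expected):
        assert bottleneck_size(N0, alpha, Td) == pytest.approx(expected, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bottleneck_size(500, 1.5, 10)
        with pytest.raises(ValueError):
            bottleneck_size(500, 0.9, -1)

    @pytest.mark.parametrize("alpha,Td", [(0.9, 10), (0.8, 15), (0.85, 25), (1.0, 5)])
    def test_trajectory_matches_closed_form_within_rounding(self, alpha, Td):
        params = SimParams(N0=500, alpha=alpha, Td=Td, Ta=Td + 5)
        schedule = copy_number_schedule(params)
        assert abs(schedule[Td - 1] - bottleneck_size(500, alpha, Td)) <= Td / 2
        # recovery and constant phase sit at N0
        assert (schedule[Td:] == 500).all()


class TestMutationPmf:
    def test_zero_mutations_is_exp_minus_u(self):
        # u = mu * L = 1e-7 * 16569
        assert mutation_pmf(U_DEFAULT, 0) == pytest.approx(0.9983445, abs=1e-7)
        assert mutation_pmf(2.0, 0) == pytest.approx(np.exp(-2.0))

    def test_normalization(self):
        total = mutation_pmf(0.7, np.arange(50)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mutation_pmf(-1.0, 0)


class TestEvolveGeneration:
    def test_mutation_free_stays_mutation_free_without_influx(self):
        rng = np.random.default_rng(0)
        state = LineageState(N=100)
        nxt = evolve_generation(state, 37, u=0.0, rng=rng)
        assert nxt.counts.size == 0 and nxt.N == 37

    def test_fixed_mutation_remains_fixed(self):
        rng = np.random.default_rng(1)
        state = LineageState(N=50, ids=[7], counts=[50])
        for next_N in (20, 80, 500):
            state = evolve_generation(state, next_N, u=0.0, rng=rng)
            assert state.registry == {7: next_N}

    def test_extinction_raises(self):
        with pytest.raises(ExtinctionError):
            evolve_generation(LineageState(N=10), 0, 0.0, np.random.default_rng(0))

    def test_neutral_drift_is_a_martingale(self):
        # offspring frequency of a 30% variant: mean within 3 SE of 0.3
        rng = np.random.default_rng(42)
        N = 50
        freqs = rng.binomial(N, 0.3, size=10_000) / N
        se = freqs.std(ddof=1) / np.sqrt(freqs.size)
        # same quantity through evolve_generation, one generation
        sim = np.array(
            [
                evolve_generation(
                    LineageState(N=N, ids=[0], counts=[15]), N, 0.0, rng
                ).counts.sum()
                for _ in range(10_000)
            ]
        ) / N
        assert abs(sim.mean() - 0.3) < 3 * se


class TestSimulateLineage:
    def test_no_mutation_rate_gives_empty_vafs(self):
        params = SimParams(alpha=0.9, Td=10, Ta=20, mu=0.0, seed=3)
        assert simulate_lineage(params).size == 0

    def test_alpha_one_keeps_copy_number_constant(self):
        params = SimParams(alpha=1.0, Td=10, Ta=15)
        assert (copy_number_schedule(params) == 500).all()

    def test_kernel_agrees_with_pure_python_reference(self):
        """Mean segregating-mutation count: compiled cohort kernel vs the
        independent numpy/evolve_generation path, within 3 SE."""
        params = SimParams(
            N0=60, alpha=0.8, Td=6, Ta=12, mu=2e-6, n_cells=400, seed=9
        )
        cellset = simulate_cellset(params)
        kernel_mean = len(cellset.vaf) / params.n_cells
        rng = np.random.default_rng(1234)
        counts = np.array(
            [simulate_lineage(params, rng).size for _ in range(400)]
        )
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        # kernel cells are iid too; combine SEs conservatively
        assert abs(kernel_mean - counts.mean()) < 3 * np.sqrt(2) * max(se, 1e-3)


class TestCellset:
    def test_single_cell(self):
        params = SimParams(alpha=0.9, Td=5, Ta=10, n_cells=1, seed=2)
        cs = simulate_cellset(params)
        assert cs.n_cells == 1 and len(cs.per_cell()) == 1

    def test_seeded_determinism(self):
        params = SimParams(alpha=0.85, Td=15, Ta=25, n_cells=100, seed=77)
        a, b = simulate_cellset(params), simulate_cellset(params)
        assert np.array_equal(a.cell_index, b.cell_index)
        assert np.array_equal(a.vaf, b.vaf)

    def test_extinction_guard(self):
        with pytest.raises(ExtinctionError):
            simulate_cellset(SimParams(N0=10, alpha=0.3, Td=10, Ta=12, n_cells=2))

    def test_vafs_in_unit_interval(self):
        cs = simulate_cellset(SimParams(alpha=0.8, Td=10, Ta=20, n_cells=200, seed=5))
        assert cs.vaf.min() > 0 and cs.vaf.max() <= 1.0


class TestDriftTheory:
    def test_heterozygosity_decay(self):
        # E[H_t] = H_0 (1 - 1/N)^t at constant N
        N, t, reps = 50, 20, 10_000
        final = drift_replicates(N, c0=25, n_gen=t, n_reps=reps, seed=11)
        p = final / N
        h = 2 * p * (1 - p)
        expected = 0.5 * (1 - 1 / N) ** t
        se = h.std(ddof=1) / np.sqrt(reps)
        assert abs(h.mean() - expected) < 3 * se

    def test_fixation_probability_is_one_over_n(self):
        N, reps = 20, 10_000
        final = drift_replicates(N, c0=1, n_gen=600, n_reps=reps, seed=13)
        assert np.isin(final, [0, N]).all(), "some replicates not absorbed"
        p_fix = (final == N).mean()
        se = np.sqrt((1 / N) * (1 - 1 / N) / reps)
        assert abs(p_fix - 1 / N) < 3 * se

    def test_bottleneck_accelerates_absorption(self):
        """A standing 10% variant is absorbed (fixed or lost) more often
        through a bottleneck (alpha=0.8, Td=10) than at constant N."""
        rng = np.random.default_rng(21)
        reps = 1500

        def absorbed_fraction(alpha, Td):
            params = SimParams(N0=500, alpha=alpha, Td=Td, Ta=20)
            schedule = copy_number_schedule(params)
            hits = 0
            for _ in range(reps):
                state = LineageState(N=500, ids=[0], counts=[50])
                for next_N in schedule:
                    state = evolve_generation(state, int(next_N), 0.0, rng)
                total = state.counts.sum()
                hits += total == 0 or total == state.N
            return hits / reps

        assert absorbed_fraction(0.8, 10) > absorbed_fraction(1.0, 0)


class TestParams:
    def test_nk_baseline_scaling(self):
        assert nk_baseline() == 300  # 500 * 0.6
        assert nk_params().N0 == 300

    def test_u_is_mu_times_l(self):
        assert SimParams().u == pytest.approx(U_DEFAULT)

    def test_nb_property(self):
        p = SimParams(alpha=0.85, Td=15, Ta=25)
        assert p.Nb == pytest.approx(43.7, abs=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"alpha": 1.2},
            {"Td": -1},
            {"Td": 20, "Ta": 10},
            {"n_cells": 0},
            {"mu": -1e-9},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs)
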