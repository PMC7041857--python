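import math

import numpy as np
import pytest

from landflat import (
    BiasPotential,
    DEFAULT_LADDER,
    EnergyMatrix,
    SamplerConfig,
    SequenceSpace,
    enumerate_exact,
    metropolis_accept,
    propose_move,
    random_state,
    remc_swap_accept,
    run_mc,
    run_remc,
)
from landflat.sampler import PopulationTable


def tvd(freq, exact):
    return 0.5 * sum(abs(freq.get(s, 0.0) - p) for s, p in exact.items())


class TestMetropolisAccept:
    def test_downhill_always_accepted(self):
        assert metropolis_accept(-1.0, 1.0, 0.999999)
        assert metropolis_accept(0.0, 1.0, 0.999999)

    def test_uphill_threshold_is_exponential(self):
        # at dE = kT the acceptance probability is exactly e^{-1}
        assert metropolis_accept(1.0, 1.0, math.exp(-1) - 1e-12)
        assert not metropolis_accept(1.0, 1.0, math.exp(-1) + 1e-12)

    def test_empirical_acceptance_rate(self, rng):
        u = rng.random(200_000)
        rate = np.mean([metropolis_accept(1.0, 1.0, x) for x in u])
        assert rate == pytest.approx(math.exp(-1), abs=4 * 0.0011)


class TestRemcSwapAccept:
    def test_equal_energies_always_swap(self):
        assert remc_swap_accept(5.0, 5.0, 1.0, 2.0, 0.999999)

    def test_directional_closed_forms(self):
        # (1/1 - 1/2)(2 - 0) = 1 -> always accept
        assert remc_swap_accept(2.0, 0.0, 1.0, 2.0, 0.999999)
        # (1/1 - 1/2)(0 - 2) = -1 -> accept with probability e^{-1}
        assert remc_swap_accept(0.0, 2.0, 1.0, 2.0, math.exp(-1) - 1e-12)
        assert not remc_swap_accept(0.0, 2.0, 1.0, 2.0, math.exp(-1) + 1e-12)

    def test_equal_temperatures_rejected(self):
        with pytest.raises(ValueError):
            remc_swap_accept(0.0, 1.0, 1.0, 1.0, 0.5)


class TestProposeMove:
    def test_move_mix_zero_touches_one_position(self, two_pos_space, rng):
        for _ in range(100):
            s = random_state(two_pos_space, rng)
            assert len(propose_move(s, two_pos_space, 0.0, rng)) == 1

    def test_single_position_only_toggles_rotamer(self, rng):
        space = SequenceSpace([1], [["A"]], 2)
        s = random_state(space, rng)
        seen = set()
        for _ in range(50):
            ((pos, t, r),) = propose_move(s, space, 0.5, rng)
            assert (pos, t) == (1, "A")
            seen.add(r)
        assert seen == {0, 1}

    def test_proposals_uniform_over_combos(self, rng):
        space = SequenceSpace([1, 2], [["A", "C"], ["A", "C", "D"]], 2)
        s = random_state(space, rng)
        n = 100_000
        counts = {}
        for _ in range(n):
            move = propose_move(s, space, 0.0, rng)
            pos, t, r = move[0]
            counts[(pos, t, r)] = counts.get((pos, t, r), 0) + 1
        # position uniform, then (type, rotamer) uniform within position
        for (pos, t, r), c in counts.items():
            ncomb = sum(space.rotamers_at(pos, u) for u in space.types_at(pos))
            p = 0.5 / ncomb
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(c - n * p) < 3.5 * sigma, (pos, t, r)


class TestRunMc:
    def test_flat_landscape_uniform(self, rng):
        space = SequenceSpace([1, 2], [["A", "C"], ["A", "C"]], 2)
        m = EnergyMatrix(space)
        cfg = SamplerConfig(kT=1.0, n_steps=400_000, seed=3, record_interval=1)
        pop = run_mc(m, None, cfg)
        n = pop.total
        for s, c in pop.counts.items():
            p = 0.25
            sigma = math.sqrt(n * p * (1 - p))
            # correlated samples: allow 4 sigma on 3x-inflated scale
            assert abs(c - n * p) < 12 * sigma, s

    def test_two_state_boltzmann_ratio(self):
        space = SequenceSpace([1], [["A", "C"]], 1)
        m = EnergyMatrix(space)
        m.set_diag(1, "C", 0, 1.0)
        cfg = SamplerConfig(kT=1.0, n_steps=500_000, seed=7, record_interval=1)
        pop = run_mc(m, None, cfg)
        ratio = pop.counts["A"] / pop.counts["C"]
        assert ratio == pytest.approx(math.e, rel=0.05)

    def test_same_seed_reproduces_table(self, toy_apo):
        cfg = SamplerConfig(kT=0.8, n_steps=50_000, seed=99)
        assert run_mc(toy_apo, None, cfg).counts == run_mc(toy_apo, None, cfg).counts

    def test_matches_exact_boltzmann_marginals(self, toy_apo):
        cfg = SamplerConfig(kT=1.0, n_steps=1_000_000, seed=5, record_interval=1)
        pop = run_mc(toy_apo, None, cfg)
        ex = enumerate_exact(toy_apo, kT=1.0)
        assert tvd(pop.frequencies(), ex.boltzmann) < 0.02

    def test_biased_sampling_matches_biased_oracle(self, toy_apo, rng):
        bias = BiasPotential(toy_apo.space)
        bias._single += rng.uniform(0, 1.5, size=bias._single.shape)
        cfg = SamplerConfig(kT=1.0, n_steps=1_000_000, seed=6, record_interval=1)
        pop = run_mc(toy_apo, bias, cfg)
        ex = enumerate_exact(toy_apo, bias, kT=1.0)
        assert tvd(pop.frequencies(), ex.boltzmann) < 0.02

    def test_bias_space_mismatch_rejected(self, toy_apo):
        other = SequenceSpace([1, 2], [["A", "C"], ["A", "C"]], 1)
        with pytest.raises(ValueError, match="different spaces"):
            run_mc(toy_apo, BiasPotential(other), SamplerConfig(n_steps=10))

    def test_block_counts_partition_total(self, toy_apo):
        cfg = SamplerConfig(kT=1.0, n_steps=40_000, seed=2)
        pop = run_mc(toy_apo, None, cfg, n_blocks=4)
        assert len(pop.block_counts) == 4
        merged = {}
        for blk in pop.block_counts:
            for s, c in blk.items():
                merged[s] = merged.get(s, 0) + c
        assert merged == pop.counts


class TestRemc:
    def test_default_ladder_constants(self):
        assert DEFAULT_LADDER == (0.17, 0.26, 0.39, 0.59, 0.88, 1.33, 2.0, 3.0)
        assert len(SamplerConfig().ladder) == 8

    def test_single_rung_reduces_to_run_mc(self, toy_apo):
        cfg = SamplerConfig(kT=0.8, n_steps=30_000, seed=4, ladder=(0.8,))
        (pop,) = run_remc(toy_apo, None, cfg)
        ref = run_mc(toy_apo, None, cfg.replace(kT=0.8))
        assert pop.counts == ref.counts

    def test_rung_marginals_match_single_temperature(self):
        space = SequenceSpace([1], [["A", "C"]], 1)
        m = EnergyMatrix(space)
        m.set_diag(1, "C", 0, 1.0)
        cfg = SamplerConfig(
            n_steps=300_000, seed=8, record_interval=1,
            ladder=(0.59, 1.0, 2.0), swap_interval=500,
        )
        tables = run_remc(m, None, cfg)
        for kT, pop in zip(cfg.ladder, tables):
            single = run_mc(m, None, cfg.replace(kT=kT, seed=81))
            fa = pop.counts.get("A", 0) / pop.total
            fb = single.counts.get("A", 0) / single.total
            assert abs(fa - fb) < 0.03, kT

    def test_remc_reproducible(self, toy_apo):
        cfg = SamplerConfig(n_steps=20_000, seed=13, ladder=(0.5, 1.0))
        a = run_remc(toy_apo, None, cfg)
        b = run_remc(toy_apo, None, cfg)
        assert [t.counts for t in a] == [t.counts for t in b]


class TestPopulationTable:
    def test_total_must_match_counts(self):
        with pytest.raises(ValueError, match="total"):
            PopulationTable({"AA": 5}, total=4)

    def test_tsv_round_trip(self, tmp_path, toy_apo):
        cfg = SamplerConfig(kT=0.8, n_steps=20_000, seed=1)
        pop = run_mc(toy_apo, None, cfg, stage_label="stage1")
        path = tmp_path / "pop.tsv"
        pop.to_tsv(path)
        back = PopulationTable.from_tsv(path)
        assert back.counts == pop.counts
        assert back.kT_recorded == pop.kT_recorded
        assert back.stage_label == "stage1"
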