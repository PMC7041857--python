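import math

import numpy as np
import pytest

from landflat import (
    BiasPotential,
    EnergyMatrix,
    SamplerConfig,
    SequenceSpace,
    bias_energy,
    enumerate_exact,
    flatness_report,
    increment,
    run_flattening,
    update_bias,
)
from landflat.sampler import PopulationTable


@pytest.fixture
def space2():
    return SequenceSpace([1, 2], [["A", "C", "D"], ["A", "C", "D"]], 1)


class TestBiasEnergy:
    def test_zero_bias_everywhere(self, space2):
        b = BiasPotential(space2)
        for seq in space2.sequences():
            assert bias_energy(b, seq) == 0.0

    def test_hand_sum_single_terms(self, space2):
        b = BiasPotential(space2)
        b._single[0, 0] = 0.3  # position 1, type A
        b._single[1, 1] = 0.1  # position 2, type C
        assert bias_energy(b, "AC") == pytest.approx(0.4)

    def test_matches_double_loop_with_pair_terms(self, space2, rng):
        b = BiasPotential(space2, pair_terms=True)
        b._single[:] = rng.uniform(0, 1, b._single.shape)
        b._pair[:] = rng.uniform(0, 1, b._pair.shape)
        for seq in space2.sequences():
            idx = [space2.allowed_types[k].index(t) for k, t in enumerate(seq)]
            expected = sum(b._single[k, idx[k]] for k in range(2))
            expected += b._pair[0, 1, idx[0], idx[1]]
            assert bias_energy(b, seq) == pytest.approx(expected, abs=1e-12)

    def test_unknown_type_rejected(self, space2):
        with pytest.raises(KeyError):
            bias_energy(BiasPotential(space2), "AW")

    def test_separable_when_pair_terms_disabled(self, space2, rng):
        b = BiasPotential(space2, pair_terms=False)
        b._single[:] = rng.uniform(0, 2, b._single.shape)
        for seq in space2.sequences():
            parts = sum(b.single_term(p, t) for p, t in zip(space2.positions, seq))
            assert bias_energy(b, seq) == pytest.approx(parts, abs=1e-12)


class TestIncrement:
    def test_fresh_term_increment_is_e0(self, space2):
        b = BiasPotential(space2)  # e0 = 0.2, E0 = 50 defaults
        assert increment(b, 1, "A") == pytest.approx(0.2)

    def test_tempered_increment_at_E0(self, space2):
        b = BiasPotential(space2)
        b._single[0, 0] = 50.0
        assert increment(b, 1, "A") == pytest.approx(0.2 * math.exp(-1), abs=1e-9)

    def test_large_E0_limit_is_constant(self, space2):
        b = BiasPotential(space2, E0=1e12)
        b._single[0, 0] = 40.0
        assert increment(b, 1, "A") == pytest.approx(0.2, abs=1e-9)


class TestUpdateBias:
    def test_first_update_adds_e0_to_each_position(self, space2):
        b = BiasPotential(space2)
        update_bias(b, "AC")
        assert b.single_term(1, "A") == pytest.approx(0.2)
        assert b.single_term(2, "C") == pytest.approx(0.2)

    def test_second_update_follows_recurrence(self, space2):
        b = BiasPotential(space2)
        update_bias(b, "AC")
        update_bias(b, "AC")
        assert b.single_term(1, "A") == pytest.approx(
            0.2 + 0.2 * math.exp(-0.2 / 50), abs=1e-9
        )
        assert b.single_term(1, "A") == pytest.approx(0.399201, abs=1e-6)

    def test_untouched_types_stay_zero(self, space2):
        b = BiasPotential(space2)
        for _ in range(5):
            update_bias(b, "AC")
        assert b.single_term(1, "C") == 0.0
        assert b.single_term(1, "D") == 0.0
        assert b.single_term(2, "A") == 0.0

    def test_well_tempered_recurrence_exact(self, space2):
        """n consecutive updates match b_{n+1} = b_n + e0 exp(-b_n/E0)."""
        b = BiasPotential(space2, e0=0.2, E0=50.0)
        expected = 0.0
        for _ in range(50):
            update_bias(b, "AA")
            expected = expected + 0.2 * math.exp(-expected / 50.0)
            assert b.single_term(1, "A") == pytest.approx(expected, abs=1e-12)

    def test_pair_terms_updated_together(self, space2):
        b = BiasPotential(space2, pair_terms=True)
        update_bias(b, "AD")
        assert b.pair_term(1, 2, "A", "D") == pytest.approx(0.2)
        assert b.pair_term(2, 1, "D", "A") == pytest.approx(0.2)  # symmetric view
        assert b.pair_term(1, 2, "A", "A") == 0.0

    def test_terms_never_decrease(self, space2, rng):
        b = BiasPotential(space2, pair_terms=True)
        prev_s, prev_p = b._single.copy(), b._pair.copy()
        seqs = list(space2.sequences())
        for _ in range(200):
            update_bias(b, seqs[rng.integers(len(seqs))])
            assert np.all(b._single >= prev_s)
            assert np.all(b._pair >= prev_p)
            prev_s, prev_p = b._single.copy(), b._pair.copy()


class TestSerialization:
    def test_round_trip_bit_exact(self, space2, tmp_path, rng):
        b = BiasPotential(space2, e0=0.11, E0=17.0, update_period=250,
                          pair_terms=True)
        b._single[:] = rng.uniform(0, 3, b._single.shape)
        b._pair[0, 1] = rng.uniform(0, 1, b._pair[0, 1].shape)
        path = tmp_path / "bias.txt"
        b.save(path)
        back = BiasPotential.load(path, space2)
        assert back.e0 == b.e0 and back.E0 == b.E0
        assert back.update_period == b.update_period
        assert np.array_equal(back._single, b._single)
        assert np.array_equal(back._pair, b._pair)


class TestFlatnessReport:
    def test_uniform_counts_give_unit_ratios(self, space2):
        counts = {s: 10 for s in space2.sequences()}
        pop = PopulationTable(counts, total=90)
        rep = flatness_report(pop, space2)
        assert all(r == pytest.approx(1.0) for r in rep.ratios.values())

    def test_unvisited_type_flagged_as_zero(self, space2):
        counts = {s: 10 for s in space2.sequences() if not s.startswith("D")}
        pop = PopulationTable(counts, total=sum(counts.values()))
        assert flatness_report(pop, space2).ratios[1] == 0.0

    def test_skewed_counts_hand_computed(self, space2):
        pop = PopulationTable({"AA": 60, "CA": 30, "DA": 10}, total=100)
        rep = flatness_report(pop, space2)
        m = rep.marginals
        row = m[(m.position == 1) & (m.type == "A")].iloc[0]
        assert row.frequency == pytest.approx(0.6)
        assert rep.ratios[1] == pytest.approx(10 / 60)
        assert rep.ratios[2] == pytest.approx(0.0)  # C, D never seen at pos 2

    def test_empty_table_rejected(self, space2):
        with pytest.raises(ValueError, match="empty"):
            flatness_report(PopulationTable({}, 0), space2)


class TestRunFlattening:
    def test_zero_energy_matrix_already_flat(self, space2):
        m = EnergyMatrix(space2)
        cfg = SamplerConfig(kT=0.59, n_steps=500_000, seed=2, record_interval=1)
        bias, pop = run_flattening(m, cfg, adapt_steps=3_000_000)
        rep = flatness_report(pop, space2)
        assert rep.min_ratio > 0.8
        # flat landscape needs no differential bias beyond adaptation jitter
        spread = np.ptp(bias._single, axis=1)
        assert np.all(spread < 0.15)

    def test_two_state_bias_approaches_negative_free_energy_gap(self):
        space = SequenceSpace([1], [["A", "C"]], 1)
        m = EnergyMatrix(space)
        m.set_diag(1, "C", 0, 1.0)  # apo free-energy gap = 1 kcal/mol
        cfg = SamplerConfig(kT=0.59, n_steps=400_000, seed=3, record_interval=1)
        bias, _ = run_flattening(m, cfg, adapt_steps=1_500_000)
        gap = bias.single_term(1, "A") - bias.single_term(1, "C")
        assert gap == pytest.approx(1.0, abs=0.1)

    def test_flatness_improves_on_rugged_landscape(self, toy_apo):
        cfg = SamplerConfig(kT=0.59, n_steps=300_000, seed=4, record_interval=1)
        from landflat import run_mc

        before = flatness_report(run_mc(toy_apo, None, cfg), toy_apo.space)
        bias, pop = run_flattening(toy_apo, cfg, adapt_steps=1_000_000)
        after = flatness_report(pop, toy_apo.space)
        assert after.min_ratio > before.min_ratio
        assert after.min_ratio >= 0.2

    def test_biased_populations_match_biased_oracle(self, toy_apo):
        cfg = SamplerConfig(kT=0.59, n_steps=600_000, seed=5, record_interval=1)
        bias, pop = run_flattening(toy_apo, cfg, adapt_steps=600_000)
        ex = enumerate_exact(toy_apo, bias, kT=0.59)
        t = 0.5 * sum(
            abs(pop.frequencies().get(s, 0.0) - p) for s, p in ex.boltzmann.items()
        )
        assert t < 0.03
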