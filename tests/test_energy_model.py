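import math

import numpy as np
import pytest

from landflat import (
    EnergyMatrix,
    MatrixFormatError,
    SequenceSpace,
    StateAssignment,
    count_sequences,
    delta_energy,
    load_energy_matrix,
    save_energy_matrix,
    total_energy,
)
from landflat.energy_model import matrix_to_json
from landflat.metrs import anl_design_space, metamp_design_space
from landflat.sampler import propose_move, random_state

from conftest import brute_force_total


class TestSequenceSpace:
    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SequenceSpace([1, 1], [["A"], ["C"]], 1)

    def test_empty_type_set_rejected(self):
        with pytest.raises(ValueError, match="no allowed types"):
            SequenceSpace([1], [[]], 1)

    def test_zero_rotamers_rejected(self):
        with pytest.raises(ValueError, match="rotamer"):
            SequenceSpace([1], [["A"]], 0)

    def test_flexible_positions_are_single_type(self, two_pos_space):
        space = SequenceSpace([1], [["A", "C"]], 2, flexible={9: ("W", 3)})
        assert space.types_at(9) == ("W",)
        assert space.rotamers_at(9, "W") == 3
        assert space.all_positions == (1, 9)
        # flexible positions do not enter the sequence projection
        assert space.n_sequences == 2

    @pytest.mark.parametrize(
        "space,expected",
        [
            (anl_design_space(), 14**3),  # 2744 sequences
            (metamp_design_space(), 18**3),  # 5832 sequences
            (SequenceSpace([1], [["A"]], 1), 1),
        ],
    )
    def test_count_sequences(self, space, expected):
        assert count_sequences(space) == expected

    def test_sequence_index_matches_iteration_order(self, two_pos_space):
        for i, s in enumerate(two_pos_space.sequences()):
            assert two_pos_space.sequence_index(s) == i


class TestTotalEnergy:
    def test_all_zero_matrix(self, two_pos_space):
        m = EnergyMatrix(two_pos_space)
        s = StateAssignment({1: "A", 2: "C"}, {1: 0, 2: 1})
        assert total_energy(m, s) == 0.0

    def test_hand_sum(self):
        space = SequenceSpace([1, 2], [["A"], ["C"]], 1)
        m = EnergyMatrix(space)
        m.set_diag(1, "A", 0, 1.0)
        m.set_diag(2, "C", 0, 2.0)
        m.set_pair(1, "A", 0, 2, "C", 0, -0.5)
        s = StateAssignment({1: "A", 2: "C"}, {1: 0, 2: 0})
        assert total_energy(m, s) == pytest.approx(2.5)

    def test_matches_brute_force_on_random_states(self, toy_apo, rng):
        for _ in range(20):
            s = random_state(toy_apo.space, rng)
            assert total_energy(toy_apo, s) == pytest.approx(
                brute_force_total(toy_apo, s), abs=1e-12
            )

    def test_invariant_to_pair_storage_order(self, toy_apo, rng):
        shuffled = EnergyMatrix(
            toy_apo.space,
            toy_apo.state_label,
            dict(toy_apo.diag),
            # reversed insertion order and swapped key orientation
            {(b, a): e for (a, b), e in reversed(list(toy_apo.pair.items()))},
        )
        s = random_state(toy_apo.space, rng)
        assert total_energy(shuffled, s) == pytest.approx(
            total_energy(toy_apo, s), abs=1e-12
        )

    def test_inconsistent_assignment_rejected(self, two_pos_space):
        m = EnergyMatrix(two_pos_space)
        bad = StateAssignment({1: "W", 2: "C"}, {1: 0, 2: 0})
        with pytest.raises(ValueError, match="not allowed"):
            total_energy(m, bad)


class TestDeltaEnergy:
    def test_null_move_is_zero(self, toy_apo, rng):
        s = random_state(toy_apo.space, rng)
        pos = toy_apo.space.positions[0]
        move = [(pos, s.type_at[pos], s.rotamer_at[pos])]
        assert delta_energy(toy_apo, s, move) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("move_mix", [0.0, 1.0])
    def test_matches_full_recompute(self, toy_apo, rng, move_mix):
        for _ in range(50):
            s = random_state(toy_apo.space, rng)
            move = propose_move(s, toy_apo.space, move_mix, rng)
            after = s.replace(move)
            assert delta_energy(toy_apo, s, move) == pytest.approx(
                total_energy(toy_apo, after) - total_energy(toy_apo, s), abs=1e-9
            )

    def test_reverse_move_cancels(self, toy_apo, rng):
        for _ in range(30):
            s = random_state(toy_apo.space, rng)
            move = propose_move(s, toy_apo.space, 0.5, rng)
            reverse = [
                (pos, s.type_at[pos], s.rotamer_at[pos]) for pos, _, _ in move
            ]
            after = s.replace(move)
            assert delta_energy(toy_apo, s, move) + delta_energy(
                toy_apo, after, reverse
            ) == pytest.approx(0.0, abs=1e-9)

    def test_three_position_move_rejected(self, toy_apo, rng):
        s = random_state(toy_apo.space, rng)
        move = [(p, s.type_at[p], s.rotamer_at[p]) for p in toy_apo.space.positions]
        with pytest.raises(ValueError, match="1 or 2"):
            delta_energy(toy_apo, s, move)


class TestFileFormat:
    def test_minimal_identity_case(self, tmp_path):
        path = tmp_path / "min.mat"
        path.write_text("STATE apo\nPOSITION 1 MUTABLE A=1\nDIAG 1 A 0 0\n")
        m = load_energy_matrix(path)
        assert count_sequences(m.space) == 1
        assert m.diag_energy(1, "A", 0) == 0.0

    def test_round_trip_full_precision(self, toy_pair, tmp_path):
        for k, m in enumerate(toy_pair):
            path = tmp_path / f"m{k}.mat"
            save_energy_matrix(m, path)
            back = load_energy_matrix(path)
            assert back.state_label == m.state_label
            for key in set(m.diag) | set(back.diag):
                assert back.diag.get(key, 0.0) == pytest.approx(
                    m.diag.get(key, 0.0), abs=1e-10
                )
            for key in set(m.pair) | set(back.pair):
                assert back.pair.get(key, 0.0) == pytest.approx(
                    m.pair.get(key, 0.0), abs=1e-10
                )

    def test_json_round_trip(self, toy_apo, tmp_path):
        import json

        path = tmp_path / "m.json"
        path.write_text(json.dumps(matrix_to_json(toy_apo)))
        back = load_energy_matrix(path)
        assert back.diag == pytest.approx(toy_apo.diag)

    def test_rotamer_out_of_range_names_line(self, tmp_path):
        path = tmp_path / "bad.mat"
        path.write_text(
            "STATE x\nPOSITION 1 MUTABLE A=2\nDIAG 1 A 0 0.5\nDIAG 1 A 2 0.5\n"
        )
        with pytest.raises(MatrixFormatError, match="line 4.*rotamer index 2"):
            load_energy_matrix(path)

    def test_non_finite_energy_rejected(self, tmp_path):
        path = tmp_path / "inf.mat"
        path.write_text("POSITION 1 MUTABLE A=1\nDIAG 1 A 0 inf\n")
        with pytest.raises(MatrixFormatError, match="non-finite"):
            load_energy_matrix(path)

    def test_unknown_record_rejected(self, tmp_path):
        path = tmp_path / "odd.mat"
        path.write_text("POSITION 1 MUTABLE A=1\nTRIPLE 1 A 0 0\n")
        with pytest.raises(MatrixFormatError, match="line 2.*TRIPLE"):
            load_energy_matrix(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_energy_matrix(tmp_path / "absent.mat")
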