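"""Gap-cost limits from score autocorrelation and final two-sided costs."""

import numpy as np
import pytest

from helpers import brute_characteristic_values, brute_gap_cost_limits

from coma import BuildParams, SearchConfig, build_gap_model, build_profile
from coma.gaps import (characteristic_values, final_gap_costs,
                       gap_cost_limits, top_max_scores, widen_z1, widen_z2)


class TestTopMaxScores:
    def test_single_row_top_w(self):
        mat = np.array([[3.0, 9.0, 1.0, 7.0, 5.0]])
        np.testing.assert_array_equal(top_max_scores(mat, axis=0, w=4),
                                      [[9.0, 7.0, 5.0, 3.0]])

    def test_all_equal_matrix_gives_constant_sequences(self):
        mat = np.full((3, 5), 2.5)
        np.testing.assert_array_equal(top_max_scores(mat, axis=1, w=4),
                                      np.full((5, 4), 2.5))

    def test_padding_repeats_smallest_kept(self):
        mat = np.array([[4.0, 2.0]])
        np.testing.assert_array_equal(top_max_scores(mat, axis=0, w=4),
                                      [[4.0, 2.0, 2.0, 2.0]])

    def test_matches_sort_oracle_on_random_matrix(self):
        rng = np.random.default_rng(31)
        mat = rng.normal(size=(10, 10))
        got = top_max_scores(mat, axis=0, w=4)
        for i in range(10):
            np.testing.assert_array_equal(got[i], np.sort(mat[i])[::-1][:4])


class TestCharacteristicValues:
    def test_constant_maxima_fixed_point(self):
        vals = characteristic_values(np.full((3, 4), 2.0), z=0.0)
        np.testing.assert_allclose(vals, 2.0)

    def test_two_maxima_hand_enumeration(self):
        # products {4*4, 4*2, 2*2}: sqrt(28/3)
        val = characteristic_values(np.array([[4.0, 2.0]]), z=0.0)
        assert val[0] == pytest.approx(np.sqrt(28 / 3), abs=1e-9)

    def test_z_strictly_increases_positive_maxima(self):
        maxima = np.array([[3.0, 2.0, 1.0, 0.5]])
        v0 = characteristic_values(maxima, z=0.0)[0]
        v1 = characteristic_values(maxima, z=1.0)[0]
        assert v1 > v0

    def test_negative_maxima_give_zero(self):
        assert characteristic_values(np.full((1, 4), -3.0))[0] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(32)
        maxima = rng.normal(size=(20, 4))
        for z in (0.0, 0.7, 2.0):
            np.testing.assert_allclose(
                characteristic_values(maxima, z),
                brute_characteristic_values(maxima, z), atol=1e-9)


class TestGapCostLimits:
    def test_zero_characteristic_values_give_zero_limits(self):
        assert (gap_cost_limits(np.zeros(10), omega=4) == 0).all()

    def test_constant_values_are_fixed_point(self):
        np.testing.assert_allclose(gap_cost_limits(np.full(10, 3.0), 4),
                                   3.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(33)
        char = rng.uniform(0, 5, size=50)
        for omega, z in [(4, 0.0), (4, 1.5), (3, 0.0), (6, 0.5)]:
            np.testing.assert_allclose(
                gap_cost_limits(char, omega, z),
                brute_gap_cost_limits(char, omega, z), atol=1e-9)

    def test_limits_nonnegative_and_monotone_in_z(self):
        rng = np.random.default_rng(34)
        char = rng.normal(1.0, 2.0, size=30)
        prev = gap_cost_limits(char, 4, 0.0)
        assert (prev >= 0).all()
        for z in (0.5, 1.0, 2.0, 5.0):
            cur = gap_cost_limits(char, 4, z)
            assert (cur >= prev - 1e-12).all()
            prev = cur


class TestWidening:
    def test_z1_vanishes_for_large_H(self):
        assert widen_z1(1e12) == pytest.approx(0.0, abs=1e-5)

    def test_z1_inverse_sqrt(self):
        assert widen_z1(4.0, zeta=2.0) == pytest.approx(1.0)

    def test_z2_substitution(self):
        assert widen_z2(1e-4, x=0.0, y=1.0) == pytest.approx(
            1.0 / (4 * np.log(10)), abs=1e-6)

    def test_z2_monotone_narrowing_with_significance(self):
        assert widen_z2(0.5) > widen_z2(1e-6)

    def test_z2_clamps_at_singularity(self):
        assert widen_z2(1.5, x=0.0, z_max=10.0) == 10.0
        assert widen_z2(np.exp(-0.5), x=0.5, z_max=10.0) == 10.0


class TestFinalGapCosts:
    def test_no_indel_signal_gives_full_limits(self):
        A, B = np.array([3.0, 2.0]), np.array([1.0, 4.0])
        zeros2 = np.zeros(2)
        G, C = final_gap_costs(A, B, zeros2, zeros2, zeros2, zeros2)
        np.testing.assert_allclose(G, A[:, None] * np.ones((2, 2)))
        np.testing.assert_allclose(C, B[None, :] * np.ones((2, 2)))

    def test_full_indel_signal_gives_zero_cost(self):
        A, B = np.array([3.0]), np.array([4.0])
        ones1 = np.ones(1)
        G, C = final_gap_costs(A, B, ones1, ones1, ones1, ones1, c_del=0.6)
        assert G[0, 0] == pytest.approx(0.0)
        assert C[0, 0] == pytest.approx(0.0)

    def test_deletion_weight_reduced_by_c_del(self):
        A, B = np.array([1.0]), np.array([1.0])
        zero1, half = np.zeros(1), np.full(1, 0.5)
        G_del, _ = final_gap_costs(A, B, half, zero1, zero1, zero1, 0.6)
        G_ins, _ = final_gap_costs(A, B, zero1, zero1, zero1, half, 0.6)
        assert (1 - G_del[0, 0]) == pytest.approx(0.6 * (1 - G_ins[0, 0]))

    def test_costs_bounded_by_limits(self):
        rng = np.random.default_rng(35)
        A, B = rng.uniform(0, 5, 6), rng.uniform(0, 5, 7)
        D1, I1 = rng.uniform(0, 1, 6), rng.uniform(0, 1, 6)
        D2, I2 = rng.uniform(0, 1, 7), rng.uniform(0, 1, 7)
        G, C = final_gap_costs(A, B, D1, I1, D2, I2)
        assert ((G >= 0) & (G <= A[:, None] + 1e-12)).all()
        assert ((C >= 0) & (C <= B[None, :] + 1e-12)).all()


class TestGapModelOnProfiles:
    def test_conserved_positions_cost_more_than_variable(self, table):
        from coma import MultipleAlignment
        from coma.pairscore import build_pair_system

        rng = np.random.default_rng(36)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        conserved = np.tile(np.array(list("ACDEFWKRHY" * 3)), (30, 1))
        variable = aa[rng.integers(0, 20, size=(30, 20))]
        rows = ["".join(r)
                for r in np.concatenate([conserved, variable], axis=1)]
        msa = MultipleAlignment(
            sequence_ids=[f"s{i}" for i in range(30)], rows=rows)
        prof = build_profile(msa, table, BuildParams(seg=False))
        cfg = SearchConfig()
        system = build_pair_system(prof, prof, cfg)
        gm = build_gap_model(system.scores, prof, prof, cfg, z=0.0)
        n_cons = 30
        assert gm.G[:n_cons].mean() > gm.G[n_cons:].mean()

    def test_two_pass_z_values_widen_then_narrow(self, profile_pair):
        cfg = SearchConfig()
        from coma.pairscore import build_pair_system
        system = build_pair_system(*profile_pair, cfg)
        z1 = widen_z1(system.H, cfg.zeta, cfg.z_max)
        assert z1 > 0
        gm = build_gap_model(system.scores, *profile_pair, cfg, z=z1)
        assert (gm.G >= -1e-12).all() and (gm.C >= -1e-12).all()
        assert (gm.G <= gm.A[:, None] + 1e-9).all()
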