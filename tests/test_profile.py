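"""Profile construction: weighting, frequencies, pseudocounts, indels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coma import BuildParams, MultipleAlignment, build_profile
from coma.alphabet import AA_INDEX, CHAR_TO_CODE, N_AA
from coma.profile import (composition_adjust_profile, deletion_probabilities,
                          henikoff_weights, insertion_probabilities,
                          observed_frequencies, reduced_alignment,
                          relative_entropy, target_probabilities,
                          thickness_adjust)
from coma.karlin import solve_lambda


def _msa(rows):
    return MultipleAlignment(
        sequence_ids=[f"s{i}" for i in range(len(rows))], rows=rows)


def _codes(rows):
    return np.array([[CHAR_TO_CODE[c] for c in row] for row in rows],
                    dtype=np.int8)


class TestReducedAlignment:
    def test_interior_positions_include_all(self):
        msa = _msa(["ACDEFGHIKL", "ACDEFGHIKL", "ACDEFGHIKL"])
        assert list(reduced_alignment(msa, 5)) == [0, 1, 2]

    def test_terminal_residue_is_excluded(self):
        # third sequence's last residue sits at column 5
        msa = _msa(["ACDEFGHIKL", "ACDEFGHIKL", "ACDEFG----"])
        assert list(reduced_alignment(msa, 5)) == [0, 1]
        assert list(reduced_alignment(msa, 4)) == [0, 1, 2]

    def test_matches_predicate_on_random_alignments(self):
        rng = np.random.default_rng(0)
        alphabet = "ACDEFGHIKLMNPQRSTVWY-"
        for _ in range(100):
            n, m = rng.integers(2, 8), rng.integers(3, 15)
            rows = []
            for _ in range(n):
                row = "".join(rng.choice(list(alphabet), size=m))
                if row.count("-") == m:
                    row = "A" + row[1:]
                rows.append(row)
            if all(c == "-" for c in rows[0]):
                rows[0] = "A" * m
            msa = _msa(rows)
            for col in range(m):
                got = set(reduced_alignment(msa, col))
                expected = set()
                for k, row in enumerate(rows):
                    if row[col] == "-":
                        continue
                    res_cols = [i for i, c in enumerate(row) if c != "-"]
                    if res_cols[0] < col < res_cols[-1]:
                        expected.add(k)
                assert got == expected


class TestHenikoffWeights:
    def test_identical_sequences_get_equal_weights(self):
        w = henikoff_weights(_codes(["ACDE"] * 4))
        np.testing.assert_allclose(w, 0.25)

    def test_single_sequence_weight_is_one(self):
        assert henikoff_weights(_codes(["ACDE"]))[0] == 1.0

    def test_three_sequence_toy_matches_hand_computation(self):
        # {AA, AA, AC}: col 0 gives 1/3 each; col 1 gives 1/4, 1/4, 1/2.
        w = henikoff_weights(_codes(["AA", "AA", "AC"]))
        np.testing.assert_allclose(w, [7 / 24, 7 / 24, 5 / 12])

    def test_weights_sum_to_one(self, small_msa):
        w = henikoff_weights(small_msa.codes())
        assert w.sum() == pytest.approx(1.0)


class TestObservedFrequencies:
    def test_conserved_column(self):
        f, f_gap = observed_frequencies(np.array([AA_INDEX["A"]] * 3),
                                        np.full(3, 1 / 3))
        assert f[AA_INDEX["A"]] == pytest.approx(1.0)
        assert f.sum() == pytest.approx(1.0)
        assert f_gap == 0.0

    def test_half_weight_gap(self):
        codes = np.array([AA_INDEX["A"], CHAR_TO_CODE["-"]])
        f, f_gap = observed_frequencies(codes, np.array([0.5, 0.5]))
        assert f_gap == pytest.approx(0.5)
        assert f.sum() + f_gap == pytest.approx(1.0)

    def test_ambiguity_codes_are_redistributed(self):
        f, _ = observed_frequencies(np.array([CHAR_TO_CODE["B"]]),
                                    np.array([1.0]))
        assert f[AA_INDEX["D"]] + f[AA_INDEX["N"]] == pytest.approx(1.0)
        assert f[AA_INDEX["A"]] == 0.0


class TestTargetProbabilities:
    def test_zero_pseudocounts_returns_frequencies(self, table):
        f = np.zeros(N_AA)
        f[[0, 3]] = 0.5
        t = target_probabilities(f, 5.0, table, beta=0.0)
        np.testing.assert_allclose(t, f, atol=1e-12)

    def test_single_sequence_is_pure_pseudocount(self, table):
        f = np.zeros(N_AA)
        f[AA_INDEX["A"]] = 1.0
        t = target_probabilities(f, 1.0, table, beta=10.0)
        g = table.q[:, AA_INDEX["A"]] / table.background[AA_INDEX["A"]]
        np.testing.assert_allclose(t, g / g.sum(), atol=1e-12)

    def test_mixture_matches_hand_evaluation(self, table):
        f = np.zeros(N_AA)
        f[AA_INDEX["A"]] = 1.0
        t = target_probabilities(f, 5.0, table, beta=10.0)
        g = (table.q / table.background[None, :]) @ f
        expected = (4.0 * f + 10.0 * g) / 14.0
        np.testing.assert_allclose(t, expected / expected.sum(), atol=1e-12)
        assert t.sum() == pytest.approx(1.0)

    def test_rejects_eff_seqs_below_one(self, table):
        with pytest.raises(ValueError):
            target_probabilities(np.full(N_AA, 0.05), 0.5, table)


class TestIndelProbabilities:
    def test_gapless_alignment_has_zero_deletions(self):
        assert (deletion_probabilities(np.zeros(10)) == 0).all()

    def test_run_is_linearly_interpolated(self):
        raw = np.array([0.0, 0.2, 0.9, 0.4, 0.0])
        np.testing.assert_allclose(deletion_probabilities(raw),
                                   [0.0, 0.2, 0.3, 0.4, 0.0])

    def test_isolated_position_unchanged(self):
        raw = np.array([0.0, 0.5, 0.0])
        np.testing.assert_allclose(deletion_probabilities(raw), raw)

    def test_interpolation_is_linear_inside_runs(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0, 1, size=50) * (rng.random(50) < 0.6)
        out = deletion_probabilities(raw)
        run = []
        for i, v in enumerate(raw):
            if v > 0:
                run.append(i)
            else:
                if len(run) >= 3:
                    seg = out[run[0]:run[-1] + 1]
                    np.testing.assert_allclose(np.diff(seg, 2), 0, atol=1e-12)
                run = []

    def test_insertions_are_raw_gap_frequency(self):
        raw = np.array([0.0, 0.2, 0.9, 0.4, 0.0])
        np.testing.assert_allclose(insertion_probabilities(raw), raw)
        # insertions differ from deletions exactly on interpolated runs
        d = deletion_probabilities(raw)
        assert (d != raw).any() and (d[raw == 0] == 0).all()


class TestThicknessAdjust:
    def test_large_thickness_leaves_probability(self):
        assert thickness_adjust(0.7, 1e6) == pytest.approx(0.7)

    def test_zero_thickness_factor(self):
        assert thickness_adjust(1.0, 0.0, u=1.0, v=2.0) == pytest.approx(
            1.0 / (1.0 + np.exp(2.0)))

    def test_stated_substitution(self):
        assert thickness_adjust(1.0, 2.0, u=1.0, v=2.0) == pytest.approx(0.5)

    @given(st.floats(1.0, 25.0), st.floats(0.5, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_factor_monotone_in_thickness(self, t, delta):
        # strictly increasing below float saturation of the logistic
        assert thickness_adjust(1.0, t + delta) > thickness_adjust(1.0, t)
        assert 0.0 < thickness_adjust(1.0, t) < 1.0


class TestRelativeEntropy:
    def test_zero_at_background(self):
        p = np.full(N_AA, 1 / N_AA)
        assert relative_entropy(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_against_uniform(self):
        p = np.full(N_AA, 1 / N_AA)
        t = np.zeros(N_AA)
        t[0] = 1.0
        assert relative_entropy(t, p) == pytest.approx(np.log(20))

    def test_nonnegative_on_random_simplex(self):
        rng = np.random.default_rng(4)
        t = rng.dirichlet(np.ones(N_AA), size=1000)
        p = rng.dirichlet(np.ones(N_AA))
        assert (relative_entropy(t, p) >= -1e-12).all()


class TestCompositionAdjust:
    def test_adjusted_lambda_matches_table(self, single_seq_profile, table):
        m = single_seq_profile.length
        probs = np.repeat(table.background[None, :], m, axis=0).ravel() / m
        lam = solve_lambda(single_seq_profile.scores.ravel(), probs)
        assert lam == pytest.approx(table.lambda_, rel=1e-4)

    def test_flat_profile_is_rejected(self, table, single_seq_profile):
        import copy
        prof = copy.deepcopy(single_seq_profile)
        prof.target = np.repeat(table.background[None, :],
                                prof.length, axis=0)
        prof.scores = np.zeros_like(prof.scores)
        with pytest.raises(ValueError, match="no positive score"):
            composition_adjust_profile(prof, table)


class TestBuildProfile:
    def test_invariants_on_fixture(self, small_profile):
        p = small_profile
        assert p.length >= 1
        np.testing.assert_allclose(p.target.sum(axis=1), 1.0, atol=1e-9)
        assert ((p.del_prob >= 0) & (p.del_prob <= 1)).all()
        assert ((p.ins_prob >= 0) & (p.ins_prob <= 1)).all()
        assert (p.eff_seqs >= 1).all()
        assert (p.rel_entropy >= 0).all()

    def test_gapless_alignment_has_no_indel_signal(self, table):
        msa = _msa(["ACDEFGHIKLMNPQRSTVWY"] * 5)
        prof = build_profile(msa, table, BuildParams(seg=False))
        assert (prof.del_prob == 0).all()
        assert (prof.ins_prob == 0).all()

    def test_masked_columns_shrink_profile(self, table):
        from helpers import noisy_block_msa
        rng = np.random.default_rng(12)
        msa, _, _ = noisy_block_msa(rng)
        full = build_profile(msa, table, BuildParams(seg=False))
        seg = build_profile(msa, table, BuildParams(seg=True))
        assert seg.length < full.length
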