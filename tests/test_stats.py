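"""Global score system, EVD fitting and E-value computation."""

import numpy as np
import pytest
from scipy.stats import gumbel_r

from coma import (FixtureSpec, SearchConfig, SignificanceParams,
                  build_global_score_system, build_pair_system, evalue,
                  fit_evd_reference, pair_gapped_params,
                  sample_unrelated_profiles, shipped_reference)
from coma.stats import EVDReference, VectorIndex, composition_scale_pair


@pytest.fixture(scope="module")
def db_profiles(table):
    spec = FixtureSpec(n_positions=50, n_sequences=15, gap_runs=(), seed=55)
    return sample_unrelated_profiles(3, spec, table=table)


class TestVectorIndex:
    def test_exact_dedup_against_brute_force(self):
        rng = np.random.default_rng(50)
        index = VectorIndex(decimals=4)
        seen = {}
        raw = rng.dirichlet(np.ones(20), size=40)
        vectors = raw[rng.integers(0, 40, size=200)]  # force duplicates
        for k, vec in enumerate(vectors):
            eff = float(rng.integers(1, 4))
            obs = vec[::-1].copy()
            idx = index.add(vec, obs, eff, payload=k)
            key = (tuple(np.round(vec, 4)), tuple(np.round(obs, 4)),
                   round(eff, 4))
            if key in seen:
                assert idx == seen[key]
            else:
                seen[key] = idx
        assert len(index) == len(seen)

    def test_find_returns_stored_index(self):
        index = VectorIndex()
        vec = np.full(20, 0.05)
        idx = index.add(vec, vec, 3.0, payload="x")
        assert index.find(vec, vec, 3.0) == idx
        assert index.find(vec, vec, 4.0) is None


class TestGlobalScoreSystem:
    def test_identical_columns_collapse_to_one_vector(self, table):
        from conftest import single_sequence_msa
        from coma import BuildParams, build_profile
        msa = single_sequence_msa("A" * 10, "polyA")
        prof = build_profile(msa, table, BuildParams(seg=False))
        gs = build_global_score_system([prof], SearchConfig())
        assert gs.n_vectors == 1
        assert np.isnan(gs.lambda_u)  # degenerate space has no statistics

    def test_dedup_count_matches_brute_force(self, db_profiles):
        gs = build_global_score_system(db_profiles, SearchConfig())
        seen = set()
        for prof in db_profiles:
            for i in range(prof.length):
                seen.add((tuple(np.round(prof.target[i], 4)),
                          tuple(np.round(prof.obs_freq[i], 4)),
                          round(float(prof.eff_seqs[i]), 4)))
        assert gs.n_vectors == len(seen)

    def test_reference_lambda_is_admissible_and_positive(self, db_profiles):
        gs = build_global_score_system(db_profiles, SearchConfig())
        assert gs.lambda_u > 0
        assert 0 < gs.K_u <= 1
        assert gs.H_u > 0

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_global_score_system([], SearchConfig())

    def test_composition_scale_pair_is_idempotent(self, db_profiles):
        cfg = SearchConfig()
        gs = build_global_score_system(db_profiles, cfg)
        system = build_pair_system(db_profiles[0], db_profiles[1], cfg)
        once = composition_scale_pair(system, gs, cfg)
        lam_once = once.lambda_
        scores_once = once.scores.copy()
        twice = composition_scale_pair(once, gs, cfg)
        np.testing.assert_allclose(twice.scores, scores_once, rtol=1e-2)
        assert twice.lambda_ == pytest.approx(lam_once, rel=1e-2)
        assert twice.lambda_ == pytest.approx(gs.lambda_u, rel=2e-2)


class TestFitEVD:
    def test_recovers_known_gumbel_parameters(self):
        rng = np.random.default_rng(60)
        lam_true, mu_true = 0.3, 50.0
        scores = gumbel_r.rvs(loc=mu_true, scale=1 / lam_true, size=20000,
                              random_state=rng)
        ref = fit_evd_reference(scores, search_space=1e4)
        assert ref.lambda_g == pytest.approx(lam_true, rel=0.05)
        assert ref.mu == pytest.approx(mu_true, rel=0.02)
        # K_g reproduces mu through mu = ln(K m n) / lambda
        assert np.log(ref.K_g * ref.search_space) / ref.lambda_g == \
            pytest.approx(ref.mu, rel=1e-6)

    def test_contaminated_sample_recovers_tail(self):
        rng = np.random.default_rng(61)
        tail = gumbel_r.rvs(loc=50, scale=1 / 0.3, size=18000,
                            random_state=rng)
        noise = rng.uniform(30, 45, size=2000)
        ref = fit_evd_reference(np.concatenate([tail, noise]),
                                search_space=1e4)
        assert ref.lambda_g == pytest.approx(0.3, rel=0.10)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_evd_reference(np.full(5000, 10.0))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_evd_reference(np.arange(50.0))


class TestPairGappedParams:
    def test_composition_scaled_pair_keeps_lambda_g(self):
        evd = EVDReference(lambda_g=0.2, mu=25.0, K_g=0.05,
                           search_space=4e4)
        lam_g, K_g = pair_gapped_params(0.31, 0.1, 0.31, 0.1, evd)
        assert lam_g == pytest.approx(0.2)
        assert K_g == pytest.approx(0.05)

    def test_ratio_rules(self):
        evd = EVDReference(lambda_g=0.2, mu=25.0, K_g=0.05,
                           search_space=4e4)
        lam_g, K_g = pair_gapped_params(0.31, 0.2, 0.31, 0.1, evd)
        assert K_g == pytest.approx(0.10)
        lam_g, _ = pair_gapped_params(0.62, 0.1, 0.31, 0.1, evd)
        assert lam_g == pytest.approx(0.4)

    def test_random_fixtures_verify_direct_formula(self):
        rng = np.random.default_rng(62)
        evd = EVDReference(lambda_g=0.3, mu=20.0, K_g=0.02,
                           search_space=1e4)
        for _ in range(20):
            lu_star, lu = rng.uniform(0.1, 0.5, 2)
            ku_star, ku = rng.uniform(0.01, 0.3, 2)
            lam_g, K_g = pair_gapped_params(lu_star, ku_star, lu, ku, evd)
            assert lam_g == pytest.approx(evd.lambda_g * lu_star / lu)
            assert K_g == pytest.approx(evd.K_g * ku_star / ku)


class TestEvalue:
    def test_substitution_example(self):
        params = SignificanceParams(lambda_g=0.25, K_g=0.1, m=100, n=100)
        E, P = evalue(40.0, params)
        assert E == pytest.approx(0.1 * 1e4 * np.exp(-10.0), rel=1e-12)
        assert E == pytest.approx(0.04540, abs=5e-5)

    def test_large_scores_vanish(self):
        params = SignificanceParams(lambda_g=0.25, K_g=0.1, m=100, n=100)
        E, P = evalue(1e4, params)
        assert E == pytest.approx(0.0, abs=1e-300)
        assert P == pytest.approx(0.0, abs=1e-300)

    def test_small_e_pvalue_expansion(self):
        params = SignificanceParams(lambda_g=0.25, K_g=0.1, m=100, n=100)
        s = np.log(0.1 * 1e4 / 1e-3) / 0.25  # score with E = 1e-3
        E, P = evalue(s, params)
        assert E == pytest.approx(1e-3, rel=1e-9)
        assert P == pytest.approx(9.995e-4, rel=1e-3)

    def test_strictly_decreasing_in_score_and_p_bounds(self):
        params = SignificanceParams(lambda_g=0.25, K_g=0.1, m=100, n=100)
        Es, Ps = zip(*(evalue(s, params) for s in np.linspace(0, 80, 30)))
        assert all(a > b for a, b in zip(Es, Es[1:]))
        assert all(0 <= p <= 1 and p <= e for p, e in zip(Ps, Es))

    def test_edge_correction_shrinks_search_space(self):
        params = SignificanceParams(lambda_g=0.25, K_g=0.1, m=100, n=100,
                                    H=0.4)
        E_plain, _ = evalue(40.0, params, edge_correction=False)
        E_edge, _ = evalue(40.0, params, edge_correction=True)
        ell = 0.25 * 40.0 / 0.4
        expected = 0.1 * (100 - ell) ** 2 * np.exp(-10.0)
        assert E_edge == pytest.approx(expected, rel=1e-9)
        assert E_edge < E_plain

    def test_lengths_floor_at_one(self):
        params = SignificanceParams(lambda_g=0.5, K_g=0.1, m=5, n=5, H=0.1)
        E, _ = evalue(100.0, params, edge_correction=True)
        assert np.isfinite(E)

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            SignificanceParams(lambda_g=0.2, K_g=0.1, m=0, n=10)


class TestShippedReference:
    def test_loads_and_is_plausible(self):
        ref = shipped_reference()
        assert ref.lambda_g > 0
        assert ref.K_g > 0
        assert ref.search_space > 0
        assert "synthetic" in ref.provenance
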