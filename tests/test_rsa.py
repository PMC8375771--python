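"""RDMs, similarity, resampling inference, trend test, searchlight."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from advrep.model import ConfigurationError, DataError
from advrep.rsa import (
    RDM,
    bootstrap_difference,
    compute_rdm,
    layer_profile,
    mann_kendall,
    permutation_null,
    rdm_similarity,
    searchlight_disks,
    searchlight_map,
    similarity_pair,
)
from advrep.synth import make_sheet, simulate_vertex_responses


def spearman_oracle(x, y):
    """Independent rank-then-Pearson computation."""
    return stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic


def mann_kendall_s_oracle(x):
    return sum(
        np.sign(x[j] - x[i]) for i, j in itertools.combinations(range(len(x)), 2)
    )


class TestComputeRdm:
    def test_forty_items_give_forty_row_matrix(self, rng):
        rdm = compute_rdm(rng.normal(size=(40, 30)))
        assert rdm.matrix.shape == (40, 40)

    def test_correlation_distance_values(self):
        acts = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [2.0, 4.0, 6.0]])
        rdm = compute_rdm(acts)
        assert rdm.matrix[0, 1] == pytest.approx(2.0)  # perfectly anticorrelated
        assert rdm.matrix[0, 2] == pytest.approx(0.0)  # collinear
        assert rdm.matrix[1, 2] == pytest.approx(2.0)

    def test_identical_vectors_have_zero_dissimilarity(self, rng):
        v = rng.normal(size=12)
        rdm = compute_rdm(np.stack([v, v, rng.normal(size=12)]))
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_zero_diagonal(self, rng):
        rdm = compute_rdm(rng.normal(size=(10, 6)))
        assert np.array_equal(rdm.matrix, rdm.matrix.T)
        assert np.all(np.diag(rdm.matrix) == 0)

    def test_zero_variance_item_named_in_error(self):
        acts = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [0.0, 1.0, 0.0]])
        with pytest.raises(DataError, match=r"\[0\]"):
            compute_rdm(acts)

    def test_euclidean_metric(self):
        acts = np.array([[0.0, 0.0], [3.0, 4.0]])
        rdm = compute_rdm(acts, metric="euclidean")
        assert rdm.matrix[0, 1] == pytest.approx(5.0)

    def test_malformed_rdm_rejected(self):
        with pytest.raises(DataError):
            RDM(matrix=np.array([[0.0, 1.0], [2.0, 0.0]]), item_ids=np.arange(2))
        with pytest.raises(DataError):
            RDM(matrix=np.array([[1.0, 2.0], [2.0, 1.0]]), item_ids=np.arange(2))


class TestRdmSimilarity:
    def test_self_similarity_is_one(self, rng):
        rdm = compute_rdm(rng.normal(size=(8, 5)))
        assert rdm_similarity(rdm, rdm) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        def rdm_from_upper(vals):
            m = np.zeros((4, 4))
            m[np.triu_indices(4, 1)] = vals
            return RDM(matrix=m + m.T, item_ids=np.arange(4))

        a = rdm_from_upper(np.arange(1.0, 7.0))
        b = rdm_from_upper(np.arange(6.0, 0.0, -1.0))
        assert rdm_similarity(a, b) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        def rdm_from_upper(vals):
            m = np.zeros((4, 4))
            m[np.triu_indices(4, 1)] = vals
            return RDM(matrix=m + m.T, item_ids=np.arange(4))

        ua = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ub = np.array([2.0, 1.0, 3.0, 4.0, 6.0, 5.0])
        expected = spearman_oracle(ua, ub)
        assert rdm_similarity(rdm_from_upper(ua), rdm_from_upper(ub)) == pytest.approx(expected)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_ties_handled_like_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        ua = rng.integers(0, 4, n * (n - 1) // 2).astype(float)
        ub = rng.integers(0, 4, ua.size).astype(float)
        if np.ptp(ua) == 0 or np.ptp(ub) == 0:
            return  # rank correlation undefined for constant triangles
        m = np.zeros((n, n))
        m[np.triu_indices(n, 1)] = ua
        a = RDM(matrix=m + m.T, item_ids=np.arange(n))
        m2 = np.zeros((n, n))
        m2[np.triu_indices(n, 1)] = ub
        b = RDM(matrix=m2 + m2.T, item_ids=np.arange(n))
        assert rdm_similarity(a, b) == pytest.approx(spearman_oracle(ua, ub))

    def test_mismatched_items_rejected(self, rng):
        a = compute_rdm(rng.normal(size=(5, 4)))
        b = compute_rdm(rng.normal(size=(6, 4)))
        with pytest.raises(DataError):
            rdm_similarity(a, b)


class TestSimilarityPair:
    def test_identical_ai_gives_unit_similarity(self, rng):
        re = rng.normal(size=(10, 20))
        an = rng.normal(size=(10, 20))
        r_an, r_ai = similarity_pair(re, an, re.copy())
        assert r_ai == pytest.approx(1.0)
        assert r_ai > r_an

    def test_independent_activations_near_zero(self, rng):
        re = rng.normal(size=(30, 500))
        r_an, _ = similarity_pair(re, rng.normal(size=(30, 500)), re)
        assert abs(r_an) < 0.1

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(DataError):
            similarity_pair(rng.normal(size=(5, 4)), rng.normal(size=(5, 4)),
                            rng.normal(size=(5, 3)))


class TestBootstrapDifference:
    def test_full_fraction_collapses_to_point(self, rng):
        re = rng.normal(size=(10, 20))
        res = bootstrap_difference(re, rng.normal(size=(10, 20)),
                                   rng.normal(size=(10, 20)),
                                   frac=1.0, n_boot=50, seed=0)
        assert np.ptp(res.diffs) == 0.0
        assert res.ci[0] == res.ci[1] == pytest.approx(res.point_diff)

    def test_replicate_count(self, rng):
        re = rng.normal(size=(8, 15))
        res = bootstrap_difference(re, rng.normal(size=(8, 15)),
                                   rng.normal(size=(8, 15)), n_boot=123, seed=1)
        assert res.diffs.size == 123

    def test_detects_coupled_vs_decoupled(self, rng):
        """With AI coupled and AN decoupled the difference test fires."""
        acts = {f"L{i}": rng.normal(size=(20, 32)) for i in range(1, 9)}
        sheet = make_sheet(12, seed=0)  # 120 vertices
        ds = simulate_vertex_responses(acts, sheet, rho_AI=0.8, rho_AN=0.0,
                                       rep_noise_sd=0.5, seed=3)
        m = {k: ds.mean_over_reps(k).T for k in ("RE", "AN", "AI")}
        res = bootstrap_difference(m["RE"], m["AN"], m["AI"], n_boot=200, seed=0)
        assert res.point_diff > 0
        assert res.p < 0.05

    def test_invalid_fraction_rejected(self, rng):
        re = rng.normal(size=(8, 15))
        with pytest.raises(ConfigurationError):
            bootstrap_difference(re, re, re, frac=1.5)


class TestPermutationNull:
    def test_identical_sets_sit_at_the_extreme(self, rng):
        re = rng.normal(size=(10, 30))
        res = permutation_null(re, re.copy(), n_perm=99, seed=0, frac=1.0)
        assert res.observed == pytest.approx(1.0)
        assert res.p <= 5 / 100  # only identity-like orderings can match 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        """The sampled null at 5 items agrees with the exhaustive
        120-permutation null distribution."""
        re = rng.normal(size=(5, 25))
        adv = rng.normal(size=(5, 25))
        rdm_adv = compute_rdm(adv)
        exhaustive = []
        for perm in itertools.permutations(range(5)):
            exhaustive.append(rdm_similarity(compute_rdm(re[list(perm)]), rdm_adv))
        exhaustive = np.array(exhaustive)
        res = permutation_null(re, adv, n_perm=2000, seed=1, frac=1.0)
        assert res.null.mean() == pytest.approx(exhaustive.mean(), abs=0.03)
        assert res.null.std() == pytest.approx(exhaustive.std(), abs=0.03)
        # every sampled value is a value the exhaustive null can produce
        assert np.all(np.isclose(res.null[:, None], exhaustive[None, :],
                                 atol=1e-12).any(axis=1))

    def test_false_positive_rate_calibrated(self):
        """Under independence the permutation test keeps its nominal size."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(20000 + seed)
            re = rng.normal(size=(10, 30))
            adv = rng.normal(size=(10, 30))
            res = permutation_null(re, adv, n_perm=99, seed=seed)
            hits += res.p < 0.05
        assert 0.01 <= hits / n_seeds <= 0.075  # within 1.5x nominal

    def test_too_few_items_rejected(self, rng):
        with pytest.raises(DataError):
            permutation_null(rng.normal(size=(3, 10)), rng.normal(size=(3, 10)))


class TestMannKendall:
    @pytest.mark.parametrize("seq,expected_s", [
        ((1, 2, 3, 4, 5), 10),
        ((5, 4, 3, 2, 1), -10),
        ((2, 2, 2, 2), 0),
        ((1, 3, 2), 1),
    ])
    def test_s_statistic(self, seq, expected_s):
        assert mann_kendall(seq).S == expected_s

    def test_constant_sequence_not_significant(self):
        res = mann_kendall([3.0, 3.0, 3.0, 3.0])
        assert res.S == 0 and res.z == 0.0 and res.p == 1.0

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 7))
    def test_matches_bruteforce_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, n).astype(float)  # integer draws force ties
        res = mann_kendall(x)
        assert res.S == mann_kendall_s_oracle(x)
        # tie-corrected variance is nonnegative and zero iff all tied
        assert res.variance >= 0
        assert 0 <= res.p <= 1

    def test_short_sequence_rejected(self):
        with pytest.raises(ConfigurationError):
            mann_kendall([1.0, 2.0])

    def test_monotone_trend_detected(self):
        res = mann_kendall(np.arange(8.0))
        assert res.S == 28
        assert res.p < 0.005


class TestLayerProfile:
    def test_one_summary_per_stage_and_degenerate_copies(self, surrogate, re_set):
        """AI = RE copies force unit similarity at every stage and a flat
        (S = 0) trend over the constant profile."""
        prof = layer_profile(surrogate, re_set, re_set, re_set,
                             n_boot=20, n_perm=20, seed=0)
        assert len(prof.summaries) == 8
        for s in prof.summaries.values():
            assert s.r_re_ai == pytest.approx(1.0)
        assert prof.trend_re_ai.S == 0


class TestSearchlight:
    def test_disk_membership_symmetric(self):
        sheet = make_sheet(15, seed=2)
        disks = searchlight_disks(sheet, radius=3.0)
        member = {v: set(d.tolist()) for v, d in
                  zip(sheet.table["vertex_id"], disks)}
        for v, disk in member.items():
            for u in disk:
                assert v in member[u]

    def test_tiny_radius_gives_missing_values(self, rng):
        acts = {f"L{i}": rng.normal(size=(10, 16)) for i in range(1, 9)}
        sheet = make_sheet(9, seed=0)
        ds = simulate_vertex_responses(acts, sheet, seed=0)
        sl = searchlight_map(ds, radius=0.05)
        assert sl["r_re_an"].isna().all()
        assert sl["r_re_ai"].isna().all()

    def test_coupled_exceeds_decoupled_on_average(self, rng):
        acts = {f"L{i}": rng.normal(size=(15, 24)) for i in range(1, 9)}
        sheet = make_sheet(25, seed=1)
        ds = simulate_vertex_responses(acts, sheet, rho_AI=0.8, rho_AN=0.0,
                                       rep_noise_sd=0.5, seed=2)
        sl = searchlight_map(ds, radius=3.0).dropna()
        assert sl["r_re_ai"].mean() > sl["r_re_an"].mean()
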