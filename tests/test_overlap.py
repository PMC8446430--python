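import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from immunofis import (
    Cohort,
    OverlapConfig,
    ValidationError,
    i_index,
    set_distance,
    similarity_matrix,
    trajectory_distance,
)
from immunofis.overlap import i_index_matrix

from conftest import make_cohort, make_profile, oracle_i_index, oracle_set_distance

PC0 = OverlapConfig(pseudocount=0.0)


class TestIIndex:
    def test_identical_profiles_give_one(self):
        p, q = make_profile([1, 2, 3], "a"), make_profile([1, 2, 3], "b")
        assert i_index([p, q]) == pytest.approx(1.0, abs=1e-12)
        # proportional profiles are identical as distributions (pseudocount 0)
        r = make_profile([2, 4, 6], "c")
        assert i_index([p, r], cfg=PC0) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_give_zero(self):
        p, q = make_profile([1, 1, 0, 0], "a"), make_profile([0, 0, 1, 1], "b")
        assert i_index([p, q], cfg=PC0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_half_overlap(self):
        # P=(.5,.5,0), Q=(0,.5,.5): H(P)=H(Q)=log2, M=(.25,.5,.25),
        # H(M)=1.5*log2 -> JSD=0.5*log2 -> I=0.5
        p, q = make_profile([5, 5, 0], "a"), make_profile([0, 5, 5], "b")
        assert i_index([p, q], cfg=PC0) == pytest.approx(0.5, abs=1e-12)

    def test_matches_direct_entropy_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(2, 6)
            K = rng.integers(2, 8)
            X = rng.gamma(1.5, 50.0, (n, K))
            assert i_index_matrix(X, 0.5) == pytest.approx(
                oracle_i_index(X, 0.5), abs=1e-12
            )

    def test_base_invariance(self, rng):
        # an oracle computed entirely in log2 gives the same normalized overlap
        X = rng.gamma(2.0, 30.0, (3, 5))
        D = X / X.sum(axis=1, keepdims=True)

        def h2(v):
            v = v[v > 0]
            return -(v * np.log2(v)).sum()

        jsd2 = h2(D.mean(axis=0)) - np.mean([h2(d) for d in D])
        assert i_index_matrix(X, 0.0) == pytest.approx(1 - jsd2 / np.log2(3), abs=1e-12)

    def test_requires_two_profiles(self):
        with pytest.raises(ValidationError):
            i_index([make_profile([1, 2])])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_symmetry_and_order_invariance(self, seed):
        r = np.random.default_rng(seed)
        X = r.gamma(1.0, 10.0, (int(r.integers(2, 5)), int(r.integers(2, 6)))) + 1e-9
        v = i_index_matrix(X, 0.5)
        assert 0.0 <= v <= 1.0
        # profile order
        assert i_index_matrix(X[::-1], 0.5) == pytest.approx(v, abs=1e-12)
        # population order
        perm = r.permutation(X.shape[1])
        assert i_index_matrix(X[:, perm], 0.5) == pytest.approx(v, abs=1e-12)

    def test_duplicate_member_never_decreases_homogeneous_overlap(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        base = i_index_matrix(X, 0.5)
        assert i_index_matrix(np.vstack([X, X[0]]), 0.5) >= base - 1e-12


class TestSetDistance:
    def _profiles(self, ctrl_rows, case_row):
        ctrls = [make_profile(r, f"c{i}") for i, r in enumerate(ctrl_rows)]
        case = make_profile(case_row, "x", Cohort.HIV_POS, 56)
        return case, ctrls

    def test_duplicate_case_of_homogeneous_controls_is_zero(self):
        case, ctrls = self._profiles([[1, 2, 3]] * 3, [1, 2, 3])
        assert set_distance(case, ctrls) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_case_strictly_positive(self):
        case, ctrls = self._profiles([[1, 1, 0, 0]] * 3, [0, 0, 1, 1])
        assert set_distance(case, ctrls, cfg=PC0) > 0

    def test_matches_two_oracle_evaluations(self, rng):
        ctrl = rng.gamma(2.0, 40.0, (3, 4))
        case = rng.gamma(2.0, 40.0, 4)
        cs, ctrls = self._profiles(ctrl, case)
        assert set_distance(cs, ctrls) == pytest.approx(
            oracle_set_distance(case, ctrl), abs=1e-12
        )

    def test_restriction_consistency(self, rng):
        # restricting to a feature subset equals explicit renormalisation
        ctrl = rng.gamma(2.0, 40.0, (4, 6))
        case = rng.gamma(2.0, 40.0, 6)
        idx = np.array([0, 2, 5])
        cs, ctrls = self._profiles(ctrl, case)
        direct = set_distance(cs, ctrls, feature_subset=idx)
        manual = oracle_set_distance(case[idx], ctrl[:, idx])
        assert direct == pytest.approx(manual, abs=1e-12)

    def test_empty_subset_and_too_few_controls(self):
        cs, ctrls = self._profiles([[1, 2]] * 3, [2, 1])
        with pytest.raises(ValidationError):
            set_distance(cs, ctrls, feature_subset=np.array([], dtype=int))
        with pytest.raises(ValidationError):
            set_distance(cs, ctrls[:1])


class TestTrajectory:
    def test_identical_case_matches_controls_alone(self):
        ctrls = [make_profile([1, 2, 3], f"c{i}") for i in range(3)]
        case = make_profile([1, 2, 3], "x", Cohort.HIV_POS, 56)
        expected = 1.0 - i_index(ctrls)
        assert trajectory_distance(case, ctrls) == pytest.approx(expected, abs=1e-12)

    def test_disjoint_case_equals_oracle(self):
        ctrl = np.tile([1.0, 1.0, 0.0, 0.0], (3, 1))
        case = np.array([0.0, 0.0, 1.0, 1.0])
        ctrls = [make_profile(r, f"c{i}") for i, r in enumerate(ctrl)]
        cp = make_profile(case, "x", Cohort.HIV_POS, 56)
        expected = 1.0 - oracle_i_index(np.vstack([case, ctrl]), 0.0)
        assert trajectory_distance(cp, ctrls, cfg=PC0) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_effect_size_on_homogeneous_controls(self):
        # shrinking the case toward the control mean never increases distance
        ctrl_vec = np.array([100.0, 200.0, 300.0, 400.0])
        ctrls = [make_profile(ctrl_vec, f"c{i}") for i in range(5)]
        far = np.array([400.0, 100.0, 100.0, 400.0])
        last = np.inf
        for lam in np.linspace(1.0, 0.0, 11):
            case = make_profile(lam * far + (1 - lam) * ctrl_vec, "x", Cohort.HIV_POS, 56)
            d = trajectory_distance(case, ctrls)
            assert d <= last + 1e-12
            last = d


class TestSimilarityMatrix:
    def test_identical_pair_all_ones(self):
        rows = [("a", Cohort.CONTROL, None, [1, 2, 3]), ("b", Cohort.CONTROL, None, [1, 2, 3])]
        cs = make_cohort(("X", "Y", "Z"), rows)
        sm = similarity_matrix(cs)
        np.testing.assert_allclose(sm.values, np.ones((2, 2)), atol=1e-12)

    def test_matches_pairwise_oracle(self, rng):
        X = rng.gamma(2.0, 30.0, (4, 5))
        rows = [(f"s{i}", Cohort.CONTROL, None, X[i]) for i in range(4)]
        cs = make_cohort(tuple("ABCDE"), rows)
        sm = similarity_matrix(cs)
        for i in range(4):
            for j in range(i + 1, 4):
                expected = oracle_i_index(X[[i, j]], 0.5)
                assert sm.values[i, j] == pytest.approx(expected, abs=1e-12)
                assert sm.values[j, i] == sm.values[i, j]

    def test_permutation_equivariance(self, rng):
        X = rng.gamma(2.0, 30.0, (4, 5))
        rows = [(f"s{i}", Cohort.CONTROL, None, X[i]) for i in range(4)]
        cs = make_cohort(tuple("ABCDE"), rows)
        sm = similarity_matrix(cs)
        perm = [2, 0, 3, 1]
        cs2 = make_cohort(tuple("ABCDE"), [rows[i] for i in perm])
        sm2 = similarity_matrix(cs2)
        np.testing.assert_allclose(sm2.values, sm.values[np.ix_(perm, perm)], atol=1e-12)
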