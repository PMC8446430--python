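import numpy as np
import pandas as pd
import pytest

from immunofis import Cohort, FISConfig, ValidationError, fis_significance, run_fis
from immunofis.fis import (
    enumerate_subsets,
    fis_one,
    fis_scores,
    median_fis,
    sample_subsets,
)
from immunofis.profiles import ImmuneProfile

from conftest import make_cohort, make_profile, oracle_set_distance


class TestSampleSubsets:
    def test_shape_distinctness_and_determinism(self):
        s1 = sample_subsets(18, 7, 500, seed=42)
        s2 = sample_subsets(18, 7, 500, seed=42)
        np.testing.assert_array_equal(s1, s2)
        assert s1.shape == (500, 7)
        # within-subset features are distinct
        assert all(len(set(row)) == 7 for row in s1)

    def test_full_panel_when_m_equals_K(self):
        s = sample_subsets(3, 3, 20, seed=0)
        assert all(set(row) == {0, 1, 2} for row in s)

    def test_m_larger_than_K_rejected(self):
        with pytest.raises(ValidationError):
            sample_subsets(5, 6, 10, seed=0)

    def test_inclusion_frequency_is_uniform(self):
        # binomial oracle: each feature included with prob m/K
        K, m, M = 18, 7, 100_000
        s = sample_subsets(K, m, M, seed=7)
        freq = np.bincount(s.ravel(), minlength=K) / M
        p = m / K
        se = np.sqrt(p * (1 - p) / M)
        assert np.all(np.abs(freq - p) < 3 * se)

    def test_enumerate_subsets(self):
        s = enumerate_subsets(4, 2)
        assert s.shape == (6, 2)
        assert {tuple(r) for r in s} == {(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)}


class TestFisOne:
    def _instance(self, rng):
        ctrl = rng.gamma(2.0, 40.0, (3, 4))
        case = rng.gamma(2.0, 40.0, 4)
        ctrls = [make_profile(r, f"c{i}") for i, r in enumerate(ctrl)]
        cp = make_profile(case, "x", Cohort.HIV_POS, 56)
        return cp, ctrls, case, ctrl

    def test_equals_two_brute_force_distances(self, rng):
        cp, ctrls, case, ctrl = self._instance(rng)
        J = np.array([0, 1, 3])
        expected = oracle_set_distance(case[J], ctrl[:, J]) - oracle_set_distance(
            case[[0, 3]], ctrl[:, [0, 3]]
        )
        assert fis_one(cp, ctrls, J, feature=1) == pytest.approx(expected, abs=1e-12)

    def test_zero_when_case_identical_to_homogeneous_controls(self):
        ctrls = [make_profile([1, 2, 3, 4], f"c{i}") for i in range(3)]
        cp = make_profile([1, 2, 3, 4], "x", Cohort.HIV_POS, 56)
        for J in ([0, 1], [0, 2, 3], [0, 1, 2, 3]):
            for j in J:
                assert fis_one(cp, ctrls, J, j) == pytest.approx(0.0, abs=1e-12)

    def test_perturbed_feature_scores_positive(self):
        # case differs from homogeneous controls only in feature 0
        ctrls = [make_profile([100, 100, 100, 100], f"c{i}") for i in range(4)]
        cp = make_profile([400, 100, 100, 100], "x", Cohort.HIV_POS, 56)
        J = [0, 1, 2]
        assert fis_one(cp, ctrls, J, 0) > 0
        # unaffected features in the same context do not out-score it
        assert fis_one(cp, ctrls, J, 1) <= fis_one(cp, ctrls, J, 0)

    def test_usage_errors(self):
        ctrls = [make_profile([1, 2], f"c{i}") for i in range(3)]
        cp = make_profile([2, 1], "x", Cohort.HIV_POS, 56)
        with pytest.raises(ValidationError):
            fis_one(cp, ctrls, [0], 0)
        with pytest.raises(ValidationError):
            fis_one(cp, ctrls, [0, 1], 5)


class TestEngine:
    def test_engine_matches_scalar_composition(self, rng):
        ctrl = rng.gamma(2.0, 50.0, (5, 6))
        case = rng.gamma(2.0, 50.0, 6)
        ctrls = [make_profile(r, f"c{i}") for i, r in enumerate(ctrl)]
        cp = make_profile(case, "x", Cohort.HIV_POS, 56)
        subsets = enumerate_subsets(6, 3)
        scores = fis_scores(case[None], ctrl, subsets, 0.5)
        for t, J in enumerate(subsets):
            for k, j in enumerate(J):
                assert scores[0, t, k] == pytest.approx(
                    fis_one(cp, ctrls, J, j), abs=1e-12
                )

    def test_median_fis_exhaustive_equals_brute_force(self, rng):
        # K=4, m=2: enumerate all C(4,2) subsets; medians must equal the
        # direct-entropy brute-force oracle exactly
        ctrl = rng.gamma(2.0, 50.0, (4, 4))
        case = rng.gamma(2.0, 50.0, 4)
        ctrls = [make_profile(r, f"c{i}") for i, r in enumerate(ctrl)]
        cp = make_profile(case, "x", Cohort.HIV_POS, 56)
        subsets = enumerate_subsets(4, 2)
        got = median_fis(cp, ctrls, subsets)
        for f in range(4):
            vals = []
            for J in subsets:
                if f in J:
                    other = [x for x in J if x != f]
                    d_full = oracle_set_distance(case[J], ctrl[:, J])
                    d_drop = oracle_set_distance(case[other], ctrl[:, other])
                    vals.append(d_full - d_drop)
            assert got[f] == pytest.approx(np.median(vals), abs=1e-12)

    def test_null_case_gives_zero_medians(self):
        ctrl = np.tile([10.0, 20.0, 30.0, 40.0], (4, 1))
        ctrls = [make_profile(r, f"c{i}") for i, r in enumerate(ctrl)]
        cp = make_profile(ctrl[0], "x", Cohort.HIV_POS, 56)
        got = median_fis(cp, ctrls, enumerate_subsets(4, 3))
        assert all(abs(v) < 1e-12 for v in got.values())


class TestSignificance:
    def test_all_positive_medians_are_significant(self, rng):
        # 20 cases all positive on feature f: minimal signed-rank p = 2^-20
        med = pd.DataFrame(
            {f"case{i}": {"f": 0.01 + rng.uniform(0, 0.01), "g": rng.normal(0, 0.01)} for i in range(20)}
        )
        rec = fis_significance(med)
        assert rec.set_index("feature").loc["f", "significant"]

    def test_symmetric_medians_not_significant(self):
        vals = np.array([-0.02, -0.01, -0.005, 0.005, 0.01, 0.02])
        med = pd.DataFrame([vals], index=["f"], columns=[f"c{i}" for i in range(6)])
        rec = fis_significance(med)
        assert not rec["significant"].any()

    def test_all_zero_medians_degenerate_p_one(self, caplog):
        med = pd.DataFrame([np.zeros(6)], index=["f"], columns=[f"c{i}" for i in range(6)])
        with caplog.at_level("WARNING"):
            rec = fis_significance(med)
        assert rec.loc[0, "p"] == 1.0

    def test_needs_five_cases(self):
        med = pd.DataFrame([np.ones(3)], index=["f"], columns=list("abc"))
        with pytest.raises(ValidationError):
            fis_significance(med)


class TestRunFis:
    def _cohort(self, rng, n_cases=6, n_ctrl=8, shift=None):
        K = 5
        rows = []
        for i in range(n_ctrl):
            rows.append((f"c{i}", Cohort.CONTROL, None, rng.gamma(50.0, 4.0, K)))
        for i in range(n_cases):
            v = rng.gamma(50.0, 4.0, K)
            if shift is not None:
                v[shift] *= 3.0
            rows.append((f"p{i}", Cohort.HIV_POS, 56, v))
        return make_cohort(tuple("ABCDE"), rows)

    def test_deterministic_rerun(self, rng):
        cs = self._cohort(rng)
        cfg = FISConfig(subset_size=3, n_subsets=500, seed=5)
        r1 = run_fis(cs, "HIV_POS", 56, cfg)
        r2 = run_fis(cs, "HIV_POS", 56, cfg)
        pd.testing.assert_frame_equal(r1.records, r2.records)
        pd.testing.assert_frame_equal(r1.case_medians, r2.case_medians)

    def test_recovers_strongly_shifted_feature(self, rng):
        cs = self._cohort(rng, n_cases=10, n_ctrl=12, shift=2)
        cfg = FISConfig(subset_size=3, n_subsets=2000, seed=5)
        res = run_fis(cs, "HIV_POS", 56, cfg)
        assert "C" in res.significant_features

    def test_pooled_mode_uses_all_visits(self, rng):
        rows = [(f"c{i}", Cohort.CONTROL, None, rng.gamma(5.0, 40.0, 3)) for i in range(6)]
        for i in range(5):
            for tp in (56, 180):
                rows.append((f"p{i}", Cohort.HIV_POS, tp, rng.gamma(5.0, 40.0, 3)))
        cs = make_cohort(("A", "B", "C"), rows)
        res = run_fis(cs, "HIV_POS", "pooled", FISConfig(subset_size=2, n_subsets=50, seed=1))
        assert res.case_medians["case"].nunique() == 10  # each case-visit is one observation
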