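"""ICC correctness (hand ANOVA + pingouin cross-checks), band errors, reports."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cobbkit import reliability as rel

from oracles import hand_anova_icc


def random_matrix(rng, n=10, k=4, subject_sd=10.0, rater_bias_sd=2.0, noise_sd=2.0):
    subjects = rng.normal(30.0, subject_sd, size=(n, 1))
    bias = rng.normal(0.0, rater_bias_sd, size=(1, k))
    return subjects + bias + rng.normal(0.0, noise_sd, size=(n, k))


class TestICC:
    def test_perfect_agreement(self):
        x = np.tile(np.array([[10.0], [20.0], [35.0], [50.0]]), (1, 3))
        for model in ("ICC_2_1", "ICC_3_1"):
            res = rel.icc(rel.RatingsMatrix(x), model)
            assert res.estimate == pytest.approx(1.0)
            assert res.grade == "excellent"

    def test_matches_hand_anova_on_toy(self):
        x = np.array(
            [[9.0, 10.0, 12.0], [20.0, 22.0, 21.0], [33.0, 29.0, 30.0], [44.0, 46.0, 47.0]]
        )
        icc21, icc31, _ = hand_anova_icc(x)
        assert rel.icc(rel.RatingsMatrix(x), "ICC_2_1").estimate == pytest.approx(icc21, abs=1e-12)
        assert rel.icc(rel.RatingsMatrix(x), "ICC_3_1").estimate == pytest.approx(icc31, abs=1e-12)

    def test_matches_hand_anova_on_random_matrices(self, rng):
        for _ in range(50):
            x = random_matrix(rng, n=int(rng.integers(4, 12)), k=int(rng.integers(2, 6)))
            icc21, icc31, _ = hand_anova_icc(x)
            assert rel.icc(rel.RatingsMatrix(x), "ICC_2_1").estimate == pytest.approx(
                icc21, abs=1e-10
            )
            assert rel.icc(rel.RatingsMatrix(x), "ICC_3_1").estimate == pytest.approx(
                icc31, abs=1e-10
            )

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = random_matrix(rng, n=12, k=5)
        df = pd.DataFrame(
            [
                {"subject": i, "rater": j, "score": x[i, j]}
                for i in range(x.shape[0])
                for j in range(x.shape[1])
            ]
        )
        table = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        table = table.set_index("Type")
        m = rel.RatingsMatrix(x)
        for model, ptype in (("ICC_2_1", "ICC(A,1)"), ("ICC_3_1", "ICC(C,1)")):
            mine = rel.icc(m, model)
            assert mine.estimate == pytest.approx(table.loc[ptype, "ICC"], abs=1e-9)
            lo, hi = table.loc[ptype, "CI95"]  # pingouin rounds the CI to 2 dp
            assert mine.ci_low == pytest.approx(lo, abs=6e-3)
            assert mine.ci_high == pytest.approx(hi, abs=6e-3)

    def test_rater_shift_decreases_absolute_agreement_only(self, rng):
        x = random_matrix(rng, n=12, k=4, rater_bias_sd=0.0)
        shifted = x.copy()
        shifted[:, 0] += 10.0
        base21 = rel.icc(rel.RatingsMatrix(x), "ICC_2_1").estimate
        new21 = rel.icc(rel.RatingsMatrix(shifted), "ICC_2_1").estimate
        assert new21 < base21
        # residual mean square is untouched by a column shift
        _, _, (_, _, mse_a) = hand_anova_icc(x)
        _, _, (_, _, mse_b) = hand_anova_icc(shifted)
        assert mse_a == pytest.approx(mse_b, abs=1e-9)

    def test_invariances(self, rng):
        x = random_matrix(rng, n=10, k=3)
        base = rel.icc(rel.RatingsMatrix(x), "ICC_2_1").estimate
        perm = rng.permutation(x.shape[0])
        assert rel.icc(rel.RatingsMatrix(x[perm]), "ICC_2_1").estimate == pytest.approx(base)
        assert rel.icc(rel.RatingsMatrix(x + 7.5), "ICC_2_1").estimate == pytest.approx(base)

    def test_consistency_at_least_agreement_with_rater_bias(self, rng):
        for _ in range(20):
            x = random_matrix(rng, n=15, k=4, rater_bias_sd=4.0)
            icc21, icc31, (msr, msc, mse) = hand_anova_icc(x)
            if msc >= mse:
                assert icc31 >= icc21 - 1e-12

    def test_zero_subject_variance_rejected(self):
        x = np.ones((5, 3)) * 20.0
        with pytest.raises(ValueError, match="variance"):
            rel.icc(rel.RatingsMatrix(x), "ICC_2_1")

    def test_parameter_recovery(self):
        # ICC converges to tau^2 / (tau^2 + sigma^2) for large n
        tau, sigma = 8.0, 4.0
        expect = tau**2 / (tau**2 + sigma**2)
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            x = rng.normal(30, tau, size=(500, 1)) + rng.normal(0, sigma, size=(500, 4))
            got = rel.icc(rel.RatingsMatrix(x), "ICC_2_1").estimate
            assert got == pytest.approx(expect, abs=0.03)

    def test_grade_thresholds(self):
        assert rel.grade_icc(0.69) == "poor"
        assert rel.grade_icc(0.70) == "fair"
        assert rel.grade_icc(0.80) == "good"
        assert rel.grade_icc(0.95) == "excellent"


class TestBandErrors:
    def test_identity_and_constant_shift(self):
        ref = np.array([5.0, 15.0, 25.0, 45.0, 55.0])
        rows = rel.band_errors(ref, ref)
        assert all(r.mean_diff == 0 for r in rows if r.n)
        rows = rel.band_errors(ref - 2.0, ref)
        for r in rows:
            if r.n:
                assert r.mean_diff == pytest.approx(-2.0)
                assert r.degenerate  # zero spread -> collapsed CI

    def test_ci_matches_direct_t_interval(self, rng):
        ref = rng.uniform(0, 60, size=600)
        ai = ref - 2.0 + rng.normal(0, 1, size=600)
        rows = rel.band_errors(ai, ref)
        for r in rows:
            sel = (ref >= r.band[0]) & (ref < r.band[1])
            d = (ai - ref)[sel]
            assert r.n == sel.sum()
            assert -2.3 < r.mean_diff < -1.7
            half = stats.t.ppf(0.975, d.size - 1) * d.std(ddof=1) / np.sqrt(d.size)
            assert r.ci_low == pytest.approx(d.mean() - half, abs=1e-12)
            assert r.ci_high == pytest.approx(d.mean() + half, abs=1e-12)

    def test_empty_band_flagged(self):
        rows = rel.band_errors(np.array([5.0, 6.0]), np.array([5.0, 6.0]))
        high = rows[-1]
        assert high.n == 0 and np.isnan(high.mean_diff)


class TestEvaluateRun:
    @staticmethod
    def _tables(rng, n=40, raters=6, rater_sd=3.0, ai_bias=-2.0, ai_sd=2.0):
        truth = rng.uniform(10, 60, size=n)
        rater_rows, ai_rows = [], []
        for i in range(n):
            for r in range(raters):
                rater_rows.append(
                    {"subject_id": i, "rater_id": r, "posture": "standing",
                     "rank": "major", "cobb_angle": truth[i] + rng.normal(0, rater_sd)}
                )
            ai_rows.append({"subject_id": i, "rank": "major",
                            "cobb_angle": truth[i] + ai_bias + rng.normal(0, ai_sd)})
        return pd.DataFrame(ai_rows), pd.DataFrame(rater_rows)

    def test_perfect_ai_equals_raters(self):
        ai = pd.DataFrame(
            [{"subject_id": i, "rank": "major", "cobb_angle": 20.0 + i} for i in range(6)]
        )
        raters = pd.DataFrame(
            [
                {"subject_id": i, "rater_id": r, "posture": "standing", "rank": "major",
                 "cobb_angle": 20.0 + i}
                for i in range(6)
                for r in range(3)
            ]
        )
        report = rel.evaluate_run(ai, raters)
        entry = report["postures"]["standing"]["ranks"]["major"]
        assert entry["mean_diff"] == pytest.approx(0.0)
        assert entry["icc_with_ai_3_1"]["estimate"] == pytest.approx(1.0)

    def test_bias_recovery_simulation(self, rng):
        ai, raters = self._tables(rng, n=50)
        report = rel.evaluate_run(ai, raters)
        entry = report["postures"]["standing"]["ranks"]["major"]
        assert entry["icc_with_ai_3_1"]["estimate"] > 0.9
        assert entry["mean_diff"] == pytest.approx(-2.0, abs=0.8)

    def test_disjoint_subjects_rejected(self, rng):
        ai, raters = self._tables(rng, n=6)
        ai["subject_id"] += 1000
        with pytest.raises(ValueError, match="common subjects"):
            rel.evaluate_run(ai, raters)

    def test_missing_rank_excluded_and_logged(self, rng):
        ai, raters = self._tables(rng, n=10)
        ai = ai[ai.subject_id != 3]  # AI found no major curve for subject 3
        report = rel.evaluate_run(ai, raters)
        assert report["excluded"]["standing/major"] == 1
        assert report["postures"]["standing"]["ranks"]["major"]["n"] == 9
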