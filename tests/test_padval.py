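"""Reliability, distinguishability, and literature-mapping statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import emospec as es

# classic 6-target x 3-rater reliability fixture; the expected ICC(2,k)
# was frozen from an independent two-way ANOVA computed by hand
ICC_FIXTURE = np.array([[9., 2, 5], [6, 1, 3], [8, 4, 6],
                        [7, 1, 2], [10, 5, 6], [6, 2, 4]])
ICC_FIXTURE_2K = 0.4634146341463414


def _anova_icc2k_oracle(M):
    """Brute-force two-way ANOVA decomposition, independent of the package."""
    n, k = M.shape
    grand = M.mean()
    msr = k * ((M.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((M.mean(0) - grand) ** 2).sum() / (k - 1)
    resid = M - M.mean(1, keepdims=True) - M.mean(0, keepdims=True) + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestICC2k:
    def test_fixture_matches_anova_oracle(self):
        assert es.icc2k(ICC_FIXTURE) == pytest.approx(
            _anova_icc2k_oracle(ICC_FIXTURE), abs=1e-10)
        assert es.icc2k(ICC_FIXTURE) == pytest.approx(ICC_FIXTURE_2K, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        n, k = ICC_FIXTURE.shape
        df = pd.DataFrame({"targets": np.repeat(np.arange(n), k),
                           "raters": np.tile(np.arange(k), n),
                           "scores": ICC_FIXTURE.ravel()})
        res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores")
        ref = float(res.loc[res["Type"].isin(["ICC2k", "ICC(A,k)"]),
                            "ICC"].iloc[0])
        assert es.icc2k(ICC_FIXTURE) == pytest.approx(ref, abs=1e-10)

    def test_perfect_agreement_is_one(self):
        M = np.tile(np.array([[1.], [4.], [2.], [9.]]), (1, 5))
        assert es.icc2k(M) == pytest.approx(1.0)

    def test_pure_noise_is_near_zero(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(50, 10))  # no target effect at all
        assert abs(es.icc2k(M)) < 0.15

    def test_increases_with_target_variance(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(size=(20, 6))
        values = []
        for target_sd in (0.5, 1.0, 2.0, 4.0):
            targets = target_sd * rng.standard_normal(20)[:, None]
            values.append(es.icc2k(targets + noise))
        assert values == sorted(values)

    def test_missing_cells_rejected(self):
        M = ICC_FIXTURE.copy()
        M[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing cell"):
            es.icc2k(M)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            es.icc2k(np.full((4, 3), 2.0))


class TestHotelling:
    def test_identical_samples_give_zero(self, rng):
        X = rng.normal(size=(25, 3))
        r = es.hotelling_two_sample(X, X.copy())
        assert r.t2 == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_p1_reduces_to_squared_pooled_t(self, rng):
        x = rng.normal(0, 1, size=(15, 1))
        y = rng.normal(0.8, 1.3, size=(20, 1))
        r = es.hotelling_two_sample(x, y)
        t, _ = stats.ttest_ind(x.ravel(), y.ravel(), equal_var=True)
        assert r.t2 == pytest.approx(t ** 2, abs=1e-10)

    def test_type_one_error_rate_at_nominal_level(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            X = rng.normal(size=(20, 3))
            Y = rng.normal(size=(20, 3))
            if es.hotelling_two_sample(X, Y).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(30, 3))
        Y = rng.normal(0.5, 1.0, size=(25, 3))
        base = es.hotelling_two_sample(X, Y).t2
        for seed in range(5):
            g = np.random.default_rng(seed)
            A = g.normal(size=(3, 3)) + 3 * np.eye(3)
            b = g.normal(size=3)
            r = es.hotelling_two_sample(X @ A + b, Y @ A + b)
            assert r.t2 == pytest.approx(base, abs=1e-8 * max(1, base))

    def test_singular_covariance_rejected(self):
        X = np.zeros((10, 2))
        X[:, 0] = np.arange(10)
        X[:, 1] = 2 * X[:, 0]  # perfectly collinear
        Y = X + 1
        with pytest.raises(ValueError, match="singular|too few"):
            es.hotelling_two_sample(X, Y)

    def test_pairwise_table_covers_all_pairs(self, rng):
        samples = {e: rng.normal(i, 1, size=(12, 3))
                   for i, e in enumerate(["fear", "optimism", "neutral"])}
        table = es.pairwise_distinguishability(samples)
        assert len(table) == 3
        assert set(table.columns) >= {"emotion_a", "emotion_b", "t2", "p"}


class TestMappingMethods:
    def test_method3_angry_triads(self):
        """Distance between the RM and BL/LA published 'angry' PAD triads."""
        rm = (-0.510, 0.590, 0.250)
        bl = (-0.538, 0.543, 0.138)
        assert es.map_method3(rm, bl) == pytest.approx(0.1246, abs=0.0005)

    def test_method3_self_distance_zero(self):
        x = (0.1, -0.2, 0.3)
        assert es.map_method3(x, x) == 0.0

    def test_method2_self_reference_gives_null(self, rng):
        X = rng.normal(size=(40, 3))
        r = es.map_method2(X, X.mean(axis=0), X.std(axis=0, ddof=1), 40)
        assert r.t2 == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_method2_consistent_with_two_sample_test(self, rng):
        """Replacing the reference by a real sample with the same mean,
        covariance, and n reproduces the two-sample statistic."""
        X = rng.normal(size=(60, 3))
        Y = rng.normal(0.4, 1.0, size=(60, 3))
        # construct Y' with exactly X's covariance and Y's mean
        Yc = (Y - Y.mean(0))
        cov_y = np.cov(Yc, rowvar=False, ddof=1)
        L = np.linalg.cholesky(np.cov(X, rowvar=False, ddof=1))
        Ly = np.linalg.cholesky(cov_y)
        Yp = Yc @ np.linalg.inv(Ly).T @ L.T + Y.mean(0)
        r_two = es.hotelling_two_sample(X, Yp)
        r_m2 = es.map_method2(X, Yp.mean(axis=0), Yp.std(axis=0, ddof=1), 60)
        # method 2 uses S1 alone; the two-sample pooled covariance averages
        # S1 with S(Y')=S1, which equals S1 -- so the statistics agree
        assert r_m2.t2 == pytest.approx(r_two.t2, rel=1e-8)

    def test_method1_pools_diagonal_reference(self, rng):
        X = rng.normal(size=(30, 3))
        sd = np.array([1.0, 2.0, 0.5])
        mean = np.array([0.3, -0.1, 0.2])
        r = es.map_method1(X, mean, sd, 50)
        S1 = np.cov(X, rowvar=False, ddof=1)
        Sp = (29 * S1 + 49 * np.diag(sd ** 2)) / 78
        d = X.mean(0) - mean
        t2 = 30 * 50 / 80 * d @ np.linalg.solve(Sp, d)
        assert r.t2 == pytest.approx(t2, rel=1e-12)

    def test_reference_n_required(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="n >= 2"):
            es.map_method1(X, (0, 0, 0), (1, 1, 1), None)


class TestConvertScale:
    @pytest.mark.parametrize("x,expected", [(5, 0.0), (9, 1.0), (1, -1.0)])
    def test_survey_to_literature_map(self, x, expected):
        assert es.convert_scale(x) == pytest.approx(expected)

    def test_round_trip_exact(self):
        back = es.convert_scale(es.convert_scale(1.0), (-1, 1), (1, 9))
        assert back == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            es.convert_scale(10.0)


def _reference_from_rows(rows, source="FIX"):
    df = pd.DataFrame(rows, columns=["term", "P_mean", "P_sd", "A_mean",
                                     "A_sd", "D_mean", "D_sd", "n"])
    return es.PADReference(source, df)


class TestTopMatches:
    @pytest.fixture()
    def reference(self):
        rows = [("alpha", 0.5, 0.2, 0.5, 0.2, 0.5, 0.2, 30),
                ("beta", -0.5, 0.2, 0.1, 0.2, 0.0, 0.2, 30),
                ("gamma", 0.52, 0.2, 0.48, 0.2, 0.51, 0.2, 30),
                ("delta", 0.0, 0.2, 0.0, 0.2, 0.0, 0.2, 30),
                ("kind", 0.9, 0.2, 0.1, 0.2, 0.5, 0.2, 30),
                ("butter", 0.3, 0.2, 0.2, 0.2, 0.2, 0.2, 30)]
        return _reference_from_rows(rows)

    def test_ranking_equals_brute_force_sort(self, reference, rng):
        X = rng.normal([0.5, 0.5, 0.5], 0.1, size=(25, 3))
        got = [m.term for m in es.top_matches(X, reference, k=6, method=3)]
        mean = X.mean(axis=0)
        dists = {row["term"]: float(np.linalg.norm(
            mean - row[["P_mean", "A_mean", "D_mean"]].to_numpy(dtype=float)))
            for _, row in reference.table.iterrows()}
        expected = sorted(dists, key=lambda t: (dists[t], t))
        assert got == expected

    def test_own_mean_term_ranks_first(self, reference, rng):
        X = rng.normal(size=(20, 3))
        mean = X.mean(0)
        rows = list(reference.table.itertuples(index=False, name=None))
        rows.append(("itself", mean[0], 0.2, mean[1], 0.2, mean[2], 0.2, 30))
        ref = _reference_from_rows(rows)
        assert es.top_matches(X, ref, k=1, method=3)[0].term == "itself"

    def test_exclusion_filter_applies(self, reference, rng):
        X = rng.normal([0.8, 0.1, 0.5], 0.05, size=(15, 3))
        got = [m.term for m in es.top_matches(X, reference, k=3, method=3,
                                              exclude=["kind", "butter"])]
        assert "kind" not in got and "butter" not in got

    def test_oversized_k_warns_with_full_ranking(self, reference, rng):
        X = rng.normal(size=(10, 3))
        with pytest.warns(UserWarning, match="full ranking"):
            got = es.top_matches(X, reference, k=99, method=3)
        assert len(got) == len(reference.table)

    def test_collage_order_independent(self, reference, rng):
        X = rng.normal(size=(20, 3))
        rows2 = [("omega", 0.1, 0.2, 0.1, 0.2, 0.1, 0.2, 25),
                 ("sigma", -0.2, 0.2, 0.3, 0.2, 0.1, 0.2, 25)]
        ref2 = _reference_from_rows(rows2, source="FIX2")
        a = es.top_matches(X, reference, k=3, method=3)
        b = es.top_matches(X, ref2, k=2, method=3)
        c1 = es.semantic_collage([a, b], k=5)
        c2 = es.semantic_collage([b, a], k=5)
        assert [(m.term, m.source) for m in c1] == [(m.term, m.source) for m in c2]
        assert len(c1) == 5

    def test_empty_reference_after_filter_rejected(self, reference, rng):
        X = rng.normal(size=(5, 3))
        all_terms = reference.table["term"].tolist()
        with pytest.raises(ValueError, match="empty after exclusion"):
            es.top_matches(X, reference, k=3, method=3, exclude=all_terms)


class TestSurveyDataset:
    def test_duplicate_cell_rejected(self):
        df = pd.DataFrame({"rater_id": ["r1", "r1"], "video_id": ["v1", "v1"],
                           "pleasure": [5, 6], "arousal": [5, 5],
                           "dominance": [5, 5]})
        with pytest.raises(ValueError, match="duplicate"):
            es.SurveyDataset(df)

    def test_out_of_scale_rejected(self):
        df = pd.DataFrame({"rater_id": ["r1"], "video_id": ["v1"],
                           "pleasure": [11.0], "arousal": [5.0],
                           "dominance": [5.0]})
        with pytest.raises(ValueError, match="scale"):
            es.SurveyDataset(df)

    def test_split_list_design_analyzed_per_block(self):
        # raters 0-2 saw videos A, raters 3-5 saw videos B (incomplete design)
        fix_a = es.survey_fixture(3, 6, es.SurveyEffectSpec(noise_sd=0.05,
                                                            rater_sd=0.0), seed=1)
        fix_b = es.survey_fixture(3, 6, es.SurveyEffectSpec(noise_sd=0.05,
                                                            rater_sd=0.0), seed=2)
        a = fix_a.ratings.copy()
        b = fix_b.ratings.copy()
        b["rater_id"] = b["rater_id"].str.replace("r", "q")
        b["video_id"] = b["video_id"].str.replace("v", "w")
        merged = es.SurveyDataset(pd.concat([a, b], ignore_index=True), scale=None)
        rel = es.survey_reliability(merged)
        assert all(v > 0.95 for v in rel.values())
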