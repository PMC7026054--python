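import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqtlscores import (
    bh_adjust,
    fdr_correct,
    fit_bilateral_mixed,
    fit_linear,
    fit_quadratic,
    linear_scan,
    overlap_comparison,
)
from eqtlscores.association import AssociationResult, covariate_design


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg: q_i = min_{k: p_k >= p_i} (m * p_k / rank_k), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


def make_covariates(n, rng):
    cov = pd.DataFrame(index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"))
    cov["age"] = rng.uniform(46, 80, n)
    cov["age_squared"] = cov["age"] ** 2
    cov["sex"] = rng.integers(0, 2, n)
    for k in range(1, 16):
        cov[f"pc{k}"] = rng.standard_normal(n)
    cov["pos_x"] = rng.standard_normal(n)
    cov["pos_y"] = rng.standard_normal(n)
    cov["pos_z"] = rng.standard_normal(n)
    cov["site"] = rng.choice([1, 2], n)
    cov["array"] = rng.choice([1, 2], n)
    return cov


class TestBenjaminiHochberg:
    def test_hand_example_all_adjust_to_004(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("m", [1, 2, 7, 50, 333])
    def test_matches_brute_force_stepup_oracle(self, m):
        rng = np.random.default_rng(m)
        for _ in range(20):
            p = rng.uniform(size=m)
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_stepup_property_on_arbitrary_p_vectors(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_stepup_oracle(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1.0).all()

    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestFitLinear:
    def test_planted_effect_recovered_within_ci(self):
        rng = np.random.default_rng(4)
        n = 5000
        cov = make_covariates(n, rng)
        score = pd.Series(rng.standard_normal(n), index=cov.index)
        y = 0.05 * score + rng.standard_normal(n)
        res = fit_linear(y, score, cov)
        assert res.effect == pytest.approx(0.05, abs=1.96 * res.se)
        assert res.model == "linear" and res.n_subjects == n

    def test_perfect_fit_on_orthogonal_score(self):
        rng = np.random.default_rng(5)
        n = 60
        cov = make_covariates(n, rng)
        X = pd.concat([pd.Series(1.0, index=cov.index), covariate_design(cov)], axis=1)
        raw = rng.standard_normal(n)
        Q, _ = np.linalg.qr(X.to_numpy())
        resid = raw - Q @ (Q.T @ raw)  # exactly orthogonal to covariates
        score = pd.Series(resid / resid.std(ddof=0), index=cov.index)
        res = fit_linear(score.copy(), score, cov)
        assert res.effect == pytest.approx(1.0, abs=1e-10)
        assert res.r2_increment_pct == pytest.approx(100.0, abs=1e-6)

    def test_constant_covariate_named_in_error(self):
        rng = np.random.default_rng(6)
        cov = make_covariates(50, rng)
        cov["pc3"] = 2.5
        score = pd.Series(rng.standard_normal(50), index=cov.index)
        with pytest.raises(ValueError, match="pc3"):
            fit_linear(score * 0.1, score, cov)

    def test_type_one_error_calibrated(self):
        # 500 independent null phenotypes in one scan: rejection rate ~ alpha
        rng = np.random.default_rng(7)
        n = 400
        cov = make_covariates(n, rng)
        scores = pd.DataFrame(rng.standard_normal((n, 1)), index=cov.index, columns=["s"])
        Y = pd.DataFrame(rng.standard_normal((n, 500)), index=cov.index)
        res = linear_scan(Y, scores, cov)
        rate = np.mean([r.p < 0.05 for r in res])
        assert rate == pytest.approx(0.05, abs=0.025)


class TestLinearScan:
    def test_scan_equals_per_pair_ols(self):
        rng = np.random.default_rng(8)
        n = 300
        cov = make_covariates(n, rng)
        scores = pd.DataFrame(rng.standard_normal((n, 3)), index=cov.index,
                              columns=["a", "b", "c"])
        Y = pd.DataFrame(rng.standard_normal((n, 2)), index=cov.index, columns=["p1", "p2"])
        scan = {(r.score_id, r.phenotype): r for r in linear_scan(Y, scores, cov)}
        for s in scores.columns:
            for ph in Y.columns:
                ref = fit_linear(Y[ph], scores[s], cov)
                got = scan[(s, ph)]
                assert got.effect == pytest.approx(ref.effect, abs=1e-10)
                assert got.se == pytest.approx(ref.se, abs=1e-10)
                assert got.t == pytest.approx(ref.t, abs=1e-8)
                assert got.p == pytest.approx(ref.p, rel=1e-8)
                assert got.r2_increment_pct == pytest.approx(ref.r2_increment_pct, abs=1e-8)

    def test_score_collinear_with_covariates_rejected(self):
        rng = np.random.default_rng(9)
        n = 100
        cov = make_covariates(n, rng)
        scores = pd.DataFrame({"bad": cov["age"].to_numpy()}, index=cov.index)
        Y = pd.DataFrame(rng.standard_normal((n, 1)), index=cov.index)
        with pytest.raises(ValueError, match="bad"):
            linear_scan(Y, scores, cov)


class TestMixedModel:
    def make_long(self, values_left, values_right, ids):
        return pd.DataFrame({
            "subject_id": np.repeat(ids, 2),
            "hemisphere": np.tile(["left", "right"], len(ids)),
            "value": np.column_stack([values_left, values_right]).ravel(),
        })

    def test_identical_hemispheres_reduce_to_ols(self):
        # left == right for all subjects: the mixed-model score effect must
        # equal the single-hemisphere OLS effect
        rng = np.random.default_rng(10)
        n = 400
        cov = make_covariates(n, rng)
        score = pd.Series(rng.standard_normal(n), index=cov.index)
        y = 0.1 * score.to_numpy() + rng.standard_normal(n)
        long = self.make_long(y, y, cov.index.to_numpy())
        mixed = fit_bilateral_mixed(long, score, cov)
        ols = fit_linear(pd.Series(y, index=cov.index), score, cov)
        assert mixed.effect == pytest.approx(ols.effect, abs=1e-6)

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(11)
        n = 2000
        cov = make_covariates(n, rng)
        score = pd.Series(rng.standard_normal(n), index=cov.index)
        shared = 0.05 * score.to_numpy() + np.sqrt(0.75) * rng.standard_normal(n)
        left = shared + 0.5 * rng.standard_normal(n)
        right = shared + 0.5 * rng.standard_normal(n)
        long = self.make_long(left, right, cov.index.to_numpy())
        res = fit_bilateral_mixed(long, score, cov)
        assert res.converged
        assert res.effect == pytest.approx(0.05, abs=1.96 * res.se)

    def test_hemisphere_offset_recovered(self):
        rng = np.random.default_rng(12)
        n = 1500
        ids = np.array([f"s{i}" for i in range(n)])
        score = pd.Series(rng.standard_normal(n), index=ids)
        shared = rng.standard_normal(n)
        delta = 0.3
        left = shared + 0.4 * rng.standard_normal(n)
        right = shared + delta + 0.4 * rng.standard_normal(n)
        long = self.make_long(left, right, ids)
        import statsmodels.api as sm

        # recover delta via the hemisphere fixed effect
        hemi = (long["hemisphere"] == "right").astype(float)
        X = pd.DataFrame({"const": 1.0, "score": long["subject_id"].map(score), "hemi": hemi})
        fit = sm.MixedLM(long["value"], X, groups=long["subject_id"]).fit(reml=True)
        assert fit.params["hemi"] == pytest.approx(delta, abs=1.96 * fit.bse["hemi"])
        res = fit_bilateral_mixed(long, score)
        assert res.model == "mixed_bilateral"


class TestQuadratic:
    def test_purely_linear_truth_has_negligible_quadratic_share(self):
        rng = np.random.default_rng(13)
        n = 5000
        cov = make_covariates(n, rng)
        score = pd.Series(rng.standard_normal(n), index=cov.index)
        y = 0.3 * score + rng.standard_normal(n)
        res = fit_quadratic(y, score, cov)
        assert res.r2_quadratic_pct < 0.1

    def test_planted_quadratic_dominates(self):
        rng = np.random.default_rng(14)
        n = 2000
        cov = make_covariates(n, rng)
        score = pd.Series(rng.standard_normal(n), index=cov.index)
        y = score**2 + 0.3 * rng.standard_normal(n)
        res = fit_quadratic(y, score, cov)
        assert res.r2_quadratic_pct > 50.0
        assert res.p_quadratic < 1e-10

    def test_constant_score_is_rank_deficient(self):
        rng = np.random.default_rng(15)
        cov = make_covariates(30, rng)
        score = pd.Series(1.0, index=cov.index)
        with pytest.raises(ValueError, match="constant"):
            fit_quadratic(pd.Series(0.0, index=cov.index), score, cov)


class TestFdrFamilies:
    def result(self, p, converged=True, sid="s", ph="ph"):
        return AssociationResult(sid, ph, "FA", "linear", 0.0, 1.0, 0.0, p,
                                 converged=converged)

    def test_q_assigned_within_family(self):
        res = [self.result(p) for p in (0.01, 0.02, 0.03, 0.04)]
        out = fdr_correct(res, "toy")
        assert [r.q for r in out] == pytest.approx([0.04] * 4)
        assert all(r.q >= r.p for r in out)

    def test_empty_family(self):
        assert fdr_correct([], "empty") == []

    def test_non_converged_fits_excluded_with_warning(self, caplog):
        res = [self.result(0.01), self.result(0.5, converged=False)]
        with caplog.at_level("WARNING"):
            out = fdr_correct(res, "toy")
        assert len(out) == 1
        assert "non-converged" in caplog.text


class TestOverlapComparison:
    def test_identical_scores_give_identical_results(self):
        rng = np.random.default_rng(16)
        n = 200
        cov = make_covariates(n, rng)
        s = rng.standard_normal(n)
        scores = pd.DataFrame({"G1@a": s, "G1@b": s}, index=cov.index)
        Y = pd.DataFrame({"global": rng.standard_normal(n)}, index=cov.index)
        res = overlap_comparison("G1", scores, Y, cov)
        assert len(res) == 2
        assert res[0].effect == pytest.approx(res[1].effect, abs=1e-12)

    def test_gene_absent_from_one_study_raises(self):
        rng = np.random.default_rng(17)
        cov = make_covariates(50, rng)
        scores = pd.DataFrame({"G1@a": rng.standard_normal(50)}, index=cov.index)
        Y = pd.DataFrame({"global": rng.standard_normal(50)}, index=cov.index)
        with pytest.raises(KeyError, match="both studies"):
            overlap_comparison("G1", scores, Y, cov)

    def test_correlated_study_estimates_agree_in_sign(self):
        # same underlying effect estimated twice with noise: fitted effects concordant
        rng = np.random.default_rng(18)
        n = 800
        agreements = 0
        for _ in range(10):
            cov = make_covariates(n, rng)
            base = rng.standard_normal(n)
            s_a = base + 0.3 * rng.standard_normal(n)
            s_b = base + 0.3 * rng.standard_normal(n)
            y = 0.2 * base + rng.standard_normal(n)
            scores = pd.DataFrame({"G@a": s_a, "G@b": s_b}, index=cov.index)
            Y = pd.DataFrame({"ph": y}, index=cov.index)
            ra, rb = overlap_comparison("G", scores, Y, cov)
            agreements += np.sign(ra.effect) == np.sign(rb.effect)
        assert agreements >= 9
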