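"""FP regression: transforms, OLS against a normal-equations oracle, search."""

import numpy as np
import pandas as pd
import pytest

from dfps import (
    FPModelSpec,
    GeneratorConfig,
    SingularDesignError,
    apply_exclusion,
    compare_linear_fp,
    fit_model,
    fit_ols,
    fp_search,
    fp_transform,
    gen_region_rows,
    inv_logit,
    logit,
)


def oracle_ols(X, y, groups):
    """Independent normal-equations + sandwich oracle (no shared code paths)."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    n, k = X.shape
    labels = {g: i for i, g in enumerate(dict.fromkeys(groups))}
    G = len(labels)
    meat = np.zeros((k, k))
    for g in labels:
        Xg = X[np.asarray(groups) == g]
        ug = resid[np.asarray(groups) == g]
        s = Xg.T @ ug
        meat += np.outer(s, s)
    factor = G / (G - 1) * (n - 1) / (n - k)
    cov = factor * XtX_inv @ meat @ XtX_inv
    return beta, np.sqrt(np.diag(cov)), float(resid @ resid)


class TestFPTransform:
    def test_log_square_pair(self):
        cols = fp_transform([0.5], (0, 2))
        np.testing.assert_allclose(cols[0], [np.log(0.5), 0.25])

    def test_identity_power(self):
        x = np.array([0.2, 0.7])
        np.testing.assert_allclose(fp_transform(x, (1,))[:, 0], x)

    def test_repeated_power_adds_log_multiplied_column(self):
        e = np.e
        cols = fp_transform([e], (2, 2))
        np.testing.assert_allclose(cols[0], [e**2, e**2], rtol=1e-12)

    def test_repeated_log_power(self):
        cols = fp_transform([0.5], (0, 0))
        np.testing.assert_allclose(cols[0], [np.log(0.5), np.log(0.5) ** 2])

    def test_negative_and_half_powers(self):
        cols = fp_transform([4.0], (-2, 0.5))
        np.testing.assert_allclose(cols[0], [1 / 16, 2.0])

    def test_nonpositive_input_names_row(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            fp_transform([0.5, 0.0, 0.3], (0,))


class TestFitOLS:
    def test_noise_free_linear_fit_is_exact(self):
        x = np.linspace(1, 10, 20)
        X = np.column_stack([np.ones_like(x), x])
        y = 2.0 - 3.0 * x
        fit = fit_ols(X, y, np.arange(20) % 4)
        assert fit.coefficients == pytest.approx((2.0, -3.0), abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
            y = rng.normal(size=30)
            groups = rng.integers(0, 6, 30)
            fit = fit_ols(X, y, groups)
            beta, se, rss = oracle_ols(X, y, groups)
            np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)
            np.testing.assert_allclose(fit.robust_se, se, rtol=1e-8)
            assert fit.rss == pytest.approx(rss, rel=1e-10)

    def test_singleton_clusters_reduce_to_hc1(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(25), rng.normal(size=(25, 2))])
        y = rng.normal(size=25)
        fit = fit_ols(X, y, np.arange(25))
        hc1 = sm.OLS(y, X).fit(cov_type="HC1")
        np.testing.assert_allclose(fit.robust_se, hc1.bse, rtol=1e-6)

    def test_cluster_relabeling_invariance(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = rng.normal(size=40)
        groups = rng.integers(0, 8, 40)
        relabeled = np.array([f"z{g}" for g in groups])
        a = fit_ols(X, y, groups)
        b = fit_ols(X, y, relabeled)
        assert a.robust_se == pytest.approx(b.robust_se)

    def test_rank_deficiency_names_collinear_column(self):
        x = np.linspace(0.1, 0.9, 12)
        X = np.column_stack([np.ones_like(x), x, 2 * x])
        with pytest.raises(SingularDesignError):
            fit_ols(X, x, np.arange(12) % 3, column_names=["intercept", "x", "2x"])

    def test_too_few_rows_or_clusters(self):
        X = np.ones((2, 2))
        with pytest.raises(ValueError):
            fit_ols(X, np.zeros(2), [0, 1])
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="clusters"):
            fit_ols(X, np.zeros(10), np.zeros(10))


class TestExclusion:
    def test_low_prevalence_rows_removed_and_logged(self):
        rows = pd.DataFrame(
            {"cpr_any": [0.005, 0.4, 0.2], "cpr_m": [0.004, 0.3, 0.005]}
        )
        filtered, log = apply_exclusion(rows)
        assert len(filtered) == 1 and filtered["cpr_any"].iloc[0] == 0.4
        assert set(log["row"]) == {0, 2}

    def test_sensitivity_threshold(self):
        rows = pd.DataFrame({"cpr_any": [0.10, 0.20, 0.30], "cpr_m": [0.1, 0.2, 0.3]})
        filtered, _ = apply_exclusion(rows, threshold=0.15)
        assert list(filtered["cpr_any"]) == [0.20, 0.30]

    def test_no_op_when_all_above_threshold(self):
        rows = pd.DataFrame({"cpr_any": [0.4, 0.5], "cpr_m": [0.3, 0.4]})
        filtered, log = apply_exclusion(rows)
        pd.testing.assert_frame_equal(filtered, rows)
        assert log.empty


class TestParameterRecoveryAndSearch:
    def test_noise_free_refit_recovers_truth_exactly(self, noise_free_rows):
        data, _ = apply_exclusion(noise_free_rows)
        for outcome, truth in (
            ("DFPSany", (1.05, 0.93, 2.49, 0.70)),
            ("DFPSm", (1.12, 0.97, 2.13, -1.43)),
        ):
            fit = fit_model(data, FPModelSpec(outcome))
            np.testing.assert_allclose(fit.coefficients, truth, atol=1e-6)

    def test_search_recovers_generating_specification(self, region_rows):
        rows, _ = region_rows
        data, _ = apply_exclusion(rows)
        best = fp_search(data, "DFPSany")[0]
        assert best.spec.powers == (0.0, 2.0)
        assert best.spec.extra_covariates == ("cpdiff",)

    def test_search_ranking_invariant_to_row_order(self, region_rows):
        rows, _ = region_rows
        data, _ = apply_exclusion(rows)
        data = data.head(200)
        shuffled = data.sample(frac=1, random_state=5).reset_index(drop=True)
        keys_a = [(m.spec.powers, m.spec.extra_covariates) for m in fp_search(data, "DFPSm")]
        keys_b = [(m.spec.powers, m.spec.extra_covariates) for m in fp_search(shuffled, "DFPSm")]
        assert keys_a == keys_b

    def test_nesting_monotonicity_of_rss(self, region_rows):
        rows, _ = region_rows
        data, _ = apply_exclusion(rows)
        ranked = fp_search(data, "DFPSany", candidate_extras=())
        by_spec = {m.spec.powers: m.rss for m in ranked}
        best_deg2 = min(v for p, v in by_spec.items() if len(p) == 2)
        best_deg1 = min(v for p, v in by_spec.items() if len(p) == 1)
        assert best_deg2 <= best_deg1 + 1e-12
        # adding cpdiff can only reduce the best achievable rss
        with_cd = fp_search(data, "DFPSany", candidate_extras=("cpdiff",))[0].rss
        assert with_cd <= best_deg2 + 1e-12


class TestLinearVsFP:
    @staticmethod
    def _linear_logit_rows(seed, n=80, slope=3.0, intercept=-0.5, noise=0.07):
        rng = np.random.default_rng(seed)
        cpr = rng.uniform(0.16, 0.85, n)
        cpdiff = rng.uniform(0, 0.15, n)
        eta = intercept + slope * cpr + rng.normal(0, noise, n)
        return pd.DataFrame(
            {
                "country_id": np.repeat([f"C{i}" for i in range(10)], n // 10),
                "cpr_any": cpr,
                "cpr_m": cpr - cpdiff,
                "cpdiff": cpdiff,
                "dfps_any": inv_logit(eta),
                "dfps_m": inv_logit(eta),
            }
        )

    def test_no_spurious_curvature_under_linear_truth(self):
        # data simulated from a straight-line logit relationship: the FP terms
        # should rarely test significant at the 5% level
        hits = sum(
            compare_linear_fp(self._linear_logit_rows(seed), "DFPSany").p_value < 0.05
            for seed in range(40)
        )
        assert hits <= 4  # non-significant in >= 90% of replicates

    def test_fp_beats_linear_on_curved_truth(self, region_rows):
        rows, _ = region_rows
        report = compare_linear_fp(rows, "DFPSany", threshold=0.01)
        assert report.fp_improves
        assert report.best_fp.rss < report.linear.rss
        assert report.p_value < 1e-6  # strong curvature over the full range

    def test_report_is_deterministic(self, region_rows):
        rows, _ = region_rows
        a = compare_linear_fp(rows, "DFPSm")
        b = compare_linear_fp(rows.copy(), "DFPSm")
        assert a.f_statistic == b.f_statistic and a.p_value == b.p_value

    def test_high_prevalence_restriction_weakens_curvature_evidence(self, region_rows):
        # over the restricted >=15% range the relationship is close to linear,
        # so the F statistic shrinks relative to the full-range comparison
        rows, _ = region_rows
        full = compare_linear_fp(rows, "DFPSany", threshold=0.01)
        restricted = compare_linear_fp(rows, "DFPSany", threshold=0.15)
        assert restricted.f_statistic < full.f_statistic
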