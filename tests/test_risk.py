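"""IPW estimation and weighted logistic risk models."""

import numpy as np
import pandas as pd
import pytest

import polyvoxel as pv
from polyvoxel.datatypes import CategoryError, InputError, SeparationError
from polyvoxel.risk import WeightScheme, assign_quartiles


def _cohort(n, seed=0, prevalence=0.2):
    rng = np.random.default_rng(seed)
    d = {
        "subject_id": [f"S{i}" for i in range(n)],
        "genotype_class": ["wildtype"] * n,
        "age": rng.uniform(45, 80, n),
        "sex": np.where(rng.uniform(size=n) < 0.5, "F", "M"),
        "scanner": [f"sc{j}" for j in rng.integers(0, 2, n)],
        "has_imaging": 1,
        "dx_disease": (rng.uniform(size=n) < prevalence).astype(int),
    }
    for i in range(1, 11):
        d[f"pc{i}"] = rng.standard_normal(n)
    return pd.DataFrame(d)


class TestEstimateIPW:
    def test_equal_prevalence_gives_unit_weight(self):
        t = _cohort(200, seed=1)
        scheme = pv.estimate_ipw(t, t, "dx_disease")
        assert scheme.case_weight == 1.0

    def test_arithmetic_example(self):
        full = pd.DataFrame({"dx_disease": [1] * 20 + [0] * 980})  # 0.02
        img = pd.DataFrame({"dx_disease": [1] * 2 + [0] * 398})  # 0.005
        scheme = pv.estimate_ipw(full, img, "dx_disease")
        np.testing.assert_allclose(scheme.case_weight, 4.0, atol=1e-12)

    def test_weighted_prevalence_identity(self):
        """Case weight times imaging prevalence recovers full prevalence
        exactly (by construction)."""
        rng = np.random.default_rng(2)
        full = pd.DataFrame({"dx_disease": rng.integers(0, 2, 5000)})
        img = full.sample(800, random_state=3)
        scheme = pv.estimate_ipw(full, img, "dx_disease")
        recovered = scheme.case_weight * img["dx_disease"].mean()
        assert abs(recovered - full["dx_disease"].mean()) < 1e-12

    def test_zero_imaging_cases_rejected(self):
        full = pd.DataFrame({"dx_disease": [1, 0, 0]})
        img = pd.DataFrame({"dx_disease": [0, 0]})
        with pytest.raises(InputError):
            pv.estimate_ipw(full, img, "dx_disease")


class TestWeightedLogistic:
    def test_unweighted_or_equals_contingency_cross_product(self):
        rng = np.random.default_rng(3)
        t = _cohort(600, seed=3)
        x = rng.integers(0, 2, size=600).astype(float)
        # plant an association
        t["dx_disease"] = (
            rng.uniform(size=600) < np.where(x == 1, 0.35, 0.15)
        ).astype(int)
        fit = pv.weighted_logistic(t, "dx_disease", x, covariates=False)
        y = t["dx_disease"].to_numpy()
        a = ((x == 1) & (y == 1)).sum()
        b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum()
        d = ((x == 0) & (y == 0)).sum()
        oracle = (a * d) / (b * c)
        # fitted predictor is standardized, so rescale the log-OR
        log_or_per_unit = np.log(fit.term("pvs")["or_"]) / x.std(ddof=0)
        np.testing.assert_allclose(np.exp(log_or_per_unit), oracle, rtol=1e-6)

    def test_weighted_or_equals_weighted_cross_product(self):
        rng = np.random.default_rng(4)
        t = _cohort(500, seed=4)
        x = rng.integers(0, 2, size=500).astype(float)
        t["dx_disease"] = (rng.uniform(size=500) < np.where(x == 1, 0.4, 0.2)).astype(int)
        y = t["dx_disease"].to_numpy()
        w = np.where(y == 1, 3.25, 1.0)
        fit = pv.weighted_logistic(t, "dx_disease", x, weights=w, covariates=False)
        wa = w[(x == 1) & (y == 1)].sum()
        wb = w[(x == 1) & (y == 0)].sum()
        wc = w[(x == 0) & (y == 1)].sum()
        wd = w[(x == 0) & (y == 0)].sum()
        oracle = (wa * wd) / (wb * wc)
        log_or_per_unit = np.log(fit.term("pvs")["or_"]) / x.std(ddof=0)
        np.testing.assert_allclose(np.exp(log_or_per_unit), oracle, rtol=1e-6)

    def test_doubling_weights_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(5)
        t = _cohort(400, seed=5)
        x = rng.normal(size=400)
        w = rng.uniform(1, 4, size=400)
        f1 = pv.weighted_logistic(t, "dx_disease", x, weights=w)
        f2 = pv.weighted_logistic(t, "dx_disease", x, weights=2 * w)
        np.testing.assert_allclose(f1.table["coef"], f2.table["coef"], atol=1e-8)

    def test_null_coverage_of_or_ci(self):
        """Predictor independent of outcome: 95% Wald CI covers OR=1 at
        approximately nominal rate."""
        rng = np.random.default_rng(6)
        covered = 0
        n_rep = 120
        for _ in range(n_rep):
            n = 300
            y = (rng.uniform(size=n) < 0.3).astype(int)
            x = rng.normal(size=n)
            t = _cohort(n, seed=int(rng.integers(2**31)))
            t["dx_disease"] = y
            fit = pv.weighted_logistic(t, "dx_disease", x, covariates=False)
            row = fit.term("pvs")
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered / n_rep >= 0.89

    def test_separation_detected(self):
        t = _cohort(80, seed=7)
        x = np.linspace(-1, 1, 80)
        t["dx_disease"] = (x > 0).astype(int)
        with pytest.raises(SeparationError):
            pv.weighted_logistic(t, "dx_disease", x, covariates=False)

    def test_or_per_sd_metadata(self):
        t = _cohort(300, seed=8)
        fit = pv.weighted_logistic(
            t, "dx_disease", np.random.default_rng(8).normal(size=300)
        )
        assert fit.meta["pvs_scale"] == "per-SD"
        assert (fit.table["ci_low"] <= fit.table["or_"]).all()
        assert (fit.table["or_"] <= fit.table["ci_high"]).all()


class TestAssignQuartiles:
    def test_eight_distinct_values_two_per_quartile(self):
        pvs = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        labels = assign_quartiles(pvs, np.zeros(8, bool))
        counts = pd.Series(labels).value_counts()
        assert counts["Q1"] == counts["Q2"] == counts["Q3"] == counts["Q4"] == 2

    def test_boundary_ties_go_to_lower_quartile(self):
        pvs = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        bound = np.quantile(pvs, 0.25)  # = 1.0
        labels = assign_quartiles(pvs, np.zeros(5, bool))
        assert labels[np.where(pvs == bound)[0][0]] == "Q1"

    def test_homozygotes_get_own_category_and_no_boundary_vote(self):
        pvs = np.concatenate([np.arange(8.0), [100.0, 200.0]])
        hom = np.array([False] * 8 + [True, True])
        labels = assign_quartiles(pvs, hom)
        assert (labels[-2:] == "homozygote").all()
        # boundaries from the 8 non-homozygotes only
        counts = pd.Series(labels[:8]).value_counts()
        assert counts.max() == counts.min() == 2


class TestQuantileRisk:
    def _u_shape_cohort(self, n=6000, seed=9):
        rng = np.random.default_rng(seed)
        t = _cohort(n, seed=seed)
        L = rng.normal(size=n)
        hom = rng.uniform(size=n) < 0.02
        L[hom] += 3.0
        logit = -2.5 + 0.5 * (L - 1.2) ** 2
        t["dx_disease"] = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
        t.loc[hom, "genotype_class"] = "homozygote"
        return t, L, hom

    def test_reference_level_absent_and_groups_reported(self):
        t, L, hom = self._u_shape_cohort()
        fit = pv.quantile_risk(t, L, hom, "dx_disease")
        terms = set(fit.table["term"])
        assert "Q4" not in terms
        assert {"Q1", "Q2", "Q3", "homozygote"} <= terms
        assert fit.meta["reference"] == "Q4"

    def test_u_shape_recovered(self):
        t, L, hom = self._u_shape_cohort()
        fit = pv.quantile_risk(t, L, hom, "dx_disease", covariates=False)
        or_q1 = fit.term("Q1")["or_"]
        or_hom = fit.term("homozygote")["or_"]
        assert or_q1 > 1 and fit.term("Q1")["ci_low"] > 1
        assert or_hom > 1
        assert max(fit.term("Q2")["or_"], fit.term("Q3")["or_"]) < or_q1

    def test_weight_scheme_applies_to_imaged_cases_only(self):
        scheme = WeightScheme(case_weight=3.0, outcome="dx_disease")
        y = np.array([1, 1, 0, 0])
        img = np.array([1, 0, 1, 0])
        np.testing.assert_allclose(
            scheme.weights_for(y, img), [3.0, 1.0, 1.0, 1.0]
        )

    def test_empty_category_rejected(self):
        t, L, hom = self._u_shape_cohort(n=500)
        with pytest.raises(CategoryError):
            pv.quantile_risk(t, L, np.zeros(len(t), bool), "dx_disease")
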