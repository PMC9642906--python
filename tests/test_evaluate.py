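import math

import numpy as np
import pandas as pd
import pytest

import trajclust as tc
from trajclust.evaluate import (LRTResult, ModelFit, ModelSpec, _stratified_folds,
                                auroc, information_criteria, likelihood_ratio_test)

from _oracles import auroc_pairwise_oracle


def intercept_only_fit(loglik, n_params, n_obs, family="binary"):
    """Stub ModelFit for testing the comparison arithmetic in isolation."""
    return ModelFit(
        spec=ModelSpec("y", family, ()),
        loglik=loglik, n_params=n_params, n_obs=n_obs,
        params=pd.Series(np.zeros(n_params),
                         index=["const"] + [f"b{i}" for i in range(n_params - 1)]),
        bse=pd.Series(np.ones(n_params)),
        fitted=np.full(n_obs, 0.5),
    )


class TestFitGlm:
    def test_binomial_closed_form(self):
        d = pd.DataFrame({"y": [1] * 7 + [0] * 3})
        fit = tc.fit_glm(ModelSpec("y", "binary", ()), d)
        assert fit.fitted[0] == pytest.approx(0.7, abs=1e-8)
        assert fit.loglik == pytest.approx(7 * math.log(0.7) + 3 * math.log(0.3),
                                           abs=1e-8)
        assert fit.n_params == 1 and fit.n_obs == 10

    def test_poisson_closed_form(self):
        d = pd.DataFrame({"y": [0, 1, 2, 3]})
        fit = tc.fit_glm(ModelSpec("y", "count", ()), d)
        assert fit.fitted[0] == pytest.approx(1.5, abs=1e-8)
        expected_ll = sum(-1.5 + y * math.log(1.5) - math.lgamma(y + 1)
                          for y in [0, 1, 2, 3])
        assert fit.loglik == pytest.approx(expected_ll, abs=1e-8)

    def test_constant_outcome_flagged(self):
        d = pd.DataFrame({"y": [0] * 20, "age": np.linspace(20, 60, 20)})
        fit = tc.fit_glm(ModelSpec("y", "binary", ("age",)), d)
        assert fit.flagged

    def test_perfect_separation_flagged_not_silent(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        d = pd.DataFrame({"y": x.astype(int), "age": 30 + 20 * x})
        fit = tc.fit_glm(ModelSpec("y", "binary", ("age",)), d)
        assert fit.flagged and fit.messages

    def test_rank_deficient_design_names_columns(self):
        d = pd.DataFrame({
            "y": [0, 1, 0, 1, 1, 0],
            "ever": [0, 1, 0, 1, 1, 0.0],
            "mean": [0, 1, 0, 1, 1, 0.0],  # exact copy of ever
        })
        with pytest.raises(ValueError, match="collinear.*(ever|mean)"):
            tc.fit_glm(ModelSpec("y", "binary", ("ever", "mean")), d)

    def test_missing_covariate_rejected(self):
        d = pd.DataFrame({"y": [0, 1], "age": [40.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            tc.fit_glm(ModelSpec("y", "binary", ("age",)), d)

    def test_prior_syphilis_coding_switches_with_family(self):
        d = pd.DataFrame({
            "y": [0, 1, 2, 0, 1, 3],
            "prior_syphilis": [0, 1, 1, 0, 0, 1],
            "prior_syphilis_count": [0, 1, 3, 0, 0, 2],
        })
        fit_bin = tc.fit_glm(ModelSpec("y", "binary", ("prior_syphilis",)),
                             d.assign(y=(d["y"] > 0).astype(int)))
        fit_cnt = tc.fit_glm(ModelSpec("y", "count", ("prior_syphilis",)), d)
        assert "prior_syphilis" in fit_bin.params.index
        assert "prior_syphilis_count" in fit_cnt.params.index


class TestLikelihoodRatio:
    def test_identical_fits_give_p_one(self):
        f = intercept_only_fit(-10.0, 2, 50)
        assert likelihood_ratio_test(f, f).pvalue == 1.0

    @pytest.mark.parametrize("stat,df,expected",
                             [(3.841, 1, 0.0500), (13.28, 4, 0.0100)])
    def test_chi_square_tail_examples(self, stat, df, expected):
        nested = intercept_only_fit(-100.0, 1, 200)
        full = intercept_only_fit(-100.0 + stat / 2, 1 + df, 200)
        res = likelihood_ratio_test(full, nested)
        assert res.statistic == pytest.approx(stat)
        assert res.pvalue == pytest.approx(expected, abs=5e-5)

    def test_non_nested_specs_rejected(self):
        nested = intercept_only_fit(-10.0, 3, 50)
        full = intercept_only_fit(-9.0, 2, 50)
        with pytest.raises(ValueError):
            likelihood_ratio_test(full, nested)

    def test_worse_full_loglik_rejected(self):
        nested = intercept_only_fit(-10.0, 1, 50)
        full = intercept_only_fit(-11.0, 2, 50)
        full.params.index = ["const", "extra"]
        with pytest.raises(ValueError, match="nesting"):
            likelihood_ratio_test(full, nested)


class TestInformationCriteria:
    def test_formula_example(self):
        fit = intercept_only_fit(-100.0, 3, 100)
        aic, bic = information_criteria(fit)
        assert aic == pytest.approx(206.0, abs=1e-9)
        assert bic == pytest.approx(200 + 3 * math.log(100), abs=1e-9)

    def test_useless_parameter_raises_bic_by_log_n(self):
        f1 = intercept_only_fit(-80.0, 2, 400)
        f2 = intercept_only_fit(-80.0, 3, 400)
        _, b1 = information_criteria(f1)
        _, b2 = information_criteria(f2)
        assert b2 - b1 == pytest.approx(math.log(400), abs=1e-9)

    def test_identities_against_loglik(self, small_run):
        data = small_run["data"]
        fit = tc.fit_glm(ModelSpec("first_nsCAI", "binary",
                                   ("age", "last_flag", "prior_syphilis")), data)
        aic, bic = information_criteria(fit)
        assert aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params, abs=1e-9)
        assert bic == pytest.approx(-2 * fit.loglik + fit.n_params * math.log(fit.n_obs),
                                    abs=1e-9)


class TestAuroc:
    def test_worked_examples(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5
        assert auroc([0.9, 0.8, 0.3], [1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 5, size=n) / 4.0  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == auroc_pairwise_oracle(scores, labels)


class TestCrossValidation:
    def _data(self, n=200, seed=0, signal=True):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-6 * x)) if signal else np.full(n, 0.4)
        return pd.DataFrame({
            "y": (rng.random(n) < p).astype(int),
            "age": 40 + 10 * x,
            "last_flag": rng.integers(0, 2, n).astype(float),
            "prior_syphilis": rng.integers(0, 2, n).astype(float),
        })

    def test_fold_structure(self):
        y = np.r_[np.ones(13), np.zeros(40)]
        folds = _stratified_folds(y, 5, seed=1)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds)) == list(range(53))

    def test_same_seed_identical_reports(self):
        d = self._data()
        spec_w = ModelSpec("y", "binary", ("age", "last_flag", "prior_syphilis"))
        spec_wo = ModelSpec("y", "binary", ("last_flag", "prior_syphilis"))
        r1 = tc.kfold_cv(spec_w, spec_wo, d, seed=4)
        r2 = tc.kfold_cv(spec_w, spec_wo, d, seed=4)
        assert r1[0].fold_accuracy == r2[0].fold_accuracy
        assert r1[1].pooled_auroc == r2[1].pooled_auroc

    def test_strong_signal_high_accuracy(self):
        d = self._data(signal=True)
        spec_w = ModelSpec("y", "binary", ("age",))
        spec_wo = ModelSpec("y", "binary", ())
        cv_w, cv_wo = tc.kfold_cv(spec_w, spec_wo, d, seed=0)
        assert cv_w.pooled_accuracy > 0.85
        assert cv_w.pooled_auroc > 0.9

    def test_null_signal_matches_majority_class(self):
        d = self._data(n=2000, seed=3, signal=False)
        spec_w = ModelSpec("y", "binary", ("age", "last_flag"))
        spec_wo = ModelSpec("y", "binary", ())
        cv_w, _ = tc.kfold_cv(spec_w, spec_wo, d, seed=0)
        base = max(d["y"].mean(), 1 - d["y"].mean())
        se = np.sqrt(base * (1 - base) / len(d))
        assert abs(cv_w.pooled_accuracy - base) < 3 * se

    def test_count_family_rejected(self):
        d = self._data()
        spec = ModelSpec("y", "count", ("age",))
        with pytest.raises(ValueError):
            tc.kfold_cv(spec, spec, d)


class TestCompareModels:
    def test_comparator_none_reduces_to_nested(self, small_run):
        row = tc.compare_models("first_nsCAI", small_run["data"], "none")
        assert row.p_lrt == 1.0
        assert row.aic_with == row.aic_without

    def test_comparator_last_duplicates_adjustment_set(self, small_run):
        row = tc.compare_models("first_nsCAI", small_run["data"], "last")
        assert row.p_lrt == 1.0

    def test_unknown_comparator_rejected(self, small_run):
        with pytest.raises(ValueError):
            tc.compare_models("first_nsCAI", small_run["data"], "bogus")

    def test_cluster_comparator_on_planted_data(self, small_run):
        row = tc.compare_models("first_nsCAI", small_run["data"], "cluster")
        assert row.p_lrt < 0.05
        assert row.auroc_with > row.auroc_without


class TestSweep:
    def test_loglik_monotone_in_k(self, small_run):
        table, _ = tc.sweep_cluster_number(
            small_run["dendrogram"], small_run["matrix"], small_run["data"],
            "first_nsCAI", range(1, 7))
        assert np.all(np.diff(table["loglik"]) >= -1e-6)

    def test_k1_equals_ever_style_two_level_fit(self, small_run):
        """One hierarchical cluster + baseline is exactly an ever/never split."""
        table, _ = tc.sweep_cluster_number(
            small_run["dendrogram"], small_run["matrix"], small_run["data"],
            "first_nsCAI", [1])
        direct = tc.fit_glm(
            ModelSpec("first_nsCAI", "binary",
                      ("age", "last_flag", "prior_syphilis", "ever")),
            small_run["data"])
        assert table.loc[0, "loglik"] == pytest.approx(direct.loglik, abs=1e-6)

    def test_empty_k_range_rejected(self, small_run):
        with pytest.raises(ValueError):
            tc.sweep_cluster_number(small_run["dendrogram"], small_run["matrix"],
                                    small_run["data"], "first_nsCAI", [])

    def test_true_labels_never_hurt_loglik(self, small_study, small_run):
        data = small_run["data"].copy()
        planted = small_study["truth"].labels_series().reindex(data.index)
        data["cluster"] = planted
        nested = tc.fit_glm(ModelSpec("first_nsCAI", "binary",
                                      ("age", "last_flag", "prior_syphilis")), data)
        full = tc.fit_glm(ModelSpec("first_nsCAI", "binary",
                                    ("age", "last_flag", "prior_syphilis", "cluster")),
                          data)
        assert full.loglik >= nested.loglik - 1e-6
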