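"""Correctness of the four treatment-effect analyses and the variance LRT.

The mixed model and the meta-analysis are checked against values computed
with the reference R implementations (lmerTest for the Satterthwaite mixed
model, metafor::rma(method="REML") with a tightened convergence threshold
for the meta-analysis) on datasets regenerated here from their seeds.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multibatch import (
    SimConfig,
    StructuralError,
    analyze_all,
    analyze_fixed,
    analyze_meta,
    analyze_pooled,
    analyze_random,
    simulate_experiment,
    variance_model_lrt,
)
from tests.conftest import rates_frame


def per_batch_mean_diffs(data: pd.DataFrame) -> pd.Series:
    cm = data.groupby(["batch_id", "group"])["rate"].mean().unstack()
    return cm["treated"] - cm["control"]


class TestPooled:
    def test_identical_groups_give_zero_effect(self):
        data = rates_frame(
            {"B1": {"control": [0.1, 0.12, 0.09], "treated": [0.1, 0.12, 0.09]}}
        )
        r = analyze_pooled(data)
        assert r.estimate == 0.0
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_equal_variance_t_test(self, seed):
        data = simulate_experiment(
            SimConfig(gri=0.2, batch_sd_prop=0.3, seed=seed)
        )
        r = analyze_pooled(data)
        t, p = stats.ttest_ind(
            data.loc[data.group == "treated", "rate"],
            data.loc[data.group == "control", "rate"],
            equal_var=True,
        )
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)
        assert r.estimate == pytest.approx(
            data.loc[data.group == "treated", "rate"].mean()
            - data.loc[data.group == "control", "rate"].mean(),
            abs=1e-12,
        )

    def test_single_group_rejected(self):
        data = rates_frame({"B1": {"control": [0.1, 0.2, 0.15]}})
        with pytest.raises(StructuralError):
            analyze_pooled(data)


class TestFixed:
    def test_estimate_is_unweighted_mean_of_batch_differences(
        self, effect_dataset
    ):
        r = analyze_fixed(effect_dataset)
        assert r.estimate == pytest.approx(
            per_batch_mean_diffs(effect_dataset).mean(), abs=1e-12
        )

    def test_matches_statsmodels_type3_anova_unbalanced(self, effect_dataset):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        data = effect_dataset.drop(index=[0, 7, 22]).reset_index(drop=True)
        r = analyze_fixed(data)
        m = smf.ols("rate ~ C(group, Sum) * C(batch_id, Sum)", data).fit()
        a = anova_lm(m, typ=3)
        assert r.statistic**2 == pytest.approx(
            a.loc["C(group, Sum)", "F"], rel=1e-9
        )
        assert r.p_value == pytest.approx(
            a.loc["C(group, Sum)", "PR(>F)"], abs=1e-12
        )
        assert r.df == m.df_resid

    def test_copied_batches_match_pooled_with_tighter_residual(self):
        base = {"control": [0.10, 0.13, 0.08, 0.12], "treated": [0.07, 0.09, 0.06, 0.08]}
        data = rates_frame({"B1": base, "B2": base, "B3": base})
        fixed = analyze_fixed(data)
        pooled = analyze_pooled(data)
        assert fixed.estimate == pytest.approx(pooled.estimate, abs=1e-12)
        # no batch signal: batch and interaction explain nothing, so the
        # factorial model's residual SS cannot exceed the pooled model's
        ss_fixed = fixed.components["sigma2_e"] * fixed.df
        ss_pooled = pooled.components["sigma2_e"] * pooled.df
        assert ss_fixed <= ss_pooled + 1e-12

    def test_empty_cell_named_in_error(self, effect_dataset):
        broken = effect_dataset[
            ~((effect_dataset.batch_id == "B2")
              & (effect_dataset.group == "treated"))
        ]
        with pytest.raises(StructuralError, match="B2.*treated"):
            analyze_fixed(broken)

    def test_single_batch_rejected(self):
        data = rates_frame(
            {"B1": {"control": [0.1, 0.11, 0.09], "treated": [0.08, 0.07, 0.09]}}
        )
        with pytest.raises(StructuralError):
            analyze_fixed(data)


class TestRandom:
    def test_balanced_estimate_equals_mean_batch_difference(
        self, effect_dataset
    ):
        r = analyze_random(effect_dataset)
        assert r.estimate == pytest.approx(
            per_batch_mean_diffs(effect_dataset).mean(), abs=1e-8
        )

    def test_matches_lmerTest_ml_fit(self, effect_dataset):
        # reference: R lmerTest, lmer(rate ~ group + (1|batch) + (1|batch:group),
        # REML=FALSE) on this exact dataset
        r = analyze_random(effect_dataset)
        assert r.estimate == pytest.approx(-0.01849606099, abs=1e-9)
        assert r.se == pytest.approx(0.007540951533, rel=1e-3)
        assert r.df == pytest.approx(3.00079, abs=0.05)
        assert r.p_value == pytest.approx(0.091432859, abs=5e-4)
        assert r.components["sigma2_b"] == pytest.approx(6.8938805e-05, rel=0.02)
        assert r.components["sigma2_e"] == pytest.approx(0.00040979725, rel=0.02)

    def test_matches_lmerTest_reml_fit(self, effect_dataset, null_dataset):
        r = analyze_random(effect_dataset, reml=True)
        assert r.estimate == pytest.approx(-0.01849606099, abs=1e-9)
        assert r.se == pytest.approx(0.009231992007, rel=1e-3)
        assert r.df == pytest.approx(2.00045, abs=0.05)
        assert r.p_value == pytest.approx(0.18300292, abs=5e-4)
        assert r.components["sigma2_c"] == pytest.approx(4.5876806e-05, rel=0.02)
        assert r.components["sigma2_b"] == pytest.approx(0.00010339564, rel=0.02)
        # boundary dataset: the interaction component truncates at zero and
        # the Satterthwaite df adapts to the residual df
        rn = analyze_random(null_dataset, reml=True)
        assert rn.components["sigma2_c"] == 0.0
        assert rn.boundary
        assert rn.df == pytest.approx(26.0, abs=0.05)
        assert rn.p_value == pytest.approx(0.1929025, abs=5e-4)

    def test_matches_statsmodels_mixedlm_components(self, effect_dataset):
        sm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        data = effect_dataset.copy()
        data["treated"] = (data.group == "treated").astype(float)
        m = sm.MixedLM.from_formula(
            "rate ~ treated",
            groups="batch_id",
            re_formula="1",
            vc_formula={"cell": "0 + C(group)"},
            data=data,
        ).fit(reml=True)
        mine = analyze_random(effect_dataset, reml=True)
        assert mine.estimate == pytest.approx(m.params["treated"], abs=1e-6)
        assert mine.components["sigma2_e"] == pytest.approx(m.scale, rel=1e-3)

    def test_vanishing_components_approach_pooled_analysis(self):
        data = simulate_experiment(
            SimConfig(n_batches=30, batch_sd_prop=0.0, gri=0.3,
                      gri_sd_prop=0.0, seed=11)
        )
        r = analyze_random(data)
        pooled = analyze_pooled(data)
        # with no true batch structure the fitted components are small
        # relative to the residual variance and the inference approaches
        # the batch-ignoring analysis
        assert r.components["sigma2_b"] < 0.15 * r.components["sigma2_e"]
        assert r.components["sigma2_c"] < 0.15 * r.components["sigma2_e"]
        assert r.p_value == pytest.approx(pooled.p_value, abs=0.03)

    def test_single_batch_rejected(self):
        data = rates_frame(
            {"B1": {"control": [0.1, 0.11, 0.09], "treated": [0.08, 0.07, 0.09]}}
        )
        with pytest.raises(StructuralError):
            analyze_random(data)


class TestMeta:
    def test_homogeneous_batches_give_zero_tau2(self):
        base = {"control": [0.10, 0.12, 0.11], "treated": [0.08, 0.10, 0.09]}
        data = rates_frame({"B1": base, "B2": base, "B3": base})
        r = analyze_meta(data)
        assert r.components["tau2"] == 0.0
        assert r.estimate == pytest.approx(-0.02, abs=1e-12)

    def test_equal_sampling_variances_weights_cancel(self):
        # same within-batch spread everywhere -> equal v_i -> plain mean of T_i
        data = rates_frame(
            {
                "B1": {"control": [0.10, 0.12], "treated": [0.06, 0.08]},
                "B2": {"control": [0.11, 0.13], "treated": [0.09, 0.11]},
                "B3": {"control": [0.09, 0.11], "treated": [0.08, 0.10]},
            }
        )
        r = analyze_meta(data)
        assert r.estimate == pytest.approx(
            per_batch_mean_diffs(data).mean(), abs=1e-10
        )

    def test_p_value_is_normal_tail(self, effect_dataset):
        r = analyze_meta(effect_dataset)
        expected = 2.0 * (1.0 - stats.norm.cdf(abs(r.estimate / r.se)))
        assert r.p_value == pytest.approx(expected, abs=1e-12)
        assert r.df is None

    def test_matches_metafor_reml(self, effect_dataset):
        # reference: R metafor::rma(yi, vi, method="REML") at threshold 1e-10
        r = analyze_meta(effect_dataset)
        assert r.estimate == pytest.approx(-0.0176656338946, rel=1e-6)
        assert r.se == pytest.approx(0.0104511817524, rel=1e-6)
        assert r.p_value == pytest.approx(0.09097054989, abs=1e-7)
        assert r.components["tau2"] == pytest.approx(0.000176900727209, rel=1e-5)

    def test_small_cell_rejected(self):
        data = rates_frame(
            {
                "B1": {"control": [0.1, 0.11], "treated": [0.08]},
                "B2": {"control": [0.1, 0.12], "treated": [0.07, 0.09]},
            }
        )
        with pytest.raises(StructuralError, match="inestimable"):
            analyze_meta(data)


class TestCrossMethodInvariants:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_balanced_point_estimates_agree(self, seed):
        data = simulate_experiment(
            SimConfig(baseline_mean=0.105, baseline_sd=0.026, gri=0.3,
                      gri_sd_prop=0.3, batch_sd_prop=0.3, seed=seed)
        )
        results = analyze_all(data)
        target = per_batch_mean_diffs(data).mean()
        for method in ("pooled", "fixed", "random"):
            assert results[method].estimate == pytest.approx(target, abs=1e-8)
        signs = {np.sign(r.estimate) for r in results.values()}
        assert len(signs) == 1

    def test_heterogeneity_inflates_tau2_and_sigma2_c(self):
        """tau2 and sigma2_c grow (in Monte-Carlo mean) with the between-batch
        spread of the treatment effect."""
        lo, hi = [], []
        for seed in range(40):
            d0 = simulate_experiment(
                SimConfig(baseline_mean=0.105, baseline_sd=0.026, gri=0.3,
                          gri_sd_prop=0.0, seed=1000 + seed)
            )
            d1 = simulate_experiment(
                SimConfig(baseline_mean=0.105, baseline_sd=0.026, gri=0.3,
                          gri_sd_prop=1.0, seed=1000 + seed)
            )
            lo.append((analyze_meta(d0).components["tau2"],
                       analyze_random(d0).components["sigma2_c"]))
            hi.append((analyze_meta(d1).components["tau2"],
                       analyze_random(d1).components["sigma2_c"]))
        lo, hi = np.array(lo), np.array(hi)
        assert hi[:, 0].mean() > lo[:, 0].mean()
        assert hi[:, 1].mean() > lo[:, 1].mean()


class TestVarianceModelLRT:
    def test_identical_levels_give_null_result(self):
        base = {"control": [0.10, 0.12, 0.11, 0.13], "treated": [0.10, 0.12, 0.11, 0.13]}
        data = rates_frame({"B1": base})
        stat, df, p = variance_model_lrt(data, variance_by="treatment")
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_statistic_nonnegative(self, seed):
        data = simulate_experiment(SimConfig(batch_sd_prop=0.3, seed=seed))
        for variance_by, mean_by in [("treatment", None), ("treatment", "treatment"),
                                     ("batch", "batch"), ("batch", "treatment")]:
            stat, df, p = variance_model_lrt(data, variance_by, mean_by)
            assert stat >= 0.0
            assert 0.0 <= p <= 1.0

    def test_detects_threefold_variance_ratio(self):
        """Two groups of n=200 with a 3-fold variance ratio: the LRT flags
        heterogeneity in the large majority of replicates."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame(
                {
                    "animal_id": [f"A{i}" for i in range(400)],
                    "batch_id": "B1",
                    "group": ["control"] * 200 + ["treated"] * 200,
                    "rate": np.concatenate(
                        [rng.normal(0.1, 0.03, 200),
                         rng.normal(0.1, 0.03 * np.sqrt(3.0), 200)]
                    ),
                }
            )
            _, _, p = variance_model_lrt(data, "treatment", mean_by="treatment")
            hits += p < 0.05
        assert hits >= 15

    def test_tiny_level_rejected(self):
        data = rates_frame(
            {"B1": {"control": [0.1, 0.11, 0.12], "treated": [0.08]}}
        )
        with pytest.raises(StructuralError, match="< 2 observations"):
            variance_model_lrt(data, "treatment")
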