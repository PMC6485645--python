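"""Bayesian mixed-effects fitting: priors, recovery, AIC, cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from pdacsim import (
    LesionClass,
    McmcOptions,
    MixedEffectsSpec,
    ModelKind,
    TreatmentContext,
    VolumeSeries,
    fit_mixed_model,
    generate_cohort,
    recovery_cohort_config,
    sample_prior,
    select_model,
    summarize_cohort,
)
from pdacsim.inference import (
    RATE_PRIOR_METASTASIS,
    RATE_PRIOR_PRIMARY,
    PosteriorSummary,
    rank_sum_comparisons,
)


class TestSpec:
    def test_rate_prior_selected_by_lesion_class(self):
        sp = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.PRIMARY)
        assert (sp.rate_prior.mean, sp.rate_prior.sd) == (0.16, 0.14)
        sm = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.METASTASIS)
        assert (sm.rate_prior.mean, sm.rate_prior.sd) == (0.58, 2.72)
        assert RATE_PRIOR_PRIMARY.sd == 0.14 and RATE_PRIOR_METASTASIS.sd == 2.72


class TestPriorPredictive:
    def test_posterior_equals_prior_with_no_data(self):
        """KS distance of sampler draws vs the analytic priors < 0.05."""
        spec = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.PRIMARY)
        draws = sample_prior(spec, n_draws=4000, seed=3)
        ks_rate = kstest(draws["rate_fixed"], norm(0.16, 0.14).cdf).statistic
        ks_logk = kstest(draws["log_capacity_fixed"], norm(0.0, 10.0).cdf).statistic
        assert ks_rate < 0.05
        assert ks_logk < 0.05


class TestFitValidation:
    def test_empty_cohort_rejected(self):
        spec = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.PRIMARY)
        with pytest.raises(ValueError):
            fit_mixed_model([], spec)

    def test_heterogeneous_cohort_rejected(self):
        t = np.array([0.0, 2.0, 4.0])
        v = np.array([3.0, 4.0, 5.0])
        a = VolumeSeries("a", "a1", LesionClass.PRIMARY, TreatmentContext.NONE, t, v)
        b = VolumeSeries("b", "b1", LesionClass.METASTASIS, TreatmentContext.NONE, t, v)
        spec = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.PRIMARY)
        with pytest.raises(ValueError):
            fit_mixed_model([a, b], spec)

    def test_short_series_rejected(self):
        t = np.array([0.0, 2.0])
        v = np.array([3.0, 4.0])
        a = VolumeSeries("a", "a1", LesionClass.PRIMARY, TreatmentContext.NONE, t, v)
        spec = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.PRIMARY)
        with pytest.raises(ValueError):
            fit_mixed_model([a], spec)


class TestSmallCohortFit:
    def test_recovery_and_quartile_ordering(self):
        cfg = recovery_cohort_config(n=15, seed=5, noise_sd=0.1)
        truth, cohort = generate_cohort(cfg)
        spec = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.PRIMARY)
        post = fit_mixed_model(cohort, spec, McmcOptions(chains=2, iterations=3000, seed=4))
        est = post.fixed.set_index("param")
        assert abs(est.loc["rate_fixed", "median"] - 0.28) / 0.28 < 0.25
        assert abs(est.loc["capacity_fixed", "median"] - 62.0) / 62.0 < 0.25
        # quartile ordering invariant for every reported parameter
        assert (post.fixed["q1"] <= post.fixed["median"]).all()
        assert (post.fixed["median"] <= post.fixed["q3"]).all()
        pp = post.per_patient
        for name in ("rate", "capacity"):
            assert (pp[f"{name}_q1"] <= pp[f"{name}_median"]).all()
            assert (pp[f"{name}_median"] <= pp[f"{name}_q3"]).all()
        # diagnostics present for every reported parameter
        assert post.fixed["rhat"].notna().all() and post.fixed["ess"].notna().all()

    def test_flat_series_concentrates_rate_near_zero(self):
        """A constant series at V = K/2 pins the growth rate near 0."""
        t = np.arange(0.0, 10.0, 2.0)
        v = np.full_like(t, 6.0)
        s = VolumeSeries("p", "l", LesionClass.PRIMARY, TreatmentContext.NONE, t, v)
        spec = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.PRIMARY)
        post = fit_mixed_model([s], spec, McmcOptions(chains=2, iterations=3000, seed=0))
        rate = post.per_patient["rate_median"].iloc[0]
        assert abs(rate) < 0.06

    def test_parameter_table_export(self):
        cfg = recovery_cohort_config(n=6, seed=9)
        _, cohort = generate_cohort(cfg)
        spec = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.PRIMARY)
        post = fit_mixed_model(cohort, spec, McmcOptions(chains=1, iterations=1000, seed=0))
        table = post.to_parameter_table()
        assert list(table.columns) == [
            "patient_id", "lesion_class", "context",
            "rate_median", "rate_q1", "rate_q3",
            "capacity_median", "capacity_q1", "capacity_q3", "B",
        ]
        assert (table.capacity_q1 <= table.capacity_median).all()


def _fake_fit(loglik, k, key="same"):
    return PosteriorSummary(
        model_kind=ModelKind.LOGISTIC,
        lesion_class=LesionClass.PRIMARY,
        context=TreatmentContext.NONE,
        patient_ids=["p"],
        fixed=pd.DataFrame(),
        per_patient=pd.DataFrame(),
        draws={},
        aic=2 * k - 2 * loglik,
        max_loglik=loglik,
        n_params=k,
        n_obs=10,
        converged=True,
        cohort_key=key,
    )


class TestSelectModel:
    def test_equal_loglik_prefers_fewer_parameters(self):
        table = select_model({"small": _fake_fit(100.0, 4), "big": _fake_fit(100.0, 5)})
        assert table.model.iloc[0] == "small"
        assert table.delta_aic.iloc[1] == pytest.approx(2.0)

    def test_mismatched_cohorts_rejected(self):
        with pytest.raises(ValueError):
            select_model({"a": _fake_fit(1.0, 4, "k1"), "b": _fake_fit(1.0, 4, "k2")})


class TestRankSum:
    @staticmethod
    def _table(rng, shift=0.0, n=30):
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(2 * n)],
                "lesion_class": "primary",
                "context": ["none"] * n + ["FFX"] * n,
                "rate_median": np.concatenate(
                    [rng.normal(0.28, 0.08, n), rng.normal(0.28 + shift, 0.08, n)]
                ),
            }
        )

    def test_null_calibration(self):
        """Identical groups: rank-sum p approximately uniform over replicates."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(1000):
            out = rank_sum_comparisons(self._table(rng))
            ps.append(out.p_value.iloc[0])
        frac = np.mean(np.array(ps) < 0.05)
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(2)
        out = rank_sum_comparisons(self._table(rng, shift=-5.0))
        assert out.p_value.iloc[0] < 0.01

    def test_small_group_omitted_with_warning(self):
        rng = np.random.default_rng(3)
        t = self._table(rng).iloc[[0, 30, 31, 32]]  # one lesion in group none
        with pytest.warns(UserWarning):
            out = rank_sum_comparisons(t)
        assert len(out) == 0


class TestSummarizeCohort:
    def test_treatment_effect_ordering_recovered(self):
        """Synthetic FFX cohort has smaller summarized rates than untreated."""
        from pdacsim import CohortConfig

        sizes = {
            (TreatmentContext.NONE, LesionClass.PRIMARY): 12,
            (TreatmentContext.FFX, LesionClass.PRIMARY): 12,
        }
        cfg = CohortConfig(group_sizes=sizes, scan_times=(0, 2, 4, 6, 8), seed=0)
        _, cohort = generate_cohort(cfg)
        fits = []
        for ctx in (TreatmentContext.NONE, TreatmentContext.FFX):
            sub = [s for s in cohort if s.context is ctx]
            spec = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.PRIMARY)
            fits.append(
                fit_mixed_model(sub, spec, McmcOptions(chains=1, iterations=1500, seed=2))
            )
        summary, comparisons = summarize_cohort(fits)
        by_ctx = summary.set_index("context")
        assert by_ctx.loc["FFX", "rate_median"] < by_ctx.loc["none", "rate_median"]
        assert len(comparisons) == 1
        assert comparisons.p_value.iloc[0] < 0.05


class TestPipelineClosure:
    def test_posterior_medians_track_truth(self, recovery_fit):
        """generate -> fit: per-patient capacity medians rank-correlate with truth."""
        from scipy.stats import spearmanr

        _, truth, _, post = recovery_fit
        rho_cap = spearmanr(truth.capacity_cm3, post.per_patient.capacity_median)[0]
        assert rho_cap > 0.8
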