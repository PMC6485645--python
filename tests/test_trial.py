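"""Trial engine: triage, randomization, survival endpoints, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from pdacsim import (
    Drug,
    NormalDist,
    PatientParameters,
    PopulationModel,
    TrialDesign,
    TriageCategory,
    TumorState,
    polyserial_correlation,
    run_trial,
    standard_regimen,
    summarize_phenotype,
    triage_at_diagnosis,
)


def state_with_mets(y, w=2e9, x=1e6):
    y = np.asarray(y, dtype=float)
    return TumorState(
        w=w, x=x, y=y, mai=np.full(y.size, 1e9), tbirth=np.zeros(y.size), diagnosed=True
    )


class TestTriage:
    def test_no_mets_is_non_metastatic(self):
        p = PatientParameters()
        st = state_with_mets([], w=2e9)
        assert triage_at_diagnosis(st, p) is TriageCategory.NON_METASTATIC_RESECTABLE

    def test_detection_boundary_inclusive(self):
        p = PatientParameters()  # met_detect_threshold 1e8
        st = state_with_mets([1e8])
        assert triage_at_diagnosis(st, p) is TriageCategory.METASTATIC

    def test_occult_micrometastasis_is_non_metastatic(self):
        p = PatientParameters()
        st = state_with_mets([1e7])
        assert triage_at_diagnosis(st, p) is not TriageCategory.METASTATIC

    def test_large_primary_is_lapc(self):
        p = PatientParameters()
        st = state_with_mets([], w=5e9)  # 25 cm^3 at 80% stroma
        assert triage_at_diagnosis(st, p) is TriageCategory.LAPC


class TestDesignValidation:
    def test_surgery_requires_resectable_eligibility(self):
        with pytest.raises(ValueError):
            TrialDesign(
                arms=(("s", standard_regimen(4, Drug.GEM)),), eligibility="any"
            )

    def test_rtx_requires_non_metastatic(self):
        with pytest.raises(ValueError):
            TrialDesign(
                arms=(("r", standard_regimen(1, Drug.FFX)),), eligibility="metastatic"
            )

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            TrialDesign(arms=(("a", standard_regimen(5)),), n_per_arm=1)


class TestRunTrial:
    @pytest.fixture(scope="class")
    def small_trial(self):
        design = TrialDesign(
            arms=(("obs", standard_regimen(5)), ("ffx", standard_regimen(7, Drug.FFX))),
            n_per_arm=8,
            eligibility="any",
            record_dt=6.0,
        )
        return run_trial(design, PopulationModel(), seed=12)

    def test_overall_survival_positive(self, small_trial):
        assert (small_trial.records["os_months"] > 0).all()

    def test_reproducible_given_seed(self, small_trial):
        design = TrialDesign(
            arms=(("obs", standard_regimen(5)), ("ffx", standard_regimen(7, Drug.FFX))),
            n_per_arm=8,
            eligibility="any",
            record_dt=6.0,
        )
        again = run_trial(design, PopulationModel(), seed=12)
        pd.testing.assert_frame_equal(small_trial.records, again.records)

    def test_km_reproduces_empirical_survival(self, small_trial):
        """Without censoring the KM estimate equals the empirical survivor
        fraction at every event time."""
        rec = small_trial.records
        for arm, km in small_trial.km.items():
            dur = rec.loc[(rec.arm == arm) & rec.event, "os_months"].to_numpy()
            if not len(dur):
                continue
            for _, row in km.iloc[1:].iterrows():
                t = row["time_months"]
                empirical = np.mean(dur > t)
                assert row["survival"] == pytest.approx(empirical, abs=1e-12)

    def test_dominating_treatment_extends_survival(self):
        """CTx that halts all division strictly beats observation."""
        zero = {
            d: (NormalDist(0.0, 0.0), NormalDist(0.0, 0.0))
            for d in (Drug.GEM, Drug.FFX, Drug.GEM_NAB)
        }
        pop = PopulationModel(chemo_rates=zero)
        design = TrialDesign(
            arms=(("none", standard_regimen(5)), ("ctx6", standard_regimen(8, Drug.FFX))),
            n_per_arm=100,
            eligibility="any",
            record_dt=8.0,
        )
        res = run_trial(design, pop, seed=7)
        med = res.records.groupby("arm")["os_months"].median()
        assert med["ctx6"] > med["none"]
        assert res.pairwise_logrank.p_value.iloc[0] < 0.05

    def test_impossible_eligibility_aborts_with_diagnostic(self):
        pop = PopulationModel(
            lai_dist=__import__("pdacsim").lognormal_from_quartiles(2e9, 1.5e9, 3e9),
            fixed_m_diag=10**9.0,
        )
        design = TrialDesign(
            arms=(("a", standard_regimen(5)), ("b", standard_regimen(5))),
            n_per_arm=2,
            eligibility="LAPC",  # primary can never exceed 20 cm^3 at diagnosis
            record_dt=10.0,
            max_screen_factor=5,
        )
        with pytest.raises(RuntimeError, match="aborted"):
            run_trial(design, pop, seed=0)


class TestPhenotypeSummary:
    @staticmethod
    def _record(**kw):
        base = dict(
            case_id=1, arm="a", os_months=10.0, event=True, triage="metastatic",
            lai_cells=1e10, m_diag=3e9, primary_cells_final=1e10,
            primary_volume_cm3_final=50.0, complication=False,
            n_mets_detectable_dx=0, n_mets_detectable_final=5,
            n_mets_total_final=10, largest_met_cells_final=1e9,
        )
        base.update(kw)
        return base

    def test_complication_threshold(self):
        rec = pd.DataFrame([
            self._record(primary_volume_cm3_final=66.0, complication=True),
            self._record(case_id=2, primary_volume_cm3_final=64.0),
        ])
        out = summarize_phenotype(rec)
        assert out["complication_rate"] == pytest.approx(0.5)

    def test_identical_records_concentrate_in_one_bin(self):
        rec = pd.DataFrame([self._record(case_id=i) for i in range(6)])
        out = summarize_phenotype(rec)
        assert len(out["met_bins_final"]) == 1
        assert out["met_bins_final"].iloc[0] == 6

    def test_met_count_bins(self):
        rec = pd.DataFrame(
            [self._record(case_id=i, n_mets_detectable_final=n)
             for i, n in enumerate([1, 10, 11, 49, 50, 80])]
        )
        out = summarize_phenotype(rec)
        assert out["met_bins_final"].to_dict() == {"10-50": 2, "<=10": 2, ">=50": 2}


class TestPolyserial:
    def test_perfect_concordance(self):
        x = np.arange(60, dtype=float)
        o = np.repeat([0, 1, 2], 20)
        assert polyserial_correlation(x, o) > 0.95

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        o = rng.integers(0, 3, size=500)
        assert abs(polyserial_correlation(x, o)) < 0.1

    def test_degenerate_ordinal_flagged_nan(self):
        with pytest.warns(UserWarning):
            out = polyserial_correlation(np.arange(5.0), np.ones(5))
        assert np.isnan(out)

    def test_matches_grid_search_oracle(self):
        """ML estimate agrees with brute-force maximization of the same
        two-step likelihood on a small instance."""
        rng = np.random.default_rng(42)
        n = 20
        z_lat = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n)
        x = 3.0 + 2.0 * z_lat[:, 0]
        o = np.digitize(z_lat[:, 1], [-0.4, 0.6])
        est = polyserial_correlation(x, o)

        levels, codes = np.unique(o, return_inverse=True)
        props = np.bincount(codes) / n
        tau = norm.ppf(np.cumsum(props)[:-1])
        up = np.concatenate([tau, [np.inf]])[codes]
        lo = np.concatenate([[-np.inf], tau])[codes]
        z = (x - x.mean()) / x.std()

        def ll(rho):
            s = np.sqrt(1 - rho**2)
            p = norm.cdf((up - rho * z) / s) - norm.cdf((lo - rho * z) / s)
            return np.sum(np.log(np.maximum(p, 1e-300)))

        grid = np.linspace(-0.998, 0.998, 4001)
        brute = grid[np.argmax([ll(r) for r in grid])]
        assert est == pytest.approx(brute, abs=1e-3)
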