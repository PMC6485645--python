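"""Treatment operators: surgery, LQ radiotherapy, rate substitution/recovery."""

import math

import numpy as np
import pytest

from pdacsim import (
    ChemoEffect,
    Drug,
    Modality,
    PatientParameters,
    Regimen,
    RegimenInterval,
    RTxCourse,
    TumorState,
    apply_surgery,
    compile_schedule,
    effective_rates,
    rtx_surviving_fraction,
    run_to_event,
    sample_surgical_remnant,
    standard_regimen,
)


class TestSurgery:
    def test_identity_at_epsilon_one(self):
        st = TumorState(w=5e8, x=1e8, y=[1e7], mai=[1e9], tbirth=[0.0])
        out = apply_surgery(st, 1.0)
        assert out.w == st.w and out.x == st.x

    def test_remnant_arithmetic(self):
        st = TumorState(w=8e8, x=2e8, y=[4e7], mai=[1e9], tbirth=[0.0])
        out = apply_surgery(st, 0.1)
        assert out.w == pytest.approx(8e7)
        assert out.x == pytest.approx(2e7)
        np.testing.assert_array_equal(out.y, st.y)

    @pytest.mark.parametrize("eps", [-0.1, 1.2])
    def test_epsilon_domain(self, eps):
        with pytest.raises(ValueError):
            apply_surgery(TumorState(w=1.0), eps)

    def test_remnant_sampler_range_and_spread(self):
        rng = np.random.default_rng(0)
        draws = np.array([sample_surgical_remnant(rng) for _ in range(10_000)])
        assert draws.min() >= 1e-5 and draws.max() <= 1e-1
        # log-uniform: median near geometric center of the interval
        assert np.median(np.log10(draws)) == pytest.approx(-3.0, abs=0.1)


class TestLinearQuadratic:
    def test_zero_dose_spares_everything(self):
        course = RTxCourse(n_fractions=30, dose_per_fraction=1e-12)
        assert rtx_surviving_fraction(course, 10) == pytest.approx(1.0)

    def test_single_fraction_value(self):
        course = RTxCourse(n_fractions=30, dose_per_fraction=1.8, alpha=0.3)
        # exp(-(0.3*1.8 + 0.03*1.8^2)) = exp(-0.6372)
        assert course.beta == pytest.approx(0.03)
        assert rtx_surviving_fraction(course, 1) == pytest.approx(math.exp(-0.6372))
        assert rtx_surviving_fraction(course, 1) == pytest.approx(0.5288, abs=2e-4)

    def test_full_course_is_power_of_single_fraction(self):
        course = RTxCourse()
        sf1 = rtx_surviving_fraction(course, 1)
        assert rtx_surviving_fraction(course, 30) == pytest.approx(sf1**30)
        # exp(-0.6372)^30 = 4.989e-9
        assert rtx_surviving_fraction(course, 30) == pytest.approx(4.99e-9, rel=5e-3)

    def test_conventional_course_totals(self):
        course = RTxCourse()
        assert course.total_dose == pytest.approx(54.0)
        assert course.n_fractions == 30 and course.dose_per_fraction == 1.8

    def test_monotone_in_fractions_and_dose(self):
        course = RTxCourse()
        sfs = [rtx_surviving_fraction(course, k) for k in range(0, 31)]
        assert all(0 < b < a <= 1 for a, b in zip(sfs, sfs[1:]))
        doses = [RTxCourse(dose_per_fraction=d) for d in (1.0, 1.8, 2.5)]
        vals = [rtx_surviving_fraction(c, 1) for c in doses]
        assert vals[0] > vals[1] > vals[2]

    def test_invalid_fraction_count(self):
        with pytest.raises(ValueError):
            rtx_surviving_fraction(RTxCourse(), 31)


class TestRegimenSchema:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            Regimen(
                intervals=(
                    RegimenInterval(0.0, 4.0, Modality.CTX, Drug.FFX),
                    RegimenInterval(2.0, 4.0, Modality.CTX, Drug.GEM),
                )
            )

    def test_surgery_must_be_instantaneous(self):
        with pytest.raises(ValueError):
            RegimenInterval(0.0, 1.0, Modality.SURGERY)

    def test_ctx_requires_drug(self):
        with pytest.raises(ValueError):
            RegimenInterval(0.0, 1.0, Modality.CTX)

    @pytest.mark.parametrize("number", range(1, 10))
    def test_standard_regimens_expressible_and_round_trip(self, number):
        reg = standard_regimen(number, Drug.FFX, second_drug=Drug.GEM)
        # schema round-trip through plain tuples
        rebuilt = Regimen(
            intervals=tuple(
                RegimenInterval(iv.start, iv.duration, iv.modality, iv.drug)
                for iv in reg.intervals
            ),
            scenario=reg.scenario,
            label=reg.label,
        )
        assert rebuilt == reg

    def test_standard_regimen_shapes(self):
        reg1 = standard_regimen(1)
        assert [iv.modality for iv in reg1.intervals] == [
            Modality.CTX, Modality.RTX, Modality.CTX,
        ]
        reg3 = standard_regimen(3)
        assert any(iv.modality is Modality.SURGERY and iv.start == 4.0 for iv in reg3.intervals)
        reg6 = standard_regimen(6)
        ctx = reg6.ctx_intervals
        assert [(iv.start, iv.end) for iv in ctx] == [(0.0, 2.0), (4.0, 6.0)]
        reg9 = standard_regimen(9, Drug.FFX, second_drug=Drug.GEM)
        assert [iv.drug for iv in reg9.ctx_intervals] == [Drug.FFX, Drug.GEM]
        assert standard_regimen(5).intervals == ()


class TestEffectiveRates:
    def setup_method(self):
        self.params = PatientParameters()
        self.baseline = (0.28, 0.28, 1.16)

    def effect(self, scenario):
        return ChemoEffect.with_scenario(Drug.FFX, -0.10, 0.25, scenario)

    def test_on_treatment_substitution(self):
        reg = standard_regimen(7, Drug.FFX, scenario=1)
        r = effective_rates(self.params, reg, self.effect(1), 2.0)
        assert r == pytest.approx((-0.10, -0.10, 0.25))

    def test_scenario1_instantaneous_full_reversal(self):
        reg = standard_regimen(7, Drug.FFX, scenario=1)
        r = effective_rates(self.params, reg, self.effect(1), 4.0 + 1e-6)
        assert r == pytest.approx(self.baseline)

    def test_scenario6_permanent_ninety_percent(self):
        reg = standard_regimen(7, Drug.FFX, scenario=6)
        r = effective_rates(self.params, reg, self.effect(6), 30.0)
        assert r == pytest.approx(tuple(0.9 * b for b in self.baseline))

    def test_scenario3_linear_ramp_midpoint(self):
        reg = standard_regimen(7, Drug.FFX, scenario=3)  # 1-month recovery
        eff = self.effect(3)
        r = effective_rates(self.params, reg, eff, 4.5)
        expected = tuple(
            0.5 * (on + base)
            for on, base in zip((-0.10, -0.10, 0.25), self.baseline)
        )
        assert r == pytest.approx(expected)

    def test_ramp_truncated_by_next_interval(self):
        reg = standard_regimen(6, Drug.FFX, scenario=4)  # 2-month recovery, holiday 2-4
        eff = self.effect(4)
        # at month 4 the ramp (2->4) has just completed: rates back at baseline
        r = effective_rates(self.params, reg, eff, 3.0)
        mid = tuple(0.5 * (on + b) for on, b in zip((-0.10, -0.10, 0.25), self.baseline))
        assert r == pytest.approx(mid)
        # inside the second block rates are the on-treatment draws again
        r2 = effective_rates(self.params, reg, eff, 5.0)
        assert r2 == pytest.approx((-0.10, -0.10, 0.25))


class TestScheduleCoupling:
    def test_explicit_observation_is_identical_to_implicit(self):
        """CTx then explicit rest compiles to the same schedule as CTx alone,
        so per-seed trajectories coincide after treatment ends."""
        params = PatientParameters(lai=1.2e10)
        eff = ChemoEffect.with_scenario(Drug.FFX, -0.1, 0.25, 1)
        reg_a = standard_regimen(7, Drug.FFX)  # CTx 0-4
        reg_b = Regimen(
            intervals=(
                RegimenInterval(0.0, 4.0, Modality.CTX, Drug.FFX),
                RegimenInterval(4.0, 8.0, Modality.NONE),
            )
        )
        sa = compile_schedule(params, reg_a, eff, horizon=24.0)
        sb = compile_schedule(params, reg_b, eff, horizon=24.0)
        for t in np.linspace(0, 23.9, 100):
            assert sa.rates_at(t) == pytest.approx(sb.rates_at(t))
        start = TumorState(w=2e9, x=5e6)
        ta = run_to_event(params, "death", seed=21, schedule=sa, initial_state=start, record_dt=1.0)
        tb = run_to_event(params, "death", seed=21, schedule=sb, initial_state=start, record_dt=1.0)
        assert ta.death_time == tb.death_time
        np.testing.assert_array_equal(ta.total, tb.total)

    def test_rtx_events_cover_course(self):
        params = PatientParameters()
        reg = standard_regimen(1, Drug.FFX)
        eff = ChemoEffect.with_scenario(Drug.FFX, -0.1, 0.25, 1)
        sched = compile_schedule(params, reg, eff, surgical_remnant=None, horizon=24.0)
        fracs = [e for e in sched.events if e[1] == "rtx_fraction"]
        assert len(fracs) == 30
        course = RTxCourse()
        assert all(v == pytest.approx(rtx_surviving_fraction(course, 1)) for _, _, v in fracs)
        assert fracs[0][0] > 3.0 and fracs[-1][0] <= 3.0 + course.duration_months + 1e-9

    def test_surgery_requires_remnant(self):
        params = PatientParameters()
        reg = standard_regimen(3, Drug.FFX)
        eff = ChemoEffect.with_scenario(Drug.FFX, -0.1, 0.25, 1)
        with pytest.raises(ValueError):
            compile_schedule(params, reg, eff, surgical_remnant=None)
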