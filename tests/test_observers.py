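"""Generative observers: SDT and drift-diffusion response models."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pareidolia.design import CounterbalanceSpec, build_subject_schedule
from pareidolia.observers import (
    CohortSpec,
    DDMObserverParams,
    SDTObserverParams,
    TRAIT_RANGES,
    analytic_sdt_rates,
    ddm_closed_form,
    run_experiment,
    sample_cohort,
    simulate_ddm_block,
    simulate_sdt_block,
    simulate_sdt_response,
)
from pareidolia.sdt import criterion, dprime


def phi(x: float) -> float:
    """Normal CDF oracle via the error function."""
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def _sdt_params(d=1.0, c=0.0):
    cats = ("face", "flower")
    levels = {"face": (0.44, 0.46, 0.48, 0.50), "flower": (0.38, 0.40, 0.42, 0.44)}
    dp = {(cat, lv): d for cat in cats for lv in levels[cat]}
    cr = {(cat, vf): c for cat in cats for vf in ("LVF", "RVF")}
    return SDTObserverParams(dp, cr)


def _trials(n, stimulus_type="noise_only", vf="LVF", cat="face", level=0.44):
    return pd.DataFrame(
        {
            "block": [cat] * n,
            "stimulus_type": [stimulus_type] * n,
            "visual_field": [vf] * n,
            "noise_fraction": [level if stimulus_type == "signal" else None] * n,
        }
    )


class TestAnalyticRates:
    def test_chance_point(self):
        assert analytic_sdt_rates(0.0, 0.0) == (0.5, 0.5)

    def test_unit_dprime_against_cdf_oracle(self):
        hr, far = analytic_sdt_rates(1.0, 0.0)
        assert hr == pytest.approx(phi(0.5), abs=1e-12)
        assert far == pytest.approx(phi(-0.5), abs=1e-12)

    @given(
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=-1.5, max_value=1.5),
    )
    @settings(derandomize=True, max_examples=50)
    def test_inverse_identity(self, d, c):
        hr, far = analytic_sdt_rates(d, c)
        assert dprime(hr, far) == pytest.approx(d, abs=1e-9)
        assert criterion(hr, far) == pytest.approx(c, abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            analytic_sdt_rates(float("nan"), 0.0)


class TestSDTObserver:
    def test_far_at_chance(self, rng):
        params = _sdt_params(d=0.0, c=0.0)
        params.lapse_rate = 0.0
        out = simulate_sdt_block(params, _trials(10_000), rng)
        far = (out["response"] == "present").mean()
        assert far == pytest.approx(0.5, abs=0.015)

    def test_conservative_criterion_rate(self, rng):
        params = _sdt_params(d=0.0, c=2.0)
        params.lapse_rate = 0.0
        out = simulate_sdt_block(params, _trials(10_000), rng)
        rate = (out["response"] == "present").mean()
        assert rate == pytest.approx(phi(-2.0), abs=0.005)

    def test_huge_dprime_signal_always_present(self, rng):
        params = _sdt_params(d=50.0, c=0.0)
        params.lapse_rate = 0.0
        out = simulate_sdt_block(params, _trials(500, "signal"), rng)
        assert (out["response"] == "present").all()
        assert out["correct"].all()

    def test_single_trial_wrapper(self):
        from pareidolia.design import Trial

        trial = Trial(0, "face", "signal", "LVF", None, 0.44, 1)
        rec = simulate_sdt_response(_sdt_params(), trial, seed=0)
        assert rec["response"] in {"present", "absent"}
        assert rec["rt_s"] > 0

    def test_lapse_rate_bounds(self):
        with pytest.raises(ValueError):
            SDTObserverParams({}, {}, lapse_rate=0.2)


class TestDDMClosedForm:
    def test_symmetric_start_zero_drift(self):
        p, _ = ddm_closed_form(0.0, 0.1, 0.05)
        assert p == 0.5

    def test_start_near_upper_boundary(self):
        p, _ = ddm_closed_form(0.0, 0.1, 0.0999)
        assert p == pytest.approx(0.999, abs=1e-9)

    def test_printed_example(self):
        p, mdt = ddm_closed_form(0.2, 0.1, 0.05, 0.1)
        expect_p = (1 - math.exp(-2.0)) / (1 - math.exp(-4.0))
        assert p == pytest.approx(expect_p, abs=1e-12)
        assert mdt == pytest.approx(0.25 * math.tanh(1.0), abs=1e-12)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            ddm_closed_form(0.1, 0.1, 0.0)
        with pytest.raises(ValueError):
            ddm_closed_form(0.1, -1.0, 0.05)


class TestDDMSimulator:
    def test_choice_probability_matches_closed_form(self, rng):
        n = 20_000
        params = DDMObserverParams(
            drift_scale=0.2, start_bias={"LVF": 0.5, "RVF": 0.5}
        )
        trials = _trials(n, "signal", level=0.0)  # strength 1 -> v = 0.2
        out = simulate_ddm_block(params, trials, rng)
        p_emp = (out["response"] == "present").mean()
        p_th, _ = ddm_closed_form(0.2, 0.1, 0.05, 0.1)
        se = math.sqrt(p_th * (1 - p_th) / n)
        assert abs(p_emp - p_th) <= 3 * se

    def test_unbiased_zero_drift_symmetry(self, rng):
        params = DDMObserverParams(start_bias={"LVF": 0.5, "RVF": 0.5})
        out = simulate_ddm_block(params, _trials(5000), rng)
        p = (out["response"] == "present").mean()
        assert p == pytest.approx(0.5, abs=0.03)

    def test_start_bias_raises_false_alarms(self, rng):
        params = DDMObserverParams(start_bias={"LVF": 0.4, "RVF": 0.6})
        lvf = simulate_ddm_block(params, _trials(10_000, vf="LVF"), rng)
        rvf = simulate_ddm_block(params, _trials(10_000, vf="RVF"), rng)
        assert (rvf["response"] == "present").mean() > (
            lvf["response"] == "present"
        ).mean()

    def test_rt_bounded_below_by_nondecision_time(self, rng):
        params = DDMObserverParams(nondecision_t0=0.3)
        out = simulate_ddm_block(params, _trials(200), rng)
        assert (out["rt_s"] >= 0.3).all()

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DDMObserverParams(start_bias={"LVF": 1.5, "RVF": 0.5})


class TestCohortSampling:
    def test_traits_within_ranges_and_count(self):
        cohort = sample_cohort(CohortSpec(n_subjects=26), seed=0)
        assert len(cohort) == 26
        for _, traits in cohort:
            for name, hi in TRAIT_RANGES.items():
                assert 0 <= getattr(traits, name) <= hi

    def test_trait_coupling_hits_target_correlation(self):
        spec = CohortSpec(
            n_subjects=10_000,
            trait_coupling={"trait": "UnEx", "category": "face", "target_r": -0.559},
        )
        cohort = sample_cohort(spec, seed=1)
        unex = np.array([t.UnEx for _, t in cohort])
        c_face = np.array(
            [
                np.mean([p.criterion_true[("face", vf)] for vf in ("LVF", "RVF")])
                for p, _ in cohort
            ]
        )
        r = np.corrcoef(unex, c_face)[0, 1]
        assert r == pytest.approx(-0.559, abs=0.02)

    def test_zero_coupling_uncorrelated(self):
        spec = CohortSpec(
            n_subjects=10_000,
            trait_coupling={"trait": "UnEx", "category": "face", "target_r": 0.0},
        )
        cohort = sample_cohort(spec, seed=2)
        unex = np.array([t.UnEx for _, t in cohort])
        c_face = np.array([p.criterion_true[("face", "LVF")] for p, _ in cohort])
        assert abs(np.corrcoef(unex, c_face)[0, 1]) < 0.03

    def test_impossible_correlation_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(trait_coupling={"trait": "UnEx", "category": "face", "target_r": -1.2})

    def test_determinism(self):
        a = sample_cohort(CohortSpec(n_subjects=5), seed=9)
        b = sample_cohort(CohortSpec(n_subjects=5), seed=9)
        assert a[0][1] == b[0][1]
        assert a[3][0].criterion_true == b[3][0].criterion_true


class TestRunExperiment:
    def test_full_session_record_count(self):
        cb = CounterbalanceSpec("face_first", "up_present", "right")
        sched = build_subject_schedule(0, 1, cb, None, seed=0, practice_trials=0)
        log = run_experiment(_sdt_params(), sched, seed=1)
        assert len(log) == 512
        assert set(log["block"]) == {"face", "flower"}
        assert not log[["response", "correct", "rt_s"]].isna().any().any()

    def test_end_to_end_determinism(self):
        cb = CounterbalanceSpec("face_first", "up_present", "right")
        sched = build_subject_schedule(0, 1, cb, None, seed=0, practice_trials=0)
        a = run_experiment(_sdt_params(), sched, seed=1)
        b = run_experiment(_sdt_params(), sched, seed=1)
        pd.testing.assert_frame_equal(a, b)
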