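"""Wiener diffusion core: closed-form choice probabilities, first-passage
densities and Euler simulation, cross-checked against each other."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from tonebias import ddm


def params(**kw):
    base = dict(v=0.5, a=0.12, z=0.5, t0=0.3, s=0.1)
    base.update(kw)
    return ddm.DDMParams(**base)


class TestChoiceProbability:
    def test_zero_drift_symmetric_start(self):
        assert ddm.choice_probability(params(v=0.0)) == 0.5

    def test_zero_drift_equals_start_fraction(self):
        for z in (0.1, 0.3, 0.7, 0.9):
            assert ddm.choice_probability(params(v=0.0, z=z)) == pytest.approx(z)

    def test_strong_drift_limits(self):
        assert ddm.choice_probability(params(v=5.0)) == pytest.approx(1.0, abs=1e-12)
        assert ddm.choice_probability(params(v=-5.0)) == pytest.approx(0.0, abs=1e-12)

    def test_against_euler_simulation(self):
        p = params(v=1.0, a=0.1, z=0.5, t0=0.0)
        n = 200_000
        _, up = ddm.simulate_trials(p, n, dt=1e-4, rng=1)
        expect = ddm.choice_probability(p)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(up.mean() - expect) < 3 * max(se, 1e-4)

    def test_scale_invariance(self):
        p1 = params(v=0.3, a=0.14)
        p2 = p1.rescaled(1.0)
        assert ddm.choice_probability(p1) == pytest.approx(ddm.choice_probability(p2), rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(v=st.floats(-3, 3), a=st.floats(0.05, 0.3), z=st.floats(0.05, 0.95))
    def test_in_unit_interval_and_reflection(self, v, a, z):
        p = ddm.DDMParams(v=v, a=a, z=z, s=0.1)
        pr = ddm.choice_probability(p)
        assert 0.0 <= pr <= 1.0
        if abs(2 * v * a / p.s**2) < 30:  # away from float saturation
            assert 0.0 < pr < 1.0
        mirrored = ddm.DDMParams(v=-v, a=a, z=1 - z, s=0.1)
        assert pr == pytest.approx(1.0 - ddm.choice_probability(mirrored), abs=1e-12)


class TestWfptDensity:
    def test_zero_before_nondecision_time(self):
        p = params()
        assert ddm.wfpt_density(p.t0, p, "upper") == 0.0
        assert ddm.wfpt_density(0.0, p, "lower") == 0.0

    def test_normalization(self):
        p = params()
        total, err = quad(lambda t: ddm.wfpt_density(t, p, "upper")
                          + ddm.wfpt_density(t, p, "lower"), p.t0, 30, limit=300)
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_upper_mass_equals_choice_probability(self):
        p = params(v=0.3, z=0.4)
        mass, _ = quad(lambda t: ddm.wfpt_density(t, p, "upper"), p.t0, 30, limit=300)
        assert mass == pytest.approx(ddm.choice_probability(p), abs=1e-4)

    def test_mean_decision_time_against_density(self):
        p = params(v=0.25, a=0.14, z=0.45)
        m, _ = quad(lambda t: (t - p.t0) * (ddm.wfpt_density(t, p, "upper")
                                            + ddm.wfpt_density(t, p, "lower")),
                    p.t0, 40, limit=400)
        assert m == pytest.approx(ddm.mean_decision_time(p), rel=1e-6)

    def test_reflection_symmetry(self):
        p = params(v=0.4, z=0.35)
        q = ddm.DDMParams(v=-p.v, a=p.a, z=1 - p.z, t0=p.t0, s=p.s)
        ts = np.linspace(0.31, 1.5, 50)
        np.testing.assert_allclose(ddm.wfpt_density(ts, p, "upper"),
                                   ddm.wfpt_density(ts, q, "lower"), rtol=1e-10)

    def test_truncation_error_within_bound(self):
        # default truncation (eps=1e-7) agrees with a near-exact evaluation
        # across the whole support, including the series-switchover region
        p = params(v=0.2)
        ts = np.linspace(p.t0 + 1e-4, 3.0, 500)
        coarse = ddm.wfpt_density(ts, p, "upper", eps=1e-7)
        fine = ddm.wfpt_density(ts, p, "upper", eps=1e-12)
        assert np.max(np.abs(coarse - fine)) < 1e-7

    def test_invalid_boundary(self):
        with pytest.raises(ValueError, match="boundary"):
            ddm.wfpt_density(0.5, params(), "sideways")


class TestSimulation:
    def test_rt_exceeds_nondecision_time(self):
        p = params()
        rts, _ = ddm.simulate_trials(p, 500, dt=1e-3, rng=0)
        assert np.all(rts > p.t0)

    def test_zero_drift_symmetry(self):
        p = params(v=0.0)
        n = 100_000
        _, up = ddm.simulate_trials(p, n, dt=1e-3, rng=3)
        se = 0.5 / math.sqrt(n)
        assert abs(up.mean() - 0.5) < 3 * se

    def test_determinism(self):
        p = params()
        r1 = ddm.simulate_trials(p, 200, dt=1e-3, rng=42)
        r2 = ddm.simulate_trials(p, 200, dt=1e-3, rng=42)
        np.testing.assert_array_equal(r1[0], r2[0])
        np.testing.assert_array_equal(r1[1], r2[1])

    def test_dt_convergence_of_mean_rt(self):
        p = params()
        m = {}
        for dt in (1e-3, 5e-4):
            rts, _ = ddm.simulate_trials(p, 40_000, dt=dt, rng=5)
            m[dt] = rts.mean()
        assert abs(m[1e-3] - m[5e-4]) / m[5e-4] < 0.01

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            ddm.simulate_trials(params(), 10, dt=0.0)


class TestSimulateDataset:
    def test_one_outcome_per_trial(self, rng):
        from tonebias import design

        sched = design.generate_schedule(design.make_design("study1_main"), seed=9)
        by_type = {t: params(v=v) for t, v in
                   [("low", 0.25), ("high", 0.25), ("mid", 0.0)]}
        out = ddm.simulate_dataset(by_type, sched, rng=rng)
        assert len(out) == 120
        assert all(o["boundary"] in ("upper", "lower") for o in out)

    def test_negative_mid_drift_biases_low(self, rng):
        from tonebias import design

        sched = design.generate_schedule(design.make_design("study1_main"), seed=9)
        by_type = {"low": params(v=0.25), "high": params(v=0.25),
                   "mid": params(v=-0.08)}
        fracs = []
        for seed in range(40):
            out = ddm.simulate_dataset(by_type, sched, rng=seed)
            mids = [o for o in out if o["tone"] == "mid"]
            fracs.append(np.mean([o["boundary"] == "upper" for o in mids]))
        assert np.mean(fracs) < 0.5
        assert np.mean(fracs) == pytest.approx(
            ddm.choice_probability(by_type["mid"]), abs=0.05)

    def test_missing_trialtype_params(self, rng):
        from tonebias import design

        sched = design.generate_schedule(design.make_design("study1_main"), seed=9)
        with pytest.raises(KeyError, match="mid"):
            ddm.simulate_dataset({"low": params(), "high": params()}, sched, rng=rng)

    def test_lapse_marks_missed_trials(self, rng):
        from tonebias import design

        sched = design.generate_schedule(design.make_design("study1_main"), seed=9)
        by_type = {t: params() for t in ("low", "mid", "high")}
        out = ddm.simulate_dataset(by_type, sched, rng=rng, lapse_prob=0.5)
        missed = sum(o["boundary"] == "none" for o in out)
        assert 30 <= missed <= 90  # ~Binomial(120, 0.5)
        assert all(math.isnan(o["rt"]) for o in out if o["boundary"] == "none")


def test_params_validation():
    with pytest.raises(ValueError):
        ddm.DDMParams(v=0.1, a=-1.0)
    with pytest.raises(ValueError):
        ddm.DDMParams(v=0.1, a=0.1, z=1.2)
    with pytest.raises(ValueError):
        ddm.DDMParams(v=0.1, a=0.1, t0=-0.1)
    with pytest.raises(ValueError):
        ddm.DDMParams(v=0.1, a=0.1, s=0.0)
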