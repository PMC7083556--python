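"""Hierarchical DDM machinery: grid, likelihood mixture, diagnostics, DIC
bookkeeping, sampler determinism and single-fit recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from tonebias import cohort, ddm, hier


class TestModelGrid:
    def test_sixteen_trialtype_models(self):
        grid = hier.build_model_grid(include_cohort=False)
        assert len(grid) == 16
        assert len({g.name for g in grid}) == 16
        assert any(g.split_by_trialtype == frozenset(hier.PARAMS) for g in grid)

    def test_cohort_variants_include_v_by_group(self):
        grid = hier.build_model_grid(include_cohort=True, cohort_kind="group")
        assert len(grid) == 21
        assert any(g.split_by_cohort == (("v", "group"),) for g in grid)

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            hier.HierModelSpec(split_by_trialtype=frozenset({"q"}))


class TestPreprocess:
    def test_missed_trials_dropped(self, small_study1):
        records, _ = small_study1
        out = hier.preprocess_rts(records)
        assert (out["response"] != "none").all()
        n_missed = (records["response"] == "none").sum()
        assert len(out) == len(records) - n_missed

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hier.preprocess_rts(pd.DataFrame(columns=["response", "rt_ms"]))


class TestMixtureLikelihood:
    def test_outlier_robustness(self):
        rt = np.array([0.5, 0.6, 10.0])  # one absurd RT
        upper = np.array([1, 0, 1], dtype=np.int8)
        pure = hier._cell_loglik(rt, upper, 1.0, 1.2, 0.5, 0.3, 0.0, 10.0)
        mixed = hier._cell_loglik(rt, upper, 1.0, 1.2, 0.5, 0.3, 0.05, 10.0)
        assert math.isfinite(mixed)
        assert pure < mixed - 5  # the pure WFPT likelihood collapses

    def test_zero_outlier_prob_is_pure_wfpt(self):
        rt = np.array([0.5, 0.7])
        upper = np.array([1, 0], dtype=np.int8)
        ll = hier._cell_loglik(rt, upper, 1.0, 1.2, 0.5, 0.3, 0.0, 5.0)
        par = ddm.DDMParams(v=1.0, a=1.2, z=0.5, t0=0.3, s=1.0)
        expect = (math.log(ddm.wfpt_density(0.5, par, "upper"))
                  + math.log(ddm.wfpt_density(0.7, par, "lower")))
        assert ll == pytest.approx(expect, rel=1e-9)


class TestGelmanRubin:
    def test_identical_chains(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal(500)
        r = hier.gelman_rubin(np.stack([c, c]))
        assert r == pytest.approx(math.sqrt((len(c) - 1) / len(c)), rel=1e-9)

    def test_separated_chains_flag(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 400), rng.normal(10, 1, 400)])
        assert hier.gelman_rubin(chains) > 1.5

    def test_single_stationary_chain_split(self):
        rng = np.random.default_rng(2)
        assert hier.gelman_rubin(rng.standard_normal((1, 4000))) < 1.05

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((2, 800)) + np.array([[0.0], [0.3]])
        ours = hier.gelman_rubin(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"].values.ravel()[0])
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_single_short_chain_rejected(self):
        with pytest.raises(ValueError):
            hier.gelman_rubin(np.ones((1, 3)))


class TestCompareModels:
    def _fake_fit(self, dic, data_hash="h"):
        class F:  # minimal stand-in carrying the compared fields
            pass

        f = F()
        f.dic, f.pD, f.data_hash = dic, 5.0, data_hash
        f.spec = hier.HierModelSpec(frozenset({"v"}))
        return f

    def test_ranking_and_parity(self):
        fits = [self._fake_fit(1000.0), self._fake_fit(1003.0), self._fake_fit(1000.5)]
        table = hier.compare_models(fits, parity_threshold=2.0)
        assert table["dic"].iloc[0] == 1000.0 and table["winner"].iloc[0]
        assert list(table["at_parity"]) == [True, True, False]

    def test_shift_invariance(self):
        fits = [self._fake_fit(d) for d in (500.0, 504.0, 501.0)]
        shifted = [self._fake_fit(d + 123.0) for d in (500.0, 504.0, 501.0)]
        t1 = hier.compare_models(fits)
        t2 = hier.compare_models(shifted)
        assert list(t1["delta_dic"]) == list(t2["delta_dic"])

    def test_single_fit_wins(self):
        table = hier.compare_models([self._fake_fit(10.0)])
        assert table["winner"].iloc[0]

    def test_different_data_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            hier.compare_models([self._fake_fit(1.0, "a"), self._fake_fit(2.0, "b")])


@pytest.fixture(scope="module")
def tiny_fit(small_study1_module):
    records, _ = small_study1_module
    spec = hier.HierModelSpec(split_by_trialtype=frozenset({"v"}))
    settings = hier.MCMCSettings(n_samples=150, n_burn=150, n_chains=2, seed=5)
    return hier.fit_hierarchical(records, spec, settings)


@pytest.fixture(scope="module")
def small_study1_module():
    config = cohort.CohortConfig(n_asymptomatic=6, n_symptomatic=5)
    return cohort.generate_study1_cohort(config, seed=21)


class TestFit:
    def test_deterministic_under_seed(self, small_study1_module):
        records, _ = small_study1_module
        spec = hier.HierModelSpec(split_by_trialtype=frozenset())
        s = hier.MCMCSettings(n_samples=40, n_burn=40, n_chains=1, seed=9)
        f1 = hier.fit_hierarchical(records, spec, s)
        f2 = hier.fit_hierarchical(records, spec, s)
        np.testing.assert_array_equal(f1.mu, f2.mu)
        np.testing.assert_array_equal(f1.subject_draws, f2.subject_draws)
        assert f1.dic == f2.dic

    def test_fit_outputs_well_formed(self, tiny_fit):
        assert np.isfinite(tiny_fit.mu).all()
        assert np.isfinite(tiny_fit.deviance).all()
        assert tiny_fit.pD > 0
        assert tiny_fit.dic == pytest.approx(
            tiny_fit.deviance.mean() + tiny_fit.pD, rel=1e-9)
        recomputed = hier.compute_dic(tiny_fit)
        assert recomputed[0] == pytest.approx(tiny_fit.dic, rel=1e-9)

    def test_needs_two_subjects(self, small_study1_module):
        records, _ = small_study1_module
        one = records[records["subject_id"] == records["subject_id"].iloc[0]]
        with pytest.raises(ValueError, match="2 subjects"):
            hier.fit_hierarchical(one, hier.HierModelSpec())

    def test_group_split_needs_two_cohorts(self, small_study1_module):
        records, _ = small_study1_module
        solo = records[records["cohort"] == "asymptomatic"]
        spec = hier.HierModelSpec(split_by_trialtype=frozenset({"v"}),
                                  split_by_cohort=(("v", "group"),))
        with pytest.raises(ValueError, match="single cohort"):
            hier.fit_hierarchical(solo, spec)

    def test_contrast_requires_split(self, tiny_fit):
        with pytest.raises(ValueError, match="not split"):
            hier.group_contrast_posterior(tiny_fit, "v", "a", "b")


def test_single_subject_posterior_concentrates():
    """With many trials from one subject the subject-level posterior should
    land on the generating parameters (fixed-effects consistency check)."""
    par = ddm.DDMParams(v=0.05, a=0.12, z=0.5, t0=0.3, s=0.1)
    rts, up = ddm.simulate_trials(par, 2500, dt=1e-3, rng=8)
    rows = []
    for j in range(2):  # two clones: the hierarchy needs >= 2 subjects
        for i in range(j * 1250, (j + 1) * 1250):
            rows.append({"subject_id": f"s{j}", "cohort": "n/a",
                         "condition": "neutral", "block": 0, "trial_index": i,
                         "tone": "mid", "tone_hz": 750, "reward_map_variant": 0,
                         "response": "high" if up[i] else "low", "correct": None,
                         "rt_ms": int(rts[i] * 1000), "outcome": "£4",
                         "scheduled_mid_outcome": "high"})
    records = pd.DataFrame(rows)
    fit = hier.fit_hierarchical(
        records, hier.HierModelSpec(),
        hier.MCMCSettings(n_samples=400, n_burn=400, n_chains=1, seed=3))
    summary = fit.summary().set_index("param")
    assert summary.loc["v", "mean"] == pytest.approx(par.v, abs=0.03)
    assert summary.loc["a", "mean"] == pytest.approx(par.a, abs=0.015)
    assert summary.loc["t0", "mean"] == pytest.approx(par.t0, abs=0.02)
    assert summary.loc["z", "mean"] == pytest.approx(par.z, abs=0.05)
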