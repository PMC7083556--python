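"""Synthetic cohorts for the judgement-bias task.

The generator draws per-subject diffusion parameters from cohort-level
distributions and simulates every scheduled trial through the Wiener
process, producing trial-level records in the interchange schema plus a
truth record (the generating parameters) for recovery scoring.

Default calibration (drift rates in the s = 0.1 convention):

* mid-tone drift: asymptomatic N(0.013, 0.075), symptomatic N(-0.032, 0.066)
  -- the group-level affective-bias difference expressed as a drift shift;
* boundary separation log-normal around 0.09: the value that makes the
  printed drift SDs and the printed bias SDs (0.17 / 0.14) mutually
  consistent, since the small-drift bias slope is a / (4 s^2);
* unambiguous drift magnitude N(0.32, 0.05) toward the correct response,
  yielding >= 93% accuracy at that boundary;
* non-decision time N(0.30, 0.04 s) truncated positive; mid-tone starting
  point ~ N(0.5, 0.03); 1% lapse (missed-response) probability.

With these values mid-tone decisions are slower than unambiguous ones and
the cohorts reproduce the direction and magnitude of the observed group
bias difference (means ~ 0.52 v. 0.43).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import ddm, design as _design

__all__ = [
    "CohortConfig",
    "CovariateConfig",
    "generate_study1_cohort",
    "generate_study2_cohort",
    "generate_covariates",
]


@dataclass(frozen=True)
class CohortConfig:
    # study-1 cohort sizes
    n_asymptomatic: int = 47
    n_symptomatic: int = 30
    # study-2 size
    n_subjects: int = 47
    # mid-tone drift populations (s = 0.1 convention)
    mid_v_mean_asymptomatic: float = 0.013
    mid_v_sd_asymptomatic: float = 0.075
    mid_v_mean_symptomatic: float = -0.032
    mid_v_sd_symptomatic: float = 0.066
    # unambiguous drift magnitude (toward correct)
    unambiguous_v_mean: float = 0.32
    unambiguous_v_sd: float = 0.05
    # boundary separation: log-normal with this median / CV
    a_median: float = 0.09
    a_log_sd: float = 0.15
    # non-decision time (s), truncated > t0_floor
    t0_mean: float = 0.30
    t0_sd: float = 0.04
    t0_floor: float = 0.10
    # mid-tone starting fraction
    z_mean: float = 0.5
    z_sd: float = 0.03
    # within-subject condition effect on mid drift (threat minus safe); the
    # default 0 encodes the null threat effect
    condition_effect_on_v: float = 0.0
    lapse_prob: float = 0.01
    s: float = 0.1
    sim_dt: float = 1e-3

    def __post_init__(self):
        if min(self.n_asymptomatic, self.n_symptomatic, self.n_subjects) < 2:
            raise ValueError("cohort sizes must be >= 2")
        for name in ("mid_v_sd_asymptomatic", "mid_v_sd_symptomatic",
                     "unambiguous_v_sd", "a_log_sd", "t0_sd", "z_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.lapse_prob < 1.0):
            raise ValueError("lapse_prob must be in [0, 1)")


@dataclass(frozen=True)
class CovariateConfig:
    """Retrospective anxiety ratings and trait-anxiety questionnaire scores."""

    rating_safe_mean: float = 1.64
    rating_safe_sd: float = 1.05
    rating_threat_mean: float = 4.93
    rating_threat_sd: float = 2.21
    rating_lo: float = 0.0
    rating_hi: float = 10.0
    trait_mean_asymptomatic: float = 36.0
    trait_sd_asymptomatic: float = 9.0
    trait_mean_symptomatic: float = 55.0
    trait_sd_symptomatic: float = 10.0
    #: target correlation between trait score and generative mid-tone drift
    #: (negative: more anxious -> lower drift toward the high-reward choice)
    trait_drift_corr: float = -0.21

    def __post_init__(self):
        if abs(self.trait_drift_corr) >= 1.0:
            raise ValueError("trait-drift correlation magnitude must be < 1")


def _draw_subject_params(rng, config: CohortConfig, mid_v_mean, mid_v_sd,
                         v_shift: float = 0.0):
    """One subject's DDMParams per trial type (keys low/mid/high).

    Unambiguous tones are accuracy-coded (upper boundary = correct), so both
    carry a positive drift of the same magnitude; the mid tone is
    stimulus-coded (upper = high-reward response).
    """
    v_mid = rng.normal(mid_v_mean, mid_v_sd) + v_shift
    v_un = abs(rng.normal(config.unambiguous_v_mean, config.unambiguous_v_sd))
    a = config.a_median * np.exp(rng.normal(0.0, config.a_log_sd))
    t0 = max(config.t0_floor, rng.normal(config.t0_mean, config.t0_sd))
    z = float(np.clip(rng.normal(config.z_mean, config.z_sd), 0.05, 0.95))
    s = config.s
    return {
        "low": ddm.DDMParams(v=v_un, a=a, z=0.5, t0=t0, s=s),
        "high": ddm.DDMParams(v=v_un, a=a, z=0.5, t0=t0, s=s),
        "mid": ddm.DDMParams(v=v_mid, a=a, z=z, t0=t0, s=s),
    }


def _records_for_subject(subject_id, cohort, params_by_tone, schedule,
                         reward_variant, rng, config):
    """Simulate a schedule and serialize to trial records."""
    outcomes = ddm.simulate_dataset(params_by_tone, schedule, dt=config.sim_dt,
                                    rng=rng, lapse_prob=config.lapse_prob)
    rmap = _design.reward_map(reward_variant)
    rows = []
    for out, (_, sched_row) in zip(outcomes, schedule.frame.iterrows()):
        tone = out["tone"]
        missed = out["boundary"] == "none"
        if missed:
            response, rt_ms, correct, outcome = "none", None, None, "timeout"
        elif tone == "mid":
            response = "high" if out["boundary"] == "upper" else "low"
            rt_ms = int(round(out["rt"] * 1000))
            correct = None
            sched = out["scheduled_outcome"]
            outcome = rmap[sched] if response == sched else "timeout"
        else:
            correct_resp = "high" if tone == "high" else "low"
            hit = out["boundary"] == "upper"
            response = correct_resp if hit else ("low" if correct_resp == "high" else "high")
            rt_ms = int(round(out["rt"] * 1000))
            correct = int(hit)
            outcome = rmap[tone] if hit else "timeout"
        rows.append({
            "subject_id": subject_id,
            "cohort": cohort,
            "condition": sched_row["condition"],
            "block": int(sched_row["block"]),
            "trial_index": int(sched_row["trial_index"]),
            "tone": tone,
            "tone_hz": int(sched_row["tone_hz"]),
            "reward_map_variant": reward_variant,
            "response": response,
            "correct": correct,
            "rt_ms": rt_ms,
            "outcome": outcome,
            "scheduled_mid_outcome": out["scheduled_outcome"] or None,
        })
    return rows


def _truth_row(subject_id, cohort, params):
    return {
        "subject_id": subject_id,
        "cohort": cohort,
        "v_mid": params["mid"].v,
        "v_unambiguous": params["low"].v,
        "a": params["mid"].a,
        "t0": params["mid"].t0,
        "z_mid": params["mid"].z,
    }


def generate_study1_cohort(config: CohortConfig = CohortConfig(), seed: int = 0):
    """Two-group (asymptomatic/symptomatic) cohort on the 120-trial task.

    Returns (records DataFrame, truth dict).  Reward maps are
    counterbalanced by subject parity within each cohort.
    """
    rng = np.random.default_rng(seed)
    groups = [("asymptomatic", config.n_asymptomatic,
               config.mid_v_mean_asymptomatic, config.mid_v_sd_asymptomatic),
              ("symptomatic", config.n_symptomatic,
               config.mid_v_mean_symptomatic, config.mid_v_sd_symptomatic)]
    all_rows, truth_rows = [], []
    sid = 0
    for cohort, n, v_mean, v_sd in groups:
        for i in range(n):
            variant = i % 2
            params = _draw_subject_params(rng, config, v_mean, v_sd)
            sched = _design.generate_schedule(
                _design.make_design("study1_main", reward_map_variant=variant),
                seed=int(rng.integers(0, 2**31 - 1)))
            all_rows.extend(_records_for_subject(
                f"s{sid:03d}", cohort, params, sched, variant, rng, config))
            truth_rows.append(_truth_row(f"s{sid:03d}", cohort, params))
            sid += 1
    records = pd.DataFrame(all_rows)
    truth = {"config": asdict(config), "seed": seed,
             "subjects": pd.DataFrame(truth_rows)}
    return records, truth


def generate_study2_cohort(config: CohortConfig = CohortConfig(), seed: int = 0):
    """Within-subject threat/safe cohort: 4 blocks x 60 trials per subject.

    Condition order (threat-first v. safe-first) alternates with subject
    parity; the shock-schedule variant rotates across subjects.  The mid-tone
    drift shifts by ``condition_effect_on_v`` under threat (default 0: null).
    """
    rng = np.random.default_rng(seed)
    shock_variants = ("first", "second", "both")
    all_rows, truth_rows = [], []
    for i in range(config.n_subjects):
        order = i % 2
        variant = (i // 2) % 2
        shock_variant = shock_variants[i % 3]
        base = _draw_subject_params(rng, config,
                                    config.mid_v_mean_asymptomatic,
                                    config.mid_v_sd_asymptomatic)
        des = _design.make_design("study2", reward_map_variant=variant,
                                  order=order, shock_variant=shock_variant)
        sched = _design.generate_schedule(des, seed=int(rng.integers(0, 2**31 - 1)))
        # simulate each condition with its own mid-tone drift
        frame = sched.frame
        rows_subject = []
        for cond in ("safe", "threat"):
            shift = config.condition_effect_on_v if cond == "threat" else 0.0
            params = dict(base)
            params["mid"] = ddm.DDMParams(v=base["mid"].v + shift, a=base["mid"].a,
                                          z=base["mid"].z, t0=base["mid"].t0,
                                          s=base["mid"].s)
            sub_sched = _design.TrialSchedule(frame[frame["condition"] == cond])
            rows_subject.extend(_records_for_subject(
                f"s{i:03d}", "n/a", params, sub_sched, variant, rng, config))
        rows_subject.sort(key=lambda r: r["trial_index"])
        all_rows.extend(rows_subject)
        truth_rows.append(dict(_truth_row(f"s{i:03d}", "n/a", base),
                               condition_effect_on_v=config.condition_effect_on_v,
                               order="threat_first" if order == 0 else "safe_first",
                               shock_variant=shock_variant))
    records = pd.DataFrame(all_rows)
    truth = {"config": asdict(config), "seed": seed,
             "subjects": pd.DataFrame(truth_rows)}
    return records, truth


def generate_covariates(cov_config: CovariateConfig, truth, seed: int = 0):
    """Per-subject anxiety ratings (study 2) and trait-anxiety scores.

    Ratings are truncated normals on [0, 10] with the configured parent
    moments.  Trait scores are tied to each subject's generative mid-tone
    drift through a Gaussian copula at the configured correlation (within
    cohort), then mapped to the cohort's trait distribution.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    subjects = truth["subjects"]
    rho = cov_config.trait_drift_corr
    rows = []
    for cohort, grp in subjects.groupby("cohort", sort=False):
        if cohort == "symptomatic":
            t_mean, t_sd = (cov_config.trait_mean_symptomatic,
                            cov_config.trait_sd_symptomatic)
        else:
            t_mean, t_sd = (cov_config.trait_mean_asymptomatic,
                            cov_config.trait_sd_asymptomatic)
        v = grp["v_mid"].to_numpy()
        zv = (v - v.mean()) / v.std(ddof=0) if v.std(ddof=0) > 0 else np.zeros(len(v))
        z_trait = rho * zv + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(v))
        trait = t_mean + t_sd * z_trait
        for sid, tr in zip(grp["subject_id"], trait):
            lo, hi = cov_config.rating_lo, cov_config.rating_hi
            def _trunc(mean, sd):
                aa, bb = (lo - mean) / sd, (hi - mean) / sd
                return float(sps.truncnorm.rvs(aa, bb, loc=mean, scale=sd,
                                               random_state=rng))
            rows.append({
                "subject_id": sid,
                "cohort": cohort,
                "rating_safe": _trunc(cov_config.rating_safe_mean,
                                      cov_config.rating_safe_sd),
                "rating_threat": _trunc(cov_config.rating_threat_mean,
                                        cov_config.rating_threat_sd),
                "trait_anxiety": float(tr),
            })
    return pd.DataFrame(rows)
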