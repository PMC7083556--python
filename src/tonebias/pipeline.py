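"""End-to-end study analyses from trial-level records to a report.

``run_study1`` mirrors the between-group analysis sequence (choice bias,
accuracy, RT, EZ-diffusion, hierarchical DDM model search with a group
split, correlations); ``run_study2`` the within-subject threat/safe
sequence (manipulation check, paired comparisons, EZ per condition,
hierarchical DDM with condition splits).  Every statistic in the report is
a direct call of the corresponding library operation on the same records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ez as _ez
from . import hier, stats

__all__ = ["AnalysisConfig", "AnalysisReport", "subject_summaries",
           "affective_bias", "run_study1", "run_study2"]


def affective_bias(mid_trials: pd.DataFrame) -> float:
    """High-reward responses divided by total key presses to the mid tone.

    Missed trials enter neither numerator nor denominator.
    """
    responded = mid_trials[mid_trials["response"] != "none"]
    if len(responded) == 0:
        raise ValueError("no responded mid-tone trials")
    return float((responded["response"] == "high").mean())


def subject_summaries(records: pd.DataFrame, by_condition: bool = False) -> pd.DataFrame:
    """Per-subject (optionally per-condition) behavioral summaries.

    bias: mid-tone high-reward proportion among responded trials;
    acc_low/acc_high: accuracy on unambiguous tones (responded trials only);
    mrt_*: mean RT (ms) per tone; vrt_mid: mid RT variance (ms^2, n-1);
    n_missed: trials without a response.
    """
    keys = ["subject_id"] + (["condition"] if by_condition else [])
    rows = []
    for key, grp in records.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        resp = grp[grp["response"] != "none"]
        mid = resp[resp["tone"] == "mid"]
        row = dict(zip(keys, key))
        row["bias"] = float((mid["response"] == "high").mean()) if len(mid) else np.nan
        for tone in ("low", "mid", "high"):
            sub = resp[resp["tone"] == tone]
            row[f"mrt_{tone}"] = float(sub["rt_ms"].mean()) if len(sub) else np.nan
            if tone != "mid":
                row[f"acc_{tone}"] = float(sub["correct"].mean()) if len(sub) else np.nan
        row["vrt_mid"] = float(mid["rt_ms"].var(ddof=1)) if len(mid) > 1 else np.nan
        row["n_mid_responded"] = int(len(mid))
        row["n_missed"] = int((grp["response"] == "none").sum())
        if "cohort" in grp:
            row["cohort"] = grp["cohort"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def ez_by_subject(records: pd.DataFrame, by_condition: bool = False,
                  s: float = 0.1) -> pd.DataFrame:
    """Per-subject EZ estimates on mid-tone trials (edge-corrected)."""
    keys = ["subject_id"] + (["condition"] if by_condition else [])
    rows = []
    for key, grp in records.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        mid = grp[(grp["tone"] == "mid") & (grp["response"] != "none")]
        if len(mid) < 2:
            continue
        upper = (mid["response"] == "high").to_numpy().astype(int)
        rt = mid["rt_ms"].to_numpy() / 1000.0
        est = _ez.ez_from_trials(upper, rt, s=s)
        row = dict(zip(keys, key))
        row.update(v=est.v, a=est.a, ter=est.ter)
        if "cohort" in grp:
            row["cohort"] = grp["cohort"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnalysisConfig:
    mcmc: hier.MCMCSettings = field(default_factory=lambda: hier.MCMCSettings(
        n_samples=1500, n_burn=500, n_chains=2))
    prior_scale: float = stats.DEFAULT_PRIOR_SCALE
    parity_threshold: float = 2.0
    run_hddm: bool = True
    #: restrict the trial-type grid (list of HierModelSpec) — None = all 16
    hddm_grid: list | None = None
    include_cohort_models: bool = True
    seed: int = 0


@dataclass
class AnalysisReport:
    study: str
    tables: dict  # name -> DataFrame
    results: dict  # name -> scalar/dict results
    provenance: dict

    def to_json(self) -> dict:
        return {
            "study": self.study,
            "tables": {k: v.to_dict(orient="records") for k, v in self.tables.items()},
            "results": self.results,
            "provenance": self.provenance,
        }


def _bf_entry(res: stats.BayesFactorResult) -> dict:
    return {"bf10": res.bf10, "label": res.label, "t": res.t_input, "df": res.df}


def _group_test(values_a, values_b, prior_scale):
    t, df = stats.two_sample_t(values_a, values_b)
    d = stats.cohens_d_from_t(t, n1=len(values_a), n2=len(values_b),
                              family="independent")
    bf = stats.jzs_bf_independent(t, len(values_a), len(values_b), prior_scale)
    return {"t": t, "df": df, "d": d, **_bf_entry(bf)}


def _paired_test(diff, prior_scale):
    t, df = stats.paired_t(diff)
    d = stats.cohens_d_from_t(t, n=len(diff), family="paired")
    bf = stats.jzs_bf_paired(t, len(diff), prior_scale)
    return {"t": t, "df": df, "d": d, **_bf_entry(bf)}


def run_study1(records: pd.DataFrame, config: AnalysisConfig = AnalysisConfig(),
               covariates: pd.DataFrame | None = None) -> AnalysisReport:
    """Between-group analysis (asymptomatic v. symptomatic)."""
    cohorts = sorted(set(records["cohort"]) - {"n/a"})
    if len(cohorts) != 2:
        raise ValueError("study-1 analysis needs exactly two cohorts")
    ref, other = "asymptomatic", "symptomatic"
    if set(cohorts) != {ref, other}:
        ref, other = cohorts

    summ = subject_summaries(records)
    ezs = ez_by_subject(records)
    results = {}

    def split(frame, col):
        return (frame.loc[frame["cohort"] == ref, col].dropna().to_numpy(),
                frame.loc[frame["cohort"] == other, col].dropna().to_numpy())

    results["bias"] = _group_test(*split(summ, "bias"), config.prior_scale)
    for col in ("acc_low", "acc_high", "mrt_mid"):
        results[col] = _group_test(*split(summ, col), config.prior_scale)
    for col in ("v", "a", "ter"):
        results[f"ez_{col}"] = _group_test(*split(ezs, col), config.prior_scale)

    merged = summ.merge(ezs[["subject_id", "v"]], on="subject_id")
    r, p2, p1 = stats.pearson_r(merged["bias"], merged["v"])
    results["corr_bias_ez_v"] = {"r": r, "p_two_tailed": p2, "p_one_tailed": p1}
    if covariates is not None and "trait_anxiety" in covariates:
        cov = summ.merge(covariates[["subject_id", "trait_anxiety"]], on="subject_id")
        r, p2, p1 = stats.pearson_r(cov["bias"], cov["trait_anxiety"])
        results["corr_bias_trait"] = {"r": r, "p_two_tailed": p2, "p_one_tailed": p1}
        cov2 = ezs.merge(covariates[["subject_id", "trait_anxiety"]], on="subject_id")
        r, p2, p1 = stats.pearson_r(cov2["v"], cov2["trait_anxiety"])
        results["corr_ez_v_trait"] = {"r": r, "p_two_tailed": p2, "p_one_tailed": p1}

    tables = {"subject_summaries": summ, "ez_estimates": ezs}

    if config.run_hddm:
        grid = config.hddm_grid or hier.build_model_grid(include_cohort=False)
        fits = []
        for i, spec in enumerate(grid):
            ms = hier.MCMCSettings(n_samples=config.mcmc.n_samples,
                                   n_burn=config.mcmc.n_burn,
                                   n_chains=config.mcmc.n_chains,
                                   seed=config.seed + i)
            fits.append(hier.fit_hierarchical(records, spec, ms))
        comparison = hier.compare_models(fits, config.parity_threshold)
        tables["hddm_dic"] = comparison.drop(columns=["spec"])
        results["hddm_winner"] = comparison["model"].iloc[0]
        if config.include_cohort_models:
            winner_tt = comparison["spec"].iloc[0].split_by_trialtype
            gspec = hier.HierModelSpec(split_by_trialtype=winner_tt or frozenset({"v"}),
                                       split_by_cohort=(("v", "group"),))
            gfit = hier.fit_hierarchical(records, gspec, hier.MCMCSettings(
                n_samples=config.mcmc.n_samples, n_burn=config.mcmc.n_burn,
                n_chains=config.mcmc.n_chains, seed=config.seed + 1000))
            results["hddm_v_group_contrast"] = hier.group_contrast_posterior(
                gfit, "v", other, ref,
                trialtype="m" if "v" in gspec.split_by_trialtype else None)
            results["hddm_v_group_contrast"]["contrast"] = f"{other} - {ref}"

    prov = {"seed": config.seed, "n_subjects": int(records["subject_id"].nunique()),
            "cohorts": {ref: int((summ["cohort"] == ref).sum()),
                        other: int((summ["cohort"] == other).sum())}}
    return AnalysisReport("study1", tables, results, prov)


def run_study2(records: pd.DataFrame, config: AnalysisConfig = AnalysisConfig(),
               ratings: pd.DataFrame | None = None) -> AnalysisReport:
    """Within-subject threat/safe analysis."""
    conds = set(records["condition"])
    if not {"safe", "threat"} <= conds:
        raise ValueError("study-2 analysis needs safe and threat conditions")

    summ = subject_summaries(records, by_condition=True)
    ezs = ez_by_subject(records, by_condition=True)
    results = {}

    def paired(frame, col):
        wide = frame.pivot(index="subject_id", columns="condition", values=col).dropna()
        return (wide["threat"] - wide["safe"]).to_numpy()

    if ratings is not None:
        diff = (ratings["rating_threat"] - ratings["rating_safe"]).to_numpy()
        results["manipulation_check"] = _paired_test(diff, config.prior_scale)
    results["bias"] = _paired_test(paired(summ, "bias"), config.prior_scale)
    results["mrt_mid"] = _paired_test(paired(summ, "mrt_mid"), config.prior_scale)
    for col in ("acc_low", "acc_high"):
        results[col] = _paired_test(paired(summ, col), config.prior_scale)
    for col in ("v", "a", "ter"):
        results[f"ez_{col}"] = _paired_test(paired(ezs, col), config.prior_scale)

    tables = {"subject_summaries": summ, "ez_estimates": ezs}

    if config.run_hddm:
        base_spec = hier.HierModelSpec(split_by_trialtype=frozenset(hier.PARAMS))
        specs = [base_spec] + [
            hier.HierModelSpec(split_by_trialtype=frozenset(hier.PARAMS),
                               split_by_cohort=((p, "condition"),))
            for p in hier.PARAMS]
        fits = []
        for i, spec in enumerate(specs):
            ms = hier.MCMCSettings(n_samples=config.mcmc.n_samples,
                                   n_burn=config.mcmc.n_burn,
                                   n_chains=config.mcmc.n_chains,
                                   seed=config.seed + i)
            fits.append(hier.fit_hierarchical(records, spec, ms))
        comparison = hier.compare_models(fits, config.parity_threshold)
        tables["hddm_dic"] = comparison.drop(columns=["spec"])
        results["hddm_winner"] = comparison["model"].iloc[0]
        base_dic = comparison.loc[comparison["model"] == base_spec.name, "dic"].iloc[0]
        best_cond = comparison[comparison["model"] != base_spec.name]["dic"].min()
        results["condition_split_beats_base"] = bool(
            best_cond < base_dic - config.parity_threshold)

    prov = {"seed": config.seed,
            "n_subjects": int(records["subject_id"].nunique())}
    return AnalysisReport("study2", tables, results, prov)
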