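"""Hierarchical Bayesian drift-diffusion fitting with DIC model search.

Model
-----
Trials are stratified into unambiguous ("u", accuracy-coded: upper boundary
= correct response) and ambiguous mid-tone ("m", stimulus-coded: upper =
high-reward response) trial types.  A model specification says which of the
four diffusion parameters {v, a, t0, z} take separate values per trial type
and which are split by a cohort factor — either a between-subject group
(separate group-level hyperparameters per cohort) or a within-subject
condition (separate subject-level values per condition).

Each subject-level parameter component is drawn from a group-level normal
(mean mu, SD sigma); hyperpriors are weakly informative (internal s = 1
fitting scale):

    mu_v ~ N(0, 5);  mu_a ~ N(1.5, 1) (>0);  mu_t0 ~ N(0.3, 0.25) (>0);
    mu_z ~ Beta(2, 2);  sigma ~ Half-Normal(0.5).

The trial likelihood is a 5% uniform-outlier mixture,

    (1 - p_out) * WFPT(rt | v, a, z, t0) + p_out * 0.5 / rt_max,

which keeps occasional extreme RTs from dominating the fit.  Sampling is
adaptive Metropolis-within-Gibbs (random-walk updates per subject-parameter
and per hyperparameter, proposal scales tuned toward ~40% acceptance during
burn-in).  Model comparison uses DIC = Dbar + pD with pD = Dbar - D(theta-bar),
the deviance focused on subject-level parameters; convergence is monitored
with the Gelman-Rubin potential-scale-reduction factor.

Internally everything is fitted on the s = 1 diffusion scale; summaries are
reported in the s = 0.1 convention (v and a divided by 10) so that they are
commensurable with the EZ estimates.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._accel import njit
from .ddm import _wfpt_lower_unit
from . import ez as _ez

__all__ = [
    "HierModelSpec",
    "MCMCSettings",
    "PosteriorFit",
    "build_model_grid",
    "preprocess_rts",
    "fit_hierarchical",
    "compute_dic",
    "gelman_rubin",
    "compare_models",
    "group_contrast_posterior",
]

PARAMS = ("v", "a", "t0", "z")
REPORT_DIVISOR = {"v": 10.0, "a": 10.0, "t0": 1.0, "z": 1.0}

# subject-level support bounds (internal s = 1 scale)
_BOUNDS = {"v": (-12.0, 12.0), "a": (0.15, 6.0), "t0": (0.01, 10.0), "z": (0.02, 0.98)}
_MU_PRIOR_SD = {"v": 5.0, "a": 1.0, "t0": 0.25}
_MU_PRIOR_MEAN = {"v": 0.0, "a": 1.5, "t0": 0.3}
_SIGMA_SCALE = 0.5  # half-normal scale for subject-level SDs


@dataclass(frozen=True)
class HierModelSpec:
    """Which parameters split by trial type and/or by a cohort factor.

    ``split_by_cohort`` maps parameter name -> "group" (between-subject) or
    "condition" (within-subject).
    """

    split_by_trialtype: frozenset = frozenset()
    split_by_cohort: tuple = ()  # tuple of (param, kind) pairs, hashable
    outlier_prob: float = 0.05

    def __post_init__(self):
        unknown = set(self.split_by_trialtype) - set(PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters in trial-type split: {unknown}")
        for p, kind in self.split_by_cohort:
            if p not in PARAMS or kind not in ("group", "condition"):
                raise ValueError(f"bad cohort split ({p}, {kind})")
        if not (0.0 <= self.outlier_prob < 1.0):
            raise ValueError("outlier_prob must be in [0, 1)")

    @property
    def cohort_split(self) -> dict:
        return dict(self.split_by_cohort)

    @property
    def name(self) -> str:
        tt = ",".join(p for p in PARAMS if p in self.split_by_trialtype) or "-"
        if self.split_by_cohort:
            co = ",".join(f"{p}|{k}" for p, k in self.split_by_cohort)
            return f"tt({tt})+co({co})"
        return f"tt({tt})"


@dataclass(frozen=True)
class MCMCSettings:
    n_samples: int = 1000
    n_burn: int = 500
    n_chains: int = 2
    seed: int = 0
    #: reproduce the historical short-burn configuration (2000 samples,
    #: burn-in 20) if desired
    @classmethod
    def paper_settings(cls, seed: int = 0) -> "MCMCSettings":
        return cls(n_samples=2000, n_burn=20, n_chains=1, seed=seed)


def build_model_grid(include_cohort: bool = False, cohort_kind: str = "group"):
    """All 16 trial-type-split models; optionally the cohort-split variants.

    The cohort variants sit on top of the full trial-type model: each single
    parameter split by the cohort factor, plus all four at once.
    """
    grid = []
    from itertools import combinations

    for r in range(len(PARAMS) + 1):
        for combo in combinations(PARAMS, r):
            grid.append(HierModelSpec(split_by_trialtype=frozenset(combo)))
    if include_cohort:
        full = frozenset(PARAMS)
        for p in PARAMS:
            grid.append(HierModelSpec(split_by_trialtype=full,
                                      split_by_cohort=((p, cohort_kind),)))
        grid.append(HierModelSpec(split_by_trialtype=full,
                                  split_by_cohort=tuple((p, cohort_kind) for p in PARAMS)))
    return grid


def preprocess_rts(records: pd.DataFrame) -> pd.DataFrame:
    """Drop missed trials; outliers are handled by the mixture likelihood,
    not by exclusion."""
    if len(records) == 0:
        raise ValueError("no records")
    out = records[(records["response"] != "none") & records["rt_ms"].notna()].copy()
    if len(out) == 0:
        raise ValueError("all trials missed")
    return out


@njit(cache=True)
def _cell_loglik(rt, upper, v, a, z, t0, p_out, rt_max):
    """Mixture log-likelihood of one subject-cell (internal s = 1 scale)."""
    total = 0.0
    u_out = 0.5 * p_out / rt_max
    for i in range(rt.shape[0]):
        if upper[i] == 1:
            dens = _wfpt_lower_unit(rt[i] - t0, -v, a, 1.0 - z, 1e-9)
        else:
            dens = _wfpt_lower_unit(rt[i] - t0, v, a, z, 1e-9)
        lik = (1.0 - p_out) * dens + u_out
        if lik <= 0.0:
            return -np.inf
        total += math.log(lik)
    return total


# ---------------------------------------------------------------------------
# data preparation


class _PreparedData:
    """Per-subject trial cells with coded boundaries, internal units."""

    def __init__(self, records: pd.DataFrame, cond_levels):
        records = preprocess_rts(records)
        self.cond_levels = cond_levels  # () when condition plays no role
        self.subjects = []
        self.cells = []  # list per subject: dict (tt, cond) -> (rt, upper)
        self.cohorts = []
        self.min_rt = []
        self.data_hash = hashlib.sha1(
            pd.util.hash_pandas_object(
                records[["subject_id", "trial_index", "rt_ms", "response"]]
            ).values.tobytes()
        ).hexdigest()
        for sid, grp in records.groupby("subject_id", sort=True):
            cells = {}
            for _, row in grp.iterrows():
                tt = "m" if row["tone"] == "mid" else "u"
                cond = row.get("condition", "neutral") if cond_levels else None
                key = (tt, cond)
                cells.setdefault(key, []).append(row)
            coded = {}
            for key, rows in cells.items():
                tt = key[0]
                rts = np.array([r["rt_ms"] / 1000.0 for r in rows])
                if tt == "m":
                    upper = np.array([1 if r["response"] == "high" else 0 for r in rows],
                                     dtype=np.int8)
                else:
                    upper = np.array([int(r["correct"]) for r in rows], dtype=np.int8)
                coded[key] = (rts, upper)
            self.subjects.append(sid)
            self.cells.append(coded)
            co = grp["cohort"].iloc[0] if "cohort" in grp else "n/a"
            self.cohorts.append(co)
            self.min_rt.append(min(r[0].min() for r in coded.values()))
        self.rt_max = float(records["rt_ms"].max() / 1000.0)
        self.cohort_levels = sorted(set(self.cohorts))


def _needs_condition(spec: HierModelSpec) -> bool:
    return any(kind == "condition" for _, kind in spec.split_by_cohort)


class _ModelLayout:
    """Index bookkeeping: components, hyper groups, cell -> component map."""

    def __init__(self, spec: HierModelSpec, data: _PreparedData):
        self.spec = spec
        cond_split = {p for p, k in spec.split_by_cohort if k == "condition"}
        group_split = {p for p, k in spec.split_by_cohort if k == "group"}
        self.group_split = group_split
        tt_levels = lambda p: ("u", "m") if p in spec.split_by_trialtype else (None,)
        cond_levels = lambda p: tuple(data.cond_levels) if p in cond_split else (None,)
        self.components = []  # (param, tt, cond)
        for p in PARAMS:
            for tt in tt_levels(p):
                for c in cond_levels(p):
                    self.components.append((p, tt, c))
        self.comp_index = {c: i for i, c in enumerate(self.components)}
        self.n_comp = len(self.components)
        # hyper groups: list per component of cohort levels (1 unless group split)
        self.hyper_levels = []
        for (p, tt, c) in self.components:
            if p in group_split and len(data.cohort_levels) > 1:
                self.hyper_levels.append(tuple(data.cohort_levels))
            else:
                self.hyper_levels.append((None,))
        # map every cell key to its 4 component indices
        self.cell_params = {}
        cell_keys = set()
        for coded in data.cells:
            cell_keys.update(coded.keys())
        for (tt, cond) in cell_keys:
            idx = []
            for p in PARAMS:
                tt_lv = tt if p in spec.split_by_trialtype else None
                c_lv = cond if p in cond_split else None
                idx.append(self.comp_index[(p, tt_lv, c_lv)])
            self.cell_params[(tt, cond)] = tuple(idx)
        # inverse: component -> affected cell keys
        self.comp_cells = [[] for _ in range(self.n_comp)]
        for key, idx in self.cell_params.items():
            for ci in idx:
                if key not in self.comp_cells[ci]:
                    self.comp_cells[ci].append(key)
        # per-subject upper bound for each t0 component: the minimum RT over
        # the cells that component actually governs (a global bound would
        # wrongly cap a slow stratum's non-decision time at the fast
        # stratum's leading edge)
        n_subj = len(data.subjects)
        self.t0_cap = np.full((n_subj, self.n_comp), np.inf)
        for ci, (p, tt, c) in enumerate(self.components):
            if p != "t0":
                continue
            for j in range(n_subj):
                mins = [data.cells[j][key][0].min() for key in self.comp_cells[ci]
                        if key in data.cells[j]]
                if mins:
                    self.t0_cap[j, ci] = min(mins)

    def hyper_index(self, ci: int, cohort) -> int:
        levels = self.hyper_levels[ci]
        return levels.index(cohort) if levels[0] is not None else 0


# ---------------------------------------------------------------------------
# prior densities (log, unnormalized where harmless)


def _log_mu_prior(param: str, x: float) -> float:
    if param == "z":
        if not (0.0 < x < 1.0):
            return -np.inf
        return math.log(x) + math.log(1.0 - x)  # Beta(2,2) kernel
    m, s = _MU_PRIOR_MEAN[param], _MU_PRIOR_SD[param]
    if param in ("a", "t0") and x <= 0:
        return -np.inf
    return -0.5 * ((x - m) / s) ** 2


def _log_sigma_prior(x: float) -> float:
    if x <= 0:
        return -np.inf
    return -0.5 * (x / _SIGMA_SCALE) ** 2


# ---------------------------------------------------------------------------
# posterior fit container


@dataclass
class PosteriorFit:
    spec: HierModelSpec
    settings: MCMCSettings
    components: list  # (param, tt, cond) triples
    hyper_levels: list
    subjects: list
    cohorts: list
    mu: np.ndarray  # (chains, draws, comp, max_levels)
    sigma: np.ndarray  # same shape
    subject_draws: np.ndarray  # (chains, draws, n_subj, comp)
    deviance: np.ndarray  # (chains, draws)
    dic: float
    pD: float
    gelman_rubin: dict
    accept_rates: dict
    data_hash: str
    _data: object = field(repr=False, default=None)
    _layout: object = field(repr=False, default=None)

    def hyper_mean_draws(self, param, tt=None, cond=None, cohort=None, report_scale=True):
        """Pooled posterior draws of a group-level mean, optionally on the
        s = 0.1 reporting convention."""
        layout = self._layout
        ci = layout.comp_index[(param, tt, cond)]
        hi = layout.hyper_index(ci, cohort)
        draws = self.mu[:, :, ci, hi].reshape(-1)
        return draws / REPORT_DIVISOR[param] if report_scale else draws.copy()

    def summary(self) -> pd.DataFrame:
        rows = []
        for ci, (p, tt, c) in enumerate(self.components):
            for hi, lev in enumerate(self.hyper_levels[ci]):
                d = self.mu[:, :, ci, hi].reshape(-1) / REPORT_DIVISOR[p]
                rows.append({
                    "param": p, "trialtype": tt or "shared", "condition": c or "shared",
                    "cohort": lev or "all", "mean": d.mean(),
                    "ci2.5": np.quantile(d, 0.025), "ci97.5": np.quantile(d, 0.975),
                    "rhat": self.gelman_rubin.get(("mu", ci, hi), np.nan),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the sampler


def _init_state(data: _PreparedData, layout: _ModelLayout, rng):
    """Moment-based initialization: EZ estimates per subject-cell (internal
    s = 1 scale), averaged over the cells each component covers."""
    n_subj = len(data.subjects)
    theta = np.zeros((n_subj, layout.n_comp))
    for j in range(n_subj):
        cell_est = {}
        for key, (rts, upper) in data.cells[j].items():
            try:
                est = _ez.ez_from_trials(upper, rts, s=1.0)
                cell_est[key] = {"v": est.v, "a": est.a, "t0": est.ter, "z": 0.5}
            except Exception:
                cell_est[key] = {"v": 0.0, "a": 1.5, "t0": 0.2, "z": 0.5}
        for ci, (p, tt, c) in enumerate(layout.components):
            vals = [cell_est[key][p] for key in layout.comp_cells[ci] if key in cell_est]
            v0 = float(np.mean(vals)) if vals else {"v": 0.0, "a": 1.5, "t0": 0.2, "z": 0.5}[p]
            lo, hi = _BOUNDS[p]
            if p == "t0":
                cap = layout.t0_cap[j, ci]
                hi = min(hi, cap * 0.98)
                v0 = min(max(v0, 0.3 * cap), 0.85 * cap)
            theta[j, ci] = float(np.clip(v0 + 0.01 * rng.standard_normal(), lo, hi))
    max_lv = max(len(lv) for lv in layout.hyper_levels)
    mu = np.zeros((layout.n_comp, max_lv))
    sig = np.full((layout.n_comp, max_lv), 0.2)
    for ci, (p, tt, c) in enumerate(layout.components):
        for hi, lev in enumerate(layout.hyper_levels[ci]):
            members = [j for j in range(n_subj)
                       if lev is None or data.cohorts[j] == lev]
            mu[ci, hi] = np.mean(theta[members, ci])
            sig[ci, hi] = max(0.05, np.std(theta[members, ci]))
    return theta, mu, sig


def _run_chain(data: _PreparedData, layout: _ModelLayout, settings: MCMCSettings,
               chain_seed: int, outlier_prob: float):
    rng = np.random.default_rng(chain_seed)
    n_subj = len(data.subjects)
    n_comp = layout.n_comp
    theta, mu, sigma = _init_state(data, layout, rng)
    p_out = outlier_prob
    rt_max = data.rt_max

    # cached per-cell log-likelihoods
    cell_ll = []
    def eval_cell(j, key, th_row):
        idx = layout.cell_params[key]
        rts, upper = data.cells[j][key]
        return _cell_loglik(rts, upper, th_row[idx[0]], th_row[idx[1]],
                            th_row[idx[3]], th_row[idx[2]], p_out, rt_max)
    # note component order in cell_params follows PARAMS = (v, a, t0, z):
    # idx[0]=v, idx[1]=a, idx[2]=t0, idx[3]=z; _cell_loglik takes (v,a,z,t0).
    for j in range(n_subj):
        cell_ll.append({key: eval_cell(j, key, theta[j]) for key in data.cells[j]})

    # proposal scales
    step_theta = np.full((n_subj, n_comp), 0.15)
    step_mu = np.full(mu.shape, 0.1)
    step_sigma = np.full(sigma.shape, 0.2)
    acc_theta = np.zeros((n_subj, n_comp)); try_theta = np.zeros((n_subj, n_comp))
    acc_hyper = np.zeros(mu.shape); try_hyper = np.zeros(mu.shape)

    n_total = settings.n_burn + settings.n_samples
    keep_mu = np.empty((settings.n_samples, *mu.shape))
    keep_sigma = np.empty((settings.n_samples, *sigma.shape))
    keep_theta = np.empty((settings.n_samples, n_subj, n_comp))
    keep_dev = np.empty(settings.n_samples)

    hyper_members = {}
    for ci in range(n_comp):
        for hi, lev in enumerate(layout.hyper_levels[ci]):
            hyper_members[(ci, hi)] = np.array(
                [j for j in range(n_subj) if lev is None or data.cohorts[j] == lev])

    for it in range(n_total):
        adapting = it < settings.n_burn
        # --- subject-level updates
        for j in range(n_subj):
            for ci, (p, tt, c) in enumerate(layout.components):
                cur = theta[j, ci]
                prop = cur + step_theta[j, ci] * rng.standard_normal()
                lo, hi_b = _BOUNDS[p]
                if p == "t0":
                    hi_b = min(hi_b, layout.t0_cap[j, ci] * 0.999)
                try_theta[j, ci] += 1
                if not (lo < prop < hi_b):
                    continue
                hidx = layout.hyper_index(ci, data.cohorts[j])
                m, s = mu[ci, hidx], sigma[ci, hidx]
                dprior = (-0.5 * ((prop - m) / s) ** 2) - (-0.5 * ((cur - m) / s) ** 2)
                theta[j, ci] = prop
                new_ll = {}
                dll = 0.0
                ok = True
                for key in layout.comp_cells[ci]:
                    if key not in data.cells[j]:
                        continue
                    ll = eval_cell(j, key, theta[j])
                    if not np.isfinite(ll):
                        ok = False
                        break
                    new_ll[key] = ll
                    dll += ll - cell_ll[j][key]
                if ok and math.log(rng.random() + 1e-300) < dll + dprior:
                    cell_ll[j].update(new_ll)
                    acc_theta[j, ci] += 1
                else:
                    theta[j, ci] = cur
        # --- hyper updates
        for ci, (p, tt, c) in enumerate(layout.components):
            for hi in range(len(layout.hyper_levels[ci])):
                members = hyper_members[(ci, hi)]
                vals = theta[members, ci]
                # mu
                cur = mu[ci, hi]
                prop = cur + step_mu[ci, hi] * rng.standard_normal()
                try_hyper[ci, hi] += 1
                s = sigma[ci, hi]
                lp_cur = _log_mu_prior(p, cur) - 0.5 * np.sum(((vals - cur) / s) ** 2)
                lp_prop = _log_mu_prior(p, prop) - 0.5 * np.sum(((vals - prop) / s) ** 2)
                if math.log(rng.random() + 1e-300) < lp_prop - lp_cur:
                    mu[ci, hi] = prop
                    acc_hyper[ci, hi] += 1
                # sigma (log-scale random walk; Jacobian = log sigma)
                cur_s = sigma[ci, hi]
                prop_s = cur_s * math.exp(step_sigma[ci, hi] * rng.standard_normal())
                n_m = len(members)
                m_now = mu[ci, hi]
                lp_cur = (_log_sigma_prior(cur_s) - n_m * math.log(cur_s)
                          - 0.5 * np.sum(((vals - m_now) / cur_s) ** 2) + math.log(cur_s))
                lp_prop = (_log_sigma_prior(prop_s) - n_m * math.log(prop_s)
                           - 0.5 * np.sum(((vals - m_now) / prop_s) ** 2) + math.log(prop_s))
                if prop_s > 1e-4 and math.log(rng.random() + 1e-300) < lp_prop - lp_cur:
                    sigma[ci, hi] = prop_s
        # --- adaptation
        if adapting and (it + 1) % 25 == 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(try_theta > 0, acc_theta / try_theta, 0.4)
                step_theta *= np.exp(np.clip(r - 0.4, -0.5, 0.5))
                step_theta = np.clip(step_theta, 1e-4, 5.0)
                rh = np.where(try_hyper > 0, acc_hyper / try_hyper, 0.4)
                step_mu *= np.exp(np.clip(rh - 0.4, -0.5, 0.5))
                step_mu = np.clip(step_mu, 1e-4, 5.0)
            acc_theta[:] = 0; try_theta[:] = 0
            acc_hyper[:] = 0; try_hyper[:] = 0
        if not adapting:
            k = it - settings.n_burn
            keep_mu[k] = mu
            keep_sigma[k] = sigma
            keep_theta[k] = theta
            keep_dev[k] = -2.0 * sum(sum(d.values()) for d in cell_ll)

    acc = {
        "theta": float(np.sum(acc_theta) / max(1.0, np.sum(try_theta))),
        "hyper": float(np.sum(acc_hyper) / max(1.0, np.sum(try_hyper))),
    }
    return keep_mu, keep_sigma, keep_theta, keep_dev, acc


def _deviance_at(data: _PreparedData, layout: _ModelLayout, theta: np.ndarray,
                 p_out: float) -> float:
    total = 0.0
    for j in range(len(data.subjects)):
        for key, (rts, upper) in data.cells[j].items():
            idx = layout.cell_params[key]
            total += _cell_loglik(rts, upper, theta[j, idx[0]], theta[j, idx[1]],
                                  theta[j, idx[3]], theta[j, idx[2]],
                                  p_out, data.rt_max)
    return -2.0 * total


def fit_hierarchical(records: pd.DataFrame, spec: HierModelSpec,
                     settings: MCMCSettings = MCMCSettings()) -> PosteriorFit:
    """Fit one hierarchical model specification by MCMC.

    ``records`` follow the trial-record schema (rt_ms in milliseconds; RTs
    are converted to seconds and drift/boundary to the internal s = 1 scale
    automatically because the likelihood is evaluated at unit scale).
    """
    if records["subject_id"].nunique() < 2:
        raise ValueError("hierarchical fit needs >= 2 subjects")
    cond_levels = ()
    if _needs_condition(spec):
        if "condition" not in records:
            raise ValueError("condition split requested but records lack a condition column")
        cond_levels = tuple(sorted(set(records["condition"]) - {"neutral"}))
        if len(cond_levels) < 2:
            raise ValueError("condition split needs >= 2 condition levels")
    data = _PreparedData(records, cond_levels)
    if any(k == "group" for _, k in spec.split_by_cohort) and len(data.cohort_levels) < 2:
        raise ValueError("group split requested but records contain a single cohort")
    layout = _ModelLayout(spec, data)

    chains = []
    ss = np.random.SeedSequence(settings.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(settings.n_chains)]
    for cs in chain_seeds:
        chains.append(_run_chain(data, layout, settings, cs, spec.outlier_prob))

    mu = np.stack([c[0] for c in chains])        # (chain, draw, comp, lv)
    sigma = np.stack([c[1] for c in chains])
    theta = np.stack([c[2] for c in chains])     # (chain, draw, subj, comp)
    dev = np.stack([c[3] for c in chains])
    acc = {k: float(np.mean([c[4][k] for c in chains])) for k in chains[0][4]}

    dbar = float(dev.mean())
    theta_bar = theta.reshape(-1, *theta.shape[2:]).mean(axis=0)
    d_hat = _deviance_at(data, layout, theta_bar, spec.outlier_prob)
    pD = dbar - d_hat
    dic = dbar + pD

    rhat = {}
    for ci in range(layout.n_comp):
        for hi in range(len(layout.hyper_levels[ci])):
            rhat[("mu", ci, hi)] = gelman_rubin(mu[:, :, ci, hi])
            rhat[("sigma", ci, hi)] = gelman_rubin(sigma[:, :, ci, hi])

    return PosteriorFit(
        spec=spec, settings=settings, components=layout.components,
        hyper_levels=layout.hyper_levels, subjects=data.subjects,
        cohorts=data.cohorts, mu=mu, sigma=sigma, subject_draws=theta,
        deviance=dev, dic=dic, pD=pD, gelman_rubin=rhat, accept_rates=acc,
        data_hash=data.data_hash, _data=data, _layout=layout)


def compute_dic(fit: PosteriorFit) -> tuple:
    """(DIC, pD) recomputed from the stored draws and data."""
    if fit._data is None:
        raise ValueError("fit carries no data reference")
    dbar = float(fit.deviance.mean())
    theta_bar = fit.subject_draws.reshape(-1, *fit.subject_draws.shape[2:]).mean(axis=0)
    d_hat = _deviance_at(fit._data, fit._layout, theta_bar, fit.spec.outlier_prob)
    pD = dbar - d_hat
    return dbar + pD, pD


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential-scale-reduction factor from >= 2 chains of equal length.

    A single chain is split in half.  R-hat = sqrt(V-hat / W) with
    V-hat = (n-1)/n W + (1 + 1/m) B/n.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_draws)")
    if chains.shape[0] < 2:
        n = chains.shape[1] // 2
        if n < 2:
            raise ValueError("need >= 2 chains or enough draws to split one")
        chains = np.stack([chains[0, :n], chains[0, n:2 * n]])
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return 1.0
    v_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(math.sqrt(v_hat / W))


def compare_models(fits, parity_threshold: float = 2.0) -> pd.DataFrame:
    """Rank fits of the same data by DIC.

    The winner is the lowest DIC; models within ``parity_threshold`` of the
    winner are flagged at parity.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    if len({f.data_hash for f in fits}) > 1:
        raise ValueError("fits were computed on different data")
    rows = [{"model": f.spec.name, "dic": f.dic, "pD": f.pD, "spec": f.spec}
            for f in fits]
    table = pd.DataFrame(rows).sort_values("dic", kind="mergesort").reset_index(drop=True)
    table["delta_dic"] = table["dic"] - table["dic"].iloc[0]
    table["winner"] = [i == 0 for i in range(len(table))]
    table["at_parity"] = table["delta_dic"] <= parity_threshold
    return table


def group_contrast_posterior(fit: PosteriorFit, parameter: str,
                             cohort_a: str, cohort_b: str,
                             trialtype: str = "m", condition=None,
                             ci: float = 0.95) -> dict:
    """Posterior of hyper-mean(A) - hyper-mean(B) for a cohort-split
    parameter, on the s = 0.1 reporting scale.

    Returns posterior mean, equal-tailed credible interval and
    P(difference < 0).
    """
    if parameter not in {p for p, k in fit.spec.split_by_cohort if k == "group"}:
        raise ValueError(f"parameter {parameter!r} is not split by group in this model")
    tt = trialtype if parameter in fit.spec.split_by_trialtype else None
    da = fit.hyper_mean_draws(parameter, tt=tt, cond=condition, cohort=cohort_a)
    db = fit.hyper_mean_draws(parameter, tt=tt, cond=condition, cohort=cohort_b)
    diff = da - db
    alpha = (1.0 - ci) / 2.0
    return {
        "mean": float(diff.mean()),
        "ci_low": float(np.quantile(diff, alpha)),
        "ci_high": float(np.quantile(diff, 1.0 - alpha)),
        "p_lt_0": float(np.mean(diff < 0.0)),
    }
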