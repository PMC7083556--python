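# tonebias

Simulation and decision-model analysis of the **ambiguous-tone
judgement-bias task**, a two-alternative forced-choice paradigm in which a
low (500 Hz) and a high (1000 Hz) tone predict small (£1) and large (£4)
rewards and an ambiguous 750 Hz mid tone — reinforced 50/50 at random —
probes *affective bias*: the tendency to interpret an ambiguous cue as
predicting the better or worse outcome.  The paradigm is a direct human
translation of a rodent judgement-bias task used in computational
psychiatry to compare pathological and induced anxiety.

The package targets researchers analysing this task (or structurally
similar 2AFC reward-bias tasks).  It provides:

* **Task designs and schedules** (`tonebias.design`): the acquisition,
  120-trial main, and 240-trial threat/safe paradigms with exact timing
  accounting and seeded, balanced trial schedules.
* **Wiener diffusion core** (`tonebias.ddm`): choice probabilities,
  first-passage-time densities via adaptive small-/large-time series, and
  Euler–Maruyama trial simulation.  Choice = boundary reached; RT =
  crossing time + non-decision time `t0`; parameters (v, a, z, t0, s).
* **EZ-diffusion** (`tonebias.ez`): the closed-form map between
  (proportion positive, RT mean, RT variance) and (v, a, Ter), its exact
  forward model, and edge correction for degenerate proportions.
* **Hierarchical Bayesian DDM** (`tonebias.hier`): MCMC fitting with
  trial-type/group/condition parameter splits, a 5% uniform-outlier
  mixture likelihood, DIC model search over the 16-model grid, and
  Gelman–Rubin diagnostics.
* **Inference layer** (`tonebias.stats`): t tests, Cohen's d, Pearson
  correlations, and default-prior (JZS, Cauchy scale 0.707) Bayes factors
  with verbal evidence labels.
* **Synthetic cohorts** (`tonebias.cohort`): trial-level datasets with the
  statistical structure the analyses assume (two groups of 47/30 subjects,
  or 47 subjects under threat/safe conditions), carrying their generating
  parameters for recovery scoring.
* **Pipeline + CLI** (`tonebias.pipeline`, `tonebias.cli`): end-to-end
  study analyses from trial-level CSVs, and a `tonebias` command with
  `simulate | ez-fit | hddm-fit | compare | stats | report` subcommands.

## Worked example

Recompute the default-prior Bayes factor for a group difference in
affective bias (t(75) = 3.08 between groups of 47 and 30), and analyse a
synthetic cohort:

```python
>>> from tonebias import stats, cohort, pipeline
>>> res = stats.jzs_bf_independent(3.08, 47, 30)
>>> round(res.bf10, 2), res.label
(12.5, 'strong')

>>> records, truth = cohort.generate_study1_cohort(seed=1)
>>> summ = pipeline.subject_summaries(records)
>>> ezs = pipeline.ez_by_subject(records)
>>> merged = summ.merge(ezs[["subject_id", "v"]], on="subject_id")
>>> r, p2, p1 = stats.pearson_r(merged["bias"], merged["v"])
>>> round(r, 3)
0.978
```

The Bayes factor of 12.5 is *strong* evidence for a group difference; the
correlation of ~0.98 between per-subject mid-tone choice proportion and
EZ drift shows the two bias measures are nearly collinear, as expected
when the drift rate carries the choice asymmetry.

From the shell:

```bash
tonebias simulate --study 1 --seed 7 --out-dir out/
tonebias ez-fit  --trials out/study1_trials.csv --out-dir out/
tonebias compare --trials out/study1_trials.csv --out-dir out/   # 16-model DIC grid
tonebias report  --trials out/study1_trials.csv --study 1 --out-dir out/
```

Every command writes a provenance JSON (seed, config, version) next to
its outputs; identical invocations produce identical files.

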