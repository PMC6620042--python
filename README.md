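# dopanet

Simulation and analysis pipeline linking striatal dopamine D2/3 receptor
availability (PET), working-memory-load-dependent cortical network
connectivity (fMRI), and n-back task performance.

## The scientific problem

Working memory performance depends both on striatal D2/3 receptor
signalling and on how cortical networks reorganise under cognitive load:
as n-back load rises, functional connectivity within the default mode
network (DMN) falls while task-positive network (TPN) connectivity rises,
and the size of the DMN reduction tracks both striatal receptor
availability and behavioural robustness. `dopanet` implements the full
analysis chain needed to test that mediation hypothesis — and, because the
original subject-level data are not publicly deposited, a synthetic-cohort
generator that plants the hypothesised structure with known ground truth,
so every stage of the pipeline is verifiable end to end.

The pipeline stages:

1. **Behaviour** — proportional penalized reaction time
   (pRT: incorrect/omitted trials contribute `ratio x` the subject- and
   condition-specific mean correct RT), robustness `-dpRT` (negated OLS
   slope of pRT on load), and d' = Z(hit) - Z(false alarm) with 1/(2n)
   extreme-score adjustment.
2. **Connectivity** — Fisher z edges per load condition (haemodynamic-lag
   shifted, per-block demeaned), per-edge load regression
   `zFC = w0 + w1*load`, and network means of w1 over DMN / TPN /
   between-network edge sets.
3. **Network detection** — Louvain modularity maximisation
   (`Q = (1/v) sum_ij (w_ij - gamma s_i s_j / v) delta(M_i, M_j)`) with
   agreement-matrix consensus clustering at subject and group level, and
   Sorensen-Dice scoring against the a-priori parcel labels.
4. **PET kinetics** — simplified reference tissue model (SRTM) simulation
   and basis-function fitting of regional time-activity curves, yielding
   BP_ND per striatal region.
5. **Inference** — Spearman correlations with Fisher-transform CIs, Meng's
   test for dependent correlations, repeated-measures ANOVA, a
   within-subject block-level regression of performance on DMN strength,
   and linear-model causal mediation (ACME = a*b) with BCa bootstrap
   intervals.

## Worked example

```python
from dopanet import CohortConfig, AnalysisConfig, simulate_cohort, run_analysis

cohort = simulate_cohort(CohortConfig(seed=1))          # 51 subjects
report = run_analysis(cohort, AnalysisConfig(network_detection="apriori",
                                             n_boot=999, seed=1))

conn = report["connectivity"]["dmn_w1"]
rho = report["correlations"]["bp_vs_w1"]["caudate"]["dmn"]
acme = report["mediation"]["caudate"]["dmn"]["acme"]
print(f"group mean DMN w1 = {conn['mean']:.3f} "
      f"(t_{conn['df']} = {conn['t']:.2f}, p = {conn['p']:.2g})")
print(f"rho(caudate BP_ND, DMN w1) = {rho['rho']:.2f}, p = {rho['p']:.3g}")
print(f"ACME = {acme['est']:.3f} [{acme['ci_low']:.3f}, {acme['ci_high']:.3f}], "
      f"p = {acme['p']:.3g}")
```

prints

```
group mean DMN w1 = -0.088 (t_50 = -8.18, p = 8.7e-11)
rho(caudate BP_ND, DMN w1) = 0.41, p = 0.0026
ACME = 0.069 [0.024, 0.135], p = 0.00103
```

Read: within-DMN connectivity falls by ~0.09 z per load step at the group
level; subjects with higher caudate BP_ND show smaller reductions
(rho = 0.41); and the receptor-performance association runs through that
connectivity change (positive, significant average causal mediation
effect). The cohort was generated with exactly this structure planted
(slope -0.10, BP-slope Spearman 0.45, purely mediated behavioural path),
so the numbers double as a recovery check.

The same workflow is available from the shell:

```bash
dopanet simulate --n-subjects 51 --seed 1 --out cohort/
dopanet analyze --cohort cohort/ --seed 1 --out results/
dopanet check --report-dir results/     # re-derive statistics from stage files
```

## Layout

```
src/dopanet/
  config.py        cohort + analysis configuration
  synthetic.py     seeded cohort generator (trials, BOLD, TACs, latents)
  behavior.py      pRT, -dpRT, d'
  connectivity.py  Fisher-z edges, load regression, block-wise strength
  community.py     modularity, Louvain, consensus clustering, Dice
  srtm.py          SRTM forward model and basis-function fitting
  stats.py         Spearman CI, Meng z, rm-ANOVA, BCa mediation
  pipeline.py      orchestration, reports, independent checker
  cli.py           simulate / analyze / report / check subcommands
docs/methods.md    models, defaults, calibration rationale, limitations
```
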