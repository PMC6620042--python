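# Methods

`dopanet` simulates and analyses multimodal cohorts in which striatal
dopamine D2/3 receptor availability (PET binding potential) couples to the
working-memory-load-dependent reorganisation of cortical functional
connectivity (fMRI), which in turn carries the association between receptor
availability and task performance. This note documents the models, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions inside each stage.

## Study design being emulated

A letter n-back session: 18 task blocks of 20 s (six each of 0-, 1- and
2-back in pseudo-random order), each followed by 10 s of rest, acquired as
275 EPI volumes at TR = 2 s. Each block presents 10 letters for 2 s each;
the subject answers target/non-target. Cortical signals are summarised as
97 parcel time courses, 42 a-priori default-mode (DMN) and 55 task-positive
(DAN + FPN) nodes. The same subjects have a 90-min PET acquisition binned
into 31 frames (8 x 15 s, 3 x 60 s, 5 x 120 s, 15 x 300 s), summarised as
regional time-activity curves (TACs) for caudate, putamen, accumbens and
SN/VTA plus a cerebellar reference curve.

## Behavioural metrics

**Penalized reaction time (pRT).** Within a subject x load cell, the
baseline is the mean RT of *correct* trials; each incorrect or omitted
trial contributes `ratio x baseline` (ratio 2.5 by default, 2.5-4
analysed), correct trials contribute their own RT, and pRT is the mean over
all trials. We interpret the "subject- and condition-specific RT" baseline
as the mean over correct trials only: penalizing relative to RTs that are
themselves contaminated by errors would be circular. Wrong-key responses
and omissions are penalized identically.

**Robustness (-dpRT).** The negated OLS slope of pRT on load (0/1/2);
0 means load-invariant performance, negative values mean degradation.
With loads coded 0/1/2 the slope reduces to (pRT(2) - pRT(0))/2.

**d'.** Z(hit rate) - Z(false-alarm rate) per load, with extreme rates
adjusted to 1 - 1/(2n) and 1/(2n). By default n is the *whole-task* count
of targets (for hits) or non-targets (for false alarms); a per-load scope
is available (`scope="load"`) since the two readings are both defensible.

## Connectivity

Edges are Fisher z-transformed Pearson correlations between parcel time
courses. Condition-wise estimates concatenate all blocks of a load, with
each block window shifted forward by `lag_volumes` (default 2 volumes =
4 s) to account for haemodynamic delay, and each block segment demeaned per
node before concatenation. The demeaning matters: block-to-block variation
of the sample means is shared across all nodes and otherwise inflates every
correlation by a common offset (~+0.06 z under the default design). It
plays the role that condition-regressor removal plays in a real
preprocessing chain. Correlations are clamped to +-(1 - 1e-12) before
atanh.

Per edge, the load effect is the OLS slope w1 of z on load in {0, 1, 2}
(uncentred, so the intercept w0 is the 0-back fitted value). Network
summaries are arithmetic means of w1 over within-DMN, within-TPN and
between-network edge sets. Negative-weight edges are retained here; they
are zeroed only for community detection. Block-wise DMN strength (one mean
within-DMN z per block, 10 volumes each) feeds the within-subject analysis
only; condition-wise concatenation is used everywhere else because it
maximises samples per estimate.

A practical accuracy note: with ~57 usable volumes per condition, the
per-subject network-mean w1 carries an irreducible sd of about 0.03-0.045
z/load, dominated by common-mode sampling fluctuation of the shared
network factor (it grows with the baseline correlation). Group means over
51 subjects are accurate to ~0.005; individual subject estimates are not
precise, which attenuates between-subject correlations by roughly 10%.

## Community detection

Graphs are the 0-back z-matrices with negatives zeroed. Modularity is

    Q = (1/v) * sum_ij (w_ij - gamma * s_i * s_j / v) * delta(M_i, M_j)

with v = sum_ij w_ij counting both orderings, s_i = sum_j w_ij, gamma = 1.
Louvain runs best-gain local moves over a seeded random node order,
aggregates, and repeats until no move improves Q; ties break to the lowest
community index for determinism; the returned partition is never worse
than the single-community partition (Q >= 0 at gamma = 1). The number of
communities is not forced to two: each empirical community is labelled DMN
or TPN by its larger Sorensen-Dice overlap with the a-priori sets (an
exact tie is an error).

Consensus clustering runs `n_iter` seeded Louvain partitions per round
(sub-seeds derive from (seed, round, iteration), so runs are reproducible
and order-independent); if the round is not unanimous, the agreement
matrix (co-assignment proportions, entries strictly below 0.5 zeroed,
diagonal cleared) is re-clustered. A `max_rounds` guard (default 50) turns
non-convergence into an explicit error; the underlying procedure has no
failure path of its own. The group partition applies the same procedure to
the mean of the subjects' binary co-assignment matrices. Inner rounds
cluster agreement weights directly, without re-normalisation.

## PET kinetics (SRTM)

The simplified reference tissue model,

    C_T(t) = R1 C_R(t) + (k2 - R1 k2a) * (C_R (*) exp(-k2a t)),
    k2a = k2 / (1 + BP_ND),

is simulated by exact exponential convolution on a 1-s grid (trapezoid
recursion, unconditionally stable) and frame-averaged. Fitting uses the
basis-function form: 100 log-spaced k2a values in [0.001, 1] /min, weighted
linear least squares per basis (weights proportional to frame duration),
best-residual selection, then a bounded 1-D refinement of k2a between the
neighbouring grid points. The reference curve is reconstructed from its
frame averages by monotone cubic interpolation through (0, 0) and the
frame midpoints, with three fixed-point corrections so the interpolant's
frame averages reproduce the measured values; this keeps the noise-free
round trip below 0.01% error in BP_ND. Fits that select a grid boundary
are flagged unconverged. BP_ND, R1 and k2 are invariant to rescaling both
TACs, so the activity calibration is arbitrary.

The reference input for simulation is a bi-exponential
A(e^(-0.04 t) - e^(-0.6 t)) (rates per minute) peaking near 5 min — a
conventional bolus shape, not a fitted tracer model. Whole-striatum BP_ND
is the volume-weighted mean of caudate (0.40), putamen (0.45) and
accumbens (0.15) fits.

## Inferential layer

* Spearman rho via ranked Pearson (average ranks for ties), p from the t
  approximation on n - 2 df, CI by Fisher transform with variance
  1.06/(n - 3) — a standard choice; the interval construction in the
  emulated analyses is not otherwise pinned down.
* Meng-Rosenthal-Rubin z for dependent overlapping correlations, with the
  CI reported on the Fisher-z difference scale.
* One-sample/paired t-tests and one-way repeated-measures ANOVA with
  sphericity assumed (no correction), df = (k-1, (k-1)(n-1)).
* Mediation: OLS product-of-coefficients (ACME = a*b, ADE = c', total =
  a*b + c', identity exact per bootstrap draw), nonparametric case
  resampling, BCa intervals (bias correction from the bootstrap
  distribution, acceleration from a closed-form leave-one-out jackknife),
  and p defined as the smallest alpha at which the BCa interval excludes
  zero (found by bisection). Default 10,000 draws; tests use 999.
* Within-subject analysis: per subject, block pRT is regressed on block
  DMN strength alone and with block load as a covariate; group inference
  is a one-sample t on the strength coefficients across subjects.
* No multiple-testing correction anywhere; all p-values are two-tailed and
  reported raw.

## The synthetic cohort

Volumes are drawn from zero-mean multivariate normals whose correlation
switches with the task condition. Within-DMN correlation at load L is
tanh(z0_s + slope_s * L + eta_b): z0_s = atanh(base_corr_dmn) plus a stable
subject offset, slope_s the subject's true load slope, eta_b a
block-specific fluctuation. Within-TPN is analogous (positive slope, no
block fluctuation); between-network correlation is constant; rest volumes
use the load-0 structure. The condition governing a volume's covariance is
the one active one haemodynamic delay (4 s = 2 volumes) earlier, matching
the lag convention of the analysis stage; covariance switching itself is
instantaneous (no convolution), which is appropriate because the emulated
pipeline operates on residual time series after task-evoked mean effects
are removed. Gaussian iid noise (sd 0.1) is added to the unit-variance
network signal.

Planted couplings are calibrated at the *sample* level so that recovery
tests measure the pipeline rather than latent re-sampling noise: subject
slopes are standardised to exactly mean_dmn_slope / sd_dmn_slope; the
Spearman correlation between caudate BP and slope is driven to exactly
rho_bp_slope by bisecting the mixing weight of a Gaussian copula; the
behavioural noise is orthogonalised against slope and BP before scaling.
Behavioural robustness is planted as
behav_slope_coupling * slope_s + direct_bp_behaviour * bp_s + noise and
enters trial generation as the subject's pRT load slope; block RT is
additionally coupled to eta_b so block-wise DMN strength genuinely
predicts block-wise performance within subject. Error and omission
probabilities rise with load and fall with a standardised ability latent
(itself the standardised robustness), at rates of a few percent per load
step; targets occur on 30% of trials (the emulated task reports no rate).

Key defaults, with reasoning:

| parameter | default | unit | why |
|---|---|---|---|
| base_corr_dmn | 0.45 | r | must clear the equicorrelation floor -1/41 at load 2 by >3 sd (see below) |
| base_corr_tpn / between | 0.25 / 0.05 | r | typical within/between task-network values |
| mean_dmn_slope | -0.10 | z/load | planted DMN load effect |
| sd_dmn_slope | 0.08 | z/load | between-subject spread; keeps measured BP-slope correlations near the planted 0.45 after estimation attenuation |
| mean_tpn_slope | +0.06 | z/load | opposite-signed TPN effect |
| bp_mean / bp_sd | 2.0 / 0.35 | BP_ND | typical caudate D2/3 agonist-tracer binding |
| rho_bp_slope | 0.45 | Spearman | the planted receptor-connectivity coupling |
| behav_slope_coupling | 0.5 | s per z | maps slope spread to a plausible -dpRT spread (~0.04 s/load) |
| behav_noise_sd | 0.060 | s | puts the measured w1-robustness Spearman at ~0.5, inside the reported interval estimate [0.20, 0.64] |
| dmn_block_jitter_sd | 0.10 | z | block-level connectivity fluctuation, same order as the load effect; centred within each load so it does not perturb condition means |
| block_strength_coupling | -0.10 | s per z | the reported within-subject strength coefficient |
| subject_base_z_sd | 0.08 | z | stable individual differences in overall connectivity; cancels in w1 but dominates session means, making the whole-session control a real contrast |
| noise_sd | 0.10 | a.u. | mild measurement noise on top of unit-variance signal |
| tac_noise_frac | 0.05 | - | frame noise sd = 5% of curve peak for a 60-s frame, variance proportional to 1/duration |

**The equicorrelation floor.** A block of 42 equicorrelated nodes cannot
have mean correlation below -1/41 = -0.024. Block targets that fall below
it are repaired to the nearest positive-definite correlation (eigenvalue
clipping + diagonal renormalisation, logged as a warning), which floors
the realised correlation near -0.024 and would bias slope recovery if it
happened often. The DMN baseline (0.45) is therefore chosen so the load-2
z distribution stays >3 sd above the floor; with the defaults, repairs are
rare tail events and group-mean slope recovery is unbiased to ~0.005.

**What the generator does not emulate.** No haemodynamic convolution or
HRF variability, no physiological/scanner noise structure (drift, motion,
spatial autocorrelation), no voxel space, no parcel-size heterogeneity, no
RT distributional skew beyond a truncated normal, no learning or fatigue
across blocks, no D2R/D3R fraction differences between regions, no PET
attenuation/scatter physics. Passing recovery tests therefore shows the
*pipeline* is correct and well calibrated under the planted model, not
that the scientific findings would replicate on real data.

## Orchestration and reproducibility

A master seed fans out to named per-stage seeds (CRC-tagged seed
sequences), so any stage can be rerun in isolation; identical config +
seed reproduce cohorts byte-for-byte on disk. The analysis report is
written as JSON plus a markdown summary embedding the same JSON payload
(lossless round trip), and `dopanet check` re-derives the core group
statistics (group w1 t-tests, headline Spearman correlations, the ACME
point estimate) from the stage tables and compares them to the report.

Problem sizes in the shipped tests and in `scripts/acceptance.py` are the
package's own choices: consensus clustering uses 200 iterations per round
(the procedure converges in 1-2 rounds on these graphs; the stochastic
partitions are already unanimous at far fewer iterations than the 1000
used historically), end-to-end recovery uses 20 master seeds with the
a-priori partition (data-driven partition recovery is established
separately and is exact under these conditions, so re-running consensus
inside every seed would only re-measure a solved subproblem), the
bootstrap uses 999 draws in tests versus the 10,000 default, and
calibration experiments use 200-500 replicates.

## Known limitations

* Per-subject w1 estimates are noisy (sd ~0.04) at the emulated session
  length; only group-level and rank-based statements are well powered.
* The equicorrelation covariance model cannot represent mean within-network
  correlations below -1/(n-1); strongly negative planted slopes saturate.
* The BCa p-value convention (smallest alpha excluding zero) is one of
  several in circulation; mediation p-values from other packages can
  differ by a factor ~2 in either direction.
* SRTM assumes a one-tissue target and a displaceable-free reference; the
  simulator generates data from the same model, so fit quality on real
  TACs (model mismatch, motion) will be worse than the round-trip numbers.
* The a-priori node labelling fixes 42 DMN / 55 TPN nodes; the emulated
  study's empirical networks had 42/53 with two nodes effectively
  unassigned, a distinction the generator does not reproduce.
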