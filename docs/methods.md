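# Methods

## Generative model

Two cortical regions ("l", "r"), each a four-population canonical
microcircuit: spiny stellate (ss, granular), superficial pyramidal (sp) and
inhibitory interneurons (ii, supragranular), deep pyramidal (dp,
infragranular).  Each population carries five states — membrane potential V
(mV) and unit-less AMPA, GABA, NMDA and leak conductances — evolving as

    dV/dt  = (1/C)[ g_L(V_L−V) + g_AMPA(V_AMPA−V) + g_GABA(V_GABA−V)
                    + g_NMDA·m(V)·(V_NMDA−V) ] + u
    dg/dt  = (Σ_k S_k σ_k − g)/τ + u          (AMPA, GABA, NMDA)
    dg_L/dt = (g_L0 − g_L)/τ_L + u

σ_k = logistic(V_k; slope, threshold) is the presynaptic firing of source
population k.  The leak channel is written with the same first-order kinetics
as the synaptic channels; since it receives no synaptic drive it relaxes to
its baseline g_L0 (the literal zero-drive form would extinguish the leak).
The exogenous input u is a Gaussian bump delivered to the spiny stellate
cells of both regions (configurable), and — following the printed form of the
state equations — also to their conductance equations
(`input_to_conductances`, on by default).

Voltage dependence of the NMDA channel (magnesium block) with the regional
blockade latent `blk`:

    α = exp(blk),   m(V) = 1.50265 / (1 + 0.33·exp(−0.06·α·V))

The modified numerator is 1.50265; the standard, unmodified function uses 1.5
(both exposed: `mg_switch` / `mg_switch_standard`, numerator configurable as
`ModelConfig.mg_numerator`).  m(V) is bounded in (0, numerator), increasing
in V; at V = 0 it is invariant to `blk`; for physiological (negative) V it
decreases with `blk` — more blockade, less tonic NMDA conductance.

All subject-specific parameters are latent with Gaussian priors and
exponential positivity transforms: `blk_{l,r}` ~ N(0, 1/64); log-scalings of
the AMPA/GABA/NMDA time constants ~ N(0, 1/64); condition (deviant vs
standard) log-modulations `b_{l,r}` of the self-inhibition gains ~ N(0,
1/16), active only for the deviant trial; a shared observation log-gain ~
N(0, 1/8).  Fixing a latent is expressed by zero prior variance.

### Fixed constants (defaults; mV, ms)

| constant | value | note |
|---|---|---|
| V_L, V_AMPA, V_GABA, V_NMDA | −70, 60, −90, 60 | satisfy V_GABA < V_L < 0 < V_AMPA ≤ V_NMDA |
| C, g_L | 8, 1 | 8 ms membrane time constant |
| τ_AMPA, τ_GABA, τ_NMDA, τ_L | 4, 16, 100, 16 | first-order channel kinetics |
| firing slope, threshold | 0.1 /mV, V_L + 30 | logistic midpoint 30 mV above rest |
| input onset, width, amplitude | 95, 16, 0.02 | see "Regime" below |
| forward / backward gain | 0.5 / 0.25 | l.sp→r.{ss,dp}; r.dp→l.{sp,ii}; no lateral coupling |

Intrinsic coupling is a fixed signed topology (ascending excitation
ss→sp→dp, interneurons driven by all excitatory populations, GABAergic
inhibition from ii plus self-inhibition on every population); magnitudes are
config entries (`intrinsic_exc`, `intrinsic_inh`).  NMDA drive mirrors the
excitatory topology scaled per target population (`nmda_weights`, default
(0.25, 0.25, 2, 0.25)): NMDA is enriched on inhibitory interneurons
(NMDA-dependent inhibition), which keeps the blockade effect graded over the
latent range of interest.

### Regime and the direction of the blockade effect

Defaults were chosen once so that (i) the drift has a stable fixed point and
a damped evoked transient, (ii) the deviant−standard difference peaks inside
the canonical 140–160 ms window (the input latency of 95 ms lumps subcortical
and earlier cortical stages that are not modelled), and (iii) the difference
waveform varies smoothly and monotonically with `blk` across ±0.6.  In this
regime — and in every stable regime of this model class we examined —
*lowering* the blockade amplifies the evoked difference, because extra tonic
NMDA conductance depolarises the circuit and increases excitatory driving
force.  A drug-like +0.42 shift therefore shrinks the difference waveform; a
disease-like −0.125 shift enlarges it.

Consequently the sensor-level amplitude *decline* seen in the disease cohort
cannot be produced by the blockade reduction alone.  The longitudinal
generator plants it on the deviance modulation instead: at follow-up, B moves
toward zero by +0.2 (`session_b_shift`), weakening deviance detection and
attenuating the windowed MMN amplitude, while the blockade latents carry the
−0.125 follow-up shift that the second-level analysis recovers.  Disease thus
affects two mechanisms in the synthetic twin — one visible at the sensor
level, one inferred at the parameter level — which is a modelling choice,
documented here, not a claim about the biology.

## Forward and observation model

Trials integrate from the condition-specific numerical equilibrium (damped
Picard iteration, tolerance 1e−13; the equilibrium is independent of the time
constants, so it is cached across Jacobian probes keyed on exact parameter
values) over 0–300 ms with fixed-step RK4 at 1 ms (step-halving agreement
< 1e−3 of the response range is enforced in the tests).  Integration aborts
with a named error if any |V| exceeds 200 mV.

Observation: depolarisations (V minus the equilibrium) of the superficial
and deep pyramidal populations are projected through a gain matrix onto 8
sensor modes and Hanning-tapered over the epoch.  Anatomical lead fields are
out of scope; the default gain is a fixed pseudo-random pyramidal topography
(weights 1 and 0.5 for sp and dp) shared across hemispheres up to the single
log-gain latent, standing in for symmetric equivalent-current dipoles.  The
taper is applied to model predictions and (by construction of the generator)
to the data, so residuals live in the same windowed space.  Multichannel data
can be reduced to modes by SVD of the data matrix (`reduce_to_modes`), with
captured-variance fractions reported.

## Inversion (variational Laplace)

Gauss–Newton ascent on the latent vector with central finite-difference
Jacobians (step 1e−3 — the forward model is an ODE integral, so no analytic
gradients), Levenberg–Marquardt damping (factor ×8 on rejection, ×0.25 on
acceptance), and one noise log-precision per sensor mode updated in closed
form between parameter steps under a diffuse Gamma(1, 1e−6) hyperprior.
Candidate steps are scored by the full free energy (accuracy with the
expected-curvature correction, minus KL to the prior, plus hyperprior terms)
and rejected if F would decrease, so the accepted-step F trace is
non-decreasing by construction.  Convergence: ΔF < 0.01 nats on 3 consecutive
accepted steps, at most 64 iterations (32 in the cohort experiments);
exhausting the damping schedule counts as convergence at a local optimum,
exhausting iterations flags the result unconverged.  On linear observation
models with fixed noise the fixed point is exact conjugate regression and F
the exact log evidence (tested to 1e−6 on random instances).

Identifiability: the blockade and the observation gain trade off (both scale
response amplitude, the blockade nonlinearly), so recovery experiments fix
the gain at its true value via the variance mask; experiment configurations
estimate `blk`, the time-constant scalings and B.

## Second level (PEB, BMR, BMA)

Each subject/session posterior over the selected fields, minus its prior,
gives a Gaussian likelihood summary (precision floor 1e−8 guards numerical
indefiniteness).  A GLM over rows θ_i = (x_i ⊗ I)β + ε with β ~ N(0, 1/16 I)
and between-row covariance Σ_b = exp(γ)/16 · I (γ empirical-Bayes-optimised
by bounded scalar search on F) yields closed-form Gaussian inference on β and
a second-level free energy, exact for this linear-Gaussian form (verified
against a dense joint-Gaussian oracle).  Hypotheses that restrict which
fields carry a (non-constant) regressor effect are re-scored by Bayesian
model reduction — prior switching without refitting, with switched-off prior
variances set to 1e−8 — and compared by softmax of free energies; Bayesian
model averaging moment-matches the probability-weighted posterior mixture
over all parameter-set combinations.  Per-subject empirical-Bayes
re-estimates under the group model are reported with their posterior
variances (the inverse variance is the "precision" weight used for plotting).
A parameter's "posterior probability" is the probability that the effect
shares the sign of its posterior mean; the >0.95 convention is a reporting
flag, not a decision rule inside estimation.  Planted effects act on both
regions, so recovery is scored on the mean of the left/right blockade
effects (a linear contrast of the β posterior).

Designs: crossover — constant + drug session (0/1); severity — constant +
mean-centred baseline MMSE, baseline rows only; progression — constant +
session (0/1) + scan interval, the interval column being 0 at baseline and
the follow-up years centred and standardised *within the follow-up rows*
(centring over all rows would make it nearly collinear with the session
column and arbitrarily split a pure session effect between the two).

## Synthetic cohorts

Crossover: n = 19 (two sessions, placebo/drug), drug adds +0.42 to both
blockade latents.  Longitudinal: n = 42 at baseline, the first 30 return at
0.8–2.2 years (uniform); MMSE ~ N(24.9, 3.61²) truncated to [10, 30];
baseline blockade = 0.06 · (MMSE − cohort mean) + N(0, 0.125²) per region;
follow-up adds −0.125 to the blockade and +0.2 to B.  Only the blockade
latents vary across subjects (sd 0.125, matching the prior width) — a
deliberate simplification of biological heterogeneity that keeps recovery
well-posed; B is fixed at −0.4 across subjects.  Sensor noise is IID Gaussian
(sd 0.05) added in windowed mode space, calibrated so a single subject's
difference waveform shows a clear 100–200 ms deflection (enforced by a
fixture test; the deviant response has max amplitude ~1.6 in these units).
Ground-truth latents are stored beside the data for exact scoring.

What the generator does *not* emulate: temporally and spatially correlated
sensor noise, per-subject lead fields and head geometry, trial-count
differences, preprocessing artefacts, non-NMDA disease effects, attrition
that is informative rather than by enrolment order, or between-subject
variability in time constants and connectivity.  Passing tests therefore
demonstrate internal consistency of the estimation machinery under the
model's own assumptions, not robustness to real MEG data.

## Sensor-level analysis

Difference waveforms (deviant − mean of repeats; the generator provides one
standard condition, repetition 5) are collapsed onto the leading spatial
component of the cohort's stacked differences, oriented so the grand-average
140–160 ms amplitude is positive — the analogue of a combined-gradiometer
MMN trace.  Statistics: windowed mean amplitude; exclusion of subjects more
than 3 scaled MADs (×1.4826) from the median at *both* sessions (a zero MAD
excludes nobody and warns); paired t with Cohen's d = mean/sd of differences;
OLS amplitude-vs-covariate with Pearson r.  All are textbook formulas
cross-checked against scipy to 1e−10; tests are two-sided, directional claims
reported via sign + two-sided p.

## Problem sizes and reproducibility

The test suite runs the model-selection criterion at n = 12 subjects × 10
seeds, the longitudinal recovery at n = 30 pairs × 20 replicates, and the
sensor suite at n = 30 × 50 replicates; the analysis drivers use the full
cohort sizes (19; 42/30).  These sizes keep the whole suite within minutes on
one CPU while leaving the statistical margins wide.  All randomness flows
from per-stage `numpy` SeedSequences derived from a single integer seed;
forward integration is deterministic, and repeated runs of an experiment
yield byte-identical reports (hash-checked in the tests).

## Known limitations

* One fixed intrinsic topology; magnitudes are configurable but not
  estimated, and only two regions with forward/backward (no lateral)
  coupling are supported.
* Finite-difference Jacobians make inversion cost linear in the number of
  free latents; the default experiments free at most 10.
* The IID noise model ignores the variance tapering introduced by windowing.
* The blockade–gain trade-off is resolved by fixing the gain in recovery
  settings rather than by richer priors.
* PEB treats rows as exchangeable given the design; crossover/longitudinal
  pairing enters only through the regressors, as in the standard approach.
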