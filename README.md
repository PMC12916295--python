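# nmda-dcm

Non-invasive inference of NMDA-receptor magnesium blockade from evoked MEG
responses, as a tested, reusable Python package.  It is aimed at computational
neuroscientists and methodologists who want a desk-scale, fully synthetic twin
of a drug/disease study built on dynamic causal modelling (DCM) of the
auditory mismatch negativity (MMN): every stage — cohort simulation,
sensor-level statistics, model inversion, second-level group inference — runs
in minutes on one CPU with no data download.

## The model

Each of two cortical regions is a conductance-based canonical microcircuit:
spiny stellate (ss), superficial pyramidal (sp), inhibitory interneuron (ii)
and deep pyramidal (dp) populations, each with a membrane potential and
AMPA/GABA/NMDA/leak conductances (Morris–Lecar-type mean-field dynamics):

    dV/dt  = (1/C) [ g_L (V_L − V) + g_AMPA (V_AMPA − V) + g_GABA (V_GABA − V)
                     + g_NMDA · m(V) · (V_NMDA − V) ] + u
    dg*/dt = (1/τ*) ( Σ_k S_k σ_k − g* ) + u

with logistic presynaptic firing σ_k, intrinsic/extrinsic coupling S_k, and a
hump-shaped thalamic input u.  The NMDA channel is voltage-gated through the
magnesium switch, modified by a regional blockade latent `blk`:

    α = exp(blk)
    m(V) = 1.50265 / (1 + 0.33 · exp(−0.06 · α · V))

Larger `blk` means the channel needs more depolarisation to conduct (the
drug-like regime); smaller `blk` opens it at lower depolarisation (the
disease-like regime).  `blk` has prior N(0, 1/64), like the log-scalings of
the channel time constants.

Predicted responses (standard = repetition 5 vs deviant, 0–300 ms, 8 sensor
modes, Hanning-windowed) are inverted by **variational Laplace**: Gauss–Newton
ascent on the free energy F (accuracy − complexity) with Levenberg–Marquardt
damping and closed-form noise-precision updates; on linear-Gaussian problems
the scheme reproduces conjugate Bayesian regression and F equals the log
evidence exactly.  Subject posteriors then enter **parametric empirical Bayes
(PEB)**: a GLM over subjects/sessions with Bayesian model reduction to score
hypotheses about *which* synaptic parameters carry a group effect, softmax
model probabilities, and Bayesian model averaging.

## Worked example

The numbered drivers under `analysis/` reproduce the full study on synthetic
cohorts (`python analysis/02_simulate_cohorts.py` writes the data first;
`data/` and `results/` are regenerated, not shipped):

```text
$ python analysis/04_crossover_drug_effect.py        # n = 19 crossover, drug shifts blk by +0.42
model comparison (softmax probabilities):
   gaba_tau  F =   -163.13  P = 0.0000
   ampa_tau  F =   -163.56  P = 0.0000
   nmda_tau  F =   -109.32  P = 0.0000
   nmda_blk  F =    343.72  P = 1.0000
        all  F =    330.96  P = 0.0000
winning model: nmda_blk
drug effect on blockade: +0.415 (P = 1.000); BMA estimate +0.415
```

The comparison asks which parameter set (GABA/AMPA/NMDA time constants, NMDA
blockade, or all) best explains the placebo–drug difference; the blockade-only
model wins with probability ~1 and the recovered effect (+0.415) matches the
planted +0.42 shift.

```text
$ python analysis/03_sensor_mmn.py                   # sensor level, longitudinal cohort
follow-up vs baseline amplitude: t = -6.85, p = 0.0000, d = -1.25
baseline amplitude vs MMSE: slope = -0.0812, r = -0.93, p = 0.0000

$ python analysis/05_disease_effects.py              # PEB on the patient cohort
severity: blockade ~ mmse: +0.0585 (P = 1.000); BMA +0.0585
progression: blockade ~ group: -0.1212 (P = 0.999); BMA -0.0661
```

The windowed (140–160 ms) MMN amplitude declines at follow-up; the PEB
analyses recover the planted MMSE gradient on the blockade (0.06 per point)
and the planted follow-up reduction (−0.125) with high posterior probability.

A CLI wraps the same stages (`nmda-dcm simulate|sensor-stats|invert|peb|run`).

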