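# Methods

This note documents the models, conventions and numerical choices behind
`stressaxis`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic data model

The generators define the study conditions under which everything downstream
is validated.

**PSC traces.** Event peak times follow a homogeneous Poisson process
(default 0.5 Hz) over the recording (default 240 s at 10 kHz, the
acquisition rate of the emulated protocol). Each event is a
difference-of-exponentials waveform
g(t) = (1 − e^(−t/τ_rise)) · e^(−t/τ_decay), peak-normalized and scaled by a
log-normal amplitude (mean 25 pA, CV 0.4; defaults chosen to be plausible
for GABAergic PSCs in these neurons, roughly 10–50 pA at rates 0.1–2 Hz —
no empirical amplitude/interval distributions are published to calibrate
against). Defaults τ_rise = 1 ms, τ_decay = 8 ms. Events superpose
linearly — the simplest physically plausible model — on a holding-current
baseline (−20 pA at −65 mV), with additive white Gaussian noise (2 pA SD).
An optional zero-phase Butterworth low-pass stands in for the acquisition
filter; at 10 kHz sampling the emulated 5 kHz filter sits at the Nyquist
limit, so it is off by default. Events are simulated positive-going;
amplitudes are reported as absolute peak−baseline differences, so polarity
is a labelling convention, not a modelling one. Ground truth records peak
times (strictly increasing) and amplitudes.

**LH profiles.** Each animal gets morning (AM) baseline draws (normal,
mean 0.8, SD 1.0 ng/ml, floored at zero) and five hourly evening (PM)
samples. With probability `surge_probability` an animal is surge-labelled
and one random PM sample is drawn from the surge law (normal, mean 25,
SD 8 ng/ml). Values are censored to the assay's reportable range
(0.16–40 ng/ml) with flags. The AM law is chosen so that the mean + 3 SD
threshold recomputes near the 3.8 ng/ml study constant; the surge law sits
far enough above threshold that label recovery is a property of the
classifier, not of luck.

**Estrous stages.** A first-order Markov chain over {D, P, E} with default
transitions D→D 0.5 / D→P 0.5, P→E 1, E→D 0.8 / E→E 0.2: mean stage runs of
~2 d diestrus, 1 d proestrus, ~1.25 d estrus, hence a ~4.25 d period and
4–5 cycles per 21-day window. Start states are drawn from the chain's
stationary distribution. A fixed repeating pattern (e.g. "DDPE") is also
accepted as the transition law, because a deterministic multi-day cycle is
not expressible as a first-order chain and is the natural oracle for the
cycle-scoring rules.

**Corticosterone.** log10(cort) = baseline (1.0 → 10 ng/ml) + dam effect +
mouse effect + group-specific post-paradigm shift + residual, all Gaussian
on the log scale (SDs 0.10/0.10/0.15). Controls get a +0.5 diurnal shift
(~3.2×); stressed groups add log10(3), emulating the 2–3-fold post-stress
elevation over controls. Values are back-transformed and censored to
3.9–1,000 ng/ml. Because the shift is additive on the log scale, the
geometric-mean post/pre ratio recovers the programmed fold change exactly
in expectation.

**Cohort.** Dams are assigned to the four groups (STD/LBN × CON/ALPS);
litter sizes are uniform on 5–8 (the normalization window); every mouse
inherits its dam's random effect. One seed per generator call drives all
randomness; no global state is touched, so equal seeds give bit-identical
outputs.

What the generators do **not** emulate: bursty/non-Poisson event timing,
rundown or drift within recordings, correlated noise, LH pulsatility,
assay measurement error structure, or litter-sex composition. Passing tests
therefore demonstrate correctness of the algorithms under clean, known
conditions — not performance on real recordings.

## Event detection

Detection operates on the boxcar-smoothed trace (default 9 points, the
"Box 9" convention for these recordings). The noise scale is the median
absolute deviation (×1.4826) of the smoothed first difference — robust to
the events themselves. Candidate onsets are upward threshold crossings of
the derivative at `threshold_mads` (default 4) times that scale; each peak
is the maximum of the smoothed trace within 10 ms of its onset; peaks
closer than `min_peak_separation_ms` (default 5 ms) are merged, keeping the
taller. The baseline is the median of the 10 ms window before the peak;
amplitude is |peak − baseline|.

Manual curation is replaced by two documented filters: the amplitude must
exceed `threshold_mads` × the trace noise SD (estimated from first
differences of the raw trace), and the smoothed trace must return to within
half the amplitude of baseline inside a 100 ms post-peak window unless
another candidate event intervenes (events at the trace end are kept).
These choices favour precision at the stated operating point (amplitudes
≥ 5× noise SD); recall degrades gracefully as amplitude approaches the
noise floor, and both are measured, not assumed, in the acceptance checks.

**Passive properties.** The 16 membrane-test step responses are averaged
first. Holding current is the pre-step mean; the steady-state deflection
(last quarter of the step) gives input resistance by Ohm's law; the peak
transient gives series resistance; capacitance is the transient charge
∫(I − I_ss)dt divided by the step voltage. For a single-compartment RC cell
this charge estimator returns C·R_m/(R_s+R_m) — within 2% of C at typical
values (R_s 20 MΩ, R_m 1 GΩ) and robust to biexponential transients, which
is why it is standard membrane-test practice. Deflections below 3× the
baseline noise SD raise an estimation error rather than returning garbage.

## Event metrics

The conventions are deliberately asymmetric and follow the field's wording
exactly rather than harmonizing:

* intervals are **backward** peak-to-peak differences; the first event's
  interval is unknown and excluded;
* amplitude eligibility is **inclusive** (backward interval ≥ 200 ms), and
  a first event qualifies when **strictly** more than 200 ms of recording
  precedes it;
* isolation is **strict** (> 200 ms both directions); at the recording
  edges the start/end stands in for the missing neighbour, symmetric with
  the first-event amplitude rule;
* cells with zero events contribute frequency 0 (a meaningful zero) but are
  absent from interval statistics.

Isolated-event snippets (20 ms pre, 100 ms post peak) are baseline-
subtracted, averaged per cell, then peak-normalized; normalization happens
per cell before any cross-cell averaging. The 80–20% decay time
interpolates linearly between samples around each crossing, making the
measure resolution-independent; for a pure exponential it equals τ·ln 4,
which the tests verify to 1% at 10 kHz.

## Distribution comparison

The k-sample Anderson–Darling criterion is computed from its defining
double sum in the midrank (tied-data) version; the continuous version is
available for untied data. The statistic is standardized by the exact
finite-sample null mean (k−1) and variance, and the p-value interpolates
the published critical-value surface (quadratic in the standardized
statistic against log tail probability). Beyond the largest tabulated
critical value the fitted quadratic turns around, so log p is continued
linearly with the fit's edge slope — without this, extreme statistics would
be assigned large p-values. The table covers tail probabilities 0.25–0.001;
outside it the asymptotic value is an extrapolation, and the permutation
method (criterion recomputed over random relabellings; add-one p-estimate)
is the reference for small samples.

Post hoc testing runs exactly the four design pairs (CON vs ALPS within
each rearing condition; STD vs LBN within each adult treatment) with Holm's
step-down adjustment over m = 4, monotone and capped at 1.

**Bootstrap.** The default resampling unit is the cell: events within a
cell share a neuron and are not exchangeable, so cells are drawn with
replacement within group and their events pooled ("mouse" and "event" units
are available and logged in output). Defaults: 5,000 iterations,
percentile intervals at 2.5/97.5 via linear-interpolation quantiles (stable
across iteration counts), point estimate = mean over iterations. Intervals
are reported unadjusted for multiplicity; only p-values receive Holm
adjustment. When every unit holds equally many events the pooled mean is
computed by vectorized indexing; otherwise units are concatenated per
iteration — identical results, different speed. With one event per unit,
the procedure reduces exactly to the ordinary nonparametric bootstrap
(verified by test).

A percentile bootstrap of a mean with ~30 units per group is expected to
sit slightly below nominal coverage; the acceptance band (93–97% at 95%
nominal) reflects that known behaviour.

## Scoring rules

The surge threshold is mean + 3 × **sample** SD (the population-vs-sample
choice is not documented in the field's descriptions; sample SD is chosen
and stated). The surge comparison is strictly greater-than — a PM value
exactly at threshold is not a surge. The 3.8 ng/ml constant is stored in a
versioned YAML (`assay_constants.yaml`) but table-level scoring always
recomputes the threshold from supplied AM data when at least two AM values
exist. Cycle length is measured between **first days** of successive
proestrous runs; "days between successive proestrous stages" is ambiguous
for multi-day runs, and the first-day convention is deterministic.

Effect sizes from printed summaries use t = Δmean/√(SEM₁²+SEM₂²) with
df = n₁+n₂−2, Cohen's d with pooled SD from SDᵢ = SEMᵢ√nᵢ, and contrast
t = estimate/SE. Reconstructions are validated at ±0.02 because printed
inputs are rounded to 1–2 decimals. These identities satisfy
t = d/√(1/n₁+1/n₂) exactly for equal-SEM inputs, which the tests assert.

## Pipeline

`run_pipeline` derives all stage seeds from one `SeedSequence`, so a run is
fully determined by its seed; the report echoes config, seed and version,
and CSV intermediates are byte-stable across reruns. Default problem sizes
(6 ephys mice/group × 2 cells at 120 s; 12 LH animals/group; 40 cycle
animals) keep a full run in single-digit seconds while leaving every
group-level contrast well identified; all sizes are configuration fields.
The acceptance script uses the sizes stated in its docstrings (e.g. 500
coverage datasets × 1,000 bootstrap iterations, 1,000 null simulations) as
its own choice of Monte-Carlo precision.

## Known limitations

* The detector is a documented surrogate for rig-specific custom detection
  plus manual confirmation; no claim is made that it reproduces any
  particular lab's curation.
* Asymptotic AD p-values outside the tabulated tail are extrapolations;
  use the permutation method for small samples or deep-null inference.
* The bootstrap unit for published analyses of this design is typically not
  stated; results depend on it, which is why it is configurable and echoed
  into every output.
* Mixed-model inference (LMM/GLMM families, Kenward–Roger dfs, marginal
  means) is out of scope; those analyses belong to established statistical
  packages.
* The corticosterone generator censors to the assay range but downstream
  summaries treat censored values as observed, as is conventional for
  geometric-mean fold changes when censoring is rare.
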