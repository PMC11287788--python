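# stressaxis

Analysis pipeline for studies of how early-life stress (limited bedding and
nesting, LBN) and acute adult psychosocial stress (ALPS) interact in the
neuroendocrine control of reproduction in mice. It covers the quantitative
core of such a study end to end:

* **GABAergic postsynaptic current (PSC) detection** in whole-cell
  voltage-clamp traces, with passive-property estimation (series/input
  resistance, capacitance, holding current) from membrane-test steps;
* **per-cell event metrics**: frequency, backward interevent intervals,
  eligibility-filtered amplitudes, isolated-event averaging, and the 80–20%
  decay time;
* **group-distribution comparison**: the k-sample Anderson–Darling test
  (midrank version) with Holm-adjusted post hoc pairs, plus a design-aware
  percentile bootstrap of group means and mean differences that resamples
  cells (or mice) rather than raw events;
* **endocrine scoring**: LH-surge thresholding (mean + 3 SD of proestrous
  morning LH; surge iff any PM value is strictly above), assay-range
  censoring, diestrous LH averaging, estrous-cycle metrics, and effect sizes
  (t, Cohen's *d*, contrast t-ratios) reconstructable from printed summaries;
* **synthetic data generators** for every input — Poisson-timed PSCs with
  difference-of-exponentials kinetics on a noisy holding-current baseline,
  LH profiles with optional surges censored at 40 ng/ml, Markov estrous-stage
  sequences, and log-normal corticosterone with dam/mouse random effects —
  so the whole pipeline is testable against ground truth.

## The statistics at the core

For pooled per-event values $x_{ij}$ (event $j$ of group $i$, $k$ groups,
pooled size $N$), the comparison uses the rank-based k-sample
Anderson–Darling criterion (midrank version for ties)

$$A = \frac{N-1}{N}\sum_{i=1}^{k}\frac{1}{n_i}\sum_{j}\frac{l_j}{N}\,
\frac{(N M_{ij}-n_i B_j)^2}{B_j(N-B_j)-N l_j/4},$$

standardized as $T=(A-(k-1))/\sigma_N$ with the finite-sample null variance
$\sigma_N^2$, and referred to the published critical-value surface (a
permutation p-value is available for small samples). Because events within a
cell are dependent, interval and amplitude effect sizes come from a
hierarchical percentile bootstrap: cells are resampled with replacement
within group, their events pooled, group means and the four design
differences (CON vs ALPS within rearing; STD vs LBN within adult treatment)
recorded over 5,000 iterations, and 95% intervals taken at the 2.5th/97.5th
percentiles.

## Worked example

```python
from stressaxis import TraceSpec, generate_psc_trace, detect_events, summarize_cell

spec = TraceSpec(duration_s=120.0, event_rate_hz=0.5, amplitude_mean_pa=25.0,
                 noise_sd_pa=2.0, seed=7)
trace, truth = generate_psc_trace(spec)
events = detect_events(trace)
s = summarize_cell(events, trace)
print(f"true events: {len(truth)}  detected: {len(events)}")
print(f"frequency: {s.frequency_hz:.3f} Hz")
print(f"mean interevent interval: {s.mean_interval_s:.3f} s")
print(f"mean eligible amplitude: {s.mean_amplitude_pa:.1f} pA")
print(f"80-20% decay time: {s.decay_time_80_20_ms:.2f} ms")
```

```
true events: 61  detected: 59
frequency: 0.492 Hz
mean interevent interval: 2.003 s
mean eligible amplitude: 24.1 pA
80-20% decay time: 10.38 ms
```

A 2-minute recording simulated at 0.5 Hz contains 61 events; the detector
recovers 59 of them (the two missed fall inside refractory overlaps), the
frequency estimate matches the generator rate, the mean interval is the
expected 1/rate = 2 s, amplitudes average near the 25 pA generator mean, and
the 80–20% decay of the averaged waveform reflects the 8 ms decay constant
(for a pure exponential the measure equals τ·ln 4).

Group-level comparison with the Model/Results interface:

```python
from stressaxis import GroupDistributionComparison, BootstrapSpec
# df: one row per event with columns value, cell_id, group
res = GroupDistributionComparison(df).fit(bootstrap=BootstrapSpec(n_iterations=5000, seed=1))
print(res.summary())
```

```
Group distribution comparison (k-sample Anderson-Darling)
==============================================================
Omnibus: criterion=111.5067  standardized=82.3661  p=3.372e-46

Group means (percentile bootstrap):
  STD-CON    mean=1.7284  95% CI [1.6430, 1.8247]  (units=12, events=917)
  STD-ALPS   mean=3.3217  95% CI [2.9450, 3.6729]  (units=12, events=408)
  ...
Pairwise comparisons (Holm-adjusted p; unadjusted CIs):
  STD-CON vs STD-ALPS      AD=48.3020  p=2.453e-22  p_holm=7.359e-22  diff=1.5933 [1.2082, 1.9500]
  ...
```

Here the simulated adult stress halves the PSC rate, so mean interevent
intervals in the ALPS groups are ~1.6–1.8 s longer, the stress-vs-control
pairs are clearly separated while rearing-only pairs are not, exactly the
pattern the comparison machinery is built to resolve.

The full study pipeline (simulate → detect → summarize → compare → score)
runs from the shell:

```sh
stressaxis report --seed 1 --out runs/demo
stressaxis validate
```

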