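"""Synthetic inputs for every stage of the pipeline.

Generates the four kinds of raw data the analysis consumes, each with ground
truth attached so downstream stages can be validated without any recordings:

* voltage-clamp current traces with Poisson-timed postsynaptic currents
  (PSCs) of difference-of-exponentials shape on a holding-current baseline,
* luteinizing-hormone (LH) time courses with morning baselines and optional
  evening surges, right-censored at the assay maximum,
* daily estrous-stage sequences from a Markov chain (or a fixed repeating
  pattern) over diestrus/proestrus/estrus,
* pre/post corticosterone tables for a nested cohort
  (dam -> litter -> mouse), log-normal with additive effects on the log scale.

All randomness flows from one explicit seed per call; there is no global
random state, so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .endocrine_scores import AssayRange, CORT_RANGE, censor_to_range

__all__ = [
    "TraceSpec",
    "GroundTruth",
    "GroupEffects",
    "CohortSpec",
    "GROUP_LABELS",
    "STAGES",
    "psc_template",
    "generate_psc_trace",
    "generate_lh_profiles",
    "generate_cycle_sequences",
    "build_cohort",
    "generate_cort_profiles",
    "default_cycle_transitions",
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_atf",
    "read_trace_atf",
    "write_ground_truth_csv",
]

GROUP_LABELS = ("STD-CON", "STD-ALPS", "LBN-CON", "LBN-ALPS")
STAGES = ("D", "P", "E")


class InvalidSpecError(ValueError):
    """A generator specification violates its invariants."""


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one simulated voltage-clamp recording.

    Defaults emulate a 2-4 min GABAergic PSC recording at 10 kHz from a
    neuron held at -65 mV: events at ~0.5 Hz, amplitudes log-normal around
    25 pA (amplitudes in real recordings span roughly 10-50 pA), ~1 ms rise
    and ~8 ms decay kinetics, a few pA of baseline noise.
    """

    duration_s: float = 240.0
    sample_rate_hz: float = 10_000.0
    event_rate_hz: float = 0.5
    amplitude_mean_pa: float = 25.0
    amplitude_cv: float = 0.4
    rise_tau_ms: float = 1.0
    decay_tau_ms: float = 8.0
    noise_sd_pa: float = 2.0
    baseline_pa: float = -20.0
    lowpass_hz: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise InvalidSpecError("duration_s and sample_rate_hz must be > 0")
        if self.event_rate_hz < 0:
            raise InvalidSpecError("event_rate_hz must be >= 0")
        if self.rise_tau_ms <= 0 or self.decay_tau_ms <= 0:
            raise InvalidSpecError("kinetic time constants must be > 0")
        if self.noise_sd_pa < 0:
            raise InvalidSpecError("noise_sd_pa must be >= 0")
        if self.amplitude_mean_pa <= 0 or self.amplitude_cv < 0:
            raise InvalidSpecError("amplitude law must have positive mean, cv >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True event peak times (s, strictly increasing) and amplitudes (pA)."""

    event_times_s: np.ndarray
    event_amplitudes_pa: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times_s, dtype=float)
        a = np.asarray(self.event_amplitudes_pa, dtype=float)
        if t.shape != a.shape:
            raise InvalidSpecError("times and amplitudes must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise InvalidSpecError("event times must be strictly increasing")
        object.__setattr__(self, "event_times_s", t)
        object.__setattr__(self, "event_amplitudes_pa", a)

    def __len__(self) -> int:
        return int(self.event_times_s.size)


def psc_template(
    t_s: np.ndarray, rise_tau_ms: float, decay_tau_ms: float
) -> np.ndarray:
    """Peak-normalized difference-of-exponentials PSC waveform.

    g(t) = (1 - exp(-t/tau_r)) * exp(-t/tau_d) for t >= 0, scaled so the
    peak equals 1.  The peak occurs at t* = tau_r * ln(1 + tau_d/tau_r).
    """
    tr = rise_tau_ms / 1000.0
    td = decay_tau_ms / 1000.0
    t = np.asarray(t_s, dtype=float)
    g = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / tr)) * np.exp(-np.maximum(t, 0) / td), 0.0)
    t_peak = tr * np.log1p(td / tr)
    peak = (1.0 - np.exp(-t_peak / tr)) * np.exp(-t_peak / td)
    return g / peak


def template_peak_offset_s(rise_tau_ms: float, decay_tau_ms: float) -> float:
    """Time from template onset to its peak, in seconds."""
    tr = rise_tau_ms / 1000.0
    td = decay_tau_ms / 1000.0
    return tr * np.log1p(td / tr)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_psc_trace(spec: TraceSpec):
    """Simulate one voltage-clamp trace with ground-truth PSC events.

    Event peak times follow a homogeneous Poisson process on the recording;
    overlapping events superpose linearly.  Returns ``(trace, ground_truth)``
    where ``trace`` is a :class:`~stressaxis.psc_detection.Trace`.
    """
    from .psc_detection import Trace  # local import to avoid cycle at import time

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    samples = np.full(n, spec.baseline_pa, dtype=float)
    dt = 1.0 / spec.sample_rate_hz

    # Poisson peak times via cumulative exponential waiting times.
    peak_times = []
    if spec.event_rate_hz > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / spec.event_rate_hz)
            if t >= spec.duration_s:
                break
            peak_times.append(t)
    peak_times = np.asarray(peak_times, dtype=float)

    if peak_times.size:
        mu, sigma = _lognormal_params(spec.amplitude_mean_pa, max(spec.amplitude_cv, 1e-12))
        amplitudes = rng.lognormal(mu, sigma, size=peak_times.size)
    else:
        amplitudes = np.zeros(0)

    t_off = template_peak_offset_s(spec.rise_tau_ms, spec.decay_tau_ms)
    span = int(round((t_off + 10 * spec.decay_tau_ms / 1000.0) / dt)) + 1
    local_t = np.arange(span) * dt
    kernel = psc_template(local_t, spec.rise_tau_ms, spec.decay_tau_ms)
    for tp, amp in zip(peak_times, amplitudes):
        onset = tp - t_off
        i0 = int(np.ceil(onset / dt))
        shift = i0 * dt - onset
        seg = amp * psc_template(local_t[: max(0, min(span, n - i0))] + shift,
                                 spec.rise_tau_ms, spec.decay_tau_ms)
        lo = max(i0, 0)
        samples[lo : i0 + seg.size] += seg[lo - i0 :]

    if spec.noise_sd_pa > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd_pa, size=n)

    if spec.lowpass_hz is not None and spec.lowpass_hz < spec.sample_rate_hz / 2:
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, spec.lowpass_hz, btype="low", fs=spec.sample_rate_hz, output="sos")
        samples = sosfiltfilt(sos, samples)

    trace = Trace(samples_pa=samples, sample_rate_hz=spec.sample_rate_hz, holding_mv=-65.0)
    truth = GroundTruth(event_times_s=peak_times, event_amplitudes_pa=amplitudes)
    return trace, truth


# ---------------------------------------------------------------------------
# LH profiles


def generate_lh_profiles(
    n_animals: int,
    surge_probability: float,
    am_baseline_mean: float = 0.8,
    am_baseline_sd: float = 1.0,
    surge_peak_law: tuple[float, float] = (25.0, 8.0),
    censor_max: float = 40.0,
    seed: int = 0,
    n_am_samples: int = 1,
    pm_times_h: Sequence[float] = (15.0, 16.0, 17.0, 18.0, 19.0),
    assay_min: float = 0.16,
) -> pd.DataFrame:
    """Simulate per-animal LH time courses with true surge labels.

    Morning (AM) samples are baseline draws; each surge-labelled animal gets
    one evening (PM) sample drawn from ``surge_peak_law`` (normal mean, sd),
    other PM samples are baseline.  Concentrations are censored to
    ``[assay_min, censor_max]`` and flagged.  Columns: ``animal_id``,
    ``period`` (AM/PM), ``time_h``, ``lh_ng_ml``, ``censored``, ``true_surge``.
    """
    if not 0.0 <= surge_probability <= 1.0:
        raise InvalidSpecError("surge_probability must be in [0, 1]")
    if am_baseline_mean < 0 or censor_max <= 0 or surge_peak_law[0] < 0:
        raise InvalidSpecError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    lh_range = AssayRange("LH", assay_min, censor_max)

    rows = []
    surged = rng.random(n_animals) < surge_probability
    for i in range(n_animals):
        for j in range(n_am_samples):
            v = max(rng.normal(am_baseline_mean, am_baseline_sd), 0.0)
            rows.append((i, "AM", 9.5 + j, v, bool(surged[i])))
        peak_idx = rng.integers(0, len(pm_times_h)) if surged[i] else -1
        for j, th in enumerate(pm_times_h):
            if j == peak_idx:
                v = max(rng.normal(*surge_peak_law), 0.0)
            else:
                v = max(rng.normal(am_baseline_mean, am_baseline_sd), 0.0)
            rows.append((i, "PM", th, v, bool(surged[i])))
    df = pd.DataFrame(rows, columns=["animal_id", "period", "time_h", "lh_ng_ml", "true_surge"])
    censored_vals, flags = censor_to_range(df["lh_ng_ml"].to_numpy(), lh_range)
    df["lh_ng_ml"] = censored_vals
    df["censored"] = flags
    return df[["animal_id", "period", "time_h", "lh_ng_ml", "censored", "true_surge"]]


# ---------------------------------------------------------------------------
# Estrous cycles


def default_cycle_transitions() -> pd.DataFrame:
    """Transition matrix giving ~4-5 day cycles.

    Mean stage runs: diestrus ~2 d, proestrus 1 d, estrus ~1.25 d, so the
    expected period is ~4.25 d and a 21 d window holds ~4.7 cycles.
    """
    m = pd.DataFrame(
        [[0.5, 0.5, 0.0], [0.0, 0.0, 1.0], [0.8, 0.0, 0.2]],
        index=list(STAGES),
        columns=list(STAGES),
    )
    return m


def generate_cycle_sequences(
    n_animals: int,
    n_days: int = 21,
    transition_law: pd.DataFrame | Sequence[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate daily estrous-stage sequences over {D, P, E}.

    ``transition_law`` is either a row-stochastic 3x3 matrix indexed by
    stage (first-order Markov chain) or a fixed stage pattern (e.g.
    ``"DDPE"``) repeated deterministically.  Returns long-format columns
    ``animal_id``, ``day``, ``stage``.
    """
    if transition_law is None:
        transition_law = default_cycle_transitions()

    rows = []
    if isinstance(transition_law, (str, list, tuple)):
        pattern = [str(s) for s in transition_law]
        if any(s not in STAGES for s in pattern):
            raise InvalidSpecError(f"stages must be in {STAGES}")
        for i in range(n_animals):
            seq = [pattern[d % len(pattern)] for d in range(n_days)]
            rows.extend((i, d, s) for d, s in enumerate(seq))
    else:
        m = pd.DataFrame(transition_law)
        if list(m.index) != list(STAGES) or list(m.columns) != list(STAGES):
            m = pd.DataFrame(np.asarray(transition_law, dtype=float),
                             index=list(STAGES), columns=list(STAGES))
        p = m.to_numpy(dtype=float)
        if p.shape != (3, 3) or np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0):
            raise InvalidSpecError("transition rows must be non-negative and sum to 1")
        rng = np.random.default_rng(seed)
        # start states from the chain's stationary distribution
        evals, evecs = np.linalg.eig(p.T)
        k = int(np.argmin(np.abs(evals - 1.0)))
        pi = np.real(evecs[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
        for i in range(n_animals):
            s = rng.choice(3, p=pi)
            for d in range(n_days):
                rows.append((i, d, STAGES[s]))
                s = rng.choice(3, p=p[s])
    return pd.DataFrame(rows, columns=["animal_id", "day", "stage"])


# ---------------------------------------------------------------------------
# Cohort and corticosterone


@dataclass(frozen=True)
class GroupEffects:
    """Per-group simulation effects.

    ``event_rate_hz``: PSC rate for cells of this group; ``surge_probability``:
    chance a proestrous animal mounts an LH surge; ``cort_post_log10_shift``:
    added to the post-paradigm corticosterone on the log10 scale (diurnal
    rise for controls, larger for stressed groups).
    """

    event_rate_hz: float = 0.5
    surge_probability: float = 0.9
    cort_post_log10_shift: float = 0.5


def default_group_effects() -> dict[str, GroupEffects]:
    # ALPS halves GABAergic drive (longer intervals), suppresses the LH
    # surge, and roughly triples the evening corticosterone rise seen in
    # controls; early-life treatment alone leaves all three unchanged.
    return {
        "STD-CON": GroupEffects(0.6, 0.9, 0.5),
        "STD-ALPS": GroupEffects(0.3, 0.2, 0.5 + np.log10(3.0)),
        "LBN-CON": GroupEffects(0.6, 0.9, 0.5),
        "LBN-ALPS": GroupEffects(0.3, 0.2, 0.5 + np.log10(3.0)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Nested study design: dams -> litters (5-8 pups) -> mice -> cells."""

    n_dams_per_group: int = 3
    pups_per_litter: tuple[int, int] = (5, 8)
    groups: tuple[str, ...] = GROUP_LABELS
    effects: Mapping[str, GroupEffects] = field(default_factory=default_group_effects)
    dam_sd: float = 0.10
    mouse_sd: float = 0.10
    residual_sd: float = 0.15
    cort_baseline_log10: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pups_per_litter
        if not (5 <= lo <= hi <= 8):
            raise InvalidSpecError("pups_per_litter must lie within 5-8")
        if self.n_dams_per_group < 1:
            raise InvalidSpecError("need at least one dam per group")
        for g in self.groups:
            eff = self.effects[g]
            if not 0.0 <= eff.surge_probability <= 1.0:
                raise InvalidSpecError("surge probabilities must be in [0, 1]")
            if eff.event_rate_hz < 0:
                raise InvalidSpecError("event rates must be >= 0")
        if min(self.dam_sd, self.mouse_sd, self.residual_sd) < 0:
            raise InvalidSpecError("random-effect SDs must be >= 0")


def build_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Enumerate the mice of a cohort: dam_id, mouse_id, group, litter size."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    dam_counter = 0
    for g in spec.groups:
        for _ in range(spec.n_dams_per_group):
            dam_id = f"dam{dam_counter:03d}"
            dam_counter += 1
            n_pups = int(rng.integers(spec.pups_per_litter[0], spec.pups_per_litter[1] + 1))
            for p in range(n_pups):
                rows.append((dam_id, f"{dam_id}-m{p}", g, n_pups))
    return pd.DataFrame(rows, columns=["dam_id", "mouse_id", "group", "litter_size"])


def generate_cort_profiles(spec: CohortSpec) -> pd.DataFrame:
    """Simulate pre/post serum corticosterone for every mouse in the cohort.

    log10(cort) = baseline + dam effect + mouse effect + (post ? group shift
    : 0) + residual; values are back-transformed and censored to the assay's
    reportable range (3.9-1000 ng/ml).  Columns: dam_id, mouse_id, group,
    time (pre/post), cort_ng_ml, censored.
    """
    spec.validate()
    cohort = build_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1)
    dam_eff = {d: rng.normal(0.0, spec.dam_sd) if spec.dam_sd > 0 else 0.0
               for d in cohort["dam_id"].unique()}
    rows = []
    for _, mouse in cohort.iterrows():
        m_eff = rng.normal(0.0, spec.mouse_sd) if spec.mouse_sd > 0 else 0.0
        base = spec.cort_baseline_log10 + dam_eff[mouse.dam_id] + m_eff
        shift = spec.effects[mouse.group].cort_post_log10_shift
        for time, s in (("pre", 0.0), ("post", shift)):
            noise = rng.normal(0.0, spec.residual_sd) if spec.residual_sd > 0 else 0.0
            val = 10.0 ** (base + s + noise)
            rows.append((mouse.dam_id, mouse.mouse_id, mouse.group, time, val))
    df = pd.DataFrame(rows, columns=["dam_id", "mouse_id", "group", "time", "cort_ng_ml"])
    vals, flags = censor_to_range(df["cort_ng_ml"].to_numpy(), CORT_RANGE)
    df["cort_ng_ml"] = vals
    df["censored"] = flags
    return df


# ---------------------------------------------------------------------------
# File formats


def write_trace_csv(path: str | Path, trace) -> None:
    """Two-column CSV: time_s, current_pa."""
    t = np.arange(len(trace.samples_pa)) / trace.sample_rate_hz
    pd.DataFrame({"time_s": t, "current_pa": trace.samples_pa}).to_csv(path, index=False)


def read_trace_csv(path: str | Path):
    from .psc_detection import Trace

    df = pd.read_csv(path)
    dt = float(np.median(np.diff(df["time_s"].to_numpy())))
    return Trace(samples_pa=df["current_pa"].to_numpy(float), sample_rate_hz=1.0 / dt)


def write_trace_atf(path: str | Path, trace) -> None:
    """Tab-delimited ATF-style text (header + time/current columns)."""
    t = np.arange(len(trace.samples_pa)) / trace.sample_rate_hz
    with open(path, "w") as fh:
        fh.write("ATF\t1.0\n")
        fh.write("1\t2\n")
        fh.write(f'"SampleRateHz={trace.sample_rate_hz}"\n')
        fh.write('"Time (s)"\t"Current (pA)"\n')
        for ti, yi in zip(t, trace.samples_pa):
            fh.write(f"{ti:.6f}\t{yi:.6f}\n")


def read_trace_atf(path: str | Path):
    from .psc_detection import Trace

    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise ValueError("not an ATF-style file")
    n_header = int(lines[1].split("\t")[0])
    data_lines = lines[2 + n_header + 1 :]
    arr = np.array([[float(x) for x in ln.split("\t")] for ln in data_lines if ln])
    dt = float(np.median(np.diff(arr[:, 0])))
    return Trace(samples_pa=arr[:, 1], sample_rate_hz=1.0 / dt)


def write_ground_truth_csv(path: str | Path, truth: GroundTruth) -> None:
    pd.DataFrame(
        {"time_s": truth.event_times_s, "amplitude_pa": truth.event_amplitudes_pa}
    ).to_csv(path, index=False)


def cohort_spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    d = asdict(spec)
    d["effects"] = {g: asdict(e) for g, e in spec.effects.items()}
    d["groups"] = list(spec.groups)
    d["pups_per_litter"] = list(spec.pups_per_litter)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def cohort_spec_from_yaml(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["effects"] = {g: GroupEffects(**e) for g, e in d["effects"].items()}
    d["groups"] = tuple(d["groups"])
    d["pups_per_litter"] = tuple(d["pups_per_litter"])
    return CohortSpec(**d)
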