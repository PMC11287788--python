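"""Reproductive and stress-hormone scoring rules and summary effect sizes.

Covers the study-style scoring conventions:

* LH surge threshold = mean + 3 SD of proestrous morning (0 h) LH; the
  stored study constant is 3.8 ng/ml, but the threshold is always
  recomputed from supplied AM data when available,
* surge classification: strictly greater than the threshold for ANY
  evening (PM) sample; values censored at the assay maximum count as
  exceeding any threshold below that maximum,
* assay-range censoring (LH reportable range 0.16-40 ng/ml after 1:10
  dilution; corticosterone 3.9-1,000 ng/ml), idempotent with flags,
* estrous-cycle metrics over a 21-day window: a cycle is a proestrous day
  preceded by diestrus or estrus; cycle length is measured between first
  days of successive proestrous runs,
* effect sizes reconstructable from printed summaries: Welch-style
  two-sample t from means/SEMs, pooled-SD Cohen's d, and contrast
  t-ratios (estimate / SE).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayRange",
    "SurgeRule",
    "CycleMetrics",
    "LH_RANGE",
    "CORT_RANGE",
    "DEFAULT_SURGE_RULE",
    "surge_threshold",
    "classify_surge",
    "mean_diestrus_lh",
    "censor_to_range",
    "cycle_metrics",
    "two_sample_t_from_summary",
    "cohens_d_from_summary",
    "contrast_t",
    "score_lh_table",
    "score_cycle_table",
    "load_assay_constants",
]


class ScoreError(ValueError):
    pass


@dataclass(frozen=True)
class AssayRange:
    """Reportable range of an immunoassay; values outside are censored."""

    analyte: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ScoreError("assay range requires lower < upper")


LH_RANGE = AssayRange("LH", 0.16, 40.0)
CORT_RANGE = AssayRange("corticosterone", 3.9, 1000.0)


@dataclass(frozen=True)
class SurgeRule:
    """LH-surge call: any PM value strictly above the threshold (ng/ml)."""

    threshold: float = 3.8
    sd_multiplier: float = 3.0
    strict: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ScoreError("threshold must be > 0")


DEFAULT_SURGE_RULE = SurgeRule()


@dataclass(frozen=True)
class CycleMetrics:
    n_cycles: int
    mean_cycle_length_d: float  # NaN when fewer than two proestrous runs
    pct_days: dict[str, float]  # keys D, P, E; sums to 100


def surge_threshold(am_values: Sequence[float], sd_multiplier: float = 3.0) -> float:
    """Mean + ``sd_multiplier`` x sample SD of morning LH values (ng/ml)."""
    v = np.asarray(am_values, dtype=float)
    if v.size < 2:
        raise ScoreError("need at least two AM values")
    return float(v.mean() + sd_multiplier * v.std(ddof=1))


def classify_surge(
    pm_values: Sequence[float], rule: SurgeRule = DEFAULT_SURGE_RULE
) -> tuple[bool, float]:
    """Surge call and maximum PM LH for one animal.

    Returns ``(surged, max_pm)``; surged is True iff any PM value exceeds
    the rule's threshold (strictly, by default).  Values censored at the
    assay maximum (40 ng/ml) exceed any threshold below that maximum by
    construction.
    """
    v = np.asarray(pm_values, dtype=float)
    if v.size == 0:
        raise ScoreError("no PM samples")
    mx = float(v.max())
    surged = mx > rule.threshold if rule.strict else mx >= rule.threshold
    return bool(surged), mx


def mean_diestrus_lh(end_of_paradigm: float, lights_out: float) -> float:
    """Average of the two designated diestrous PM samples."""
    for v in (end_of_paradigm, lights_out):
        if v is None or not np.isfinite(v):
            raise ScoreError("both diestrous PM samples are required")
    return (float(end_of_paradigm) + float(lights_out)) / 2.0


def censor_to_range(
    values: Sequence[float], rng: AssayRange
) -> tuple[np.ndarray, np.ndarray]:
    """Clip to the reportable range; flag clipped entries.  Idempotent."""
    v = np.asarray(values, dtype=float)
    clipped = np.clip(v, rng.lower, rng.upper)
    flags = clipped != v
    return clipped, flags


def cycle_metrics(stages: Sequence[str]) -> CycleMetrics:
    """Estrous-cycle metrics from a daily stage sequence over {D, P, E}.

    A cycle is counted on each proestrous day whose previous day was
    diestrus or estrus.  Cycle length is the day gap between first days of
    successive proestrous runs, averaged; NaN when fewer than two runs.
    """
    seq = [str(s) for s in stages]
    if len(seq) < 2:
        raise ScoreError("need at least two days")
    if any(s not in ("D", "P", "E") for s in seq):
        bad = next(s for s in seq if s not in ("D", "P", "E"))
        raise ScoreError(f"unknown stage symbol: {bad!r}")

    n_cycles = sum(
        1 for i in range(1, len(seq)) if seq[i] == "P" and seq[i - 1] in ("D", "E")
    )
    run_starts = [
        i for i in range(len(seq)) if seq[i] == "P" and (i == 0 or seq[i - 1] != "P")
    ]
    if len(run_starts) >= 2:
        mean_len = float(np.mean(np.diff(run_starts)))
    else:
        mean_len = float("nan")
    n = len(seq)
    pct = {s: 100.0 * seq.count(s) / n for s in ("D", "P", "E")}
    return CycleMetrics(n_cycles=n_cycles, mean_cycle_length_d=mean_len, pct_days=pct)


# ---------------------------------------------------------------------------
# Summary-statistic effect sizes


def _check_summary(sem1: float, n1: int, sem2: float, n2: int) -> None:
    if n1 < 2 or n2 < 2:
        raise ScoreError("need n >= 2 per group")
    if sem1 <= 0 or sem2 <= 0:
        raise ScoreError("SEMs must be > 0")


def two_sample_t_from_summary(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> tuple[float, int]:
    """Two-sample t from printed means and SEMs.

    t = (mean1 - mean2) / sqrt(sem1^2 + sem2^2), df = n1 + n2 - 2.
    """
    _check_summary(sem1, n1, sem2, n2)
    t = (mean1 - mean2) / np.sqrt(sem1**2 + sem2**2)
    return float(t), n1 + n2 - 2


def cohens_d_from_summary(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> float:
    """Pooled-SD Cohen's d from printed means and SEMs (SD_i = SEM_i*sqrt(n_i))."""
    _check_summary(sem1, n1, sem2, n2)
    sd1 = sem1 * np.sqrt(n1)
    sd2 = sem2 * np.sqrt(n2)
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return float((mean1 - mean2) / pooled)


def contrast_t(estimate: float, se: float) -> float:
    """t-ratio of a model contrast: estimate / SE."""
    if se <= 0:
        raise ScoreError("SE must be > 0")
    return float(estimate / se)


# ---------------------------------------------------------------------------
# Table-level scoring


def load_assay_constants() -> dict:
    """Load the versioned assay constants (surge rule, reportable ranges)."""
    from importlib.resources import files

    import yaml

    with files(__package__).joinpath("assay_constants.yaml").open() as fh:
        return yaml.safe_load(fh)


def score_lh_table(
    lh: pd.DataFrame,
    rule: SurgeRule | None = None,
    recompute_threshold: bool = True,
) -> pd.DataFrame:
    """Per-animal surge scores from a long LH table.

    Expects columns ``animal_id``, ``period`` (AM/PM), ``lh_ng_ml``.  When
    ``recompute_threshold`` and AM samples are present, the threshold is
    rebuilt as mean + 3 SD of the AM values; otherwise the rule's stored
    threshold applies.
    """
    rule = rule or DEFAULT_SURGE_RULE
    am = lh.loc[lh["period"] == "AM", "lh_ng_ml"].to_numpy(float)
    if recompute_threshold and am.size >= 2:
        rule = SurgeRule(
            threshold=surge_threshold(am, rule.sd_multiplier),
            sd_multiplier=rule.sd_multiplier,
            strict=rule.strict,
        )
    rows = []
    for animal, sub in lh.groupby("animal_id", sort=False):
        pm = sub.loc[sub["period"] == "PM", "lh_ng_ml"].to_numpy(float)
        surged, mx = classify_surge(pm, rule)
        rows.append((animal, surged, mx, rule.threshold))
    return pd.DataFrame(rows, columns=["animal_id", "surged", "max_pm_lh", "threshold"])


def score_cycle_table(stages: pd.DataFrame) -> pd.DataFrame:
    """Per-animal cycle metrics from a long stage table (animal_id, day, stage)."""
    rows = []
    for animal, sub in stages.sort_values("day").groupby("animal_id", sort=False):
        m = cycle_metrics(sub["stage"].tolist())
        rows.append(
            (animal, m.n_cycles, m.mean_cycle_length_d,
             m.pct_days["D"], m.pct_days["P"], m.pct_days["E"])
        )
    return pd.DataFrame(
        rows, columns=["animal_id", "n_cycles", "mean_cycle_length_d", "pct_d", "pct_p", "pct_e"]
    )
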