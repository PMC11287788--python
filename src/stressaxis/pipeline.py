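"""End-to-end synthetic study: simulate -> detect -> summarize -> compare -> score.

`run_pipeline` drives the whole analysis on a simulated cohort with the
study's nesting (dam -> litter -> mouse -> cell), writes tidy CSV
intermediates plus a JSON report, and is deterministic given its seed.
`validate_printed_examples` recomputes a set of worked effect-size numbers
from printed summary inputs and reports pass/fail at a +/-0.02 tolerance
(printed inputs are rounded to 1-2 decimals).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .endocrine_scores import (
    SurgeRule,
    cohens_d_from_summary,
    contrast_t,
    score_cycle_table,
    score_lh_table,
    surge_threshold,
    two_sample_t_from_summary,
)
from .event_metrics import MetricConfig, summarize_cell
from .psc_detection import DetectionConfig, detect_events, events_to_frame
from .resampling_stats import BootstrapSpec, GroupDistributionComparison
from .synthetic_data import (
    CohortSpec,
    TraceSpec,
    build_cohort,
    generate_cort_profiles,
    generate_cycle_sequences,
    generate_lh_profiles,
    generate_psc_trace,
)

log = logging.getLogger("stressaxis.pipeline")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_printed_examples"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; the seed feeds every stage."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    bootstrap: BootstrapSpec = field(default_factory=lambda: BootstrapSpec(n_iterations=1000))
    surge_rule: SurgeRule = field(default_factory=SurgeRule)
    ephys_mice_per_group: int = 6
    cells_per_mouse: int = 2
    trace_duration_s: float = 120.0
    trace_noise_sd_pa: float = 3.0
    trace_amplitude_mean_pa: float = 30.0
    n_cycle_animals: int = 40
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .synthetic_data import GroupEffects

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "cohort" in d:
            c = d["cohort"]
            if "effects" in c:
                c["effects"] = {g: GroupEffects(**e) for g, e in c["effects"].items()}
            if "groups" in c:
                c["groups"] = tuple(c["groups"])
            if "pups_per_litter" in c:
                c["pups_per_litter"] = tuple(c["pups_per_litter"])
            d["cohort"] = CohortSpec(**c)
        for key, cls_ in (
            ("detection", DetectionConfig),
            ("metrics", MetricConfig),
            ("bootstrap", BootstrapSpec),
            ("surge_rule", SurgeRule),
        ):
            if key in d:
                d[key] = cls_(**d[key])
        return cls(**d)


@dataclass
class RunReport:
    """Stage counts, group summaries and comparison results for one run."""

    seed: int
    software_version: str
    config_echo: dict
    stage_counts: dict
    group_event_summary: list
    comparison: dict
    surge_by_group: list
    cycle_summary: dict
    cort_fold_by_group: list

    def to_json(self, path: str | Path | None = None) -> str:
        txt = json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(txt)
        return txt


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _config_echo(config: RunConfig) -> dict:
    d = asdict(config)
    d["cohort"]["effects"] = {g: asdict(e) for g, e in config.cohort.effects.items()}
    return d


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full synthetic study; deterministic given ``config.seed``."""
    config.cohort.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(4)]
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: cohort ---------------------------------------------------
    cohort = build_cohort(
        CohortSpec(**{**asdict(config.cohort), "effects": config.cohort.effects,
                      "seed": seeds[0] % 2**31})
    )
    log.info("cohort: %d mice, %d dams", len(cohort), cohort["dam_id"].nunique())

    # --- stage 2: ephys simulate + detect + summarize ----------------------
    rows = []
    cell_rows = []
    trace_seed = seeds[1] % 2**31
    cell_counter = 0
    for g in config.cohort.groups:
        eff = config.cohort.effects[g]
        mice = cohort.loc[cohort["group"] == g].head(config.ephys_mice_per_group)
        for _, mouse in mice.iterrows():
            for c in range(config.cells_per_mouse):
                spec = TraceSpec(
                    duration_s=config.trace_duration_s,
                    event_rate_hz=eff.event_rate_hz,
                    amplitude_mean_pa=config.trace_amplitude_mean_pa,
                    noise_sd_pa=config.trace_noise_sd_pa,
                    seed=trace_seed + cell_counter,
                )
                cell_id = f"{mouse.mouse_id}-c{c}"
                cell_counter += 1
                trace, _truth = generate_psc_trace(spec)
                events = detect_events(trace, config.detection)
                summary = summarize_cell(events, trace, config.metrics)
                cell_rows.append(
                    (cell_id, mouse.mouse_id, mouse.dam_id, g, summary.frequency_hz,
                     summary.mean_interval_s, summary.mean_amplitude_pa,
                     summary.decay_time_80_20_ms, summary.n_events)
                )
                ev = events_to_frame(events)
                ev["interval_s"] = np.concatenate(([np.nan], summary.intervals_s)) \
                    if len(events) else np.zeros(0)
                ev["cell_id"] = cell_id
                ev["mouse_id"] = mouse.mouse_id
                ev["dam_id"] = mouse.dam_id
                ev["group"] = g
                rows.append(ev)
    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "mouse_id", "dam_id", "group", "frequency_hz",
                 "mean_interval_s", "mean_amplitude_pa", "decay_ms", "n_events"],
    )
    events_df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    n_events = int(events_df.shape[0])
    log.info("ephys: %d cells, %d events", len(cells), n_events)

    # --- stage 3: group comparison of interevent intervals -----------------
    pooled = events_df.dropna(subset=["interval_s"]).rename(columns={"interval_s": "value"})
    model = GroupDistributionComparison(
        pooled[["value", "cell_id", "mouse_id", "dam_id", "group"]]
    )
    results = model.fit(
        bootstrap=BootstrapSpec(
            n_iterations=config.bootstrap.n_iterations,
            lower_percentile=config.bootstrap.lower_percentile,
            upper_percentile=config.bootstrap.upper_percentile,
            resample_unit=config.bootstrap.resample_unit,
            seed=seeds[2] % 2**31,
        )
    )
    comparison = {
        "omnibus": {
            "criterion": results.omnibus.criterion,
            "standardized": results.omnibus.standardized,
            "pvalue": results.omnibus.pvalue,
        },
        "pairwise": results.to_frame().to_dict(orient="records"),
        "group_means": results.bootstrap.group_stats.to_dict(orient="records"),
    }

    # --- stage 4: LH surge scoring -----------------------------------------
    surge_rows = []
    lh_tables = []
    for i, g in enumerate(config.cohort.groups):
        eff = config.cohort.effects[g]
        lh = generate_lh_profiles(
            n_animals=12,
            surge_probability=eff.surge_probability,
            seed=(seeds[3] + i) % 2**31,
        )
        lh["animal_id"] = [f"{g}-a{j}" for j in lh["animal_id"]]
        lh["group"] = g
        scores = score_lh_table(lh, config.surge_rule)
        surge_rows.append(
            {"group": g, "n": int(scores.shape[0]),
             "surge_proportion": float(scores["surged"].mean()),
             "threshold": float(scores["threshold"].iloc[0])}
        )
        lh_tables.append(lh)
    lh_df = pd.concat(lh_tables, ignore_index=True)

    # --- stage 5: estrous cycles -------------------------------------------
    stages = generate_cycle_sequences(config.n_cycle_animals, seed=(seeds[3] + 101) % 2**31)
    cycles = score_cycle_table(stages)
    cycle_summary = {
        "mean_n_cycles": float(cycles["n_cycles"].mean()),
        "mean_cycle_length_d": float(cycles["mean_cycle_length_d"].mean()),
        "pct_days": {
            "D": float(cycles["pct_d"].mean()),
            "P": float(cycles["pct_p"].mean()),
            "E": float(cycles["pct_e"].mean()),
        },
    }

    # --- stage 6: corticosterone -------------------------------------------
    cort = generate_cort_profiles(
        CohortSpec(**{**asdict(config.cohort), "effects": config.cohort.effects,
                      "seed": seeds[0] % 2**31})
    )
    folds = []
    for g, sub in cort.groupby("group", sort=False):
        wide = sub.pivot_table(index="mouse_id", columns="time", values="cort_ng_ml")
        ratio = float(np.exp(np.mean(np.log(wide["post"] / wide["pre"]))))
        folds.append({"group": g, "geometric_fold_change": ratio, "n_mice": int(wide.shape[0])})

    report = RunReport(
        seed=config.seed,
        software_version=__version__,
        config_echo=_config_echo(config),
        stage_counts={
            "mice": int(len(cohort)),
            "cells": int(len(cells)),
            "events_detected": n_events,
            "events_summarized": n_events,
            "intervals_compared": int(pooled.shape[0]),
            "lh_animals": int(lh_df["animal_id"].nunique()),
            "cycle_animals": int(config.n_cycle_animals),
            "cort_mice": int(cort["mouse_id"].nunique()),
        },
        group_event_summary=cells.groupby("group", sort=False)
        .agg(n_cells=("cell_id", "count"), mean_frequency_hz=("frequency_hz", "mean"),
             mean_interval_s=("mean_interval_s", "mean"),
             mean_amplitude_pa=("mean_amplitude_pa", "mean"))
        .reset_index()
        .to_dict(orient="records"),
        comparison=comparison,
        surge_by_group=surge_rows,
        cycle_summary=cycle_summary,
        cort_fold_by_group=folds,
    )

    if out is not None:
        cells.to_csv(out / "cell_summaries.csv", index=False)
        if not events_df.empty:
            events_df.to_csv(out / "events.csv", index=False)
        results.to_frame().to_csv(out / "comparison_pairs.csv", index=False)
        lh_df.to_csv(out / "lh_profiles.csv", index=False)
        stages.to_csv(out / "cycle_stages.csv", index=False)
        cycles.to_csv(out / "cycle_metrics.csv", index=False)
        cort.to_csv(out / "cort_profiles.csv", index=False)
        report.to_json(out / "report.json")
        log.info("wrote outputs to %s", out)
    return report


# ---------------------------------------------------------------------------
# Printed worked examples


def validate_printed_examples(tolerance: float = 0.02) -> pd.DataFrame:
    """Recompute worked effect-size numbers from printed summary inputs.

    Inputs are published group means/SEMs/ns and contrast estimates/SEs
    (rounded in print, hence the +/-0.02 tolerance).  Returns a table with
    one row per check: name, computed, expected, tolerance, passed.
    """
    checks = []

    # Litter-average pup mass before treatment: 2.8 +/- 0.06 g (25 litters)
    # vs 2.9 +/- 0.06 g (24 litters).
    t, df = two_sample_t_from_summary(2.8, 0.06, 25, 2.9, 0.06, 24)
    checks.append(("pretreatment_litter_mass_t", t, -1.18))
    checks.append(("pretreatment_litter_mass_df", float(df), 47.0))
    d = cohens_d_from_summary(2.8, 0.06, 25, 2.9, 0.06, 24)
    checks.append(("pretreatment_litter_mass_cohens_d", d, -0.34))

    # Model contrast t-ratios: estimate / SE.
    checks.append(("uterine_mass_stage_contrast_t", contrast_t(-71.38, 2.981), -23.95))
    checks.append(("testes_mass_rearing_contrast_t", contrast_t(15.52, 3.565), 4.35))
    checks.append(("body_mass_change_stress_contrast_t", contrast_t(3.66, 0.229), 16.00))

    # Surge threshold arithmetic: AM LH mean 0.8, sample SD 1.0 -> 3.8 ng/ml.
    am = [0.8 - np.sqrt(2) / 2, 0.8 + np.sqrt(2) / 2]
    checks.append(("lh_surge_threshold_ng_ml", surge_threshold(am), 3.8))

    rows = [
        (name, computed, expected, tolerance, abs(computed - expected) <= tolerance)
        for name, computed, expected in checks
    ]
    return pd.DataFrame(rows, columns=["check", "computed", "expected", "tolerance", "passed"])
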