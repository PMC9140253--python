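"""End-to-end orchestration of the behavioural analysis.

ingest/simulate -> completeness filter -> TDT20 + mean curves ->
fish-level bootstrap of the SRH parameters per group x time ->
between-time parameter deltas -> mixed ANOVA + per-group RM ANOVAs +
pairwise contrasts -> structured report (JSON + tidy CSV tables +
optional figures).  Every stage is seeded explicitly; rerunning with the
same config reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import (MixedAnovaResult, make_tdt20_table, mixed_anova,
                    pairwise_times, rm_anova_per_group)
from .config import GROUPS, TEST_TIMES, load_defaults
from .habituation import mean_curve
from .motion import MotionLimits, generate_profile, profile_metrics
from .resample import bootstrap_fits, parameter_deltas
from .synth import (CohortConfig, default_generative_params,
                    read_tracking_table, simulate_cohort)

__all__ = ["RunConfig", "RunReport", "filter_complete", "run_pipeline",
           "save_report"]


class PipelineStageError(RuntimeError):
    """An analysis stage failed; carries the stage and offending cell."""

    def __init__(self, stage: str, detail: str, cell=None):
        self.stage, self.cell = stage, cell
        at = f" at cell {cell}" if cell else ""
        super().__init__(f"stage {stage!r}{at}: {detail}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run; exactly one input source."""

    tracking_file: str | None = None
    simulation: CohortConfig | None = None
    n_boot: int = 500
    bootstrap_seed: int = 1234
    pairwise_correction: str = "bonferroni"
    motion_limits: MotionLimits | None = None
    make_figures: bool = False
    delta_times: tuple = ("baseline", "5min", "24h")

    def __post_init__(self):
        if (self.tracking_file is None) == (self.simulation is None):
            raise ValueError("exactly one input source required: "
                             "tracking_file or simulation")


@dataclass
class RunReport:
    cohort_summary: dict
    exclusions: list
    tdt20_table: pd.DataFrame
    curves: dict                      # (group, time) -> HabituationCurve
    bootstrap_results: dict           # (group, time) -> BootstrapResult
    bootstrap_summary: pd.DataFrame
    deltas: pd.DataFrame
    mixed_anova: MixedAnovaResult
    rm_anovas: dict                   # group -> MixedAnovaResult
    pairwise: dict                    # group -> PairwiseTable
    kinematics: dict | None
    provenance: dict


def filter_complete(traces, required_times=TEST_TIMES):
    """Keep only fish with a trace at every required test time.

    Fish carrying an ``inspection_pass`` attribute set falsy at any time
    (the visual-inspection criterion applied before tracking) are excluded
    too.  Returns ``(retained_traces, exclusion_log)``; the log lists each
    dropped fish with its missing times.
    """
    traces = list(traces)
    by_fish: dict[str, list] = {}
    for t in traces:
        by_fish.setdefault(t.fish_id, []).append(t)
    retained, exclusions = [], []
    required = set(required_times)
    for fish_id, fish_traces in by_fish.items():
        times = {t.test_time for t in fish_traces}
        missing = sorted(required - times, key=list(required_times).index)
        failed = [t for t in fish_traces
                  if not getattr(t, "inspection_pass", True)]
        if missing or failed:
            reason = {}
            if missing:
                reason["missing_times"] = missing
            if failed:
                reason["failed_inspection"] = sorted(t.test_time for t in failed)
            exclusions.append({"fish_id": fish_id, **reason})
        else:
            retained.extend(fish_traces)
    return retained, exclusions


def _bootstrap_summary_frame(results) -> pd.DataFrame:
    rows = []
    for (group, tt), r in results.items():
        for p in ("amplitude", "decay_constant", "offset"):
            rows.append((group, tt, p, r.means[p], r.ses[p], r.n_boot,
                         r.n_capped))
    return pd.DataFrame(rows, columns=["group", "test_time", "parameter",
                                       "mean", "se", "n_boot", "n_capped"])


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and return the structured report."""
    # --- ingest -----------------------------------------------------------
    try:
        if config.simulation is not None:
            traces = simulate_cohort(config.simulation)
            source = {"kind": "simulation", "seed": config.simulation.seed}
        else:
            traces = read_tracking_table(config.tracking_file)
            source = {"kind": "tracking_file", "path": str(config.tracking_file)}
    except Exception as e:  # noqa: BLE001 - annotate with stage
        raise PipelineStageError("ingest", str(e)) from e

    # --- inclusion criteria ----------------------------------------------
    times = tuple(dict.fromkeys(t.test_time for t in traces))
    time_order = [t for t in TEST_TIMES if t in times] or list(times)
    retained, exclusions = filter_complete(traces, required_times=time_order)
    if not retained:
        raise PipelineStageError("filter", "no fish passed the completeness filter")
    groups = tuple(dict.fromkeys(t.group for t in retained))

    cells = {(g, tt): [t for t in retained if t.group == g and t.test_time == tt]
             for g in groups for tt in time_order}

    # --- per-cell summaries ----------------------------------------------
    tdt = make_tdt20_table(retained)
    curves = {}
    for cell, cell_traces in cells.items():
        try:
            curves[cell] = mean_curve(cell_traces)
        except Exception as e:
            raise PipelineStageError("mean_curve", str(e), cell) from e

    # --- bootstrap --------------------------------------------------------
    boot = {}
    for cell, cell_traces in cells.items():
        try:
            # same sub-seed across times within a group -> paired replicates
            cell_seed = config.bootstrap_seed + 1009 * groups.index(cell[0])
            boot[cell] = bootstrap_fits(cell_traces, n_boot=config.n_boot,
                                        seed=cell_seed)
        except Exception as e:
            raise PipelineStageError("bootstrap", str(e), cell) from e

    delta_rows = []
    delta_times = [t for t in config.delta_times if t in time_order]
    for g in groups:
        per_time = {tt: boot[(g, tt)] for tt in time_order}
        if len(delta_times) >= 2:
            for d in parameter_deltas(per_time,
                                      comparisons=[(delta_times[i], delta_times[j])
                                                   for i in range(len(delta_times))
                                                   for j in range(i + 1, len(delta_times))]):
                delta_rows.append((g, d.parameter, d.from_time, d.to_time,
                                   d.mean_change, d.se_change, d.paired))
    deltas = pd.DataFrame(delta_rows, columns=["group", "parameter", "from_time",
                                               "to_time", "mean_change",
                                               "se_change", "paired"])

    # --- ANOVA stack ------------------------------------------------------
    try:
        anova = mixed_anova(tdt, time_order=time_order)
    except Exception as e:
        raise PipelineStageError("mixed_anova", str(e)) from e
    rm, pw = {}, {}
    for g in groups:
        sub = tdt[tdt["group"] == g]
        try:
            rm[g] = rm_anova_per_group(sub, time_order=time_order)
            pw[g] = pairwise_times(sub, correction=config.pairwise_correction,
                                   time_order=time_order)
        except Exception as e:
            raise PipelineStageError("rm_anova", str(e), (g,)) from e

    # --- optional kinematics report --------------------------------------
    kinematics = None
    if config.motion_limits is not None:
        try:
            metrics = profile_metrics(generate_profile(config.motion_limits))
            kinematics = {k: getattr(metrics, k) for k in
                          ("duration_ms", "travel_length_mm", "peak_velocity",
                           "peak_acceleration", "peak_deceleration",
                           "peak_deceleration_g")}
        except Exception as e:
            raise PipelineStageError("kinematics", str(e)) from e

    n_fish_by_group = {g: tdt[tdt["group"] == g]["fish_id"].nunique()
                       for g in groups}
    provenance = {
        "package_version": __version__,
        "source": source,
        "n_boot": config.n_boot,
        "bootstrap_seed": config.bootstrap_seed,
        "pairwise_correction": config.pairwise_correction,
        "config_hash": hashlib.sha256(
            repr(sorted(source.items())).encode()
            + repr((config.n_boot, config.bootstrap_seed,
                    config.pairwise_correction)).encode()).hexdigest()[:16],
    }
    return RunReport(
        cohort_summary={"groups": list(groups), "test_times": time_order,
                        "n_fish_by_group": n_fish_by_group,
                        "n_excluded": len(exclusions)},
        exclusions=exclusions, tdt20_table=tdt, curves=curves,
        bootstrap_results=boot, bootstrap_summary=_bootstrap_summary_frame(boot),
        deltas=deltas, mixed_anova=anova, rm_anovas=rm, pairwise=pw,
        kinematics=kinematics, provenance=provenance)


# ---------------------------------------------------------------------------
# report serialisation


def _effect_dict(e):
    return {"F": e.F, "df_num": e.df_num, "df_den": e.df_den, "p_raw": e.p_raw,
            "gg_epsilon": e.gg_epsilon, "df_num_gg": e.df_num_gg,
            "df_den_gg": e.df_den_gg, "p_gg": e.p_gg, "ss": e.ss}


def _anova_dict(a: MixedAnovaResult) -> dict:
    return {"effects": {k: _effect_dict(v) for k, v in a.effects.items()},
            "gg_epsilon": a.gg_epsilon, "n_subjects": a.n_subjects,
            "ss_table": a.ss_table,
            "marginal_means": a.marginal_means.to_dict(orient="records")}


def report_to_dict(report: RunReport) -> dict:
    return {
        "cohort_summary": report.cohort_summary,
        "exclusions": report.exclusions,
        "bootstrap_summary": report.bootstrap_summary.to_dict(orient="records"),
        "parameter_deltas": report.deltas.to_dict(orient="records"),
        "mixed_anova": _anova_dict(report.mixed_anova),
        "rm_anovas": {g: _anova_dict(a) for g, a in report.rm_anovas.items()},
        "pairwise": {g: p.frame.to_dict(orient="records")
                     for g, p in report.pairwise.items()},
        "kinematics": report.kinematics,
        "provenance": report.provenance,
    }


def save_report(report: RunReport, out_dir, make_figures: bool = False) -> Path:
    """Write report.json plus tidy CSV tables (and optional figures)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, default=float)
    report.tdt20_table.to_csv(out / "tdt20.csv", index=False)
    report.bootstrap_summary.to_csv(out / "bootstrap_summary.csv", index=False)
    report.deltas.to_csv(out / "parameter_deltas.csv", index=False)
    for g, p in report.pairwise.items():
        p.frame.to_csv(out / f"pairwise_{g}.csv", index=False)
    if make_figures:
        _write_figures(report, out)
    return out / "report.json"


def _write_figures(report: RunReport, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    times = report.cohort_summary["test_times"]
    groups = report.cohort_summary["groups"]
    # per-stimulus mean +/- SE curves per test time
    fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharey=True)
    for ax, tt in zip(axes.ravel(), times):
        for g in groups:
            c = report.curves[(g, tt)]
            x = np.arange(1, 21)
            ax.errorbar(x, c.mean_distance, yerr=c.se_distance, label=g,
                        capsize=2)
        ax.set_title(tt); ax.set_xlabel("stimulus")
    axes[0, 0].set_ylabel("distance (mm)")
    axes[0, 0].legend()
    fig.tight_layout(); fig.savefig(out / "habituation_curves.png", dpi=120)
    plt.close(fig)

    # TDT20 bars and SRH parameter bars
    mm = report.mixed_anova.marginal_means
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.38
    for i, g in enumerate(groups):
        sub = mm[mm["group"] == g].set_index("test_time").loc[times]
        ax.bar(np.arange(len(times)) + i * width, sub["mean"], width,
               yerr=sub["se"], label=g, capsize=2)
    ax.set_xticks(np.arange(len(times)) + width / 2, times)
    ax.set_ylabel("mean TDT20 (mm)"); ax.legend()
    fig.tight_layout(); fig.savefig(out / "tdt20_bars.png", dpi=120)
    plt.close(fig)

    bs = report.bootstrap_summary
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, p in zip(axes, ("amplitude", "decay_constant", "offset")):
        for i, g in enumerate(groups):
            sub = bs[(bs["group"] == g) & (bs["parameter"] == p)]
            sub = sub.set_index("test_time").loc[times]
            ax.bar(np.arange(len(times)) + i * width, sub["mean"], width,
                   yerr=sub["se"], label=g, capsize=2)
        ax.set_title(p)
        ax.set_xticks(np.arange(len(times)) + width / 2, times, rotation=45)
    axes[0].legend()
    fig.tight_layout(); fig.savefig(out / "srh_parameters.png", dpi=120)
    plt.close(fig)
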