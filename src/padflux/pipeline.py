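"""End-to-end orchestration: simulate -> detect -> estimate -> report.

Each stage reads and writes plain-text files (tab-delimited with headers,
JSON for structured sidecars) so any stage can also be run standalone from
the CLI.  All times in output files are seconds from experiment start; all
rates in summaries are per hour.  Identical config + seed give
byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig
from .detection import PeakEvent, WindowCount, count_peaks_in_windows, detect_peaks
from .growth import AnalysisUnitMeta, GrowthRateModel, GrowthRateResults
from .media import MediaSchedule
from .synthetic import (
    SyntheticExperiment,
    UnitTruth,
    apply_multiplex_schedule,
    simulate_colony,
    synthesize_trace,
)
from .traces import PhaseTrace, read_trace, trace_filename, write_trace

logger = logging.getLogger("padflux")

__all__ = [
    "PipelineError",
    "PipelineResult",
    "simulate_experiment",
    "detect_stage",
    "estimate_stage",
    "run_pipeline",
    "write_report",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    """Everything the pipeline produced, in memory plus file paths."""

    config: ExperimentConfig
    experiment: SyntheticExperiment | None
    segments: list[PhaseTrace]
    events: list[PeakEvent]
    counts: list[WindowCount]
    results: GrowthRateResults
    relative_changes: pd.DataFrame
    output_dir: Path | None = None


def simulate_experiment(config: ExperimentConfig) -> tuple[SyntheticExperiment, list[PhaseTrace]]:
    """Stage 1: simulate colonies and raw traces, then apply the multiplex schedule.

    Returns the experiment (continuous traces + ground truth) and the
    recorded segments.  Ground-truth cell counts at recording start/end are
    evaluated at each unit's first and last recorded sample time.
    """
    if not config.units:
        raise PipelineError("no analysis units in config")
    media = config.media_schedule()
    schedule = config.multiplex_schedule()
    noise = config.noise.to_domain()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * len(config.units))
    traces: list[PhaseTrace] = []
    sims = {}
    for i, unit in enumerate(config.units):
        if unit.pads_filled == 0:
            logger.info("unit %s has no filled pads; skipping simulation", unit.unit_id)
            continue
        params = unit.colony.to_domain(unit.pads_filled)
        sim = simulate_colony(
            params, config.duration_s, children[2 * i], unit_id=unit.unit_id, media=media
        )
        trace = synthesize_trace(
            sim.events,
            noise,
            sampling_rate=config.sampling_rate_hz,
            duration=config.duration_s,
            seed=children[2 * i + 1],
            frequency=unit.frequency_hz,
        )
        traces.append(trace)
        sims[unit.unit_id] = (params, sim)
    experiment = SyntheticExperiment(
        traces=traces,
        truth={
            uid: UnitTruth(params, sim.events, sim.fill_time, 0.0, 0.0)
            for uid, (params, sim) in sims.items()
        },
        schedule=schedule,
        media=media,
    )
    segments = apply_multiplex_schedule(experiment)
    for uid, (params, sim) in sims.items():
        unit_segs = [s for s in segments if s.unit_id == uid]
        if unit_segs:
            t0 = min(s.start_time for s in unit_segs)
            t1 = max(s.end_time for s in unit_segs)
        else:
            t0, t1 = 0.0, config.duration_s
        truth = experiment.truth[uid]
        truth.cell_count_start = float(sim.cell_count(t0))
        truth.cell_count_end = float(sim.cell_count(t1))
    logger.info(
        "simulate: %d units, %d recorded segments, %s events total",
        len(sims),
        len(segments),
        sum(len(t.events) for t in experiment.truth.values()),
    )
    return experiment, segments


def detect_stage(
    segments: list[PhaseTrace], config: ExperimentConfig
) -> tuple[list[PeakEvent], list[WindowCount]]:
    """Stage 2: filter each recorded segment, extract peaks, count per window.

    A warm-up margin of 1/band_low seconds at each segment edge is excluded
    from detection; counting windows tile the remaining valid span with the
    configured window length.  When the valid span is shorter than one
    nominal window (multiplexed segments), the whole span becomes a single
    window of its actual length — normalization uses per-window lengths, so
    the estimator stays unbiased.
    """
    unit_cfg = {u.unit_id: u for u in config.units}
    events: list[PeakEvent] = []
    counts: list[WindowCount] = []
    for seg in segments:
        unit = unit_cfg.get(seg.unit_id)
        if unit is None:
            raise PipelineError(f"segment for unknown unit {seg.unit_id!r}")
        det = config.detection_config(unit)
        seg_events = detect_peaks(seg, det)
        events.extend(seg_events)
        margin = det.warmup
        span_start = seg.start_time + margin
        span_end = seg.end_time - margin
        if span_end <= span_start:
            logger.warning(
                "segment %s[%d] too short for any counting window; skipped",
                seg.unit_id,
                seg.segment_index,
            )
            continue
        span = span_end - span_start
        wl = config.count_window_s
        if span >= wl:
            n_full = int(span // wl)
            counts.extend(
                count_peaks_in_windows(
                    seg_events, wl, (span_start, span_start + n_full * wl), unit_id=seg.unit_id
                )
            )
        else:
            counts.extend(
                count_peaks_in_windows(
                    seg_events, span, (span_start, span_end), unit_id=seg.unit_id
                )
            )
    events.sort(key=lambda e: (e.unit_id, e.time))
    counts.sort(key=lambda c: (c.unit_id, c.start))
    logger.info("detect: %d events, %d windows", len(events), len(counts))
    return events, counts


def estimate_stage(
    counts: list[WindowCount],
    meta: dict[str, AnalysisUnitMeta],
    media: MediaSchedule,
    config: ExperimentConfig,
) -> tuple[GrowthRateResults, pd.DataFrame]:
    """Stage 3: normalized peak rates, condition summaries, relative changes."""
    model = GrowthRateModel(
        counts,
        meta,
        media=media,
        budding_index=config.budding_index,
        switch_buffer=config.effective_switch_buffer,
    )
    results = model.fit()
    changes = results.relative_changes()
    logger.info(
        "estimate: %d estimates over %d units",
        len(results.estimates),
        len({e.unit_id for e in results.estimates}),
    )
    return results, changes


def meta_from_truth(experiment: SyntheticExperiment, config: ExperimentConfig) -> dict[str, AnalysisUnitMeta]:
    unit_cfg = {u.unit_id: u for u in config.units}
    return {
        uid: AnalysisUnitMeta(
            unit_id=uid,
            chamber_id=unit_cfg[uid].chamber_id,
            pads_filled=unit_cfg[uid].pads_filled,
            cell_count_start=t.cell_count_start,
            cell_count_end=t.cell_count_end,
        )
        for uid, t in experiment.truth.items()
    }


# ---------------------------------------------------------------------------
# file I/O


def write_events(events: list[PeakEvent], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id\ttime_s\tamplitude_deg\twidth_s\n")
        for e in events:
            fh.write(f"{e.unit_id}\t{e.time:.10g}\t{e.amplitude:.10g}\t{e.width:.10g}\n")


def read_events(path: Path) -> list[PeakEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        PeakEvent(str(r.unit_id), float(r.time_s), float(r.amplitude_deg), float(r.width_s))
        for r in df.itertuples()
    ]


def write_counts(counts: list[WindowCount], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id\twindow_start_s\twindow_length_s\tcount\n")
        for c in counts:
            fh.write(f"{c.unit_id}\t{c.start:.10g}\t{c.length:.10g}\t{c.count}\n")


def read_counts(path: Path) -> list[WindowCount]:
    df = pd.read_csv(path, sep="\t")
    return [
        WindowCount(str(r.unit_id), float(r.window_start_s), float(r.window_length_s), int(r.count))
        for r in df.itertuples()
    ]


def write_meta(meta: dict[str, AnalysisUnitMeta], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id\tchamber_id\tpads_filled\tcell_count_start\tcell_count_end\n")
        for m in meta.values():
            fh.write(
                f"{m.unit_id}\t{m.chamber_id}\t{m.pads_filled}"
                f"\t{m.cell_count_start:.10g}\t{m.cell_count_end:.10g}\n"
            )


def read_meta(path: Path) -> dict[str, AnalysisUnitMeta]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples():
        out[str(r.unit_id)] = AnalysisUnitMeta(
            unit_id=str(r.unit_id),
            chamber_id=str(r.chamber_id),
            pads_filled=int(r.pads_filled),
            cell_count_start=float(r.cell_count_start),
            cell_count_end=float(r.cell_count_end),
        )
    return out


def write_ground_truth(experiment: SyntheticExperiment, config: ExperimentConfig, path: Path) -> None:
    payload = {
        "seed": config.seed,
        "t_eis_s": config.t_eis_s,
        "media": {
            "segments": [{"start_s": s, "condition": c} for s, c in experiment.media.segments],
            "switch_duration_s": experiment.media.switch_duration,
        },
        "schedule": (
            None
            if experiment.schedule is None
            else {
                "entries": [
                    {"unit_id": u, "window_length_s": w} for u, w in experiment.schedule.entries
                ],
                "switching_overhead_s": experiment.schedule.switching_overhead,
            }
        ),
        "units": {
            uid: {
                "growth_rate_per_cell_per_h": t.params.growth_rate_per_cell,
                "pad_capacity": t.params.pad_capacity,
                "initial_cells": t.params.initial_cells,
                "budding_index": t.params.budding_index,
                "fill_model": t.params.fill_model,
                "condition_rates_per_h": (
                    dict(t.params.condition_rates) if t.params.condition_rates else None
                ),
                "fill_time_s": t.fill_time if np.isfinite(t.fill_time) else None,
                "cell_count_start": t.cell_count_start,
                "cell_count_end": t.cell_count_end,
                "event_times_s": [round(x, 6) for x in t.events.times.tolist()],
                "event_budded": t.events.budded.astype(int).tolist(),
            }
            for uid, t in experiment.truth.items()
        },
    }
    path.write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# report + driver


def write_report(
    results: GrowthRateResults,
    changes: pd.DataFrame,
    meta: dict[str, AnalysisUnitMeta],
    path: Path,
    pad_capacities: dict[str, float] | None = None,
) -> None:
    """Human-readable report: summary table, relative changes, occupancy flags."""
    lines = [results.summary(), ""]
    flagged = []
    for uid, m in meta.items():
        cap = (pad_capacities or {}).get(uid)
        if m.pads_filled < 4:
            flagged.append(f"  {uid}: only {m.pads_filled}/4 pads filled")
        if cap is not None and m.cell_count_start < cap:
            flagged.append(
                f"  {uid}: pads not fully occupied at recording start "
                f"({m.cell_count_start:.0f}/{cap:.0f} cells) — expect higher variability"
            )
    if flagged:
        lines += ["pad-occupancy flags:"] + flagged + [""]
    for e in results.estimates:
        if not e.sem_defined:
            lines.append(f"note: {e.unit_id}/{e.condition}: SEM undefined (n=1)")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: ExperimentConfig, output_dir: str | Path) -> PipelineResult:
    """Run simulate -> detect -> estimate -> report, writing all artifacts.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "traces").mkdir(exist_ok=True)

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage {name!r} failed: {err}") from err

    if not config.units:
        raise PipelineError("stage 'simulate' failed: no analysis units")

    experiment, segments = stage("simulate", simulate_experiment, config)
    for seg in segments:
        write_trace(seg, out / "traces" / trace_filename(seg.unit_id, seg.segment_index))
    write_ground_truth(experiment, config, out / "ground_truth.json")

    events, counts = stage("detect", detect_stage, segments, config)
    write_events(events, out / "events.tsv")
    write_counts(counts, out / "window_counts.tsv")

    meta = meta_from_truth(experiment, config)
    write_meta(meta, out / "unit_meta.tsv")
    results, changes = stage("estimate", estimate_stage, counts, meta, experiment.media, config)

    results.to_frame().to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.10g")
    changes.to_csv(out / "relative_changes.tsv", sep="\t", index=False, float_format="%.10g")
    caps = {uid: float(t.params.pad_capacity) for uid, t in experiment.truth.items()}
    stage("report", write_report, results, changes, meta, out / "report.txt", caps)

    run_log = {
        "padflux_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "stage_counts": {
            "units_simulated": len(experiment.truth),
            "segments_recorded": len(segments),
            "events_detected": len(events),
            "windows_counted": len(counts),
            "estimates": len(results.estimates),
        },
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))

    return PipelineResult(
        config=config,
        experiment=experiment,
        segments=segments,
        events=events,
        counts=counts,
        results=results,
        relative_changes=changes,
        output_dir=out,
    )


def load_segments(traces_dir: str | Path) -> list[PhaseTrace]:
    """Read every trace segment file in a directory (stage-2 standalone input)."""
    traces_dir = Path(traces_dir)
    return [read_trace(p) for p in sorted(traces_dir.glob("trace_*.tsv"))]
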