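"""Pipeline orchestration and per-condition summaries.

`run_pipeline` chains simulate -> segment -> score -> events -> report on a
JSON-configurable batch of synthetic cells and writes tidy CSV outputs with
a manifest.  `summarize_condition` aggregates a per-cell table the way
multi-experiment imaging studies report: per-experiment averages first,
then mean +/- s.d. across experiments (pooled per-cell medians are also
emitted).  Inferential statistics beyond descriptive summaries and Pearson
correlation are deliberately not implemented here; the tidy tables are the
hand-off point to any stats package.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage import morphology

from .errors import SchemaError, ValidationError
from .events import (
    EventLog,
    Event,
    NCTrace,
    anillin_exit_delay,
    call_ne_ruptures,
    classify_ace_timing,
    first_rupture_time,
    qc_nucleus_occlusion,
    rupture_rate,
    track_metrics,
)
from .io import ImageStack, write_stack
from .segment import SegmentationParams, extract_membrane_band, LabeledMask, segment_cell, segment_nucleus
from .simulate import GroundTruth, SimulationConfig, simulate_cell_movie, write_ground_truth

__all__ = [
    "CorrelationResult",
    "pearson",
    "summarize_condition",
    "run_pipeline",
    "analyze_movie",
]

REQUIRED_PER_CELL_COLUMNS = ("condition", "experiment_id", "cell_id")

#: per-cell metric columns summarised when present (booleans become fractions)
METRIC_COLUMNS = (
    "ace_positive",
    "has_rupture",
    "rupture_rate_per_h",
    "entry_time_min",
    "first_rupture_min",
    "anillin_exit_delay_min",
    "track_velocity_um_per_h",
    "productivity_um_per_h",
    "blebbing",
)
ACE_TIMING_CATEGORIES = ("before", "at", "after", "no_rupture")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError("r must lie in [-1, 1]")
        if self.n < 3:
            raise ValidationError("need n >= 3 for a correlation")


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-sided p-value from the
    standard t transform, t = r * sqrt((n-2) / (1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), len(x), float(res.pvalue))


def summarize_condition(
    per_cell: pd.DataFrame, grouping: str = "condition"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Aggregate a per-cell table into per-condition summaries.

    Returns ``(summary, per_experiment, quarantine)``: per-experiment means
    of every recognised metric column, then the mean and s.d. of those
    experiment means per condition (reported as ``<metric>_mean`` /
    ``<metric>_sd``), together with pooled per-cell medians
    (``<metric>_median``) and ACE-timing category frequencies.  Cells with
    a missing experiment assignment are quarantined, not silently grouped.
    """
    missing = set(REQUIRED_PER_CELL_COLUMNS) - set(per_cell.columns)
    if missing:
        raise SchemaError(f"per-cell table missing columns: {sorted(missing)}")
    df = per_cell.copy()
    bad = df["experiment_id"].isna() | (df["experiment_id"].astype(str).str.strip() == "")
    quarantine = df[bad]
    df = df[~bad]

    metrics = [c for c in METRIC_COLUMNS if c in df.columns]
    for c in metrics:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    per_exp = (
        df.groupby([grouping, "experiment_id"], sort=True)
        .agg(n_cells=("cell_id", "count"), **{c: (c, "mean") for c in metrics})
        .reset_index()
    )

    rows = []
    for cond, sub in per_exp.groupby(grouping, sort=True):
        cells = df[df[grouping] == cond]
        row: dict = {
            grouping: cond,
            "n_cells": int(cells.shape[0]),
            "n_experiments": int(sub.shape[0]),
        }
        for c in metrics:
            vals = sub[c].dropna()
            row[f"{c}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{c}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            pooled = cells[c].dropna()
            row[f"{c}_median"] = float(pooled.median()) if len(pooled) else np.nan
        if "ace_timing" in cells.columns:
            cats = cells["ace_timing"].dropna()
            cats = cats[cats.isin(ACE_TIMING_CATEGORIES)]
            total = len(cats)
            for cat in ACE_TIMING_CATEGORIES:
                row[f"freq_ace_{cat}"] = (
                    float((cats == cat).sum() / total) if total else np.nan
                )
        rows.append(row)
    summary = pd.DataFrame(rows)
    return summary, per_exp, quarantine


# ---------------------------------------------------------------------------
# movie-level analysis

DEFAULT_ANALYSIS = {
    "drop_fraction": 0.3,
    "recovery_fraction": 0.5,
    "min_separation_frames": 2,
    "baseline_window": 5,
    "ace_ratio_threshold": 2.0,
    "ace_min_length_um": 5.0,
    "cyto_reference_radius_um": 3.0,
    "anillin_exit_drop_fraction": 0.2,
    "anillin_exit_sustain_frames": 3,
    "at_tolerance_frames": 1,
}


def _region_means(
    stack: ImageStack, channel: str, region_masks: np.ndarray, offset: float
) -> np.ndarray:
    frames = stack.channel(channel)
    out = np.full(stack.n_frames, np.nan)
    for f in range(stack.n_frames):
        m = region_masks[f]
        if m.any():
            out[f] = max(float(frames[f][m].mean()) - offset, 0.0)
    return out


def _detect_ace_region(
    anillin: np.ndarray,
    band: np.ndarray,
    cyto: np.ndarray,
    pixel_size_um: float,
    band_width_um: float,
    ratio_threshold: float,
    min_length_um: float,
    reference_radius_um: float,
) -> list[tuple[str, float]]:
    """Movie-frame ACE scoring on the membrane band.

    The cytoplasmic reference is the mean of cytoplasm within
    ``reference_radius_um`` of the band.  Qualifying band pixels (at or
    above ratio_threshold x reference) are grouped into connected
    components whose membrane length is estimated as component area /
    band width; components of at least ``min_length_um`` count as ACEs.
    Returns (side, length_um) per qualifying component, side judged from
    the component centroid relative to the cell centroid along x.
    """
    radius_px = max(1, int(round(reference_radius_um / pixel_size_um)))
    near = morphology.dilation(band, morphology.disk(radius_px)) & cyto
    if not near.any():
        near = cyto
    reference = float(anillin[near].mean())
    if reference <= 0:
        return []
    qualifying = band & (anillin >= ratio_threshold * reference - 1e-12)
    labels, n = ndi.label(qualifying, structure=np.ones((3, 3)))
    results = []
    cell_cx = np.nonzero(band)[1].mean()
    for lab in range(1, n + 1):
        comp = labels == lab
        length_um = comp.sum() * pixel_size_um**2 / band_width_um
        if length_um >= min_length_um - 1e-9:
            side = "front" if np.nonzero(comp)[1].mean() >= cell_cx else "rear"
            results.append((side, float(length_um)))
    return results


def analyze_movie(
    stack: ImageStack,
    truth: GroundTruth | None = None,
    config: SimulationConfig | None = None,
    analysis: dict | None = None,
    use_ground_truth_masks: bool = True,
    cell_id: str = "cell0",
) -> dict:
    """Quantify one movie: N/C traces, rupture/repair calls, ACE onsets,
    anillin nuclear exit, entry events and track metrics.

    With ``use_ground_truth_masks`` the analysis measures on the simulator's
    exact masks (isolates the event-calling stages); otherwise nuclei and
    cells are segmented from the NLS channel frame by frame.
    """
    params = dict(DEFAULT_ANALYSIS)
    if analysis:
        params.update(analysis)
    px = stack.pixel_size_um
    dt = stack.frame_interval_s
    T = stack.n_frames
    offset = config.noise_model[2] if config is not None else 0.0
    band_width_um = config.band_width_um if config is not None else 1.0
    # rendered band thickness in µm (erosion works in whole pixels)
    band_thickness_um = max(1, int(round(band_width_um / stack.pixel_size_um))) * stack.pixel_size_um
    entrance_x_um = config.entrance_x_um if config is not None else 0.0
    entrance_col = entrance_x_um / px

    if use_ground_truth_masks:
        if truth is None:
            raise ValidationError("ground-truth masks requested but no truth given")
        cell_masks = truth.cell_masks
        nucleus_masks = truth.nucleus_masks
        band_masks = truth.band_masks
    else:
        nls = stack.channel("nls")
        cell_masks = np.zeros((T,) + nls.shape[1:], dtype=bool)
        nucleus_masks = np.zeros_like(cell_masks)
        band_masks = np.zeros_like(cell_masks)
        for f in range(T):
            cmask = segment_cell(nls[f], px, frame_index=f)
            nmask = segment_nucleus(nls[f], px, frame_index=f)
            cell_masks[f] = cmask.binary()
            nucleus_masks[f] = nmask.binary() & cell_masks[f]
            one_cell = LabeledMask(cell_masks[f].astype(np.int32), f, "cell")
            if cell_masks[f].any():
                try:
                    band_masks[f] = extract_membrane_band(one_cell, band_width_um, px).binary()
                except Exception:
                    pass

    cyto_nls = cell_masks & ~nucleus_masks
    cyto_anillin = cyto_nls & ~band_masks

    times = np.arange(T) * dt
    nls_trace = NCTrace(
        cell_id=cell_id,
        times_s=times,
        nuclear_mean=_region_means(stack, "nls", nucleus_masks, offset),
        cytoplasmic_mean=_region_means(stack, "nls", cyto_nls, offset),
    )
    excluded, reason = qc_nucleus_occlusion(
        nucleus_masks.reshape(T, -1).sum(axis=1)
    )
    if excluded:
        nls_trace.qc_excluded = True
        nls_trace.qc_reason = reason
    anillin_trace = NCTrace(
        cell_id=cell_id,
        times_s=times,
        nuclear_mean=_region_means(stack, "anillin", nucleus_masks, offset),
        cytoplasmic_mean=_region_means(stack, "anillin", cyto_anillin, offset),
    )

    if nls_trace.qc_excluded:
        log = EventLog(cell_id=cell_id, events=[])
    else:
        log = call_ne_ruptures(
            nls_trace,
            drop_fraction=params["drop_fraction"],
            recovery_fraction=params["recovery_fraction"],
            min_separation_frames=params["min_separation_frames"],
            baseline_window=params["baseline_window"],
        )
    events = list(log.events)

    # entry events from the cell masks and the entrance plane
    cols = [np.nonzero(cell_masks[f].any(axis=0))[0] for f in range(T)]
    entry_start = next(
        (f for f in range(T) if cols[f].size and cols[f].max() >= entrance_col), None
    )
    entry_complete = next(
        (f for f in range(T) if cols[f].size and cols[f].min() >= entrance_col), None
    )
    if entry_start is not None:
        events.append(Event("entry_start", entry_start * dt, entry_start))
    if entry_complete is not None:
        events.append(Event("entry_complete", entry_complete * dt, entry_complete))

    # per-frame ACE scoring; onset = first qualifying frame per side
    anillin_frames = stack.channel("anillin")
    onset: dict[str, int] = {}
    for f in range(T):
        if not band_masks[f].any() or not cyto_anillin[f].any():
            continue
        frame = np.clip(anillin_frames[f].astype(float) - offset, 0.0, None)
        hits = _detect_ace_region(
            frame,
            band_masks[f],
            cyto_anillin[f],
            px,
            band_thickness_um,
            params["ace_ratio_threshold"],
            params["ace_min_length_um"],
            params["cyto_reference_radius_um"],
        )
        for side, _length in hits:
            onset.setdefault(side, f)
        if len(onset) == 2:
            break
    for side, f in sorted(onset.items()):
        events.append(Event(f"ace_onset_{side}", f * dt, f, side))

    # anillin nuclear exit relative to the first called rupture
    exit_delay_s = None
    ruptures = log.of_type("rupture")
    if ruptures:
        try:
            exit_delay_s = anillin_exit_delay(
                anillin_trace,
                ruptures[0].time_s,
                drop_fraction=params["anillin_exit_drop_fraction"],
                sustain_frames=params["anillin_exit_sustain_frames"],
            )
        except ValidationError:
            exit_delay_s = None
        if exit_delay_s is not None:
            t_exit = ruptures[0].time_s + exit_delay_s
            events.append(Event("anillin_nuclear_exit", t_exit, int(round(t_exit / dt))))

    # observation window: nucleus at entrance until protrusion at exit (or end)
    nuc_cols = [np.nonzero(nucleus_masks[f].any(axis=0))[0] for f in range(T)]
    win_start = next(
        (f for f in range(T) if nuc_cols[f].size and nuc_cols[f].max() >= entrance_col), 0
    )
    exit_col = (
        (config.entrance_x_um + config.channel_spec.length_um) / px
        if config is not None
        else stack.shape[3]
    )
    win_end = next(
        (f for f in range(T) if cols[f].size and cols[f].max() >= exit_col), T - 1
    )
    window_s = max((win_end - win_start) * dt, dt)

    full_log = EventLog(cell_id=cell_id, events=events, observation_window_s=window_s)

    # track metrics from per-frame cell centroids
    track = np.full((T, 2), np.nan)
    for f in range(T):
        if cell_masks[f].any():
            ys, xs = np.nonzero(cell_masks[f])
            track[f] = (xs.mean() * px, ys.mean() * px)
    valid = ~np.isnan(track[:, 0])
    tm = track_metrics(times[valid], track[valid]) if valid.sum() >= 2 else None

    return {
        "event_log": full_log,
        "nls_trace": nls_trace,
        "anillin_trace": anillin_trace,
        "track_um": track,
        "track_metrics": tm,
        "anillin_exit_delay_s": exit_delay_s,
    }


def _per_cell_row(result: dict, cell_id: str, condition: str, experiment_id: str) -> dict:
    log: EventLog = result["event_log"]
    ruptures = log.of_type("rupture")
    row = {
        "condition": condition,
        "experiment_id": experiment_id,
        "cell_id": cell_id,
        "ace_positive": bool(
            log.of_type("ace_onset_front") or log.of_type("ace_onset_rear")
        ),
        "has_rupture": bool(ruptures),
        "n_ruptures": len(ruptures),
        "rupture_rate_per_h": rupture_rate(log),
    }
    try:
        frt = first_rupture_time(log)
        row["first_rupture_min"] = frt / 60.0 if frt is not None else np.nan
        starts = log.of_type("entry_start")
        completes = log.of_type("entry_complete")
        row["entry_time_min"] = (
            (completes[0].time_s - starts[0].time_s) / 60.0
            if starts and completes
            else np.nan
        )
    except ValidationError:
        row["first_rupture_min"] = np.nan
        row["entry_time_min"] = np.nan
    try:
        timing = classify_ace_timing(log)
        row["ace_timing"] = timing[0][1]
    except ValidationError:
        row["ace_timing"] = None
    delay = result.get("anillin_exit_delay_s")
    row["anillin_exit_delay_min"] = delay / 60.0 if delay is not None else np.nan
    tm = result.get("track_metrics")
    row["track_velocity_um_per_h"] = tm.track_velocity_um_per_h if tm else np.nan
    row["productivity_um_per_h"] = tm.productivity_um_per_h if tm else np.nan
    return row


def run_pipeline(config: dict, seed: int | None = None, out_dir=None) -> dict:
    """Execute simulate -> segment -> score -> events -> report.

    ``config`` keys: ``simulate`` (SimulationConfig fields), ``n_cells``,
    ``masks`` ("ground_truth" | "segment"), ``analysis`` (event-caller and
    ACE parameters), ``condition``, ``experiment_id``, ``write_images``.
    All outputs are declared in a manifest carrying the config hash; the
    same (config, seed) reruns byte-identically.
    """
    if not isinstance(config, dict):
        raise ValidationError("config must be a dict (parsed JSON)")
    sim_fields = dict(config.get("simulate", {}))
    n_cells = int(config.get("n_cells", 1))
    masks_mode = config.get("masks", "ground_truth")
    if masks_mode not in ("ground_truth", "segment"):
        raise ValidationError(f"masks must be ground_truth or segment, got {masks_mode!r}")
    analysis = config.get("analysis", {})
    condition = config.get("condition", "default")
    experiment_id = config.get("experiment_id", "exp1")
    write_images = bool(config.get("write_images", False))
    base_seed = int(seed if seed is not None else sim_fields.get("seed", 0))

    rows = []
    logs = []
    traces = []
    for i in range(n_cells):
        cell_id = f"cell{i}"
        cfg = SimulationConfig(**{**sim_fields, "seed": base_seed + i})
        stack, truth = simulate_cell_movie(cfg)
        result = analyze_movie(
            stack,
            truth=truth,
            config=cfg,
            analysis=analysis,
            use_ground_truth_masks=(masks_mode == "ground_truth"),
            cell_id=cell_id,
        )
        rows.append(_per_cell_row(result, cell_id, condition, experiment_id))
        logs.append(result["event_log"])
        traces.append(result["nls_trace"])
        if out_dir is not None and write_images:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_stack(out / f"{cell_id}_movie.ome.tif", stack)
            write_ground_truth(truth, out, cell_id=cell_id)

    per_cell = pd.DataFrame(rows)
    summary, per_exp, quarantine = summarize_condition(per_cell)
    events_df = pd.concat([lg.to_dataframe() for lg in logs], ignore_index=True)
    traces_df = pd.concat([tr.to_dataframe() for tr in traces], ignore_index=True)

    bundle = {
        "per_cell": per_cell,
        "summary": summary,
        "per_experiment": per_exp,
        "quarantine": quarantine,
        "events": events_df,
        "traces": traces_df,
        "event_logs": logs,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        outputs = {}
        for name, df in [
            ("per_cell", per_cell),
            ("condition_summary", summary),
            ("per_experiment", per_exp),
            ("events", events_df),
            ("traces", traces_df),
        ]:
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            outputs[name] = path.name
        events_json = out / "events.json"
        events_json.write_text(
            json.dumps([json.loads(lg.to_json()) for lg in logs], indent=2)
        )
        outputs["events_json"] = events_json.name
        config_text = json.dumps(config, sort_keys=True)
        manifest = {
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
            "seed": base_seed,
            "n_cells": n_cells,
            "outputs": outputs,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        bundle["manifest"] = manifest
    return bundle
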