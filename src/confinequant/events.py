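"""Event calling and timing statistics for confined-migration time series.

The central operation is the nuclear-envelope (NE) rupture caller: a rupture
is an abrupt drop of the nuclear/cytoplasmic (N/C) ratio of an NLS reporter
below a running baseline, with the nuclear signal decreasing and the
cytoplasmic signal increasing at the same frame; repair is the subsequent
recovery of the nuclear signal.  Downstream metrics — hourly rupture rate,
first-rupture latency after channel entry, the timing of anillin-rich cell
edge (ACE) formation relative to rupture, anillin nuclear-exit delay,
channel-entry metrics and track velocity/productivity — all consume the
resulting event log.

Units: seconds internally; rates are reported per hour, entry and delay
durations in minutes, matching common reporting for these assays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "NCTrace",
    "Event",
    "EventLog",
    "ChannelSpec",
    "TrackMetrics",
    "EntryMetrics",
    "call_ne_ruptures",
    "rupture_rate",
    "first_rupture_time",
    "classify_ace_timing",
    "anillin_exit_delay",
    "entry_metrics",
    "classify_channel",
    "track_metrics",
]

EVENT_TYPES = (
    "rupture",
    "repair",
    "ace_onset_front",
    "ace_onset_rear",
    "anillin_nuclear_exit",
    "entry_start",
    "entry_complete",
)

#: Channel cross-sections (width um, height um) -> confinement class.
CONFINEMENT_CLASSES = {
    (10.0, 10.0): "moderately_confining",
    (10.0, 3.0): "confining",
    (3.0, 3.0): "tightly_confining",
}


@dataclass
class NCTrace:
    """Per-cell time series of nuclear and cytoplasmic reporter intensity."""

    cell_id: str
    times_s: np.ndarray
    nuclear_mean: np.ndarray
    cytoplasmic_mean: np.ndarray
    ratio: np.ndarray | None = None
    qc_excluded: bool = False
    qc_reason: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.nuclear_mean = np.asarray(self.nuclear_mean, dtype=float)
        self.cytoplasmic_mean = np.asarray(self.cytoplasmic_mean, dtype=float)
        n = len(self.times_s)
        if len(self.nuclear_mean) != n or len(self.cytoplasmic_mean) != n:
            raise ValidationError("trace arrays must have equal length")
        if n >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValidationError("times must be strictly increasing")
        if self.ratio is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                self.ratio = np.where(
                    self.cytoplasmic_mean > np.finfo(float).eps,
                    self.nuclear_mean / self.cytoplasmic_mean,
                    np.nan,
                )
        else:
            self.ratio = np.asarray(self.ratio, dtype=float)
            if len(self.ratio) != n:
                raise ValidationError("ratio length mismatch")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.times_s)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "frame": np.arange(len(self)),
                "time_s": self.times_s,
                "nuclear_mean": self.nuclear_mean,
                "cytoplasmic_mean": self.cytoplasmic_mean,
                "ratio": self.ratio,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cell_id: str | None = None) -> "NCTrace":
        required = {"time_s", "nuclear_mean", "cytoplasmic_mean"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"trace table missing columns: {sorted(missing)}")
        cid = cell_id if cell_id is not None else str(df["cell_id"].iloc[0])
        return cls(
            cell_id=cid,
            times_s=df["time_s"].to_numpy(),
            nuclear_mean=df["nuclear_mean"].to_numpy(),
            cytoplasmic_mean=df["cytoplasmic_mean"].to_numpy(),
            ratio=df["ratio"].to_numpy() if "ratio" in df.columns else None,
        )


class Event(NamedTuple):
    type: str
    time_s: float
    frame: int
    pole: str | None = None


@dataclass
class EventLog:
    """Time-sorted rupture/repair/ACE/entry events for one cell."""

    cell_id: str
    events: list[Event] = field(default_factory=list)
    observation_window_s: float | None = None

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.type not in EVENT_TYPES:
                raise ValidationError(f"unknown event type {ev.type!r}")
        self.events = sorted(self.events, key=lambda e: (e.time_s, e.frame))
        self._check_alternation()
        starts = self.of_type("entry_start")
        completes = self.of_type("entry_complete")
        if starts and completes and starts[0].time_s > completes[0].time_s:
            raise ValidationError("entry_start must not follow entry_complete")

    def _check_alternation(self) -> None:
        open_rupture = False
        for ev in self.events:
            if ev.type == "rupture":
                if open_rupture:
                    raise ValidationError(
                        f"{self.cell_id}: two ruptures without intervening repair"
                    )
                open_rupture = True
            elif ev.type == "repair":
                if not open_rupture:
                    raise ValidationError(f"{self.cell_id}: repair without prior rupture")
                open_rupture = False

    def of_type(self, event_type: str) -> list[Event]:
        return [e for e in self.events if e.type == event_type]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": self.cell_id,
                    "event_type": e.type,
                    "time_s": e.time_s,
                    "frame": e.frame,
                    "pole": e.pole if e.pole is not None else "",
                }
                for e in self.events
            ],
            columns=["cell_id", "event_type", "time_s", "frame", "pole"],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "cell_id": self.cell_id,
                "observation_window_s": self.observation_window_s,
                "events": [e._asdict() for e in self.events],
            },
            indent=2,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, cell_id: str, observation_window_s: float | None = None
    ) -> "EventLog":
        sub = df[df["cell_id"].astype(str) == str(cell_id)]
        events = [
            Event(
                row.event_type,
                float(row.time_s),
                int(row.frame),
                row.pole if getattr(row, "pole", "") not in ("", None) else None,
            )
            for row in sub.itertuples()
        ]
        return cls(cell_id=str(cell_id), events=events, observation_window_s=observation_window_s)


@dataclass(frozen=True)
class ChannelSpec:
    """Microchannel geometry.  Area is exactly width x height."""

    width_um: float
    height_um: float
    length_um: float = 200.0

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0 and self.length_um > 0):
            raise ValidationError("channel dimensions must be positive")

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um

    @property
    def confinement_class(self) -> str:
        return CONFINEMENT_CLASSES.get((self.width_um, self.height_um), "other")


def classify_channel(width_um: float, height_um: float, length_um: float = 200.0) -> ChannelSpec:
    """Build a :class:`ChannelSpec`; class assignment is an exact match on
    the canonical cross-sections 10x10, 10x3 and 3x3 µm, else ``other``."""
    return ChannelSpec(float(width_um), float(height_um), float(length_um))


@dataclass(frozen=True)
class TrackMetrics:
    track_velocity_um_per_h: float
    productivity_um_per_h: float
    track_time_h: float

    def __post_init__(self) -> None:
        if self.track_velocity_um_per_h < 0 or self.productivity_um_per_h < 0:
            raise ValidationError("track metrics must be non-negative")
        if self.productivity_um_per_h > self.track_velocity_um_per_h * (1 + 1e-12):
            raise ValidationError("productivity cannot exceed track velocity")


@dataclass(frozen=True)
class EntryMetrics:
    eligible: bool
    entered: bool
    entry_time_min: float | None


def qc_nucleus_occlusion(
    nucleus_areas_px, drop_fraction: float = 0.5, min_frames: int = 2
) -> tuple[bool, str]:
    """Automated proxy for the obstructed-nucleus exclusion rule.

    A trace is flagged when the segmented nucleus area falls below
    ``(1 - drop_fraction)`` of its median for at least ``min_frames``
    consecutive frames (debris or another cell occluding the nucleus makes
    its reporter mask collapse).  Returns (excluded, reason).
    """
    areas = np.asarray(nucleus_areas_px, dtype=float)
    if areas.size == 0 or not np.any(areas > 0):
        return True, "nucleus never segmented"
    ref = float(np.median(areas[areas > 0]))
    low = areas < (1.0 - drop_fraction) * ref
    run = 0
    for flag in low:
        run = run + 1 if flag else 0
        if run >= min_frames:
            return True, (
                f"nucleus area below {100 * (1 - drop_fraction):.0f}% of median "
                f"for >= {min_frames} frames"
            )
    return False, ""


def call_ne_ruptures(
    trace: NCTrace,
    drop_fraction: float = 0.3,
    recovery_fraction: float = 0.5,
    min_separation_frames: int = 2,
    baseline_window: int = 5,
) -> EventLog:
    """Call NE rupture and repair events from an N/C trace.

    A rupture is called at frame ``f`` when the ratio falls to or below
    ``(1 - drop_fraction)`` of the running-median baseline AND the nuclear
    mean decreased AND the cytoplasmic mean increased relative to the
    previous frame.  Repair is detected when the ratio recovers above
    ``baseline - recovery_fraction * (baseline - trough)``; the repair event
    is timestamped at the recovery onset, i.e. the last frame at the trough,
    which under noise-free kinetics coincides with the true repair frame.
    Consecutive events are at least ``min_separation_frames`` apart; the
    caller never emits two ruptures without an intervening repair.
    """
    if trace.qc_excluded:
        raise ValidationError(f"{trace.cell_id}: trace is QC-excluded ({trace.qc_reason})")
    if len(trace) < 3:
        raise ValidationError("trace must have at least 3 frames")
    for name, val in [
        ("drop_fraction", drop_fraction),
        ("recovery_fraction", recovery_fraction),
    ]:
        if not 0 < val < 1:
            raise ValidationError(f"{name} must be in (0, 1), got {val}")

    ratio = trace.ratio
    nuc = trace.nuclear_mean
    cyt = trace.cytoplasmic_mean
    times = trace.times_s

    events: list[Event] = []
    baseline_buf: list[float] = [float(ratio[0])] if np.isfinite(ratio[0]) else []
    in_rupture = False
    base_at_rupture = np.nan
    trough = np.inf
    trough_frame = -1
    last_event_frame = -(10**9)

    for f in range(1, len(trace)):
        r = ratio[f]
        if not np.isfinite(r):
            continue
        if not in_rupture:
            if baseline_buf:
                base = float(np.median(baseline_buf[-baseline_window:]))
            else:
                base = r
            is_drop = (
                r <= (1.0 - drop_fraction) * base
                and nuc[f] < nuc[f - 1]
                and cyt[f] > cyt[f - 1]
                and f - last_event_frame >= min_separation_frames
            )
            if is_drop:
                events.append(Event("rupture", float(times[f]), f))
                in_rupture = True
                base_at_rupture = base
                trough = r
                trough_frame = f
                last_event_frame = f
            else:
                baseline_buf.append(float(r))
        else:
            if r <= trough:
                trough = r
                trough_frame = f
            recovered = r >= base_at_rupture - recovery_fraction * (base_at_rupture - trough)
            if recovered and f - last_event_frame >= min_separation_frames:
                repair_frame = max(trough_frame, last_event_frame + min_separation_frames)
                events.append(Event("repair", float(times[repair_frame]), repair_frame))
                in_rupture = False
                last_event_frame = repair_frame
                baseline_buf = [float(r)]
                trough = np.inf

    window = float(times[-1] - times[0]) if len(times) > 1 else None
    return EventLog(cell_id=trace.cell_id, events=events, observation_window_s=window)


def rupture_rate(log: EventLog) -> float:
    """Hourly rate of NE ruptures over the log's observation window."""
    if not log.observation_window_s or log.observation_window_s <= 0:
        raise ValidationError("observation_window_s must be positive")
    return len(log.of_type("rupture")) / (log.observation_window_s / 3600.0)


def first_rupture_time(log: EventLog) -> float | None:
    """Seconds from completed channel entry to the first NE rupture.

    Returns None when the cell never ruptured; raises when the log has no
    ``entry_complete`` event (the latency is undefined without a reference).
    """
    completes = log.of_type("entry_complete")
    if not completes:
        raise ValidationError(f"{log.cell_id}: no entry_complete event")
    ruptures = log.of_type("rupture")
    if not ruptures:
        return None
    return ruptures[0].time_s - completes[0].time_s


def classify_ace_timing(log: EventLog, at_tolerance_frames: int = 1) -> list[tuple[Event, str]]:
    """Categorise each ACE onset as before / at / after the nearest rupture.

    ``at`` means the onset frame is within ``at_tolerance_frames`` of the
    nearest rupture frame; cells with no rupture get ``no_rupture``.
    """
    onsets = [e for e in log.events if e.type in ("ace_onset_front", "ace_onset_rear")]
    if not onsets:
        raise ValidationError(f"{log.cell_id}: no ACE onset events to classify")
    ruptures = log.of_type("rupture")
    out = []
    for onset in onsets:
        if not ruptures:
            out.append((onset, "no_rupture"))
            continue
        nearest = min(ruptures, key=lambda r: abs(onset.frame - r.frame))
        delta = onset.frame - nearest.frame
        if abs(delta) <= at_tolerance_frames:
            out.append((onset, "at"))
        elif delta < 0:
            out.append((onset, "before"))
        else:
            out.append((onset, "after"))
    return out


def anillin_exit_delay(
    anillin_trace: NCTrace,
    first_rupture_time_s: float,
    drop_fraction: float = 0.2,
    sustain_frames: int = 3,
) -> float | None:
    """Delay (seconds) from the first NE rupture to anillin nuclear exit.

    Exit is the first time at or after the rupture at which the anillin N/C
    ratio has dropped by at least ``drop_fraction`` from its pre-rupture
    mean and stays below that level for at least ``sustain_frames`` frames.
    Returns 0 when concurrent with the rupture, None when no qualifying
    drop occurs within the trace.
    """
    times = anillin_trace.times_s
    if not (times[0] <= first_rupture_time_s <= times[-1]):
        raise ValidationError("rupture time lies outside the anillin trace")
    ratio = anillin_trace.ratio
    pre = ratio[times < first_rupture_time_s]
    pre = pre[np.isfinite(pre)]
    if pre.size == 0:
        raise ValidationError("no pre-rupture frames to establish a baseline")
    threshold = (1.0 - drop_fraction) * float(pre.mean())

    candidate_idx = np.where((times >= first_rupture_time_s) & (ratio <= threshold))[0]
    for i in candidate_idx:
        end = i + sustain_frames
        if end > len(ratio):
            break  # cannot confirm sustained drop within the trace
        if np.all(ratio[i:end] <= threshold):
            return float(times[i] - first_rupture_time_s)
    return None


def entry_metrics(
    track: np.ndarray,
    channel: ChannelSpec,
    entrance_x_um: float = 0.0,
    protrusion_time_s: float | None = None,
    full_entry_time_s: float | None = None,
    inclusion_distance_um: float = 50.0,
) -> EntryMetrics:
    """Eligibility, entry flag and entry time for one tracked cell.

    ``track`` is an ``(n, 2)`` array of (time_s, x_um) positions along the
    channel axis.  A cell is eligible when it approaches within
    ``inclusion_distance_um`` of the entrance (inclusive).  Entry time is
    the span from the first protrusion inside the channel to full cell
    entry, reported in minutes.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 2 or track.shape[0] < 1:
        raise ValidationError("track must be an (n, 2) array of (time_s, x_um)")
    dist = np.abs(track[:, 1] - entrance_x_um).min()
    eligible = bool(dist <= inclusion_distance_um)
    if not eligible:
        return EntryMetrics(eligible=False, entered=False, entry_time_min=None)
    entered = full_entry_time_s is not None
    entry_time = None
    if entered and protrusion_time_s is not None:
        if full_entry_time_s < protrusion_time_s:
            raise ValidationError("full entry cannot precede first protrusion")
        entry_time = (full_entry_time_s - protrusion_time_s) / 60.0
    return EntryMetrics(eligible=True, entered=entered, entry_time_min=entry_time)


def track_metrics(times_s: Sequence[float], positions_um: np.ndarray) -> TrackMetrics:
    """Mean speed and net-displacement rate (productivity) of one track.

    velocity = total path length / track time; productivity = straight-line
    distance from first to last position / track time; both in µm/h.
    """
    times = np.asarray(times_s, dtype=float)
    pos = np.asarray(positions_um, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, np.newaxis]
    if len(times) < 2 or len(times) != len(pos):
        raise ValidationError("need >= 2 timed positions")
    if not np.all(np.diff(times) > 0):
        raise ValidationError("track times must be strictly increasing")
    total_time_h = (times[-1] - times[0]) / 3600.0
    if total_time_h <= 0:
        raise ValidationError("zero track time")
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path_length = float(steps.sum())
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    velocity = path_length / total_time_h
    productivity = min(net / total_time_h, velocity)  # guard float rounding
    return TrackMetrics(velocity, productivity, total_time_h)
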