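"""Ground-truthed synthetic movies, linescan profiles and N/C traces.

The generator emulates the observables of a confined-migration microchannel
assay: a cell rendered as a stadium-shaped (capsule) mask translating at
constant speed into a straight microchannel, an elliptical nucleus whose
short axis is clamped to the channel opening, an NLS reporter whose
nuclear/cytoplasmic (N/C) ratio drops abruptly at scheduled nuclear-envelope
(NE) rupture times and recovers exponentially after repair, and an anillin
reporter partitioned among nucleus, diffuse cytoplasm and a membrane band
with scheduled pole enrichments (ACEs).  Poisson-Gaussian camera noise is
applied on top; all geometry and kinetics are noise-independent, so ground
truth is exact and identical across seeds.

Mass conservation is the generator's backbone: reporter "mass" (summed
intensity) moves between compartments but the total is constant, so a
rupture that removes a fraction of the nuclear NLS mass raises the
cytoplasmic mean by exactly the transferred mass divided by the cytoplasmic
pixel area.

Random numbers are drawn in a fixed, documented order (one Poisson draw
over the whole stack, then one Gaussian draw) so a (config, seed) pair is
bit-reproducible across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import tifffile
from skimage import morphology

from .errors import GeometryError, ValidationError
from .events import ChannelSpec, Event, NCTrace
from .io import ImageStack
from .scoring import Linescan

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TraceKinetics",
    "simulate_cell_movie",
    "simulate_linescan_profile",
    "simulate_nc_trace",
    "random_rupture_schedule",
    "write_ground_truth",
]


@dataclass
class SimulationConfig:
    """Everything needed to render one synthetic confined-migration movie.

    Times are in seconds, lengths in micrometres.  ``rupture_schedule`` is a
    list of (rupture_time_s, repair_time_s or None); ``ace_schedule`` a list
    of (onset_time_s, pole in {front, rear}, length_um, enrichment_ratio).
    ``anillin_partition`` gives the nuclear/cytoplasmic/membrane mass
    fractions and must sum to 1.  ``noise_model`` is
    (poisson_scale, gaussian_sd, background_offset); a zero poisson_scale
    disables shot noise.
    """

    pixel_size_um: float = 0.65
    frame_interval_s: float = 108.0
    n_frames: int = 100
    channel_spec: ChannelSpec = field(default_factory=lambda: ChannelSpec(10.0, 3.0, 200.0))
    cell_speed_um_per_min: float = 0.5
    nucleus_axes_um: tuple[float, float] = (14.0, 7.0)
    rupture_schedule: list[tuple[float, float | None]] = field(
        default_factory=lambda: [(7020.0, 7560.0)]
    )
    leak_fraction: float = 0.6
    recovery_halftime_s: float = 300.0
    ace_schedule: list[tuple[float, str, float, float]] = field(
        default_factory=lambda: [(1080.0, "rear", 6.0, 2.5)]
    )
    anillin_partition: tuple[float, float, float] = (0.7, 0.2, 0.1)
    noise_model: tuple[float, float, float] = (0.5, 2.0, 100.0)
    seed: int = 0
    # cell geometry and intensity scales
    cell_length_um: float = 40.0
    cell_width_um: float = 15.0
    band_width_um: float = 1.0
    nls_nuclear_intensity: float = 200.0
    nls_nc_baseline: float = 5.0
    anillin_intensity_scale: float = 80.0
    anillin_exit_lag_s: float | None = 300.0
    anillin_exit_fraction: float = 0.5
    entrance_x_um: float = 50.0
    approach_um: float = 8.0
    wall_margin_um: float = 3.0

    def __post_init__(self) -> None:
        if isinstance(self.channel_spec, dict):
            self.channel_spec = ChannelSpec(**self.channel_spec)
        self.nucleus_axes_um = tuple(self.nucleus_axes_um)
        self.anillin_partition = tuple(self.anillin_partition)
        self.noise_model = tuple(self.noise_model)
        self.rupture_schedule = [tuple(ev) for ev in self.rupture_schedule]
        self.ace_schedule = [tuple(ev) for ev in self.ace_schedule]
        self.validate()

    def validate(self) -> None:
        pos = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "cell_length_um": self.cell_length_um,
            "cell_width_um": self.cell_width_um,
            "band_width_um": self.band_width_um,
            "nls_nuclear_intensity": self.nls_nuclear_intensity,
            "nls_nc_baseline": self.nls_nc_baseline,
            "anillin_intensity_scale": self.anillin_intensity_scale,
            "recovery_halftime_s": self.recovery_halftime_s,
        }
        for name, v in pos.items():
            if not v > 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.cell_speed_um_per_min < 0:
            raise ValidationError("cell_speed_um_per_min must be >= 0")
        if not 0.0 <= self.leak_fraction <= 1.0:
            raise ValidationError("leak_fraction must be in [0, 1]")
        if any(a <= 0 for a in self.nucleus_axes_um) or len(self.nucleus_axes_um) != 2:
            raise ValidationError("nucleus_axes_um must be a positive (long, short) pair")
        if len(self.anillin_partition) != 3 or any(f < 0 for f in self.anillin_partition):
            raise ValidationError("anillin_partition must be three non-negative fractions")
        if abs(sum(self.anillin_partition) - 1.0) > 1e-9:
            raise ValidationError("anillin_partition must sum to 1 within 1e-9")
        if any(v < 0 for v in self.noise_model):
            raise ValidationError("noise parameters must be non-negative")
        last_time = -math.inf
        for i, (r, p) in enumerate(self.rupture_schedule):
            if r <= last_time:
                raise ValidationError("rupture times must be strictly increasing")
            if p is not None:
                if p <= r:
                    raise ValidationError(f"repair time {p} must follow rupture {r}")
                last_time = p
            else:
                if i != len(self.rupture_schedule) - 1:
                    raise ValidationError("only the final rupture may lack a repair")
                last_time = r
        for onset, pole, length, ratio in self.ace_schedule:
            if onset < 0 or length <= 0 or ratio <= 0:
                raise ValidationError("ACE schedule entries must be positive")
            if pole not in ("front", "rear"):
                raise ValidationError(f"ACE pole must be front or rear, got {pole!r}")
        if self.anillin_exit_lag_s is not None and self.anillin_exit_lag_s < 0:
            raise ValidationError("anillin_exit_lag_s must be >= 0")
        if not 0.0 <= self.anillin_exit_fraction <= 1.0:
            raise ValidationError("anillin_exit_fraction must be in [0, 1]")

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        data = json.loads(text)
        return cls(**data)

    def to_json(self) -> str:
        data = asdict(self)
        data["channel_spec"] = {
            "width_um": self.channel_spec.width_um,
            "height_um": self.channel_spec.height_um,
            "length_um": self.channel_spec.length_um,
        }
        return json.dumps(data, indent=2)


@dataclass
class GroundTruth:
    """Exact per-frame masks, noise-free traces and the true event log."""

    cell_masks: np.ndarray       # (T, Y, X) bool
    nucleus_masks: np.ndarray
    band_masks: np.ndarray
    pole_front_masks: np.ndarray
    pole_rear_masks: np.ndarray
    events: list[Event]
    entry_start_time_s: float | None
    entry_complete_time_s: float | None
    track_um: np.ndarray         # (T, 2) centroid (x, y) in um
    true_nuclear_mean: np.ndarray
    true_cyto_mean: np.ndarray
    true_nc_ratio: np.ndarray
    true_anillin_nuclear: np.ndarray
    true_anillin_cyto: np.ndarray
    true_anillin_ratio: np.ndarray

    def event_table(self, cell_id: str = "cell0") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": cell_id,
                    "event_type": e.type,
                    "time_s": e.time_s,
                    "frame": e.frame,
                    "pole": e.pole if e.pole is not None else "",
                }
                for e in self.events
            ],
            columns=["cell_id", "event_type", "time_s", "frame", "pole"],
        )


# ---------------------------------------------------------------------------
# step-drop / exponential-recovery kinetics shared by movie and trace levels

def _quantize(t: float, dt: float) -> int:
    """First frame index whose acquisition time is at or after t."""
    return int(math.ceil(t / dt - 1e-9))


def _effective_schedule(
    schedule, dt: float, n_frames: int
) -> list[tuple[float, float | None, int, int | None]]:
    """Snap event times to the frame grid; drop events past the movie end."""
    out = []
    for r, p in schedule:
        rf = _quantize(r, dt)
        if rf >= n_frames:
            continue
        if p is None:
            out.append((rf * dt, None, rf, None))
        else:
            pf = max(_quantize(p, dt), rf + 1)
            out.append((rf * dt, pf * dt, rf, pf if pf < n_frames else None))
    return out


def _step_recovery_series(
    times: np.ndarray, events, initial: float, drop_fraction: float, halftime_s: float
) -> np.ndarray:
    """Piecewise kinetics: step drop by drop_fraction at each rupture,
    exponential recovery toward the pre-rupture value after repair."""
    # precompute the pre-rupture value of each event in sequence
    pres, troughs = [], []
    pre = initial
    for i, (r, p, *_rest) in enumerate(events):
        trough = pre * (1.0 - drop_fraction)
        pres.append(pre)
        troughs.append(trough)
        nxt = events[i + 1][0] if i + 1 < len(events) else math.inf
        if p is None or not math.isfinite(nxt):
            pre = trough  # value continues evolving; only needed when more events follow
        else:
            pre = pre - (pre - trough) * 2.0 ** (-(nxt - p) / halftime_s)
    vals = np.empty(len(times), dtype=float)
    for k, t in enumerate(times):
        idx = -1
        for i, ev in enumerate(events):
            if t >= ev[0]:
                idx = i
            else:
                break
        if idx < 0:
            vals[k] = initial
            continue
        r, p = events[idx][0], events[idx][1]
        if p is None or t < p:
            vals[k] = troughs[idx]
        else:
            vals[k] = pres[idx] - (pres[idx] - troughs[idx]) * 2.0 ** (-(t - p) / halftime_s)
    return vals


# ---------------------------------------------------------------------------
# geometry rendering

def _capsule_mask(shape, cx: float, cy: float, length_px: float, radius_px: float) -> np.ndarray:
    """Stadium (capsule): points within radius of the central segment."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    half = max(length_px / 2.0 - radius_px, 0.0)
    dx = np.clip(np.abs(xx - cx) - half, 0.0, None)
    dy = yy - cy
    return dx**2 + dy**2 <= radius_px**2


def _ellipse_mask(shape, cx: float, cy: float, a_px: float, b_px: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2 <= 1.0


def simulate_cell_movie(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel (anillin, NLS) confined-migration movie.

    Returns the noisy :class:`~confinequant.io.ImageStack` and the exact
    :class:`GroundTruth`.  Identical (config, seed) pairs give bit-identical
    output; the ground truth does not depend on the seed at all.
    """
    px = config.pixel_size_um
    dt = config.frame_interval_s
    T = config.n_frames
    chan = config.channel_spec

    canvas_x_um = config.entrance_x_um + chan.length_um + 5.0
    canvas_y_um = chan.width_um + 2.0 * config.wall_margin_um
    W = int(round(canvas_x_um / px))
    H = int(round(canvas_y_um / px))
    entrance_col = config.entrance_x_um / px
    wall_lo = config.wall_margin_um / px
    wall_hi = (config.wall_margin_um + chan.width_um) / px
    cy = (wall_lo + wall_hi) / 2.0

    cell_radius_px = min(config.cell_width_um, chan.width_um) / 2.0 / px
    cell_len_px = config.cell_length_um / px
    nuc_long = config.nucleus_axes_um[0] / 2.0 / px
    short_um = min(
        config.nucleus_axes_um[1], chan.width_um - 2.0 * config.band_width_um - 0.5
    )
    if short_um <= 0:
        raise GeometryError("channel too narrow for the nucleus and membrane band")
    nuc_short = short_um / 2.0 / px

    v_px_s = config.cell_speed_um_per_min / 60.0 / px
    x0 = entrance_col - config.approach_um / px - cell_len_px / 2.0
    if x0 - cell_len_px / 2.0 < 1:
        raise GeometryError("canvas too small: cell initial position off the left edge")
    x_final = x0 + v_px_s * dt * (T - 1) + cell_len_px / 2.0
    if x_final >= W - 1:
        raise GeometryError(
            "canvas too small: cell exits the channel before the movie ends; "
            "reduce speed/frames or lengthen the channel"
        )

    band_px = max(1, int(round(config.band_width_um / px)))
    selem = morphology.disk(band_px)
    yy, xx = np.mgrid[0:H, 0:W]
    channel_interior = (yy >= wall_lo) & (yy <= wall_hi)

    # The cell shape is rendered once and translated by whole pixels per
    # frame: exact translation keeps compartment pixel areas constant, so
    # region means depend only on the scheduled kinetics, never on mask
    # discretisation.  The cell is confined to the channel opening over its
    # whole track (the entrance plane matters only for entry timing).
    cell0 = _capsule_mask((H, W), x0, cy, cell_len_px, cell_radius_px) & channel_interior
    band0 = cell0 & ~morphology.erosion(cell0, selem)
    nucleus0 = _ellipse_mask((H, W), x0, cy, nuc_long, nuc_short) & cell0 & ~band0
    if not nucleus0.any() or not (cell0 & ~nucleus0 & ~band0).any():
        raise GeometryError("degenerate geometry: empty nucleus or cytoplasm")
    # Pole arcs are cut from the band by an x-threshold chosen so the pole
    # area equals the requested arc length times the band's rendered
    # thickness — the mask itself is the ground truth for the pole.
    band_thickness_um = band_px * px
    pole_front0 = np.zeros_like(cell0)
    pole_rear0 = np.zeros_like(cell0)
    band_x = np.sort(xx[band0])
    for onset, pole, length_um, _ratio in config.ace_schedule:
        target_px = min(
            max(1, int(round(length_um * band_thickness_um / px**2))), band_x.size // 2
        )
        if pole == "front":
            pole_front0 |= band0 & (xx >= band_x[-target_px])
        else:
            pole_rear0 |= band0 & (xx <= band_x[target_px - 1])

    times = np.arange(T) * dt
    offsets = np.round(v_px_s * times).astype(int)

    cell_masks = np.zeros((T, H, W), dtype=bool)
    nucleus_masks = np.zeros_like(cell_masks)
    band_masks = np.zeros_like(cell_masks)
    pole_front = np.zeros_like(cell_masks)
    pole_rear = np.zeros_like(cell_masks)
    track = np.zeros((T, 2), dtype=float)
    for f in range(T):
        o = offsets[f]
        cell_masks[f] = np.roll(cell0, o, axis=1)
        nucleus_masks[f] = np.roll(nucleus0, o, axis=1)
        band_masks[f] = np.roll(band0, o, axis=1)
        pole_front[f] = np.roll(pole_front0, o, axis=1)
        pole_rear[f] = np.roll(pole_rear0, o, axis=1)
        ys, xs = np.nonzero(cell_masks[f])
        track[f] = (xs.mean() * px, ys.mean() * px)

    # ---- NLS channel: mass-conserving rupture/repair kinetics
    a_nuc = nucleus_masks.reshape(T, -1).sum(axis=1).astype(float)
    cyto_nls_masks = cell_masks & ~nucleus_masks
    a_cyt_nls = cyto_nls_masks.reshape(T, -1).sum(axis=1).astype(float)
    m_nuc0 = config.nls_nuclear_intensity * a_nuc[0]
    m_cyt0 = (config.nls_nuclear_intensity / config.nls_nc_baseline) * a_cyt_nls[0]
    total_nls = m_nuc0 + m_cyt0

    eff = _effective_schedule(config.rupture_schedule, dt, T)
    m_nuc = _step_recovery_series(
        times, eff, m_nuc0, config.leak_fraction, config.recovery_halftime_s
    )
    nls_nuclear = m_nuc / a_nuc
    nls_cyto = (total_nls - m_nuc) / a_cyt_nls
    true_ratio = nls_nuclear / nls_cyto

    # ---- anillin channel: partitioned pools, ACE enrichment, nuclear exit
    a_cell0 = float(cell_masks[0].sum())
    total_an = config.anillin_intensity_scale * a_cell0
    f_n, f_c, f_m = config.anillin_partition
    m_an_nuc = np.full(T, f_n * total_an)
    m_an_cyt = np.full(T, f_c * total_an)
    m_an_mem = f_m * total_an

    exit_time = None
    if config.anillin_exit_lag_s is not None and eff:
        first_rupture_t = eff[0][0]
        exit_frame = _quantize(first_rupture_t + config.anillin_exit_lag_s, dt)
        if exit_frame < T:
            exit_time = exit_frame * dt
            moved = config.anillin_exit_fraction * f_n * total_an
            m_an_nuc[exit_frame:] -= moved
            m_an_cyt[exit_frame:] += moved

    ace_eff = []  # (onset_frame, pole, ratio)
    for onset, pole, length_um, ratio in config.ace_schedule:
        of = _quantize(onset, dt)
        if of < T:
            ace_eff.append((of, pole, float(ratio)))

    an_nuclear = np.zeros(T)
    an_cyto = np.zeros(T)
    clean = np.zeros((T, 2, H, W), dtype=float)
    for f in range(T):
        nucleus = nucleus_masks[f]
        band = band_masks[f]
        cyto = cell_masks[f] & ~nucleus & ~band
        a_band = float(band.sum())
        a_cyt = float(cyto.sum())
        base_band = m_an_mem / a_band

        active = [(pole, ratio) for of, pole, ratio in ace_eff if f >= of]
        pole_masks_f = {"front": pole_front[f], "rear": pole_rear[f]}
        pole_area = {p: float(pole_masks_f[p].sum()) for p, _ in active}
        sum_ap = sum(pole_area.values())
        sum_rap = sum(r * pole_area[p] for p, r in active)
        c_final = (m_an_cyt[f] + base_band * sum_ap) / (a_cyt + sum_rap)

        an_img = np.zeros((H, W))
        an_img[nucleus] = m_an_nuc[f] / float(nucleus.sum())
        an_img[cyto] = c_final
        an_img[band] = base_band
        for p, r in active:
            an_img[pole_masks_f[p]] = r * c_final

        nls_img = np.zeros((H, W))
        nls_img[nucleus] = nls_nuclear[f]
        nls_img[cyto_nls_masks[f]] = nls_cyto[f]

        clean[f, 0] = an_img
        clean[f, 1] = nls_img
        an_nuclear[f] = m_an_nuc[f] / float(nucleus.sum())
        an_cyto[f] = c_final

    # ---- camera noise (Poisson then Gaussian then offset, fixed order)
    poisson_scale, gaussian_sd, offset = config.noise_model
    rng = np.random.default_rng(config.seed)
    noisy = clean.copy()
    if poisson_scale > 0:
        noisy = rng.poisson(noisy * poisson_scale).astype(float) / poisson_scale
    if gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, gaussian_sd, size=noisy.shape)
    noisy = np.clip(noisy + offset, 0.0, None)

    stack = ImageStack(
        pixels=noisy,
        pixel_size_um=px,
        frame_interval_s=dt,
        channel_names=["anillin", "nls"],
    )

    # ---- event log and entry times (mask-derived, so analysis can match exactly)
    events: list[Event] = []
    front_cols = [np.nonzero(cell_masks[f].any(axis=0))[0] for f in range(T)]
    inside = [cols[cols >= entrance_col] for cols in front_cols]
    entry_start = next((f for f in range(T) if inside[f].size > 0), None)
    entry_complete = next(
        (f for f in range(T) if front_cols[f].size and front_cols[f].min() >= entrance_col),
        None,
    )
    entry_start_t = entry_start * dt if entry_start is not None else None
    entry_complete_t = entry_complete * dt if entry_complete is not None else None
    if entry_start is not None:
        events.append(Event("entry_start", entry_start_t, entry_start))
    if entry_complete is not None:
        events.append(Event("entry_complete", entry_complete_t, entry_complete))
    for r_t, p_t, rf, pf in eff:
        events.append(Event("rupture", r_t, rf))
        if pf is not None:
            events.append(Event("repair", p_t, pf))
    for of, pole, _ratio in ace_eff:
        events.append(Event(f"ace_onset_{pole}", of * dt, of, pole))
    if exit_time is not None:
        events.append(Event("anillin_nuclear_exit", exit_time, int(exit_time / dt)))

    truth = GroundTruth(
        cell_masks=cell_masks,
        nucleus_masks=nucleus_masks,
        band_masks=band_masks,
        pole_front_masks=pole_front,
        pole_rear_masks=pole_rear,
        events=sorted(events, key=lambda e: (e.time_s, e.frame)),
        entry_start_time_s=entry_start_t,
        entry_complete_time_s=entry_complete_t,
        track_um=track,
        true_nuclear_mean=nls_nuclear,
        true_cyto_mean=nls_cyto,
        true_nc_ratio=true_ratio,
        true_anillin_nuclear=an_nuclear,
        true_anillin_cyto=an_cyto,
        true_anillin_ratio=an_nuclear / an_cyto,
    )
    return stack, truth


def simulate_linescan_profile(
    segments: list[tuple[float, float, float]],
    baseline: float,
    total_length_um: float,
    sampling_um: float = 0.25,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[Linescan, list[tuple[float, float, float]]]:
    """Piecewise-constant membrane profile with annotated enriched segments.

    Each segment is (start_um, length_um, ratio): the profile equals
    ``baseline * ratio`` on [start, start + length) and ``baseline``
    elsewhere.  Segments must be non-overlapping and inside
    [0, total_length_um].  The annotation is returned verbatim.
    """
    if baseline <= 0 or total_length_um <= 0 or sampling_um <= 0:
        raise ValidationError("baseline, total length and sampling must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    segs = sorted((tuple(s) for s in segments), key=lambda s: s[0])
    prev_end = 0.0
    for start, length, ratio in segs:
        if start < 0 or length <= 0 or ratio <= 0:
            raise ValidationError("segment start/length/ratio must be valid")
        if start < prev_end:
            raise ValidationError("segments overlap")
        if start + length > total_length_um + 1e-9:
            raise ValidationError("segment exceeds total length")
        prev_end = start + length

    n = int(math.floor(total_length_um / sampling_um)) + 1
    positions = np.arange(n) * sampling_um
    values = np.full(n, float(baseline))
    for start, length, ratio in segs:
        inside = (positions >= start - 1e-12) & (positions < start + length - 1e-12)
        values[inside] = baseline * ratio
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sd, size=n), 0.0, None)
    return Linescan(positions, values), [tuple(s) for s in segments]


@dataclass
class TraceKinetics:
    """Kinetic parameters for trace-level rupture/repair simulation.

    The noise-free N/C ratio drops by ``drop_fraction`` (of its current
    value) at each rupture and recovers exponentially with
    ``recovery_halftime_s`` after repair.  The cytoplasmic mean rises as
    the ratio falls (``cyto_coupling`` sets the fractional rise at full
    drop), and the nuclear mean is ratio x cytoplasmic mean, so the two
    channels move in the opposite directions a rupture caller requires.
    """

    baseline_ratio: float = 5.0
    drop_fraction: float = 0.6
    recovery_halftime_s: float = 300.0
    cytoplasm_baseline: float = 50.0
    cyto_coupling: float = 0.5

    def __post_init__(self) -> None:
        if self.baseline_ratio <= 0 or self.cytoplasm_baseline <= 0:
            raise ValidationError("baselines must be positive")
        if not 0 < self.drop_fraction <= 1:
            raise ValidationError("drop_fraction must be in (0, 1]")
        if self.recovery_halftime_s <= 0:
            raise ValidationError("recovery_halftime_s must be positive")
        if self.cyto_coupling < 0:
            raise ValidationError("cyto_coupling must be >= 0")


def simulate_nc_trace(
    schedule: list[tuple[float, float | None]],
    kinetics: TraceKinetics | None = None,
    n_frames: int = 200,
    frame_interval_s: float = 108.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    cell_id: str = "cell0",
) -> tuple[NCTrace, dict]:
    """Simulate an N/C reporter trace with scheduled ruptures.

    ``noise_sd`` is the relative (fractional) Gaussian noise applied
    multiplicatively and independently to the nuclear and cytoplasmic
    means.  Returns the trace and a ground-truth dict with the noise-free
    ratio and the frame-quantised event list.
    """
    kinetics = kinetics or TraceKinetics()
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    dt = frame_interval_s
    times = np.arange(n_frames) * dt
    eff = _effective_schedule(schedule, dt, n_frames)
    ratio_true = _step_recovery_series(
        times, eff, kinetics.baseline_ratio, kinetics.drop_fraction,
        kinetics.recovery_halftime_s,
    )
    rel_drop = (kinetics.baseline_ratio - ratio_true) / kinetics.baseline_ratio
    cyto_true = kinetics.cytoplasm_baseline * (1.0 + kinetics.cyto_coupling * rel_drop)
    nuc_true = ratio_true * cyto_true

    nuc, cyt = nuc_true, cyto_true
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        nuc = nuc_true * (1.0 + rng.normal(0.0, noise_sd, size=n_frames))
        cyt = cyto_true * (1.0 + rng.normal(0.0, noise_sd, size=n_frames))
        nuc = np.clip(nuc, 0.0, None)
        cyt = np.clip(cyt, np.finfo(float).eps, None)

    events = []
    for r_t, p_t, rf, pf in eff:
        events.append(Event("rupture", r_t, rf))
        if pf is not None:
            events.append(Event("repair", p_t, pf))
    trace = NCTrace(cell_id=cell_id, times_s=times, nuclear_mean=nuc, cytoplasmic_mean=cyt)
    truth = {
        "ratio_true": ratio_true,
        "nuclear_true": nuc_true,
        "cyto_true": cyto_true,
        "events": events,
    }
    return trace, truth


def random_rupture_schedule(
    duration_s: float,
    rate_per_h: float,
    repair_delay_s: float = 540.0,
    min_gap_s: float = 1080.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Renewal-process rupture schedule with the requested long-run rate.

    Inter-rupture intervals are a dead time (repair delay + minimum gap)
    plus an exponential tail whose mean is chosen so the overall mean
    interval equals 1 / rate, keeping the realised hourly rate unbiased.
    """
    if rng is None:
        rng = np.random.default_rng()
    if rate_per_h <= 0 or duration_s <= 0:
        raise ValidationError("rate and duration must be positive")
    mean_gap = 3600.0 / rate_per_h
    dead = repair_delay_s + min_gap_s
    if mean_gap <= dead:
        raise ValidationError(
            f"rate {rate_per_h}/h incompatible with dead time {dead}s between ruptures"
        )
    schedule = []
    t = float(rng.exponential(mean_gap - dead))
    while t < duration_s:
        repair = t + repair_delay_s
        if repair >= duration_s:
            break
        schedule.append((t, repair))
        t = repair + min_gap_s + float(rng.exponential(mean_gap - dead))
    return schedule


def write_ground_truth(truth: GroundTruth, out_dir, cell_id: str = "cell0") -> dict:
    """Write the event table (CSV) and label masks (16-bit TIFF stacks).

    Mask encoding per frame: cell = 1, membrane band = 2, nucleus = 3,
    rear pole = 4, front pole = 5 (later labels overwrite earlier ones).
    Returns a manifest of written paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events_path = out / f"{cell_id}_events.csv"
    truth.event_table(cell_id).to_csv(events_path, index=False)

    T = truth.cell_masks.shape[0]
    labels = np.zeros(truth.cell_masks.shape, dtype=np.uint16)
    labels[truth.cell_masks] = 1
    labels[truth.band_masks] = 2
    labels[truth.nucleus_masks] = 3
    labels[truth.pole_rear_masks] = 4
    labels[truth.pole_front_masks] = 5
    masks_path = out / f"{cell_id}_labels.tif"
    tifffile.imwrite(str(masks_path), labels)

    trace_path = out / f"{cell_id}_true_trace.csv"
    pd.DataFrame(
        {
            "frame": np.arange(T),
            "true_nuclear_mean": truth.true_nuclear_mean,
            "true_cyto_mean": truth.true_cyto_mean,
            "true_nc_ratio": truth.true_nc_ratio,
            "true_anillin_ratio": truth.true_anillin_ratio,
        }
    ).to_csv(trace_path, index=False)
    return {
        "events": str(events_path),
        "labels": str(masks_path),
        "true_trace": str(trace_path),
    }
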