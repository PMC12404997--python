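"""Intensity-ratio scores and threshold classifiers.

Implements the ratio-based decision rules used to quantify anillin and NLS
reporter distributions:

* ACE (anillin-rich cell edge) detection on a membrane linescan: positive
  when at least ``min_length_um`` (default 5 µm) of contiguous membrane has
  anillin intensity at least ``ratio_threshold`` (default 2x) times the
  surrounding cytoplasmic reference — both thresholds inclusive;
* NLS cytoplasmic positivity: time-averaged N/C ratio <= 2.5;
* anillin cytoplasmic level: nuclear/cytoplasmic ratio <= 3 is "high"
  cytoplasmic anillin, >= 5 is "low", strictly between is "intermediate"
  (a label of this package; such cells are simply unclassified by the
  printed bounds);
* pMLC pole enrichment: pole mean over the cytoplasmic mean excluding the
  nucleus and both pole membranes.

All ratios are offset-sensitive: subtract the camera/background offset
(:func:`subtract_background`) before classifying.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import GeometryError, ValidationError
from .segment import LabeledMask

__all__ = [
    "Linescan",
    "ACECall",
    "extract_linescan",
    "detect_ace",
    "nc_ratio",
    "classify_nls_cytoplasmic_positive",
    "classify_membrane_anillin_positive",
    "classify_anillin_cyto_level",
    "pole_pmlc_ratio",
    "subtract_background",
    "select_z_plane",
    "NLS_CYTO_POSITIVE_MAX_NC",
    "ANILLIN_CYTO_HIGH_MAX_NC",
    "ANILLIN_CYTO_LOW_MIN_NC",
    "ACE_RATIO_THRESHOLD",
    "ACE_MIN_LENGTH_UM",
]

# Printed decision boundaries (all inclusive as printed: <=, >=).
NLS_CYTO_POSITIVE_MAX_NC = 2.5
ANILLIN_CYTO_HIGH_MAX_NC = 3.0
ANILLIN_CYTO_LOW_MIN_NC = 5.0
ACE_RATIO_THRESHOLD = 2.0
ACE_MIN_LENGTH_UM = 5.0


@dataclass
class Linescan:
    """Intensity profile sampled along a path, averaged across its width."""

    positions_um: np.ndarray
    intensities: np.ndarray
    width_px: int = 1

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions_um) < 2:
            raise ValidationError("a linescan needs at least 2 samples")
        if len(self.positions_um) != len(self.intensities):
            raise ValidationError("positions/intensities length mismatch")
        if not np.all(np.diff(self.positions_um) > 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")
        if self.width_px < 1:
            raise ValidationError("width_px must be >= 1")

    @property
    def sampling_um(self) -> float:
        return float(np.median(np.diff(self.positions_um)))

    def __len__(self) -> int:
        return len(self.positions_um)


@dataclass
class ACECall:
    """Outcome of ACE scoring on one linescan.

    ``segments`` lists qualifying runs as (start_um, end_um, mean_ratio)
    with the half-open convention end = last qualifying sample + one
    sampling step, so end - start is the run length.
    """

    positive: bool
    segments: list[tuple[float, float, float]] = field(default_factory=list)
    ratio_threshold: float = ACE_RATIO_THRESHOLD
    min_length_um: float = ACE_MIN_LENGTH_UM
    cytoplasm_reference: float = float("nan")

    def __post_init__(self) -> None:
        if self.positive != bool(self.segments):
            raise ValidationError("positive flag must match segment presence")
        for start, end, mean_ratio in self.segments:
            if end - start < self.min_length_um - 1e-9:
                raise ValidationError("reported segment shorter than min_length_um")
            if mean_ratio < self.ratio_threshold - 1e-9:
                raise ValidationError("reported segment mean ratio below threshold")

    @property
    def best_segment(self) -> tuple[float, float, float] | None:
        if not self.segments:
            return None
        return max(self.segments, key=lambda s: s[1] - s[0])


def extract_linescan(
    frame: np.ndarray,
    polyline_px: np.ndarray,
    width_px: int = 4,
    pixel_size_um: float = 1.0,
    step_px: float = 1.0,
) -> Linescan:
    """Sample a width-averaged intensity profile along a polyline.

    ``polyline_px`` is an ``(k, 2)`` array of (x, y) pixel coordinates.  The
    path is resampled at ``step_px`` arc-length intervals; at each sample
    ``width_px`` bilinear probes are taken perpendicular to the local path
    direction (1-px spacing, centred on the path) and averaged.  Any probe
    outside the image raises :class:`~confinequant.errors.GeometryError`.
    """
    frame = np.asarray(frame, dtype=float)
    poly = np.asarray(polyline_px, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
        raise ValidationError("polyline must be a (k, 2) array of (x, y) pixels")
    if width_px < 1:
        raise ValidationError("width_px must be >= 1")

    # resample the polyline at uniform arc length
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        keep = np.concatenate([[True], seg_len > 0])
        poly = poly[keep]
        seg = np.diff(poly, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arclen[-1]
    if total <= 0:
        raise ValidationError("polyline has zero length")
    n_samples = int(np.floor(total / step_px)) + 1
    s = np.arange(n_samples) * step_px
    x = np.interp(s, arclen, poly[:, 0])
    y = np.interp(s, arclen, poly[:, 1])

    # local tangent by central differences, then unit normal
    tx = np.gradient(x)
    ty = np.gradient(y)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx = -ty / norm
    ny = tx / norm

    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    # probes: (width, n) coordinate grids
    px = x[np.newaxis, :] + offsets[:, np.newaxis] * nx[np.newaxis, :]
    py = y[np.newaxis, :] + offsets[:, np.newaxis] * ny[np.newaxis, :]
    h, w = frame.shape
    if px.min() < 0 or py.min() < 0 or px.max() > w - 1 or py.max() > h - 1:
        raise GeometryError("linescan probes exit the image bounds")
    # map_coordinates wants (row, col) = (y, x)
    values = ndi.map_coordinates(frame, [py.ravel(), px.ravel()], order=1, mode="nearest")
    profile = values.reshape(width_px, n_samples).mean(axis=0)
    return Linescan(s * pixel_size_um, profile, width_px=width_px)


def _runs(qualifying: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first_index, last_index) inclusive."""
    idx = np.flatnonzero(qualifying)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def detect_ace(
    profile: Linescan,
    cytoplasm_reference: float,
    ratio_threshold: float = ACE_RATIO_THRESHOLD,
    min_length_um: float = ACE_MIN_LENGTH_UM,
    statistic: str = "pointwise",
) -> ACECall:
    """Score a membrane linescan for an anillin-rich cell edge.

    With the default ``pointwise`` statistic a run qualifies when every
    sample is at or above ``ratio_threshold * cytoplasm_reference``; the
    ``mean`` alternative qualifies any contiguous window of at least
    ``min_length_um`` whose mean meets the threshold (overlapping windows
    are merged).  Run length follows the half-open convention: last minus
    first qualifying sample position plus one sampling step.  Both
    thresholds are inclusive.
    """
    if not cytoplasm_reference > 0:
        raise ValidationError(
            f"cytoplasm reference must be positive, got {cytoplasm_reference}"
        )
    pos = profile.positions_um
    inten = profile.intensities
    step = profile.sampling_um
    level = ratio_threshold * cytoplasm_reference

    if statistic == "pointwise":
        runs = _runs(inten >= level)
    elif statistic == "mean":
        runs = _mean_qualifying_runs(inten, pos, step, level, min_length_um)
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")

    segments = []
    for first, last in runs:
        length = pos[last] - pos[first] + step
        if length >= min_length_um - 1e-12:
            mean_ratio = float(inten[first : last + 1].mean() / cytoplasm_reference)
            segments.append((float(pos[first]), float(pos[first] + length), mean_ratio))
    return ACECall(
        positive=bool(segments),
        segments=segments,
        ratio_threshold=ratio_threshold,
        min_length_um=min_length_um,
        cytoplasm_reference=float(cytoplasm_reference),
    )


def _mean_qualifying_runs(
    inten: np.ndarray, pos: np.ndarray, step: float, level: float, min_length_um: float
) -> list[tuple[int, int]]:
    """Union of all contiguous windows of length >= min_length_um whose mean
    is at or above level, merged into maximal runs."""
    n = len(inten)
    member = np.zeros(n, dtype=bool)
    csum = np.concatenate([[0.0], np.cumsum(inten)])
    for i in range(n):
        for j in range(i, n):
            length = pos[j] - pos[i] + step
            if length < min_length_um - 1e-12:
                continue
            mean = (csum[j + 1] - csum[i]) / (j - i + 1)
            if mean >= level:
                member[i : j + 1] = True
    return _runs(member)


def nc_ratio(nuclear_mean: float, cytoplasmic_mean: float) -> float:
    """Nuclear/cytoplasmic mean-intensity ratio; NaN when the denominator
    is at or below machine epsilon (undefined, not an error)."""
    if nuclear_mean < 0 or cytoplasmic_mean < 0:
        raise ValidationError("intensity means must be non-negative")
    if cytoplasmic_mean <= np.finfo(float).eps:
        return float("nan")
    return nuclear_mean / cytoplasmic_mean


def classify_nls_cytoplasmic_positive(
    trace, window: tuple[float, float] | None = None
) -> bool:
    """NLS positivity in the cytoplasm: time-averaged N/C ratio <= 2.5.

    ``trace`` is an :class:`~confinequant.events.NCTrace`; ``window`` is an
    optional (t_start_s, t_end_s) interval (inclusive ends).
    """
    times = trace.times_s
    ratios = np.asarray(trace.ratio, dtype=float)
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        ratios = ratios[sel]
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        raise ValidationError("no defined ratios in the requested window")
    return bool(ratios.mean() <= NLS_CYTO_POSITIVE_MAX_NC)


def classify_membrane_anillin_positive(
    positions_um: np.ndarray,
    intensities_over_time: np.ndarray,
    cytoplasm_reference_over_time: np.ndarray,
    ratio_threshold: float = ACE_RATIO_THRESHOLD,
    min_length_um: float = ACE_MIN_LENGTH_UM,
) -> ACECall:
    """Anillin membrane positivity from a time series of linescans.

    The per-position intensities (``T x n``) and the cytoplasmic reference
    (length ``T``) are each averaged over time, and the time-averaged
    profile is scored with :func:`detect_ace`.
    """
    inten = np.atleast_2d(np.asarray(intensities_over_time, dtype=float))
    ref = np.atleast_1d(np.asarray(cytoplasm_reference_over_time, dtype=float))
    if inten.shape[0] != ref.shape[0]:
        raise ValidationError("profile frames and reference frames differ in count")
    mean_profile = Linescan(np.asarray(positions_um, dtype=float), inten.mean(axis=0))
    return detect_ace(
        mean_profile,
        float(ref.mean()),
        ratio_threshold=ratio_threshold,
        min_length_um=min_length_um,
    )


def classify_anillin_cyto_level(anillin_nc_ratio: float) -> str:
    """Anillin cytoplasmic level from the anillin N/C ratio.

    A low N/C ratio means much of the anillin is cytoplasmic: <= 3 is
    ``high`` (cytoplasmic-high), >= 5 is ``low``, in between is
    ``intermediate``.
    """
    if not np.isfinite(anillin_nc_ratio):
        raise ValidationError("anillin N/C ratio is undefined")
    if anillin_nc_ratio <= ANILLIN_CYTO_HIGH_MAX_NC:
        return "high"
    if anillin_nc_ratio >= ANILLIN_CYTO_LOW_MIN_NC:
        return "low"
    return "intermediate"


def pole_pmlc_ratio(
    frame: np.ndarray,
    cell_mask: LabeledMask | np.ndarray,
    nucleus_mask: LabeledMask | np.ndarray,
    pole_front_mask: LabeledMask | np.ndarray,
    pole_rear_mask: LabeledMask | np.ndarray,
) -> tuple[float, float]:
    """Front and rear pole pMLC enrichment over the cytoplasmic reference.

    The reference is the mean over the cell excluding the nucleus and both
    pole membranes.
    """
    frame = np.asarray(frame, dtype=float)
    cell = _as_binary(cell_mask)
    nucleus = _as_binary(nucleus_mask)
    front = _as_binary(pole_front_mask)
    rear = _as_binary(pole_rear_mask)
    for name, m in [("nucleus", nucleus), ("pole_front", front), ("pole_rear", rear)]:
        if np.any(m & ~cell):
            raise ValidationError(f"{name} mask extends outside the cell mask")
    reference = cell & ~nucleus & ~front & ~rear
    if not reference.any():
        raise ValidationError("empty cytoplasmic reference region")
    if not front.any() or not rear.any():
        raise ValidationError("empty pole mask")
    ref_mean = float(frame[reference].mean())
    if ref_mean <= 0:
        raise ValidationError("non-positive cytoplasmic reference intensity")
    return (
        float(frame[front].mean()) / ref_mean,
        float(frame[rear].mean()) / ref_mean,
    )


def subtract_background(
    frame: np.ndarray,
    background_mask: np.ndarray | None = None,
    offset: float | None = None,
) -> np.ndarray:
    """Subtract the median of a background ROI (or a fixed camera offset),
    clipping at zero.  Ratios are offset-sensitive, so this must precede
    any ratio-based classification."""
    frame = np.asarray(frame, dtype=float)
    if (background_mask is None) == (offset is None):
        raise ValidationError("pass exactly one of background_mask or offset")
    if background_mask is not None:
        m = np.asarray(background_mask, bool)
        if not m.any():
            raise ValidationError("empty background ROI")
        offset = float(np.median(frame[m]))
    return np.clip(frame - offset, 0.0, None)


def select_z_plane(zstack: np.ndarray, band_mask: np.ndarray) -> int:
    """Index of the z plane with the strongest membrane-band mean signal."""
    zstack = np.asarray(zstack, dtype=float)
    band = _as_binary(band_mask)
    if zstack.ndim != 3:
        raise ValidationError("zstack must be (Z, Y, X)")
    if not band.any():
        raise ValidationError("empty membrane band")
    means = [float(plane[band].mean()) for plane in zstack]
    return int(np.argmax(means))


def _as_binary(mask) -> np.ndarray:
    if isinstance(mask, LabeledMask):
        return mask.binary()
    return np.asarray(mask) > 0
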