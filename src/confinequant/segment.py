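"""Nuclear/cell segmentation, membrane-band extraction and region intensities.

Segmentation here targets the synthetic and reporter-style images this
package quantifies: a bright nucleus over a dimmer cytoplasm over a dark
background.  The pipeline is intentionally classical — Gaussian smoothing,
(multi-)Otsu thresholding, hole filling and small-object removal — with
every knob exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import filters, morphology

from .errors import GeometryError, ValidationError

__all__ = [
    "LabeledMask",
    "SegmentationParams",
    "segment_nucleus",
    "extract_membrane_band",
    "region_intensity",
    "write_mask",
    "read_mask",
]

MASK_ROLES = ("cell", "nucleus", "membrane_band", "pole_front", "pole_rear", "cytoplasm_ref")


@dataclass
class LabeledMask:
    """Integer label image for one frame, with a named biological role.

    ``labels`` uses 0 for background; positive integers index objects.
    ``border_labels`` lists objects touching the image border (kept, but
    flagged so morphometry can exclude them).
    """

    labels: np.ndarray
    frame: int = 0
    role: str = "nucleus"
    border_labels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        if self.role not in MASK_ROLES:
            raise ValidationError(f"role {self.role!r} not in {MASK_ROLES}")

    @property
    def n_objects(self) -> int:
        labs = np.unique(self.labels)
        return int((labs > 0).sum())

    def binary(self, label: int | None = None) -> np.ndarray:
        """Boolean mask of one object, or of all foreground when label is None."""
        if label is None:
            return self.labels > 0
        return self.labels == label


@dataclass
class SegmentationParams:
    """Knobs for :func:`segment_nucleus`.

    smoothing_sigma_px : Gaussian pre-smoothing scale (pixels).
    min_area_um2 : objects smaller than this are removed.
    n_classes : intensity classes for multi-Otsu; the brightest class is
        taken as nuclear signal.  Falls back to plain Otsu when the image
        has too few distinct grey levels for the requested class count.
    """

    smoothing_sigma_px: float = 1.0
    min_area_um2: float = 10.0
    n_classes: int = 3


def segment_nucleus(
    frame: np.ndarray,
    pixel_size_um: float,
    params: SegmentationParams | None = None,
    frame_index: int = 0,
) -> LabeledMask:
    """Segment nuclei in a single nuclear-reporter frame.

    Returns one connected component per detected nucleus, holes filled,
    objects below the minimum area removed, border-touching objects
    flagged.  An all-background frame yields an empty mask with a warning
    (not an exception): a missing nucleus is a data condition, not a bug.
    """
    params = params or SegmentationParams()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValidationError(f"frame must be 2-D, got shape {frame.shape}")
    if not pixel_size_um > 0:
        raise ValidationError("pixel_size_um must be > 0")

    if not np.any(frame > 0) or np.ptp(frame) == 0:
        warnings.warn("segment_nucleus: frame has no contrast; returning empty mask")
        return LabeledMask(np.zeros(frame.shape, dtype=np.int32), frame_index, "nucleus")

    smoothed = ndi.gaussian_filter(frame, params.smoothing_sigma_px)
    binary = _threshold_brightest(smoothed, params.n_classes)
    binary = ndi.binary_fill_holes(binary)
    min_px = max(1, int(round(params.min_area_um2 / pixel_size_um**2)))
    binary = morphology.remove_small_objects(binary, max_size=min_px - 1)

    labels, _ = ndi.label(binary)
    border = np.zeros_like(binary)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_labels = tuple(int(v) for v in np.unique(labels[border]) if v > 0)
    return LabeledMask(labels.astype(np.int32), frame_index, "nucleus", border_labels)


def _threshold_brightest(img: np.ndarray, n_classes: int) -> np.ndarray:
    """Boolean mask of the brightest multi-Otsu class (Otsu fallback)."""
    if n_classes > 2 and np.unique(img).size > n_classes:
        try:
            thresholds = filters.threshold_multiotsu(img, classes=n_classes)
            return img > thresholds[-1]
        except ValueError:
            pass
    return img > filters.threshold_otsu(img)


def segment_cell(
    frame: np.ndarray,
    pixel_size_um: float,
    smoothing_sigma_px: float = 1.0,
    min_area_um2: float = 25.0,
    frame_index: int = 0,
) -> LabeledMask:
    """Segment whole cells (any signal over background) with plain Otsu."""
    frame = np.asarray(frame, dtype=float)
    if not np.any(frame > 0) or np.ptp(frame) == 0:
        warnings.warn("segment_cell: frame has no contrast; returning empty mask")
        return LabeledMask(np.zeros(frame.shape, dtype=np.int32), frame_index, "cell")
    smoothed = ndi.gaussian_filter(frame, smoothing_sigma_px)
    binary = smoothed > filters.threshold_otsu(smoothed)
    binary = ndi.binary_fill_holes(binary)
    min_px = max(1, int(round(min_area_um2 / pixel_size_um**2)))
    binary = morphology.remove_small_objects(binary, max_size=min_px - 1)
    labels, _ = ndi.label(binary)
    return LabeledMask(labels.astype(np.int32), frame_index, "cell")


def extract_membrane_band(
    cell_mask: LabeledMask, band_width_um: float, pixel_size_um: float
) -> LabeledMask:
    """Peripheral band of a cell mask: the mask minus its inward erosion.

    The band is a subset of the cell by construction.  If the erosion
    removes the whole object (band width at or beyond the half-width of the
    cell) the cell is degenerate for band analysis and a
    :class:`~confinequant.errors.GeometryError` is raised.
    """
    if cell_mask.n_objects != 1:
        raise ValidationError(
            f"extract_membrane_band needs exactly one object, got {cell_mask.n_objects}"
        )
    width_px = int(round(band_width_um / pixel_size_um))
    if width_px < 1:
        raise ValidationError(
            f"band width {band_width_um} µm is below one pixel ({pixel_size_um} µm)"
        )
    binary = cell_mask.binary()
    eroded = morphology.erosion(binary, morphology.disk(width_px))
    if not eroded.any():
        raise GeometryError(
            f"erosion by {band_width_um} µm ({width_px} px) eliminates the cell"
        )
    band = binary & ~eroded
    return LabeledMask(
        band.astype(np.int32), cell_mask.frame, "membrane_band", cell_mask.border_labels
    )


def region_intensity(
    frame: np.ndarray,
    mask: LabeledMask | np.ndarray,
    normalize_to_total_cell: bool = False,
    cell_mask: LabeledMask | np.ndarray | None = None,
) -> float:
    """Arithmetic mean intensity over the masked pixels.

    With ``normalize_to_total_cell=True`` the region mean is divided by the
    whole-cell mean, mirroring the convention of normalising region
    fluorescence to the total cell fluorescence; ``cell_mask`` then
    designates the whole cell (defaults to the region mask itself only if
    omitted, which is a normalisation of 1 — pass the cell explicitly).
    """
    frame = np.asarray(frame, dtype=float)
    binary = mask.binary() if isinstance(mask, LabeledMask) else np.asarray(mask, bool)
    if frame.shape != binary.shape:
        raise ValidationError(
            f"frame shape {frame.shape} != mask shape {binary.shape}"
        )
    if not binary.any():
        raise ValidationError("region_intensity: empty mask (segmentation failure?)")
    mean = float(frame[binary].mean())
    if not normalize_to_total_cell:
        return mean
    if cell_mask is None:
        cell_binary = binary
    else:
        cell_binary = (
            cell_mask.binary() if isinstance(cell_mask, LabeledMask) else np.asarray(cell_mask, bool)
        )
    if not cell_binary.any():
        raise ValidationError("region_intensity: empty cell mask")
    return mean / float(frame[cell_binary].mean())


def write_mask(path, mask: LabeledMask) -> None:
    """Write a label image as 16-bit TIFF."""
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValidationError("too many labels for 16-bit storage")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def read_mask(path, role: str = "nucleus", frame: int = 0) -> LabeledMask:
    labels = tifffile.imread(str(path)).astype(np.int32)
    return LabeledMask(labels, frame, role)
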