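"""Calibrated image-stack container and (OME-)TIFF input/output.

The canonical in-memory layout is ``T x C x Y x X`` (time, channel, row,
column).  Calibration — pixel size in micrometres and frame interval in
seconds — is mandatory: it either comes from OME metadata or must be passed
explicitly, never silently defaulted.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import CalibrationError, ValidationError

__all__ = ["ImageStack", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    """Multichannel time-lapse pixel data with physical calibration.

    Parameters
    ----------
    pixels
        Intensity array of shape ``(T, C, Y, X)``.
    pixel_size_um
        Edge length of one pixel in micrometres (> 0).
    frame_interval_s
        Time between consecutive frames in seconds (> 0).
    channel_names
        One unique label per channel, e.g. ``["anillin", "nls"]``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValidationError(
                f"pixels must be 4-D (T, C, Y, X), got shape {self.pixels.shape}"
            )
        if not self.pixel_size_um > 0:
            raise CalibrationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.frame_interval_s > 0:
            raise CalibrationError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.pixels.shape[1])]
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[1]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.pixels.shape

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(T, Y, X)`` sub-stack for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.pixels[:, idx]

    def times_s(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval_s


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack to OME-TIFF, embedding axes, calibration and channel names."""
    data = np.ascontiguousarray(stack.pixels)
    metadata = {
        "axes": "TCYX",
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "TimeIncrement": stack.frame_interval_s,
        "TimeIncrementUnit": "s",
        "Channel": {"Name": list(stack.channel_names)},
    }
    tifffile.imwrite(str(path), data, ome=True, metadata=metadata)


def _parse_ome(xml_text: str) -> dict:
    """Pull calibration and channel names out of an OME-XML block."""
    out: dict = {}
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return out
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return out
    if pixels.get("PhysicalSizeX") is not None:
        out["pixel_size_um"] = float(pixels.get("PhysicalSizeX"))
    if pixels.get("TimeIncrement") is not None:
        out["frame_interval_s"] = float(pixels.get("TimeIncrement"))
    names = [c.get("Name") for c in pixels.findall(f"{ns}Channel")]
    if names and all(n is not None for n in names):
        out["channel_names"] = names
    return out


def read_stack(
    path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_names: list[str] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into a ``T x C x Y x X`` :class:`ImageStack`.

    Calibration is taken from OME metadata when present; explicit arguments
    override it.  A plain TIFF with no calibration and no override raises
    :class:`~confinequant.errors.CalibrationError` rather than assuming a
    default.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta = _parse_ome(tf.ome_metadata) if tf.ome_metadata else {}

    data, axes = _normalize_axes(data, axes)

    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    names = channel_names if channel_names is not None else meta.get("channel_names")
    if px is None:
        raise CalibrationError(
            f"{path}: no pixel size in metadata; pass pixel_size_um explicitly"
        )
    if dt is None:
        raise CalibrationError(
            f"{path}: no frame interval in metadata; pass frame_interval_s explicitly"
        )
    return ImageStack(
        pixels=data,
        pixel_size_um=px,
        frame_interval_s=dt,
        channel_names=list(names) if names else [],
    )


def _normalize_axes(data: np.ndarray, axes: str) -> tuple[np.ndarray, str]:
    """Reorder/expand an array described by a tifffile axes string to TCYX."""
    axes = axes.upper().replace("S", "C")  # samples treated as channels
    if "Q" in axes and len(axes) == data.ndim:
        # tifffile labels unidentified axes 'Q'; a leading Q on a 3-D plain
        # TIFF stack is a time axis by convention here.
        axes = axes.replace("Q", "T", 1)
    for ax in ("Y", "X"):
        if ax not in axes:
            raise ValidationError(f"cannot locate {ax} axis in axes {axes!r}")
    for ax in ("T", "C"):
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    if sorted(axes) != sorted("TCYX"):
        raise ValidationError(f"unsupported axis layout {axes!r}; expected TCYX subset")
    order = [axes.index(ax) for ax in "TCYX"]
    return np.transpose(data, order), "TCYX"
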