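"""Reading, writing and elementary transforms of image stacks.

The canonical in-memory layout is a 4-D array ordered ``(T, C, Y, X)``:
frames, channels, rows, columns.  TIFF pages map to frames unless OME
metadata declares another axis order.  Physical pixel size is carried in
nanometres, either from OME metadata or from a JSON sidecar written next
to the file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "TimeStack",
    "Image2D",
    "read_stack",
    "write_stack",
    "invert_intensity",
]


class LayoutError(ValueError):
    """Raised when the axis layout of a file cannot be determined."""


@dataclass
class TimeStack:
    """A ``(T, C, Y, X)`` fluorescence time stack with pixel-size metadata.

    Parameters
    ----------
    data : ndarray
        4-D intensity array ordered (frame, channel, row, col).  Finite,
        non-negative values are expected for fluorescence data.
    pixel_size_nm : float, optional
        Physical size of one pixel in nanometres.
    channel_names : list of str, optional
        One name per channel; defaults to ``["ch0", "ch1", ...]``.
    """

    data: np.ndarray
    pixel_size_nm: float | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"TimeStack data must be 4-D (T, C, Y, X), got {self.data.ndim}-D")
        if self.data.shape[0] < 1:
            raise ValueError("TimeStack needs at least one frame")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("TimeStack intensities must be finite (no NaN/Inf)")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match the channel axis")

    @property
    def frame_count(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def frame(self, t: int, channel: int = 0) -> "Image2D":
        """A single frame of a single channel as an :class:`Image2D`."""
        return Image2D(self.data[t, channel], pixel_size_nm=self.pixel_size_nm)


@dataclass
class Image2D:
    """A single 2-D intensity image with optional physical pixel size."""

    data: np.ndarray
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"Image2D data must be 2-D, got {self.data.ndim}-D")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("Image2D must have positive extent")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("Image2D intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _axes_to_tcyx(data: np.ndarray, axes: str | None, layout_hint: str | None) -> np.ndarray:
    """Normalize an up-to-4-D array to (T, C, Y, X)."""
    if data.ndim > 4:
        raise LayoutError(f"cannot normalize {data.ndim}-D data to (T, C, Y, X)")
    order = layout_hint or axes
    if order is not None:
        order = order.upper().replace("S", "C").replace("Z", "T").replace("Q", "T")
        if len(order) != data.ndim or set(order) - set("TCYX") or len(set(order)) != len(order):
            raise LayoutError(f"ambiguous axis layout {order!r} for {data.ndim}-D data")
        # insert missing axes at length 1, then transpose to TCYX
        for ax in "TCYX":
            if ax not in order:
                data = data[np.newaxis]
                order = ax + order
        perm = [order.index(ax) for ax in "TCYX"]
        return data.transpose(perm)
    # no metadata: pages are frames
    if data.ndim == 2:
        return data[np.newaxis, np.newaxis]
    if data.ndim == 3:
        return data[:, np.newaxis]
    raise LayoutError("4-D file without axis metadata; pass layout_hint (e.g. 'TCYX')")


def read_stack(path: str | Path, layout_hint: str | None = None) -> TimeStack:
    """Read a TIFF/OME-TIFF file into a :class:`TimeStack`.

    Axes are normalized to (T, C, Y, X); missing axes are inserted with
    length 1.  Pixel size is taken from OME metadata when present,
    otherwise from a ``<file>.meta.json`` sidecar.

    Parameters
    ----------
    path : path-like
        TIFF or OME-TIFF file with 2--4 dimensions.
    layout_hint : str, optional
        Axis-order string such as ``"TCYX"`` or ``"CYX"``; overrides
        file metadata and is required for 4-D files without metadata.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            pixel_size_nm = None
            if tif.ome_metadata:
                try:
                    import xml.etree.ElementTree as ET

                    root = ET.fromstring(tif.ome_metadata)
                    for el in root.iter():
                        if el.tag.endswith("Pixels") and "PhysicalSizeX" in el.attrib:
                            unit = el.attrib.get("PhysicalSizeXUnit", "µm")
                            scale = {"nm": 1.0, "µm": 1000.0, "um": 1000.0}.get(unit, 1000.0)
                            pixel_size_nm = float(el.attrib["PhysicalSizeX"]) * scale
                            break
                except Exception:
                    pixel_size_nm = None
    except FileNotFoundError:
        raise
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"could not read image stack from {path}: {exc}") from exc

    if not np.all(np.isfinite(np.asarray(data, dtype=float))):
        raise ValueError(f"{path} contains non-finite intensities")

    if pixel_size_nm is None and _sidecar_path(path).exists():
        meta = json.loads(_sidecar_path(path).read_text())
        pixel_size_nm = meta.get("pixel_size_nm")

    arr = _axes_to_tcyx(np.asarray(data), axes if axes else None, layout_hint)
    return TimeStack(arr, pixel_size_nm=pixel_size_nm)


def write_stack(stack: TimeStack, path: str | Path) -> None:
    """Write a :class:`TimeStack` as OME-TIFF (lossless for integer data).

    Pixel size is stored in the OME metadata and mirrored into a JSON
    sidecar so plain-TIFF readers can recover it.
    """
    path = Path(path)
    metadata: dict = {"axes": "TCYX"}
    if stack.pixel_size_nm is not None:
        metadata["PhysicalSizeX"] = stack.pixel_size_nm
        metadata["PhysicalSizeXUnit"] = "nm"
        metadata["PhysicalSizeY"] = stack.pixel_size_nm
        metadata["PhysicalSizeYUnit"] = "nm"
    try:
        tifffile.imwrite(path, stack.data, metadata=metadata, ome=True)
    except (OSError, PermissionError) as exc:
        raise OSError(f"could not write image stack to {path}: {exc}") from exc
    if stack.pixel_size_nm is not None:
        _sidecar_path(path).write_text(json.dumps({"pixel_size_nm": stack.pixel_size_nm}))


def invert_intensity(image: Image2D) -> Image2D:
    """Invert intensities the way ImageJ's Invert does.

    For an integer image of dtype maximum ``m`` the output is ``m - input``
    (pixel value 0 becomes 255 in 8-bit).  For real-valued input the
    per-image maximum replaces the dtype maximum, so double inversion
    restores the original image.
    """
    data = image.data
    if np.issubdtype(data.dtype, np.integer):
        m = np.iinfo(data.dtype).max
        out = (m - data).astype(data.dtype)
    else:
        out = data.max() - data
    return Image2D(out, pixel_size_nm=image.pixel_size_nm)
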