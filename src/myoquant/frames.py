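"""Multi-channel image frames and their on-disk TIFF representation.

A frame is a small container mapping channel names (e.g. ``"dapi"``,
``"tubulin"``, ``"myhc"``) to 2-D intensity rasters of identical shape,
plus acquisition metadata (condition, dose, group, frame id) and an
optional physical pixel size in µm/px.  Frames round-trip through
multi-page TIFF with the channel names and metadata stored as JSON in
the image description, so a directory of frames is self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError


@dataclass
class ImageFrame:
    """One multi-channel raster with pixel-size and condition annotations."""

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None  # µm per pixel; None when uncalibrated
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if not shapes:
            raise ValidationError("frame must contain at least one channel")
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValidationError(f"channels must be 2-D rasters, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValidationError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if np.issubdtype(ch.dtype, np.floating) and np.nanmin(ch) < 0:
                raise ValidationError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def frame_id(self) -> str:
        return str(self.metadata.get("frame_id", ""))


def write_frame(frame: ImageFrame, path: str | Path) -> Path:
    """Write a frame as a multi-page TIFF (one page per channel)."""
    path = Path(path)
    names = list(frame.channels)
    desc = json.dumps(
        {
            "channels": names,
            "pixel_size_um": frame.pixel_size,
            "metadata": frame.metadata,
        }
    )
    stack = np.stack([frame.channels[n] for n in names])
    tifffile.imwrite(path, stack, description=desc)
    return path


def read_frame(path: str | Path) -> ImageFrame:
    """Read a frame written by :func:`write_frame`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    try:
        info = json.loads(desc)
        names = info["channels"]
        pixel_size = info.get("pixel_size_um")
        metadata = info.get("metadata", {})
    except (json.JSONDecodeError, KeyError, TypeError):
        # Foreign TIFF: fall back to positional channel names.
        if stack.ndim == 2:
            stack = stack[None]
        names = [f"ch{i}" for i in range(stack.shape[0])]
        pixel_size, metadata = None, {}
    if stack.ndim == 2:
        stack = stack[None]
    channels = {n: stack[i] for i, n in enumerate(names)}
    return ImageFrame(channels=channels, pixel_size=pixel_size, metadata=metadata)
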