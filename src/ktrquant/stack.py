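"""5D image stacks (t, c, z, y, x) and their TIFF + sidecar persistence.

The on-disk convention is a multi-page TIFF holding the full 5D array
(axes flattened in t, c, z order) next to a plain-text sidecar
``<stem>.meta.txt`` of ``key=value`` lines carrying the physical metadata
(pixel size, frame interval, axes, shape, channel names and, optionally,
explicit frame times in minutes for non-uniform acquisition schedules).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "write_stack", "read_stack"]

#: channel index conventions used throughout the package
CH_REPORTER = 0
CH_NUCLEAR = 1


@dataclass
class ImageStack:
    """A fluorescence time-lapse: ``data[t, c, z, y, x]`` plus metadata.

    By convention channel 0 is the KTR reporter (cytoplasmic when the
    kinase is active, nuclear when inactive) and channel 1 the nuclear
    marker used for segmentation.

    Parameters
    ----------
    data:
        Nonnegative, finite 5D array.
    pixel_size_um:
        Lateral pixel size in micrometres.
    frame_interval_s:
        Nominal time between frames in seconds.
    channel_names:
        One name per channel.
    frame_times_min:
        Optional explicit per-frame times in minutes (e.g. an imaging
        schedule with pre-wound, early post-wound and late epochs).
        When absent, frames are assumed uniformly spaced at
        ``frame_interval_s``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: tuple[str, ...] = ("reporter", "nuclear")
    frame_times_min: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 5:
            raise ValueError(f"expected 5D (t,c,z,y,x) data, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all axis lengths must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("stack contains negative intensities")
        if not (self.pixel_size_um > 0 and np.isfinite(self.pixel_size_um)):
            raise ValueError("pixel_size_um must be positive")
        if not (self.frame_interval_s > 0 and np.isfinite(self.frame_interval_s)):
            raise ValueError("frame_interval_s must be positive")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("one channel name per channel required")
        if self.frame_times_min is not None:
            self.frame_times_min = np.asarray(self.frame_times_min, dtype=float)
            if self.frame_times_min.shape != (self.data.shape[0],):
                raise ValueError("frame_times_min must have one entry per frame")
            if np.any(np.diff(self.frame_times_min) <= 0):
                raise ValueError("frame_times_min must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def times_min(self) -> np.ndarray:
        """Frame times in minutes (explicit schedule or uniform grid)."""
        if self.frame_times_min is not None:
            return self.frame_times_min
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0

    def copy(self) -> "ImageStack":
        return ImageStack(
            data=self.data.copy(),
            pixel_size_um=self.pixel_size_um,
            frame_interval_s=self.frame_interval_s,
            channel_names=tuple(self.channel_names),
            frame_times_min=None if self.frame_times_min is None else self.frame_times_min.copy(),
        )


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.parent / (tiff_path.stem + ".meta.txt")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write ``stack`` as float32 TIFF plus a ``key=value`` sidecar.

    Returns the sidecar path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    side = _sidecar_path(path)
    lines = [
        "axes=TCZYX",
        "shape=" + ",".join(str(s) for s in stack.data.shape),
        f"pixel_size_um={float(stack.pixel_size_um)!r}",
        f"frame_interval_s={float(stack.frame_interval_s)!r}",
        "channel_names=" + ",".join(stack.channel_names),
    ]
    if stack.frame_times_min is not None:
        lines.append("frame_times_min=" + ",".join(repr(float(t)) for t in stack.frame_times_min))
    side.write_text("\n".join(lines) + "\n")
    return side


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (or any TCZYX TIFF with
    a conforming sidecar)."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {side}")
    meta: dict[str, str] = {}
    for line in side.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        meta[key.strip()] = value.strip()
    axes = meta.get("axes", "TCZYX").upper()
    if axes != "TCZYX":
        raise ValueError(f"unsupported axes declaration {axes!r}; expected TCZYX")
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    shape = tuple(int(s) for s in meta["shape"].split(","))
    data = data.reshape(shape)
    frame_times = None
    if "frame_times_min" in meta and meta["frame_times_min"]:
        frame_times = np.array([float(t) for t in meta["frame_times_min"].split(",")])
    return ImageStack(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        channel_names=tuple(meta.get("channel_names", "reporter,nuclear").split(",")),
        frame_times_min=frame_times,
    )
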