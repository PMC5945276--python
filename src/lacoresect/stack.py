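"""5-D image container and TIFF I/O.

Stacks are ordered (time, channel, z, y, x). Calibration metadata that TIFF
tags do not carry reliably (frame interval, z spacing, channel names) lives
in a YAML sidecar written next to the TIFF (``<stem>.meta.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["ImageStack", "write_stack", "read_stack"]


@dataclass
class ImageStack:
    """A two-channel fluorescence time-lapse Z-stack.

    ``data`` has axes (time, channel, z, y, x); intensities are camera
    counts and must be non-negative.
    """

    data: np.ndarray
    pixel_size_xy_um: float = 0.107
    z_spacing_um: float = 0.26
    frame_interval_min: float = 10.0
    channel_names: tuple[str, ...] = ("GFP", "mCherry")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"expected 5 axes (t, c, z, y, x), got {self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all axis sizes must be >= 1, got shape {self.data.shape}")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[1]} channels in data but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.frame_interval_min > 0:
            raise ValueError("frame_interval_min must be positive")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[2]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in {self.channel_names}"
            ) from None

    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml") if path.suffix == "" else path.with_name(
        path.stem + ".meta.yaml"
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus YAML sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32), metadata={"axes": "TCZYX"})
    meta = {
        "axes": "TCZYX",
        "shape": [int(s) for s in stack.data.shape],
        "pixel_size_xy_um": float(stack.pixel_size_xy_um),
        "z_spacing_um": float(stack.z_spacing_um),
        "frame_interval_min": float(stack.frame_interval_min),
        "channel_names": list(stack.channel_names),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (sidecar required)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    data = tifffile.imread(path)
    data = np.asarray(data).reshape(meta["shape"])
    return ImageStack(
        data=data,
        pixel_size_xy_um=meta["pixel_size_xy_um"],
        z_spacing_um=meta["z_spacing_um"],
        frame_interval_min=meta["frame_interval_min"],
        channel_names=tuple(meta["channel_names"]),
    )
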