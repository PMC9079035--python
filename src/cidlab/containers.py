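"""Shared data containers: image stacks and their on-disk representation.

Image stacks are stored as multi-page TIFF in TZCYX order (time, z, channel,
y, x), 16-bit unsigned, with a JSON sidecar carrying the physical metadata
(pixel size, z spacing, frame interval, channel names).  Coordinates are
0-based pixel indices with the origin at the top-left corner; z index 0 is
nearest the coverslip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack"]

SIDECAR_SUFFIX = ".json"


@dataclass
class ImageStack:
    """Two-channel 3D+time pixel array with acquisition metadata.

    ``pixels`` has shape (T, Z, C, Y, X) and an unsigned integer dtype.
    One channel holds the centromeric signal (e.g. ``CID-EGFP``), one the
    chromatin signal (e.g. ``His2Av-mRFP``).
    """

    pixels: np.ndarray
    pixel_size_um: float
    z_spacing_um: float
    frame_interval_s: float
    channel_names: tuple[str, ...] = ("CID-EGFP", "His2Av-mRFP")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ValueError(
                f"pixels must be 5D (T, Z, C, Y, X), got shape {self.pixels.shape}"
            )
        if self.pixels.shape[2] != len(self.channel_names):
            raise ValueError("channel axis length must match channel_names")
        if not np.issubdtype(self.pixels.dtype, np.unsignedinteger):
            raise ValueError("pixels must be an unsigned integer dtype")

    # -- axes ------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[3], self.pixels.shape[4]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """(T, Z, Y, X) view of one channel."""
        return self.pixels[:, :, self.channel_index(name), :, :]

    # -- I/O -------------------------------------------------------------
    def metadata_dict(self) -> dict:
        return {
            "axes": "TZCYX",
            "pixel_size_um": self.pixel_size_um,
            "z_spacing_um": self.z_spacing_um,
            "frame_interval_s": self.frame_interval_s,
            "channel_names": list(self.channel_names),
            "coordinate_convention": (
                "0-based pixel indices, origin top-left; z index 0 nearest "
                "the coverslip"
            ),
        }

    def save(self, path: str | Path) -> Path:
        """Write TIFF plus JSON sidecar; returns the TIFF path."""
        path = Path(path)
        tifffile.imwrite(path, self.pixels, metadata={"axes": "TZCYX"})
        sidecar = path.with_suffix(path.suffix + SIDECAR_SUFFIX)
        sidecar.write_text(json.dumps(self.metadata_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        pixels = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + SIDECAR_SUFFIX)
        meta = json.loads(sidecar.read_text())
        if pixels.ndim == 4:  # single-frame stack saved without T axis
            pixels = pixels[None]
        return cls(
            pixels=pixels,
            pixel_size_um=meta["pixel_size_um"],
            z_spacing_um=meta["z_spacing_um"],
            frame_interval_s=meta["frame_interval_s"],
            channel_names=tuple(meta["channel_names"]),
        )
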