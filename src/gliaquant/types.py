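"""Shared container types for multi-channel 3D microscopy volumes.

Arrays are stored in (z, y, x) axis order; the voxel size is given as
(x, y, z) in nanometres, matching the convention of microscope metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile


@dataclass
class ImageVolume:
    """A multi-channel 3D intensity volume with anisotropic voxel size.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"DAPI"``, ``"Fn14"``, ``"Iba1"``)
        to a 3D intensity array of shape (z, y, x). All channels must share
        one shape.
    voxel_size_nm
        Physical voxel pitch as (x, y, z) in nanometres; all entries > 0.
    region_mask
        Optional boolean volume restricting analysis to a region of
        interest (e.g. hippocampal CA1); same shape as the channels.
    """

    channels: dict[str, np.ndarray]
    voxel_size_nm: tuple[float, float, float]
    region_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size_nm}")
        if self.region_mask is not None and self.channels:
            shape = next(iter(shapes.values()))
            if self.region_mask.shape != shape:
                raise ValueError("region_mask shape must match channel shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        """Voxel pitch as (x, y, z) in micrometres."""
        x, y, z = self.voxel_size_nm
        return (x / 1000.0, y / 1000.0, z / 1000.0)

    @property
    def voxel_volume_um3(self) -> float:
        x, y, z = self.voxel_size_um
        return x * y * z

    def spacing_zyx_um(self) -> tuple[float, float, float]:
        """Voxel pitch reordered to array axis order (z, y, x), in μm."""
        x, y, z = self.voxel_size_um
        return (z, y, x)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not found; available: {sorted(self.channels)}"
            ) from None

    def write_tiff(self, path) -> None:
        """Write all channels as a CZYX TIFF stack with voxel-size metadata."""
        names = sorted(self.channels)
        stack = np.stack([np.asarray(self.channels[n]) for n in names])
        x_um, y_um, z_um = self.voxel_size_um
        tifffile.imwrite(
            path,
            stack,
            metadata={
                "axes": "CZYX",
                "channel_names": names,
                "spacing": z_um,
                "unit": "um",
            },
            resolution=(1.0 / x_um, 1.0 / y_um),
        )


def volume_from_tiff(path, channel_names: list[str],
                     voxel_size_nm: tuple[float, float, float]) -> ImageVolume:
    """Read a CZYX (or ZYX single-channel) TIFF stack into an ImageVolume."""
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[0] != len(channel_names):
        raise ValueError(
            f"{len(channel_names)} channel names for {arr.shape[0]} channels"
        )
    return ImageVolume(
        channels={n: arr[i] for i, n in enumerate(channel_names)},
        voxel_size_nm=voxel_size_nm,
    )
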