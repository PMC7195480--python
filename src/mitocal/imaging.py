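"""Multi-channel 3D image stacks with physical voxel sizes.

Stacks are (z, y, x) voxel grids, one grid per spectral channel.  Channel
roles follow the acquisition bands of two-photon cameleon imaging:
CFP (380-480 nm), YFP (500-540 nm) and RED (560-650 nm; angiogram and/or
amyloid-plaque label).  Physical voxel size (dz, dy, dx) in µm is mandatory
because all downstream geometry (size filters, distances, morphology) is
expressed in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack", "CFP", "YFP", "RED", "read_stack", "write_stack"]

CFP = "CFP"
YFP = "YFP"
RED = "RED"


@dataclass
class ImageStack:
    """Per-channel (z, y, x) intensity grids sharing one voxel geometry."""

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]  # (dz, dy, dx) in µm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {role: ch.shape for role, ch in self.channels.items()}
        if not shapes:
            raise ValueError("stack needs at least one channel")
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channels disagree in shape: {shapes}")
        if len(first) != 3:
            raise ValueError("channels must be 3D (z, y, x)")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive µm spacings")
        self.channels = {r: np.asarray(c, dtype=float) for r, c in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels

    def require_ratiometric(self) -> None:
        missing = {CFP, YFP} - set(self.channels)
        if missing:
            raise ValueError(f"ratiometric use requires CFP and YFP channels; missing {missing}")

    def with_channels(self, channels: dict[str, np.ndarray]) -> "ImageStack":
        """New stack with replaced channel data, same geometry and metadata."""
        merged = dict(self.channels)
        merged.update(channels)
        return ImageStack(merged, self.voxel_size, dict(self.metadata))

    def copy(self) -> "ImageStack":
        return ImageStack(
            {r: c.copy() for r, c in self.channels.items()},
            self.voxel_size,
            dict(self.metadata),
        )


def write_stack(stack: ImageStack, path) -> None:
    """Write as a (z, c, y, x) multi-page TIFF; channel order in metadata."""
    roles = sorted(stack.channels)
    arr = np.stack([stack.channels[r] for r in roles], axis=1).astype(np.float32)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        arr,
        imagej=False,
        photometric="minisblack",
        planarconfig="separate",
        metadata={"axes": "ZCYX", "channel_roles": roles, "voxel_size_um": [dz, dy, dx]},
    )


def read_stack(path, channel_roles: list[str] | None = None,
               voxel_size: tuple[float, float, float] | None = None) -> ImageStack:
    """Read a (z, c, y, x) TIFF written by :func:`write_stack`.

    For third-party TIFFs lacking embedded role/spacing metadata, pass
    ``channel_roles`` (order along the channel axis) and ``voxel_size``.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if channel_roles is None:
        channel_roles = meta.get("channel_roles")
        if channel_roles is None:
            raise ValueError("TIFF has no channel_roles metadata; pass channel_roles=")
    if voxel_size is None:
        vs = meta.get("voxel_size_um")
        if vs is None:
            raise ValueError("TIFF has no voxel_size metadata; pass voxel_size=")
        voxel_size = tuple(float(v) for v in vs)
    if arr.ndim == 3:
        arr = arr[:, None, :, :]
    channels = {role: arr[:, i].astype(float) for i, role in enumerate(channel_roles)}
    return ImageStack(channels, voxel_size)
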