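"""3D multichannel image stacks with physical voxel sizes.

Stacks are stored as ``(C, Z, Y, X)`` float arrays (single-channel data may
be 3D).  OME-TIFF round-tripping uses :mod:`tifffile`; axis order on disk is
``ZCYX`` with the physical voxel size recorded in the OME metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A 3D (or multichannel 4D) intensity array with voxel-size metadata.

    Parameters
    ----------
    voxels
        ``(Z, Y, X)`` or ``(C, Z, Y, X)`` array.
    voxel_size
        Physical voxel size in µm, ``(z, y, x)`` order, strictly positive.
    channel_names
        Unique channel labels; length must match the channel axis.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError("voxels must be 3D (Z,Y,X) or 4D (C,Z,Y,X)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive values")
        self.channel_names = tuple(self.channel_names)
        if self.voxels.ndim == 4:
            if len(self.channel_names) != self.voxels.shape[0]:
                raise ValueError("channel_names must match the channel axis")
        elif len(self.channel_names) > 1:
            raise ValueError("3D stack cannot carry multiple channel names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0] if self.voxels.ndim == 4 else 1

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape[-3:])

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D array for a named channel."""
        if self.voxels.ndim == 3:
            if self.channel_names and self.channel_names[0] == name:
                return self.voxels
            raise KeyError(name)
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(name) from None
        return self.voxels[idx]

    def single_channel(self, name: str) -> "ImageStack":
        return ImageStack(self.channel(name), self.voxel_size, (name,))

    # ------------------------------------------------------------------ I/O

    def save(self, path) -> None:
        """Write as OME-TIFF with ZCYX axes and voxel size metadata.

        Output is bit-reproducible: the OME UUID is derived from the pixel
        data and no timestamp is written.
        """
        import hashlib
        import uuid

        arr = self.voxels if self.voxels.ndim == 4 else self.voxels[None]
        zcyx = np.moveaxis(arr, 0, 1).astype(np.float32)
        digest = hashlib.sha256(zcyx.tobytes()).digest()
        stable_uuid = uuid.UUID(bytes=digest[:16], version=4)
        vz, vy, vx = self.voxel_size
        tifffile.imwrite(
            path,
            zcyx,
            ome=True,
            datetime=False,
            metadata={
                "UUID": f"urn:uuid:{stable_uuid}",
                "axes": "ZCYX",
                "PhysicalSizeZ": vz,
                "PhysicalSizeY": vy,
                "PhysicalSizeX": vx,
                "PhysicalSizeZUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeXUnit": "µm",
                "Channel": {"Name": list(self.channel_names) or None},
            },
        )

    @classmethod
    def load(cls, path) -> "ImageStack":
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            meta = tif.ome_metadata
        # normalize to (C, Z, Y, X)
        axes = axes.replace("S", "C")
        for ax in ("C", "Z"):
            if ax not in axes:
                data = data[None]
                axes = ax + axes
        order = [axes.index(ax) for ax in "CZYX"]
        data = np.transpose(data, order).astype(np.float64)
        voxel_size = (1.0, 1.0, 1.0)
        names: tuple[str, ...] = tuple(f"ch{i}" for i in range(data.shape[0]))
        if meta:
            voxel_size, names = _parse_ome(meta, data.shape[0], voxel_size, names)
        return cls(data, voxel_size, names)


def _parse_ome(meta: str, n_channels, voxel_size, names):
    """Best-effort extraction of voxel size and channel names from OME-XML."""
    import re

    def grab(attr):
        m = re.search(rf'{attr}="([\d.eE+-]+)"', meta)
        return float(m.group(1)) if m else None

    vz = grab("PhysicalSizeZ")
    vy = grab("PhysicalSizeY")
    vx = grab("PhysicalSizeX")
    if None not in (vz, vy, vx):
        voxel_size = (vz, vy, vx)
    chan = re.findall(r'<Channel[^>]*Name="([^"]*)"', meta)
    if len(chan) == n_channels:
        names = tuple(chan)
    return voxel_size, names


def save_ground_truth_json(truth, path) -> None:
    """Serialize a GroundTruth-like object (dataclass tree) to JSON."""
    from dataclasses import asdict, is_dataclass

    def default(obj):
        if is_dataclass(obj):
            return asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(type(obj))

    with open(path, "w") as fh:
        json.dump(truth, fh, default=default, indent=1)
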