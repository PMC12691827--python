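"""Reading, writing and projecting multi-channel confocal z-stacks.

Stacks are stored with axis order ``(z, y, x)``; channels are kept as
separate :class:`ImageStack` objects rather than a fourth axis, which avoids
axis-ordering ambiguity between TIFF writers.  Intensities are handled as
floating point internally regardless of the on-disk dtype and are never
rescaled on read.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "TwoChannelStack",
    "read_two_channel_stack",
    "write_two_channel_stack",
    "average_projection",
    "max_projection",
]


@dataclass(frozen=True)
class ImageStack:
    """A single-channel 3D fluorescence stack.

    Parameters
    ----------
    voxels:
        3D array of non-negative intensities, axis order ``(z, y, x)``,
        arbitrary fluorescence units.
    voxel_size:
        Physical voxel size ``(dz, dy, dx)`` in micrometres.
    channel_label:
        Free-text role of the channel (e.g. ``"vessel"`` or ``"tracer"``).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_label: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={vox.ndim}")
        if vox.shape[0] < 1 or 0 in vox.shape:
            raise ValueError(f"stack must have at least one voxel per axis, got shape {vox.shape}")
        if np.any(vox < 0):
            raise ValueError("intensities must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values (dz, dy, dx), got {self.voxel_size}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def pixel_size(self) -> tuple[float, float]:
        """In-plane pixel size ``(dy, dx)`` in µm."""
        return self.voxel_size[1], self.voxel_size[2]


@dataclass(frozen=True)
class TwoChannelStack:
    """A registered vessel-marker + tracer stack pair.

    The vessel channel carries the endothelium marker (GFP role), the tracer
    channel the cargo label (Cy3 role).  Both channels must share grid
    dimensions and voxel size.
    """

    vessel: ImageStack
    tracer: ImageStack

    def __post_init__(self) -> None:
        if self.vessel.shape != self.tracer.shape:
            raise ValueError(
                f"channel dimensions differ: vessel {self.vessel.shape} vs tracer {self.tracer.shape}"
            )
        if not np.allclose(self.vessel.voxel_size, self.tracer.voxel_size):
            raise ValueError(
                f"channel voxel sizes differ: {self.vessel.voxel_size} vs {self.tracer.voxel_size}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vessel.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.vessel.voxel_size


def _voxel_size_from_ome(ome_xml: str) -> tuple[float, float, float] | None:
    """Extract (dz, dy, dx) in µm from OME-XML Pixels attributes, if present."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if root.tag.startswith("{") else {}
    pixels = root.find(".//ome:Pixels", ns) if ns else root.find(".//Pixels")
    if pixels is None:
        return None
    try:
        dz = float(pixels.get("PhysicalSizeZ"))
        dy = float(pixels.get("PhysicalSizeY"))
        dx = float(pixels.get("PhysicalSizeX"))
    except (TypeError, ValueError):
        return None
    return (dz, dy, dx)


def _voxel_size_from_sidecar(path: Path) -> tuple[float, float, float] | None:
    """Look for ``<stem>.json`` next to the stack with a ``voxel_size_um`` entry."""
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        return None
    try:
        meta = json.loads(sidecar.read_text())
        vs = meta["voxel_size_um"]
        return (float(vs[0]), float(vs[1]), float(vs[2]))
    except (json.JSONDecodeError, KeyError, IndexError, TypeError, ValueError):
        logger.warning("sidecar %s present but unusable", sidecar)
        return None


def read_two_channel_stack(
    path: str | Path,
    channel_map: dict[int, str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> TwoChannelStack:
    """Read a multi-channel TIFF / OME-TIFF stack.

    Parameters
    ----------
    path:
        TIFF file with at least two channels, axes ``(C, Z, Y, X)``.
    channel_map:
        Mapping of channel index → role; exactly one index must map to
        ``"vessel"`` and one to ``"tracer"``.  Defaults to
        ``{0: "vessel", 1: "tracer"}``.
    voxel_size:
        Explicit ``(dz, dy, dx)`` in µm.  Precedence is explicit argument >
        file metadata > JSON sidecar; if none is available an error is raised
        (there is deliberately no silent 1 µm default).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if channel_map is None:
        channel_map = {0: "vessel", 1: "tracer"}
    roles = {role: idx for idx, role in channel_map.items()}
    for role in ("vessel", "tracer"):
        if role not in roles:
            raise ValueError(f"channel_map assigns no channel to role '{role}'")

    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        ome_xml = tif.ome_metadata

    # normalise to (C, Z, Y, X) using the axes string reported by the reader;
    # plain TIFFs without axis metadata are interpreted positionally
    if set(axes) <= {"C", "Z", "Y", "X"}:
        if "C" not in axes:
            raise ValueError(
                f"file has a single channel but channel_map requests roles {sorted(roles)}"
            )
        order = [ax for ax in ("C", "Z", "Y", "X") if ax in axes]
        data = np.moveaxis(data, [axes.index(ax) for ax in order], range(len(order)))
        if "Z" not in axes:
            data = data[:, None, :, :]
    elif data.ndim == 4:
        pass  # assume (C, Z, Y, X)
    elif data.ndim == 3:
        raise ValueError(
            f"file has a single channel but channel_map requests roles {sorted(roles)}"
        )
    else:
        raise ValueError(f"unsupported axis layout '{axes}' in {path}")
    n_channels = data.shape[0]
    for role, idx in roles.items():
        if idx >= n_channels:
            raise ValueError(
                f"role '{role}' mapped to channel {idx} but file has only {n_channels} channel(s)"
            )

    meta_vs = _voxel_size_from_ome(ome_xml) if ome_xml else None
    if meta_vs is None:
        meta_vs = _voxel_size_from_sidecar(path)
    if voxel_size is not None:
        if meta_vs is not None and not np.allclose(meta_vs, voxel_size):
            logger.info(
                "voxel size override %s replaces file metadata %s for %s",
                voxel_size, meta_vs, path,
            )
        vs = tuple(float(v) for v in voxel_size)
    elif meta_vs is not None:
        vs = meta_vs
    else:
        raise ValueError(
            f"no voxel size in metadata or sidecar for {path}; pass voxel_size explicitly"
        )

    vessel = ImageStack(data[roles["vessel"]], vs, channel_label="vessel")
    tracer = ImageStack(data[roles["tracer"]], vs, channel_label="tracer")
    return TwoChannelStack(vessel=vessel, tracer=tracer)


def write_two_channel_stack(stack: TwoChannelStack, path: str | Path) -> Path:
    """Write the stack as an OME-TIFF with voxel size in the metadata.

    Channel order on disk is (vessel, tracer); dtype is preserved if the
    voxel arrays share one, otherwise float32 is written.
    """
    path = Path(path)
    dz, dy, dx = stack.voxel_size
    data = np.stack([stack.vessel.voxels, stack.tracer.voxels])
    # keep integer dtypes intact for exact round trips
    if np.allclose(data, np.round(data)) and data.max() < 2**16 and data.min() >= 0:
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        # explicit photometric stops the writer from guessing a samples axis
        # on small stacks; singleton Z comes back as CYX and the reader
        # restores it
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def average_projection(stack: ImageStack) -> tuple[np.ndarray, tuple[float, float]]:
    """Average-intensity z-projection.

    Returns the 2D image (each pixel the arithmetic mean over z of its
    (y, x) column) together with the pixel size ``(dy, dx)`` in µm.
    """
    return stack.voxels.mean(axis=0), stack.pixel_size


def max_projection(stack: ImageStack) -> tuple[np.ndarray, tuple[float, float]]:
    """Maximum-intensity z-projection with pixel size ``(dy, dx)`` in µm.

    Used for morphometry: the maximum projection of a filled tube is a
    top-hat across the tube, so half-maximum crossings sit at the true tube
    borders, whereas the average projection of the same tube has a
    chord-length (semicircular) cross-section whose half-maximum width
    underestimates the diameter by a factor √3/2.
    """
    return stack.voxels.max(axis=0), stack.pixel_size
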