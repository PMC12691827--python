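"""Lumen-mask partitioning of tracer signal and day-normalized deltas.

The vessel channel is segmented into a binary vasculature mask; tracer
intensity is then averaged separately over voxels inside (intraluminal) and
outside (extravascular) the mask, slice by slice, and the per-slice means
are averaged across the stack.  Condition differences are expressed as

    Δ signal = signal(TF device) − mean(signal of control devices)

computed strictly within one measurement day, which removes day-to-day
drift in microscope intensity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import ImageStack, TwoChannelStack

logger = logging.getLogger(__name__)

__all__ = [
    "VesselMask",
    "SlicePartition",
    "StackPartition",
    "ConditionMeasurement",
    "DeltaSignal",
    "segment_vasculature",
    "partition_intensity",
    "delta_signal",
    "quantify_device",
]


@dataclass(frozen=True)
class VesselMask:
    """Binary per-voxel lumen segmentation with its provenance."""

    mask: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            raise ValueError(f"mask must be boolean, got dtype {m.dtype}")
        if m.ndim != 3:
            raise ValueError(f"mask must be 3D (z, y, x), got ndim {m.ndim}")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class SlicePartition:
    """Mean tracer intensity inside/outside the mask for one z-slice.

    A mean is ``nan`` (flagged undefined) when its compartment has no voxels
    in that slice.
    """

    z_index: int
    mean_in: float
    mean_out: float
    n_in: int
    n_out: int


@dataclass(frozen=True)
class StackPartition:
    """Per-slice partitions plus stack-level averages.

    ``stack_mean_in`` / ``stack_mean_out`` are unweighted means of the
    defined per-slice means; slices where a compartment is empty contribute
    no term (they are excluded rather than counted as zero).  ``pooled_*``
    are the alternative voxel-pooled means over the whole stack.
    """

    slices: tuple[SlicePartition, ...]
    stack_mean_in: float
    stack_mean_out: float
    pooled_mean_in: float
    pooled_mean_out: float


@dataclass(frozen=True)
class ConditionMeasurement:
    """One compartment-level intensity measurement for one device."""

    condition: str  # "TF" | "control"
    timepoint: str  # e.g. "30 min" | "24 h"
    device_id: str
    compartment: str  # "intraluminal" | "extravascular"
    value: float
    batch_day: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"intensity must be non-negative, got {self.value}")
        if self.compartment not in ("intraluminal", "extravascular"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class DeltaSignal:
    """Day-normalized TF-minus-control differences, one per TF device."""

    compartment: str
    timepoint: str
    deltas: tuple[float, ...]


def _structuring_element(radius_um: float, voxel_size: tuple[float, float, float]) -> np.ndarray | None:
    """Anisotropic ellipsoidal footprint for a physical radius in µm."""
    radii_vox = [radius_um / s for s in voxel_size]
    if all(r < 0.5 for r in radii_vox):
        return None
    half = [max(1, int(math.floor(r))) for r in radii_vox]
    zz, yy, xx = np.ogrid[
        -half[0]: half[0] + 1, -half[1]: half[1] + 1, -half[2]: half[2] + 1
    ]
    dz, dy, dx = voxel_size
    dist2 = (zz * dz) ** 2 + (yy * dy) ** 2 + (xx * dx) ** 2
    return dist2 <= radius_um**2 + 1e-9


def segment_vasculature(
    vessel: ImageStack,
    method: str = "global_otsu",
    fixed_threshold: float | None = None,
    min_object_volume: float = 100.0,
    closing_radius: float = 2.0,
) -> VesselMask:
    """Build the binary vasculature mask from the vessel channel.

    Parameters
    ----------
    vessel:
        Vessel-marker channel (GFP role).
    method:
        ``"global_otsu"`` (one Otsu threshold over the whole stack, default),
        ``"per_slice_otsu"`` (a threshold per z-slice), or
        ``"fixed_threshold"`` (requires *fixed_threshold*).  Voxels with
        intensity strictly above the threshold are in the mask.
    min_object_volume:
        Connected components smaller than this volume (µm³) are removed.
    closing_radius:
        Radius (µm) of the morphological closing applied after thresholding;
        0 disables it.
    """
    vox = vessel.voxels
    if method in ("global_otsu", "per_slice_otsu"):
        if np.ptp(vox) == 0:
            raise ValueError("no threshold separable: vessel channel has constant intensity")
    if method == "global_otsu":
        thr = float(threshold_otsu(vox))
        mask = vox > thr
        thresholds: float | list[float] = thr
    elif method == "per_slice_otsu":
        thresholds = []
        mask = np.empty(vox.shape, dtype=bool)
        for z in range(vox.shape[0]):
            sl = vox[z]
            if np.ptp(sl) == 0:
                # degenerate slice: fall back to the global threshold
                thr = float(threshold_otsu(vox))
            else:
                thr = float(threshold_otsu(sl))
            mask[z] = sl > thr
            thresholds.append(thr)
    elif method == "fixed_threshold":
        if fixed_threshold is None:
            raise ValueError("method 'fixed_threshold' requires fixed_threshold")
        thr = float(fixed_threshold)
        mask = vox > thr
        thresholds = thr
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    if closing_radius > 0:
        selem = _structuring_element(closing_radius, vessel.voxel_size)
        if selem is not None:
            # pad with the edge values so vessels touching the stack border
            # are not eroded by the closing
            pad = [(s // 2,) * 2 for s in selem.shape]
            padded = np.pad(mask, pad, mode="edge")
            closed = ndimage.binary_closing(padded, structure=selem)
            sl = tuple(slice(p[0], d + p[0]) for p, d in zip(pad, mask.shape))
            mask = closed[sl]

    voxel_volume = float(np.prod(vessel.voxel_size))
    min_voxels = int(math.ceil(min_object_volume / voxel_volume))
    if min_voxels > 1 and mask.any():
        labels, n_labels = ndimage.label(mask)
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_voxels)
        small = small[small > 0]  # label 0 is background
        if small.size:
            mask &= ~np.isin(labels, small)

    if not mask.any():
        logger.warning("vasculature mask is empty after cleanup")

    provenance = {
        "method": method,
        "threshold": thresholds,
        "min_object_volume_um3": min_object_volume,
        "closing_radius_um": closing_radius,
        "channel_label": vessel.channel_label,
    }
    return VesselMask(mask=mask, provenance=provenance)


def partition_intensity(tracer: ImageStack, mask: VesselMask) -> StackPartition:
    """Average tracer intensity inside vs outside the mask, per slice and overall."""
    if tracer.shape != mask.shape:
        raise ValueError(f"dimension mismatch: tracer {tracer.shape} vs mask {mask.shape}")
    vox = tracer.voxels
    m = mask.mask
    slices = []
    for z in range(vox.shape[0]):
        inside = vox[z][m[z]]
        outside = vox[z][~m[z]]
        slices.append(
            SlicePartition(
                z_index=z,
                mean_in=float(inside.mean()) if inside.size else float("nan"),
                mean_out=float(outside.mean()) if outside.size else float("nan"),
                n_in=int(inside.size),
                n_out=int(outside.size),
            )
        )
    means_in = [s.mean_in for s in slices if s.n_in > 0]
    means_out = [s.mean_out for s in slices if s.n_out > 0]
    return StackPartition(
        slices=tuple(slices),
        stack_mean_in=float(np.mean(means_in)) if means_in else float("nan"),
        stack_mean_out=float(np.mean(means_out)) if means_out else float("nan"),
        pooled_mean_in=float(vox[m].mean()) if m.any() else float("nan"),
        pooled_mean_out=float(vox[~m].mean()) if (~m).any() else float("nan"),
    )


def delta_signal(
    tf: list[ConditionMeasurement], control: list[ConditionMeasurement]
) -> DeltaSignal:
    """Day-normalized condition difference.

    For each TF measurement ``v`` the delta is ``v − mean(control values)``.
    All measurements must share compartment, timepoint and batch day: the
    normalization is meaningful only within one measurement day.
    """
    if not control:
        raise ValueError("control measurements must be non-empty")
    if not tf:
        raise ValueError("TF measurements must be non-empty")
    keys = {(m.compartment, m.timepoint, m.batch_day) for m in tf + control}
    if len(keys) != 1:
        raise ValueError(
            f"measurements mix compartments/timepoints/batch days: {sorted(keys)}"
        )
    control_mean = float(np.mean([m.value for m in control]))
    deltas = tuple(m.value - control_mean for m in tf)
    compartment, timepoint, _ = next(iter(keys))
    return DeltaSignal(compartment=compartment, timepoint=timepoint, deltas=deltas)


def quantify_device(
    stack: TwoChannelStack,
    condition: str = "",
    timepoint: str = "",
    device_id: str = "",
    batch_day: str = "",
    use_pooled: bool = False,
    **segmentation_params,
) -> tuple[ConditionMeasurement, ConditionMeasurement, VesselMask, StackPartition]:
    """Segment the vessel channel, partition the tracer channel.

    Returns the (intraluminal, extravascular) measurements plus the mask and
    full partition for auditing.  The mask is always computed from the
    vessel channel; swapping channels at the call site is only detectable
    through the mask provenance, so callers should audit the exported mask.
    """
    mask = segment_vasculature(stack.vessel, **segmentation_params)
    part = partition_intensity(stack.tracer, mask)
    mean_in = part.pooled_mean_in if use_pooled else part.stack_mean_in
    mean_out = part.pooled_mean_out if use_pooled else part.stack_mean_out
    common = dict(condition=condition, timepoint=timepoint, device_id=device_id, batch_day=batch_day)
    intraluminal = ConditionMeasurement(compartment="intraluminal", value=mean_in, **common)
    extravascular = ConditionMeasurement(compartment="extravascular", value=mean_out, **common)
    return intraluminal, extravascular, mask, part
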