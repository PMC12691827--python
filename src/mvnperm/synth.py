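"""Synthetic two-channel confocal phantoms with known ground truth.

The forward model emulates the structure of the real experiment: tubular
vessels embedded in a gel, a vessel-marker channel that is bright inside
the tubes, and a tracer channel that is bright intraluminally and decays
approximately linearly with distance from the vessel surface — the pattern
the distance-profile analysis is designed to recover.  Optics and detection
are modelled as a Gaussian PSF blur followed by Poisson shot noise and
additive Gaussian read noise.  Every generated artifact is a pure function
of its parameters and seed.

The default experiment design encodes the biological pattern under study:
transferrin-functionalized (TF) and control liposomes behave similarly
shortly after perfusion, while at 24 h the control tracer falls off several
times more steeply with distance from the lumen than the TF tracer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ImageStack, TwoChannelStack
from .lumen import VesselMask

__all__ = [
    "Tube",
    "SyntheticScene",
    "ExperimentDesign",
    "default_scene",
    "render_scene",
    "analytic_profile",
    "make_experiment",
    "make_assay_fixture",
    "default_design",
]


@dataclass(frozen=True)
class Tube:
    """A tubular vessel: a polyline centerline (µm, (z, y, x) points) and radius (µm)."""

    centerline: tuple[tuple[float, float, float], ...]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("tube radius must be positive")
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least two points")


@dataclass(frozen=True)
class SyntheticScene:
    """Full generative description of one two-channel phantom.

    ``tracer_profile`` is ``(a, b, floor)``: the extravascular tracer at
    distance d µm from the vessel surface is
    ``max(floor, tracer_luminal · (a + b·d))`` with 0 < a ≤ 1 the fractional
    intensity at the wall, b ≤ 0 the per-µm decay slope, and ``floor`` an
    absolute background level (a.u.).  ``noise`` is
    ``(gaussian_sd, poisson_scale)``: detected value =
    Poisson(value·poisson_scale)/poisson_scale + N(0, gaussian_sd), clipped
    at zero.  ``poisson_scale = 0`` disables shot noise.
    """

    shape: tuple[int, int, int] = (16, 256, 256)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)  # µm
    tubes: tuple[Tube, ...] = ()
    vessel_intensity: float = 1000.0
    tracer_luminal: float = 1000.0
    tracer_profile: tuple[float, float, float] = (0.9, -0.002, 20.0)  # (a, b /µm, floor a.u.)
    psf_sigma: float = 1.0  # µm
    noise: tuple[float, float] = (10.0, 1.0)  # (gaussian_sd a.u., poisson_scale)
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, floor = self.tracer_profile
        if not 0 < a <= 1:
            raise ValueError("tracer profile intercept a must be in (0, 1]")
        if b > 0:
            raise ValueError("tracer profile slope b must be ≤ 0")
        if floor < 0:
            raise ValueError("tracer floor must be ≥ 0")
        extent = tuple(n * s for n, s in zip(self.shape, self.voxel_size))
        for tube in self.tubes:
            for pt in tube.centerline:
                if any(not 0 <= c <= e for c, e in zip(pt, extent)):
                    raise ValueError(f"tube centerline point {pt} lies outside ROI extent {extent}")

    @property
    def roi_size(self) -> tuple[float, float, float]:
        """Physical ROI extent (µm) in (z, y, x)."""
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size))


def default_scene(seed: int = 0, **overrides) -> SyntheticScene:
    """A single straight tube spanning the ROI at mid-depth, mid-height."""
    base = SyntheticScene(seed=seed, **overrides)
    nz, ny, nx = base.shape
    dz, dy, dx = base.voxel_size
    zc, yc = nz * dz / 2, ny * dy / 2
    tube = Tube(centerline=((zc, yc, 0.0), (zc, yc, nx * dx)), radius=15.0)
    return replace(base, tubes=(tube,))


def _tube_fields(scene: SyntheticScene) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel tube geometry fields.

    Returns ``(surface_distance, inside, occupancy)``: the Euclidean
    distance (µm, ≥ 0) from the voxel centre to the nearest tube surface,
    the hard inside-any-tube mask (centre within a tube), and the fractional
    voxel occupancy.  Occupancy ramps linearly from 1 to 0 across one voxel
    centred on the tube surface — the partial-volume effect of sampling a
    sharp boundary on a finite grid — so that intensity edges in the ideal
    images sit at the true surface rather than at the nearest voxel centre.
    """
    nz, ny, nx = scene.shape
    surf_signed = np.full(scene.shape, np.inf)
    dz, dy, dx = scene.voxel_size
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    for tube in scene.tubes:
        cl = np.asarray(tube.centerline, dtype=float)
        d_axis = np.full(scene.shape, np.inf)
        for p0, p1 in zip(cl[:-1], cl[1:]):
            seg = p1 - p0
            seg_len2 = float(seg @ seg)
            if seg_len2 == 0:
                d = np.linalg.norm(pts - p0, axis=-1)
            else:
                t = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0)
                proj = p0 + t[..., None] * seg
                d = np.linalg.norm(pts - proj, axis=-1)
            d_axis = np.minimum(d_axis, d)
        surf_signed = np.minimum(surf_signed, d_axis - tube.radius)
    inside = surf_signed <= 0
    ramp = min(scene.voxel_size)
    occupancy = np.clip(0.5 - surf_signed / ramp, 0.0, 1.0)
    return np.maximum(surf_signed, 0.0), inside, occupancy


def render_scene(scene: SyntheticScene) -> tuple[TwoChannelStack, VesselMask]:
    """Render the phantom: ideal channels, PSF blur, shot + read noise.

    Returns the noisy two-channel stack and the ground-truth vessel mask
    (pre-blur voxels whose centre lies inside a tube).
    """
    from scipy.ndimage import gaussian_filter

    if not scene.tubes:
        raise ValueError("scene has no tubes")
    a, b, floor = scene.tracer_profile
    surf_dist, inside, occupancy = _tube_fields(scene)

    vessel = scene.vessel_intensity * occupancy
    extravascular = np.maximum(floor, scene.tracer_luminal * (a + b * surf_dist))
    tracer = occupancy * scene.tracer_luminal + (1.0 - occupancy) * extravascular

    if scene.psf_sigma > 0:
        sigma_vox = [scene.psf_sigma / s for s in scene.voxel_size]
        vessel = gaussian_filter(vessel, sigma=sigma_vox)
        tracer = gaussian_filter(tracer, sigma=sigma_vox)

    gaussian_sd, poisson_scale = scene.noise
    rng = np.random.default_rng(scene.seed)
    out = []
    for channel in (vessel, tracer):
        noisy = channel
        if poisson_scale > 0:
            noisy = rng.poisson(np.maximum(noisy, 0.0) * poisson_scale) / poisson_scale
        if gaussian_sd > 0:
            noisy = noisy + rng.normal(0.0, gaussian_sd, size=channel.shape)
        out.append(np.maximum(noisy, 0.0))

    vessel_stack = ImageStack(out[0], scene.voxel_size, channel_label="vessel")
    tracer_stack = ImageStack(out[1], scene.voxel_size, channel_label="tracer")
    mask = VesselMask(mask=inside, provenance={"method": "ground_truth", "seed": scene.seed})
    return TwoChannelStack(vessel=vessel_stack, tracer=tracer_stack), mask


def analytic_profile(scene: SyntheticScene, distances) -> np.ndarray:
    """Closed-form normalized tracer profile the pipeline should recover.

    Returns ``100 · max(floor / tracer_luminal, a + b·d)`` for each distance
    d ≥ 0 (percent of the luminal intensity, background taken as zero).
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be ≥ 0")
    a, b, floor = scene.tracer_profile
    return 100.0 * np.maximum(floor / scene.tracer_luminal, a + b * d)


@dataclass(frozen=True)
class ExperimentDesign:
    """Condition × timepoint layout with per-cell tracer decay parameters.

    ``cell_profiles`` maps ``(condition, timepoint)`` to the tracer (a, b)
    pair for that cell; all four cells of the 2×2 design must be present.
    Devices are split across ``batch_days`` round-robin, mirroring
    measurements acquired on separate days.
    """

    cell_profiles: dict = field(
        default_factory=lambda: {
            # intercepts/slopes chosen so that TF ≈ control shortly after
            # perfusion while the control decays ~3.6× more steeply at 24 h
            ("TF", "30 min"): (0.92, -0.0006),
            ("control", "30 min"): (0.90, -0.0006),
            ("TF", "24 h"): (0.876, -0.001),
            ("control", "24 h"): (0.875, -0.0036),
        }
    )
    devices_per_condition: int = 3
    batch_days: tuple[str, ...] = ("day1", "day2")
    master_seed: int = 0
    scene_template: SyntheticScene = field(default_factory=lambda: default_scene())

    def __post_init__(self) -> None:
        needed = {(c, t) for c in ("TF", "control") for t in ("30 min", "24 h")}
        if set(self.cell_profiles) != needed:
            raise ValueError(f"cell_profiles must parameterize exactly {sorted(needed)}")
        if self.devices_per_condition < 1:
            raise ValueError("need at least one device per condition")


def default_design(master_seed: int = 0, **overrides) -> ExperimentDesign:
    return ExperimentDesign(master_seed=master_seed, **overrides)


def make_experiment(design: ExperimentDesign):
    """Render one stack per device × condition × timepoint.

    Returns ``(stacks, truth)`` where ``stacks`` is a list of dicts with
    keys condition, timepoint, device_id, batch_day, stack, mask and
    ``truth`` is a DataFrame of the generative (a, b) per design cell.
    Per-device seeds are spawned deterministically from the master seed.
    """
    ss = np.random.SeedSequence(design.master_seed)
    cells = sorted(design.cell_profiles)
    n_children = len(cells) * design.devices_per_condition
    children = ss.spawn(n_children)
    stacks = []
    rows = []
    i = 0
    for condition, timepoint in cells:
        a, b = design.cell_profiles[(condition, timepoint)]
        rows.append({"condition": condition, "timepoint": timepoint, "a": a, "b": b})
        for dev in range(design.devices_per_condition):
            seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            floor = design.scene_template.tracer_profile[2]
            scene = replace(
                design.scene_template,
                tracer_profile=(a, b, floor),
                seed=seed,
            )
            stack, mask = render_scene(scene)
            stacks.append(
                {
                    "condition": condition,
                    "timepoint": timepoint,
                    "device_id": f"{condition}_{timepoint.replace(' ', '')}_{dev}",
                    "batch_day": design.batch_days[dev % len(design.batch_days)],
                    "stack": stack,
                    "mask": mask,
                    "scene": scene,
                }
            )
    truth = pd.DataFrame(rows)
    return stacks, truth


def make_assay_fixture(
    true_slope: float,
    true_intercept: float,
    standards,
    noise_sd: float,
    seed: int,
    true_amount: float | None = None,
):
    """Synthetic calibration standards plus one unknown with known amount.

    Returns ``(standards_df, unknown)`` where ``standards_df`` has columns
    ``amount`` and ``intensity`` (= slope·amount + intercept + noise) and
    ``unknown`` is a dict with the true amount and its noisy intensity.
    """
    amounts = np.asarray(list(standards), dtype=float)
    if amounts.size < 2:
        raise ValueError("need at least two standards")
    rng = np.random.default_rng(seed)
    intensities = true_slope * amounts + true_intercept + rng.normal(0.0, noise_sd, size=amounts.size)
    if true_amount is None:
        true_amount = float(amounts.mean())
    unknown_intensity = true_slope * true_amount + true_intercept + rng.normal(0.0, noise_sd)
    standards_df = pd.DataFrame({"amount": amounts, "intensity": intensities})
    unknown = {"true_amount": float(true_amount), "intensity": float(unknown_intensity)}
    return standards_df, unknown
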