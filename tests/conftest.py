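import numpy as np
import pytest

from mvnperm import ImageStack, SyntheticScene, Tube, TwoChannelStack, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_stack(rng):
    """A random 4×8×8 two-channel stack with integer intensities."""
    vessel = ImageStack(rng.integers(0, 500, size=(4, 8, 8)).astype(float), (2.0, 1.0, 1.0), "vessel")
    tracer = ImageStack(rng.integers(0, 500, size=(4, 8, 8)).astype(float), (2.0, 1.0, 1.0), "tracer")
    return TwoChannelStack(vessel=vessel, tracer=tracer)


def cylinder_scene(radius=15.0, shape=(16, 96, 96), voxel=2.0, psf_sigma=1.0,
                   noise=(0.0, 0.0), seed=0, **kw):
    """A single straight tube along x at mid-depth, mid-height."""
    nz, ny, nx = shape
    zc, yc = nz * voxel / 2, ny * voxel / 2
    tube = Tube(centerline=((zc, yc, 0.0), (zc, yc, nx * voxel)), radius=radius)
    return SyntheticScene(
        shape=shape, voxel_size=(voxel, voxel, voxel), tubes=(tube,),
        psf_sigma=psf_sigma, noise=noise, seed=seed, **kw,
    )


@pytest.fixture
def noiseless_cylinder():
    """Rendered noiseless cylinder phantom (stack, ground-truth mask, scene)."""
    scene = cylinder_scene()
    stack, mask = render_scene(scene)
    return stack, mask, scene
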