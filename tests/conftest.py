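import numpy as np
import pytest

from fasc3d.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ihc_block():
    """A small clean IHC-like block shared by read-only tests."""
    spec = PhantomSpec(
        n_slices=6,
        image_size=256,
        n_fascicles=4,
        fascicle_radii=(9.0, 20.0),
        noise_sd=0.0,
        seed=21,
    )
    return generate_phantom(spec)


def disk_image(size, centers_radii, fg=0.2, bg=0.9):
    """Grayscale image of filled disks: [(cy, cx, r), ...]."""
    img = np.full((size, size), bg)
    yy, xx = np.mgrid[0:size, 0:size]
    for cy, cx, r in centers_radii:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = fg
    return img


def disk_mask(size, centers_radii):
    yy, xx = np.mgrid[0:size, 0:size]
    m = np.zeros((size, size), dtype=bool)
    for cy, cx, r in centers_radii:
        m |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return m
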