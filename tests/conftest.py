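import numpy as np
import pytest

from arterymetrics.contour import ArteryAnnotation, Contour
from arterymetrics.simulate import make_artery


def circle_contour(center, radius, n=720):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(
        np.column_stack([center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)])
    )


def star_annotation(seed, canvas=256, radii=(100.0, 70.0, 40.0), n=720):
    """Smooth star-shaped artery: shared low-order radial wobble on all
    three compartments, guaranteed nesting."""
    rng = np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    wobble = np.ones_like(theta)
    for k in (2, 3, 4, 5):
        wobble += rng.uniform(0.01, 0.04) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    c = (canvas / 2, canvas / 2)

    def ring(r):
        rr = r * wobble
        return Contour(np.column_stack([c[0] + rr * np.cos(theta), c[1] + rr * np.sin(theta)]))

    return ArteryAnnotation(
        media=ring(radii[0]),
        intimas=[ring(radii[1])],
        lumens=[ring(radii[2])],
        artery_id=f"star-{seed}",
    )


@pytest.fixture
def annulus():
    """Concentric circles (r_m, r_i, r_l) = (100, 70, 40) on a 256 canvas."""
    return make_artery("nested", radii=(100.0, 70.0, 40.0), canvas=256)


@pytest.fixture
def annulus_annotation(annulus):
    return annulus.annotation
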