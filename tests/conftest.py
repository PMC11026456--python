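import numpy as np
import pytest

from mechanophen.core import SubstrateModel
from mechanophen.shape_metrics import Contour


@pytest.fixture
def substrate() -> SubstrateModel:
    return SubstrateModel(youngs_modulus=3000.0, poisson_ratio=0.5, pixel_size=1.0)


def circle_polygon(radius: float, n: int = 720, center=(0.0, 0.0)) -> Contour:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(
        np.column_stack(
            [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
        )
    )


def ellipse_polygon(a: float, b: float, n: int = 720, angle: float = 0.0) -> Contour:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    xy = np.column_stack([a * np.cos(th), b * np.sin(th)])
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return Contour(xy @ rot.T)


def star_polygon(rng: np.random.Generator, n: int = 32, r0: float = 10.0) -> Contour:
    """Random star-convex (star-shaped) simple polygon."""
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    # enforce distinct angles
    th = th + np.arange(n) * 1e-9
    r = rng.uniform(0.4 * r0, r0, n)
    return Contour(np.column_stack([r * np.cos(th), r * np.sin(th)]))
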