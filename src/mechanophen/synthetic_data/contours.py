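"""Contour populations with analytic area / perimeter / porosity truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ellipe
from shapely.geometry import Polygon

from ..shape_metrics import Contour

__all__ = ["ContourTruth", "ContourSet", "gen_contours"]

_N_VERT = 360  # vertices per generated contour
_N_DENSE = 4096  # dense evaluation for notched-truth values


@dataclass
class ContourTruth:
    contour_id: int
    family: str
    area: float  # µm²
    perimeter: float  # µm
    porosity: float


@dataclass
class ContourSet:
    contours: list[Contour]
    truths: list[ContourTruth]

    def __len__(self) -> int:
        return len(self.contours)


def _radial_polygon(r_of_theta, n: int, center=(0.0, 0.0), phase: float = 0.0) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    r = r_of_theta(th)
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def gen_contours(
    n: int,
    family: str = "circle",
    size_range: tuple[float, float] = (150.0, 350.0),  # target areas, µm²
    seed: int = 0,
) -> ContourSet:
    """Generate ``n`` contours of one family with per-contour truth.

    ``circle`` and ``ellipse`` truths are analytic (ellipse perimeter via
    the complete elliptic integral); ``notched`` truths come from a dense
    polygonal evaluation (its porosity is strictly > 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = size_range
    if not (0 < lo <= hi):
        raise ValueError("degenerate size_range")
    if family not in ("circle", "ellipse", "notched"):
        raise ValueError(f"unknown family {family!r}")
    rng = np.random.default_rng(seed)

    contours: list[Contour] = []
    truths: list[ContourTruth] = []
    for i in range(n):
        area_target = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi)
        if family == "circle":
            r0 = np.sqrt(area_target / np.pi)
            verts = _radial_polygon(lambda th: np.full_like(th, r0), _N_VERT, phase=phase)
            area, perim, poro = np.pi * r0**2, 2 * np.pi * r0, 1.0
        elif family == "ellipse":
            ratio = rng.uniform(1.2, 2.5)
            b = np.sqrt(area_target / (np.pi * ratio))
            a = ratio * b
            th0 = rng.uniform(0, 2 * np.pi)
            tt = np.linspace(0, 2 * np.pi, _N_VERT, endpoint=False) + phase
            xy = np.column_stack([a * np.cos(tt), b * np.sin(tt)])
            rot = np.array(
                [[np.cos(th0), -np.sin(th0)], [np.sin(th0), np.cos(th0)]]
            )
            verts = xy @ rot.T
            ecc2 = 1.0 - (b / a) ** 2
            area = np.pi * a * b
            perim = float(4.0 * a * ellipe(ecc2))
            poro = 1.0
        else:  # notched: circle with a smooth radial bite taken out
            r0 = np.sqrt(area_target / np.pi)
            depth = rng.uniform(0.25, 0.45)
            width = rng.uniform(0.25, 0.5)  # radians, notch sigma
            th_notch = rng.uniform(0, 2 * np.pi)

            def r_fn(th, r0=r0, depth=depth, width=width, th_notch=th_notch):
                d = np.angle(np.exp(1j * (th - th_notch)))
                return r0 * (1.0 - depth * np.exp(-(d**2) / (2 * width**2)))

            verts = _radial_polygon(r_fn, _N_VERT, phase=phase)
            dense = Polygon(_radial_polygon(r_fn, _N_DENSE, phase=phase))
            area = dense.area
            perim = dense.length
            poro = dense.convex_hull.area / dense.area
        contours.append(Contour(verts, contour_id=i))
        truths.append(
            ContourTruth(
                contour_id=i,
                family=family,
                area=float(area),
                perimeter=float(perim),
                porosity=float(poro),
            )
        )
    return ContourSet(contours=contours, truths=truths)
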