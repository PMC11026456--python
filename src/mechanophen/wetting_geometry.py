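"""Cluster wetting geometry from spherical-cap measurements.

Formulas: R_sphere = (R^2 + H^2) / (2 H); wet clusters (H <= R_sphere)
have contact angle theta = asin(R / R_sphere), dewet clusters
alpha = 180 - asin(R / R_sphere); both give 90 degrees at H = R_sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure

from .core import ImageStack

__all__ = ["ClusterGeometry", "sphere_radius", "contact_angle", "measure_cluster"]

_GEOM_TOL = 1e-9


@dataclass
class ClusterGeometry:
    contact_radius: float  # R, µm
    height: float  # H, µm
    sphere_radius: float  # µm
    angle_deg: float  # in (0, 180)
    regime: str  # "wet" | "dewet"


def sphere_radius(R: float, H: float) -> float:
    """Radius of the sphere circumscribing a cap of contact radius R and
    height H: (R^2 + H^2) / (2 H)."""
    if R <= 0 or H <= 0:
        raise ValueError("R and H must be positive")
    return float((R**2 + H**2) / (2.0 * H))


def contact_angle(R: float, H: float) -> ClusterGeometry:
    """Contact angle of a spherical-cap cluster, in degrees.

    Wet regime (H <= R_sphere): asin(R / R_sphere); dewet regime:
    180 - asin(R / R_sphere).  Continuous (90 deg) at H = R_sphere.
    """
    rs = sphere_radius(R, H)
    ratio = R / rs
    if ratio > 1.0 + _GEOM_TOL:
        raise ValueError("geometrically impossible cap: R exceeds R_sphere")
    base = float(np.degrees(np.arcsin(min(ratio, 1.0))))
    if H <= rs:
        return ClusterGeometry(R, H, rs, base, "wet")
    return ClusterGeometry(R, H, rs, 180.0 - base, "dewet")


def measure_cluster(
    stack: ImageStack,
    substrate_plane: int = 0,
    threshold: float | None = None,
    min_area_px: int = 9,
) -> tuple[float, float]:
    """Extract (R, H) in µm from a cluster z-stack.

    R is the equivalent-circle radius of the segmented basal slice;
    H comes from the highest slice containing the object, plus half a
    z-step: the true apex lies between the last occupied slice and the
    first empty one, so the midpoint halves the discretisation bias
    (an uncorrected top-slice height underestimates a hemisphere's
    angle by several degrees at z_step = 0.5 um).
    ``threshold`` defaults to Otsu's value computed on the whole stack.
    """
    if stack.n_slices < 3:
        raise ValueError("stack needs at least 3 slices")
    if not 0 <= substrate_plane < stack.n_slices:
        raise ValueError("substrate_plane outside the stack")
    data = np.asarray(stack.data, dtype=float)
    if data.max() == data.min():
        raise ValueError("blank stack: no object to measure")
    thr = filters.threshold_otsu(data) if threshold is None else threshold

    basal = data[substrate_plane] > thr
    labels = measure.label(basal)
    if labels.max() == 0:
        raise ValueError("object absent from the basal slice")
    areas = np.bincount(labels.ravel())[1:]
    area_px = int(areas.max())
    R = float(np.sqrt(area_px * stack.pixel_size**2 / np.pi))

    top = substrate_plane
    for z in range(substrate_plane, stack.n_slices):
        if np.count_nonzero(data[z] > thr) >= min_area_px:
            top = z
    H = float((top - substrate_plane + 0.5) * stack.z_step)
    return R, H
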