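"""Spherical-cap cluster z-stacks with analytic geometry truth.

A cluster sitting on the substrate is modelled as a spherical cap of
contact radius R (basal plane) and height H.  The circumscribed sphere
has radius R_sphere = (R^2 + H^2) / (2 H) and its centre sits at
z = H - R_sphere, so the slice at height z is a disk of radius
sqrt(R_sphere^2 - (z - (H - R_sphere))^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import ImageStack

__all__ = ["ClusterTruth", "gen_cluster_stack", "cap_angle_deg"]


def cap_angle_deg(R: float, H: float) -> float:
    """Analytic contact angle (degrees) of a spherical cap."""
    r_sphere = (R**2 + H**2) / (2.0 * H)
    a = np.degrees(np.arcsin(min(R / r_sphere, 1.0)))
    return float(a if H <= r_sphere else 180.0 - a)


@dataclass
class ClusterTruth:
    contact_radius: float  # µm
    height: float  # µm
    sphere_radius: float  # µm
    angle_deg: float
    substrate_index: int


def gen_cluster_stack(
    contact_radius: float,
    height: float,
    z_step: float,
    seed: int = 0,
    *,
    pixel_size: float = 0.5,
    shape: tuple[int, int] | None = None,
    intensity: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    n_slices_above: int = 2,
) -> tuple[ImageStack, ClusterTruth]:
    """Render a spherical-cap cluster as a binary-ish z-stack.

    Slices run from the substrate plane (z = 0) upward; a few empty
    slices are appended above the cap so height detection has headroom.
    """
    if contact_radius <= 0 or height <= 0 or z_step <= 0:
        raise ValueError("contact_radius, height and z_step must be positive")
    r_sphere = (contact_radius**2 + height**2) / (2.0 * height)
    if height > 2.0 * r_sphere + 1e-9:
        raise ValueError("impossible cap: H exceeds the sphere diameter")

    rng = np.random.default_rng(seed)
    max_rho = r_sphere if height > r_sphere else contact_radius
    if shape is None:
        n = int(np.ceil(2.4 * max_rho / pixel_size))
        shape = (n, n)
    ny, nx = shape
    cx = (nx - 1) / 2.0 * pixel_size
    cy = (ny - 1) / 2.0 * pixel_size
    z_center = height - r_sphere

    n_slices = int(np.floor(height / z_step)) + 1 + n_slices_above
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(xx * pixel_size - cx, yy * pixel_size - cy)

    data = np.full((n_slices, ny, nx), float(background))
    for k in range(n_slices):
        z = k * z_step
        if z > height:
            continue
        rho_sq = r_sphere**2 - (z - z_center) ** 2
        if rho_sq <= 0:
            continue
        data[k][rr <= np.sqrt(rho_sq)] = background + intensity
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    stack = ImageStack(data, pixel_size=pixel_size, z_step=z_step)
    truth = ClusterTruth(
        contact_radius=float(contact_radius),
        height=float(height),
        sphere_radius=float(r_sphere),
        angle_deg=cap_angle_deg(contact_radius, height),
        substrate_index=0,
    )
    return stack, truth
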