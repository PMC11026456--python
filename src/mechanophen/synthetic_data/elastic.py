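"""Forward elastic problem: surface displacement of a half-space under
a tangential surface traction field.

Two independent routes are provided:

* ``spectral`` — multiplication by the half-space Green's tensor in the
  Fourier domain, zero-padded by one full field size to suppress
  periodic wrap-around;
* ``direct_sum`` — real-space superposition of the point-force
  (Boussinesq/Cerruti) kernel over every non-zero traction node, with an
  analytic self-cell integral.  Slower, but algorithmically unrelated to
  the FFT route, so it serves as the oracle.

Kernel (surface displacement at r due to tangential point force F at
the origin, components in the surface plane)::

    u_i = (1 + nu) / (pi * E * r) * [ (1 - nu) d_ij + nu x_i x_j / r^2 ] F_j

whose 2-D Fourier transform is::

    G(k) = 2 (1 + nu) / (E k^3) * [[ (1-nu) k^2 + nu ky^2,  -nu kx ky ],
                                   [ -nu kx ky,  (1-nu) k^2 + nu kx^2 ]]

With lengths in µm, tractions in Pa and E in Pa, displacements come out
in µm directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import SubstrateModel, VectorField

__all__ = [
    "TractionPatch",
    "TractionSpec",
    "boussinesq_greens_fourier",
    "forward_displacement",
    "render_traction_field",
]

# integral of 1/r over a unit square centred on the singularity
_UNIT_SELF_INTEGRAL = 4.0 * np.arcsinh(1.0)  # = 4 ln(1 + sqrt 2)


@dataclass(frozen=True)
class TractionPatch:
    """Anisotropic contractile Gaussian traction patch.

    The traction points toward the patch centre with magnitude
    ``~ peak * rho * exp(-rho^2/2)`` along each principal axis, where the
    principal widths are ``width`` and ``width / anisotropy``.  Each
    patch integrates to zero net force by construction (odd symmetry),
    and its force-dipole eigenvalue ratio equals ``anisotropy`` exactly.
    """

    center: tuple[float, float]  # µm
    peak: float  # Pa scale
    width: float  # µm, major principal width (Gaussian sigma)
    orientation: float = 0.0  # degrees, major axis vs +x
    anisotropy: float = 1.0  # >= 1

    def __post_init__(self) -> None:
        if self.peak <= 0 or self.width <= 0:
            raise ValueError("peak and width must be positive")
        if self.anisotropy < 1:
            raise ValueError("anisotropy must be >= 1")


@dataclass
class TractionSpec:
    """Collection of patches plus a net-force balance flag."""

    patches: list[TractionPatch] = field(default_factory=list)
    net_force_balanced: bool = True


def render_traction_field(
    spec: TractionSpec,
    shape: tuple[int, int],
    pixel_size: float,
    grid_step: int = 1,
) -> VectorField:
    """Evaluate the analytic patch tractions on a pixel grid.

    ``grid_step`` subsamples the pixel grid (node every ``grid_step``
    pixels), matching e.g. a PIV grid.
    """
    ny, nx = shape
    x = np.arange(0, nx, grid_step) * pixel_size
    y = np.arange(0, ny, grid_step) * pixel_size
    X, Y = np.meshgrid(x, y)
    tx = np.zeros_like(X)
    ty = np.zeros_like(Y)
    for p in spec.patches:
        th = np.deg2rad(p.orientation)
        c, s = np.cos(th), np.sin(th)
        dx = X - p.center[0]
        dy = Y - p.center[1]
        # patch-frame coordinates
        xi = c * dx + s * dy
        eta = -s * dx + c * dy
        wx = p.width
        wy = p.width / p.anisotropy
        g = np.exp(-(xi**2 / (2 * wx**2) + eta**2 / (2 * wy**2)))
        # contractile: points toward the centre; e^{1/2} normalises the
        # per-axis maximum of rho*exp(-rho^2/2) to `peak`
        amp = p.peak * np.exp(0.5)
        f_xi = -amp * (xi / wx) * g
        f_eta = -amp * (eta / wy) * g
        tx += c * f_xi - s * f_eta
        ty += s * f_xi + c * f_eta
    if spec.net_force_balanced:
        tx -= tx.mean()
        ty -= ty.mean()
    return VectorField(x, y, tx, ty, units="Pa")


def boussinesq_greens_fourier(
    kx: np.ndarray, ky: np.ndarray, substrate: SubstrateModel
) -> np.ndarray:
    """Green's tensor ``G[..., 2, 2]`` on a wavevector grid (rad/µm).

    The k = 0 entry is set to zero (rigid translation of the substrate
    surface is unobservable; valid for force-balanced tractions).
    """
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    k = np.hypot(kx, ky)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k**3)
        G = np.zeros(k.shape + (2, 2))
        G[..., 0, 0] = pref * ((1 - nu) * k**2 + nu * ky**2)
        G[..., 1, 1] = pref * ((1 - nu) * k**2 + nu * kx**2)
        G[..., 0, 1] = G[..., 1, 0] = pref * (-nu * kx * ky)
    G[k == 0] = 0.0
    return G


def _forward_spectral(traction: VectorField, substrate: SubstrateModel) -> VectorField:
    ny, nx = traction.shape
    h = traction.spacing
    py, px = 2 * ny, 2 * nx  # zero-pad by one full field size
    kx = 2 * np.pi * np.fft.fftfreq(px, d=h)
    ky = 2 * np.pi * np.fft.fftfreq(py, d=h)
    KX, KY = np.meshgrid(kx, ky)
    G = boussinesq_greens_fourier(KX, KY, substrate)
    ft_x = np.fft.fft2(traction.u, s=(py, px))
    ft_y = np.fft.fft2(traction.v, s=(py, px))
    fu = G[..., 0, 0] * ft_x + G[..., 0, 1] * ft_y
    fv = G[..., 1, 0] * ft_x + G[..., 1, 1] * ft_y
    u = np.fft.ifft2(fu).real[:ny, :nx]
    v = np.fft.ifft2(fv).real[:ny, :nx]
    return traction.copy_with(u, v, units="um")


def _forward_direct(
    traction: VectorField, substrate: SubstrateModel, source_threshold: float = 1e-10
) -> VectorField:
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    h = traction.spacing
    pref = (1.0 + nu) / (np.pi * E)
    X, Y = traction.meshgrid()
    u = np.zeros(traction.shape)
    v = np.zeros(traction.shape)

    tmag = np.hypot(traction.u, traction.v)
    if tmag.max() == 0:
        return traction.copy_with(u, v, units="um")
    # skip negligible sources (cost control; relative contribution bound)
    src = np.argwhere(tmag > source_threshold * tmag.max())
    dA = h * h
    # analytic integral of the kernel over the source's own grid cell
    self_coef = pref * ((1 - nu) + nu / 2.0) * _UNIT_SELF_INTEGRAL * h

    for i, j in src:
        txs = traction.u[i, j]
        tys = traction.v[i, j]
        dx = X - X[i, j]
        dy = Y - Y[i, j]
        r2 = dx * dx + dy * dy
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_r = 1.0 / np.sqrt(r2)
            inv_r3 = inv_r / r2
            gxx = pref * ((1 - nu) * inv_r + nu * dx * dx * inv_r3)
            gyy = pref * ((1 - nu) * inv_r + nu * dy * dy * inv_r3)
            gxy = pref * (nu * dx * dy * inv_r3)
        gxx[i, j] = gyy[i, j] = gxy[i, j] = 0.0
        u += (gxx * txs + gxy * tys) * dA
        v += (gxy * txs + gyy * tys) * dA
        # self cell: uniform traction over an h x h square
        u[i, j] += self_coef * txs
        v[i, j] += self_coef * tys
    return traction.copy_with(u, v, units="um")


def forward_displacement(
    traction: VectorField,
    substrate: SubstrateModel,
    method: str = "spectral",
    source_threshold: float = 1e-10,
) -> VectorField:
    """Surface displacement (µm) produced by a tangential traction field (Pa).

    Parameters
    ----------
    traction:
        Traction on a regular rectangular grid, units "Pa".
    substrate:
        Elastic half-space parameters.
    method:
        ``"spectral"`` (FFT, zero-padded) or ``"direct_sum"`` (real-space
        superposition oracle).
    source_threshold:
        direct_sum only: skip source nodes whose traction magnitude is
        below this fraction of the field maximum (pure cost control).
    """
    if traction.units != "Pa":
        raise ValueError(f"expected traction in Pa, got units={traction.units!r}")
    if not (np.all(np.isfinite(traction.u)) and np.all(np.isfinite(traction.v))):
        raise ValueError("traction field contains non-finite values")
    if method == "spectral":
        return _forward_spectral(traction, substrate)
    if method == "direct_sum":
        return _forward_direct(traction, substrate, source_threshold)
    raise ValueError(f"unknown method {method!r}")
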