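"""Synthetic TFM bead image pairs with known ground-truth displacement."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from ..core import RasterImage, SubstrateModel, VectorField
from .elastic import TractionSpec, forward_displacement, render_traction_field

__all__ = ["BeadSceneTruth", "gen_bead_image_pair"]


@dataclass
class BeadSceneTruth:
    """Ground truth for a bead image pair."""

    positions_ref: np.ndarray  # (n, 2) µm, (x, y) before deformation
    positions_def: np.ndarray  # (n, 2) µm, after deformation
    displacement: VectorField | None  # elastic field used, if any
    traction: VectorField | None
    uniform_shift_px: tuple[float, float] | None = None
    params: dict = field(default_factory=dict)


def _render_beads(
    shape: tuple[int, int],
    positions_px: np.ndarray,
    sigma_px: float,
    amplitude: float,
) -> np.ndarray:
    """Sum of isotropic Gaussians, each evaluated on a local patch."""
    ny, nx = shape
    img = np.zeros((ny, nx))
    half = max(3, int(np.ceil(5 * sigma_px)))
    for px_, py_ in positions_px:
        i0 = int(np.floor(py_)) - half
        j0 = int(np.floor(px_)) - half
        i1, j1 = i0 + 2 * half + 1, j0 + 2 * half + 1
        ci0, cj0 = max(i0, 0), max(j0, 0)
        ci1, cj1 = min(i1, ny), min(j1, nx)
        if ci0 >= ci1 or cj0 >= cj1:
            continue
        yy = np.arange(ci0, ci1)[:, None]
        xx = np.arange(cj0, cj1)[None, :]
        img[ci0:ci1, cj0:cj1] += amplitude * np.exp(
            -((xx - px_) ** 2 + (yy - py_) ** 2) / (2 * sigma_px**2)
        )
    return img


def gen_bead_image_pair(
    truth: TractionSpec | None,
    substrate: SubstrateModel,
    shape: tuple[int, int] = (256, 256),
    bead_density: float = 0.02,  # beads / µm²
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    uniform_shift_px: tuple[float, float] | None = None,
    displacement: VectorField | None = None,
    bead_sigma_px: float = 1.5,
    amplitude: float = 1000.0,
    forward_method: str = "spectral",
) -> tuple[RasterImage, RasterImage, BeadSceneTruth]:
    """Render a (reference, deformed) fluorescent-bead image pair.

    The displacement applied to the beads comes from, in order of
    precedence: ``uniform_shift_px`` (rigid translation, exact),
    ``displacement`` (a precomputed field), or the elastic forward
    solution of ``truth`` on ``substrate``.  Beads are sub-resolution
    0.2 µm spheres rendered as Gaussian spots of ``bead_sigma_px``.

    Deterministic: the same ``seed`` gives byte-identical images.
    """
    if bead_density <= 0:
        raise ValueError("bead_density must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    ny, nx = shape
    ps = substrate.pixel_size
    rng = np.random.default_rng(seed)

    area_um2 = (ny * ps) * (nx * ps)
    n_beads = max(1, int(round(bead_density * area_um2)))
    pos_um = rng.uniform(
        low=[0.0, 0.0], high=[(nx - 1) * ps, (ny - 1) * ps], size=(n_beads, 2)
    )

    disp_field: VectorField | None = None
    if uniform_shift_px is not None:
        shift_um = np.array(uniform_shift_px, dtype=float) * ps
        pos_def = pos_um + shift_um
    else:
        if displacement is not None:
            disp_field = displacement
        elif truth is not None and truth.patches:
            tf = render_traction_field(truth, shape, ps)
            disp_field = forward_displacement(tf, substrate, method=forward_method)
        if disp_field is None:
            pos_def = pos_um.copy()
        else:
            interp_u = RegularGridInterpolator(
                (disp_field.y, disp_field.x), disp_field.u,
                bounds_error=False, fill_value=0.0,
            )
            interp_v = RegularGridInterpolator(
                (disp_field.y, disp_field.x), disp_field.v,
                bounds_error=False, fill_value=0.0,
            )
            pts = pos_um[:, ::-1]  # (y, x) order for the interpolator
            pos_def = pos_um + np.column_stack([interp_u(pts), interp_v(pts)])

    ref = _render_beads(shape, pos_um / ps, bead_sigma_px, amplitude)
    def_ = _render_beads(shape, pos_def / ps, bead_sigma_px, amplitude)
    if noise_sd > 0:
        ref = ref + rng.normal(0.0, noise_sd, size=ref.shape)
        def_ = def_ + rng.normal(0.0, noise_sd, size=def_.shape)

    truth_out = BeadSceneTruth(
        positions_ref=pos_um,
        positions_def=pos_def,
        displacement=disp_field,
        traction=render_traction_field(truth, shape, ps) if truth and truth.patches else None,
        uniform_shift_px=uniform_shift_px,
        params={
            "bead_density": bead_density,
            "noise_sd": noise_sd,
            "seed": seed,
            "bead_sigma_px": bead_sigma_px,
            "amplitude": amplitude,
        },
    )
    return RasterImage(ref, ps), RasterImage(def_, ps), truth_out
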