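"""Traction force microscopy: PIV displacement recovery and regularized
Fourier-domain inversion to tractions.

The displacement field between a reference and a deformed bead image is
estimated by window-wise normalized cross-correlation (square windows,
default side 32 px with 0.5 overlap) with three-point Gaussian
sub-pixel peak interpolation and local-median validation.  Tractions
are recovered by inverting the half-space Green's operator in the
Fourier domain with zeroth-order Tikhonov regularization; the
zero-frequency (net force / rigid translation) mode is set to zero.
Sign convention: the returned traction is the stress exerted by the
cell on the gel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline, griddata
from scipy.ndimage import map_coordinates
from skimage.feature import match_template

from .core import LabelMask, RasterImage, SubstrateModel, VectorField
from .synthetic_data.elastic import boussinesq_greens_fourier

__all__ = [
    "PivParams",
    "piv_displacement",
    "fttc_tractions",
    "mean_traction",
    "resample_field",
]


@dataclass(frozen=True)
class PivParams:
    window: int = 32  # px, square interrogation window
    overlap: float = 0.5  # fraction of window
    subpixel: str = "gaussian"  # 3-point Gaussian peak fit
    max_displacement: float | None = None  # px; None -> window / 3
    median_threshold: float = 2.0  # px residual vs local median
    passes: int = 2  # >1: image-deformation passes against gradient bias

    def __post_init__(self) -> None:
        if self.window < 8:
            raise ValueError("window must be at least 8 px")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


def _subpixel_offset(c: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Three-point Gaussian peak interpolation around the integer peak."""

    def fit(cm: float, c0: float, cp: float) -> float:
        eps = 1e-12
        cm, c0, cp = max(cm, eps), max(c0, eps), max(cp, eps)
        denom = np.log(cm) - 2 * np.log(c0) + np.log(cp)
        if denom >= 0:  # not a local max in log space; fall back to parabola
            denom = cm - 2 * c0 + cp
            return 0.0 if denom >= 0 else 0.5 * (cm - cp) / denom
        return 0.5 * (np.log(cm) - np.log(cp)) / denom

    ny, nx = c.shape
    dy = fit(c[i - 1, j], c[i, j], c[i + 1, j]) if 0 < i < ny - 1 else 0.0
    dx = fit(c[i, j - 1], c[i, j], c[i, j + 1]) if 0 < j < nx - 1 else 0.0
    return dx, dy


def _window_displacement(
    template: np.ndarray, search: np.ndarray, m: int
) -> tuple[float, float, bool]:
    """Displacement from the normalized-cross-correlation peak of
    ``template`` (w x w) inside ``search`` (w+2m x w+2m); zero
    displacement sits at NCC index (m, m)."""
    if template.std() == 0 or search.std() == 0:
        return 0.0, 0.0, False
    ncc = match_template(search, template, pad_input=False)
    i, j = np.unravel_index(np.argmax(ncc), ncc.shape)
    if ncc[i, j] >= 1.0 - 1e-9:  # exact match: integer displacement
        return float(j - m), float(i - m), True
    dx_sub, dy_sub = _subpixel_offset(ncc, i, j)
    return (j - m) + dx_sub, (i - m) + dy_sub, bool(ncc[i, j] > 0.1)


def _median_validate(u: np.ndarray, v: np.ndarray, valid: np.ndarray, threshold: float) -> np.ndarray:
    """Flag vectors deviating from their 3x3 neighbourhood median."""
    from scipy.ndimage import generic_filter

    def local_median(x):
        c = x[len(x) // 2]
        rest = np.delete(x, len(x) // 2)
        rest = rest[~np.isnan(rest)]
        return np.median(rest) if rest.size else c

    un = np.where(valid, u, np.nan)
    vn = np.where(valid, v, np.nan)
    mu = generic_filter(un, local_median, size=3, mode="nearest")
    mv = generic_filter(vn, local_median, size=3, mode="nearest")
    resid = np.hypot(u - mu, v - mv)
    return valid & (resid <= threshold)


def _single_pass(
    img_a: np.ndarray,
    img_b: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    w: int,
    m: int,
    params: PivParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    padded_b = np.pad(img_b, m, mode="constant", constant_values=img_b.mean())
    u = np.zeros((rows.size, cols.size))
    v = np.zeros_like(u)
    valid = np.zeros(u.shape, dtype=bool)
    for ii, r in enumerate(rows):
        for jj, c in enumerate(cols):
            dx, dy, ok = _window_displacement(
                img_a[r : r + w, c : c + w],
                padded_b[r : r + w + 2 * m, c : c + w + 2 * m],
                m,
            )
            u[ii, jj], v[ii, jj], valid[ii, jj] = dx, dy, ok

    valid = _median_validate(u, v, valid, params.median_threshold)
    if (~valid).any() and valid.any():
        from scipy.ndimage import generic_filter

        def fill_median(x):
            x = x[~np.isnan(x)]
            return np.median(x) if x.size else 0.0

        un = np.where(valid, u, np.nan)
        vn = np.where(valid, v, np.nan)
        u = np.where(valid, u, generic_filter(un, fill_median, size=3, mode="nearest"))
        v = np.where(valid, v, generic_filter(vn, fill_median, size=3, mode="nearest"))
    return u, v, valid


def _warp_image(img: np.ndarray, u_px: np.ndarray, v_px: np.ndarray) -> np.ndarray:
    """Sample ``img`` at x + u(x) (pulls the deformed content back onto
    the reference frame)."""
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    return map_coordinates(img, [yy + v_px, xx + u_px], order=3, mode="nearest")


def piv_displacement(
    reference: RasterImage,
    deformed: RasterImage,
    params: PivParams | None = None,
) -> VectorField:
    """Window-wise displacement (µm) of ``deformed`` relative to
    ``reference``.

    Each pass correlates reference windows against a search region in
    the (possibly warped) deformed image; from the second pass on, the
    deformed image is warped by the current estimate and only the
    residual is measured (image-deformation multi-pass, which removes
    the gradient-attenuation bias of single-pass correlation).  Spurious
    vectors are replaced by the local 3x3 median and flagged invalid.
    """
    params = params or PivParams()
    if reference.shape != deformed.shape:
        raise ValueError("image shapes differ")
    img_a = np.asarray(reference.data, dtype=float)
    img_b = np.asarray(deformed.data, dtype=float)
    if img_a.max() == img_a.min() or img_b.max() == img_b.min():
        raise ValueError("blank image: PIV is undefined")
    ny_img, nx_img = img_a.shape
    w = params.window
    if w > min(ny_img, nx_img):
        raise ValueError("image smaller than one interrogation window")
    step = max(1, int(round(w * (1 - params.overlap))))
    max_disp = params.max_displacement if params.max_displacement is not None else w / 3.0
    m = max(1, int(np.ceil(max_disp)))

    rows = np.arange(0, ny_img - w + 1, step)
    cols = np.arange(0, nx_img - w + 1, step)
    u, v, valid = _single_pass(img_a, img_b, rows, cols, w, m, params)

    node_x = cols + (w - 1) / 2.0
    node_y = rows + (w - 1) / 2.0
    for _ in range(1, params.passes):
        if u.shape[0] < 4 or u.shape[1] < 4:
            break  # too few nodes for a stable spline warp
        su = RectBivariateSpline(node_y, node_x, u, kx=3, ky=3)
        sv = RectBivariateSpline(node_y, node_x, v, kx=3, ky=3)
        yy = np.arange(ny_img, dtype=float)
        xx = np.arange(nx_img, dtype=float)
        u_px = su(yy, xx)
        v_px = sv(yy, xx)
        warped = _warp_image(img_b, u_px, v_px)
        m_res = max(2, m // 2)
        du, dv, valid = _single_pass(img_a, warped, rows, cols, w, m_res, params)
        u = su(node_y, node_x) + du
        v = sv(node_y, node_x) + dv

    ps = reference.pixel_size
    x = node_x * ps
    y = node_y * ps
    return VectorField(x, y, u * ps, v * ps, units="um", valid=valid)


def _fill_gaps(field: VectorField) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate invalid nodes (linear, nearest at the hull edge)."""
    if field.valid is None or field.valid.all():
        return field.u, field.v
    X, Y = field.meshgrid()
    good = field.valid
    pts = np.column_stack([X[good], Y[good]])
    out = []
    for comp in (field.u, field.v):
        lin = griddata(pts, comp[good], (X, Y), method="linear")
        near = griddata(pts, comp[good], (X, Y), method="nearest")
        lin[np.isnan(lin)] = near[np.isnan(lin)]
        out.append(lin)
    return out[0], out[1]


def resample_field(field: VectorField, spacing: float) -> VectorField:
    """Cubic-spline resample of a vector field onto a finer (or coarser)
    grid with the given spacing, within the original grid's extent.
    Useful for inverting coarse PIV grids on a denser wavevector grid.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    su = RectBivariateSpline(field.y, field.x, field.u, kx=3, ky=3)
    sv = RectBivariateSpline(field.y, field.x, field.v, kx=3, ky=3)
    xs = np.arange(field.x[0], field.x[-1] + 1e-9, spacing)
    ys = np.arange(field.y[0], field.y[-1] + 1e-9, spacing)
    return VectorField(xs, ys, su(ys, xs), sv(ys, xs), units=field.units)


def fttc_tractions(
    displacement: VectorField,
    substrate: SubstrateModel,
    regularization: float | None = None,
    *,
    pad: bool = True,
) -> VectorField:
    """Invert a displacement field (µm) to tractions (Pa).

    Zeroth-order Tikhonov: per wavevector solve
    ``(G^T G + lambda^2 I) T = G^T U``.  ``regularization`` defaults to
    ``1e-9 * E`` (a declared choice; the original analysis scheme is
    unpublished).  ``pad`` reflect-pads by half the field per side to
    reduce periodicity artifacts.
    """
    if displacement.units != "um":
        raise ValueError("expected displacement in um")
    if not (np.all(np.isfinite(displacement.u)) and np.all(np.isfinite(displacement.v))):
        raise ValueError("displacement contains non-finite values")
    lam = 1e-9 * substrate.youngs_modulus if regularization is None else regularization
    if lam < 0:
        raise ValueError("regularization must be non-negative")

    u, v = _fill_gaps(displacement)
    ny, nx = u.shape
    h = displacement.spacing
    if pad:
        py, px = ny // 2, nx // 2
        u = np.pad(u, ((py, py), (px, px)), mode="reflect")
        v = np.pad(v, ((py, py), (px, px)), mode="reflect")
    else:
        py = px = 0
    NY, NX = u.shape
    kx = 2 * np.pi * np.fft.fftfreq(NX, d=h)
    ky = 2 * np.pi * np.fft.fftfreq(NY, d=h)
    KX, KY = np.meshgrid(kx, ky)
    G = boussinesq_greens_fourier(KX, KY, substrate)

    fu = np.fft.fft2(u)
    fv = np.fft.fft2(v)
    # G is real symmetric per wavevector: solve (G^2 + lam^2) t = G u
    g11, g12, g22 = G[..., 0, 0], G[..., 0, 1], G[..., 1, 1]
    a11 = g11 * g11 + g12 * g12 + lam**2
    a12 = g12 * (g11 + g22)
    a22 = g22 * g22 + g12 * g12 + lam**2
    det = a11 * a22 - a12 * a12
    b1 = g11 * fu + g12 * fv
    b2 = g12 * fu + g22 * fv
    with np.errstate(divide="ignore", invalid="ignore"):
        ftx = (a22 * b1 - a12 * b2) / det
        fty = (a11 * b2 - a12 * b1) / det
    ftx[0, 0] = 0.0  # net-force-free convention
    fty[0, 0] = 0.0
    tx = np.fft.ifft2(ftx).real
    ty = np.fft.ifft2(fty).real
    if pad:
        tx = tx[py : py + ny, px : px + nx]
        ty = ty[py : py + ny, px : px + nx]
    return displacement.copy_with(tx, ty, units="Pa")


def _mask_nodes(field: VectorField, mask: LabelMask) -> np.ndarray:
    """Boolean node selector: node centre falls on a labelled pixel."""
    cols = np.round(field.x / mask.pixel_size).astype(int)
    rows = np.round(field.y / mask.pixel_size).astype(int)
    inside_c = (cols >= 0) & (cols < mask.labels.shape[1])
    inside_r = (rows >= 0) & (rows < mask.labels.shape[0])
    sel = np.zeros(field.shape, dtype=bool)
    rr, cc = np.meshgrid(rows.clip(0, mask.labels.shape[0] - 1),
                         cols.clip(0, mask.labels.shape[1] - 1), indexing="ij")
    sel = mask.labels[rr, cc] > 0
    sel &= inside_r[:, None] & inside_c[None, :]
    return sel


def mean_traction(traction: VectorField, mask: LabelMask | None = None) -> float:
    """Mean traction magnitude |T| (Pa) over masked nodes (all if none)."""
    if traction.units != "Pa":
        raise ValueError("expected traction in Pa")
    mag = traction.magnitude()
    if mask is None:
        return float(mag.mean())
    sel = _mask_nodes(traction, mask)
    if not sel.any():
        raise ValueError("mask does not overlap the traction grid")
    return float(mag[sel].mean())
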