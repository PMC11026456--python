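"""First-moment (dipole) analysis of masked traction fields.

The 2x2 moment matrix M_ij = sum over masked nodes of
(x_i - o_i) * T_j * dA is symmetrised and diagonalised; the anisotropy
ratio is the major-to-minor eigenvalue magnitude ratio.  For
contractile fields both eigenvalues are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabelMask, VectorField
from .tfm import _mask_nodes

__all__ = ["DipoleResult", "dipole_matrix", "dipole_anisotropy"]

_DEGENERACY_EPS = 1e-6


@dataclass
class DipoleResult:
    moment: np.ndarray  # symmetrised 2x2, Pa·µm³
    origin: np.ndarray  # (x, y) µm
    eigenvalues: np.ndarray | None = None  # ordered |major| >= |minor|
    eigenvectors: np.ndarray | None = None  # columns, matching order
    anisotropy: float | None = None  # M-delta = |major| / |minor|
    flags: list[str] = field(default_factory=list)


def dipole_matrix(
    traction: VectorField,
    mask: LabelMask | None = None,
    origin: str = "traction_weighted_center",
) -> DipoleResult:
    """Symmetrised first moment of the (masked) traction field.

    ``origin`` is ``"traction_weighted_center"`` (default; robust for
    slightly unbalanced fields) or ``"mask_centroid"``.
    """
    if traction.units != "Pa":
        raise ValueError("expected traction in Pa")
    if not (np.all(np.isfinite(traction.u)) and np.all(np.isfinite(traction.v))):
        raise ValueError("traction contains non-finite values")
    X, Y = traction.meshgrid()
    if mask is not None:
        sel = _mask_nodes(traction, mask)
        if not sel.any():
            raise ValueError("mask does not overlap the traction grid")
    else:
        sel = np.ones(traction.shape, dtype=bool)

    tx, ty = traction.u[sel], traction.v[sel]
    xs, ys = X[sel], Y[sel]
    dA = traction.spacing ** 2

    if origin == "traction_weighted_center":
        w = np.hypot(tx, ty)
        if w.sum() == 0:
            o = np.array([xs.mean(), ys.mean()])
        else:
            o = np.array([(xs * w).sum() / w.sum(), (ys * w).sum() / w.sum()])
    elif origin == "mask_centroid":
        o = np.array([xs.mean(), ys.mean()])
    else:
        raise ValueError(f"unknown origin {origin!r}")

    dx, dy = xs - o[0], ys - o[1]
    M = np.array(
        [
            [(dx * tx).sum(), (dx * ty).sum()],
            [(dy * tx).sum(), (dy * ty).sum()],
        ]
    ) * dA
    M = 0.5 * (M + M.T)
    return DipoleResult(moment=M, origin=o)


def dipole_anisotropy(result: DipoleResult) -> DipoleResult:
    """Diagonalise the moment matrix and fill in eigenstructure and the
    anisotropy ratio M-delta = |major| / |minor| (>= 1).

    A zero matrix yields missing values with a flag; a near-singular
    minor eigenvalue caps the ratio at 1e6 with a degeneracy flag.
    """
    M = result.moment
    if np.allclose(M, 0):
        result.flags.append("zero_moment")
        result.anisotropy = None
        return result
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(np.abs(vals))[::-1]
    vals, vecs = vals[order], vecs[:, order]
    result.eigenvalues = vals
    result.eigenvectors = vecs
    major, minor = np.abs(vals)
    if minor < _DEGENERACY_EPS * major:
        result.anisotropy = 1.0 / _DEGENERACY_EPS
        result.flags.append("degenerate_minor")
    else:
        result.anisotropy = float(major / minor)
    return result
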