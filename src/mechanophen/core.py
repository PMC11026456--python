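"""Shared raster / grid / substrate data containers.

Conventions used throughout the package:

* rasters are row-major ``(row, col)`` arrays; the origin sits at the
  centre of the top-left pixel, indices are 0-based;
* ``x`` runs along columns, ``y`` along rows; physical positions are
  ``index * pixel_size`` in micrometres;
* vector fields live on regular rectangular grids whose node positions
  are given in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RasterImage",
    "ImageStack",
    "LabelMask",
    "VectorField",
    "SubstrateModel",
]


@dataclass
class RasterImage:
    """Single-channel 2-D intensity image with physical pixel size."""

    data: np.ndarray
    pixel_size: float  # µm / pixel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"RasterImage needs a 2-D array, got ndim={self.data.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ImageStack:
    """Z-stack of 2-D slices: ``data[z, row, col]``."""

    data: np.ndarray
    pixel_size: float  # µm / pixel, in-plane
    z_step: float  # µm between consecutive slices

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageStack needs a 3-D array, got ndim={self.data.ndim}")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("pixel_size and z_step must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def slice(self, z: int) -> RasterImage:
        return RasterImage(self.data[z], self.pixel_size)


@dataclass
class LabelMask:
    """Integer-labelled object mask; 0 is background."""

    labels: np.ndarray
    pixel_size: float  # µm / pixel

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMask needs a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMask labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive labels present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def support(self, label: int) -> np.ndarray:
        return self.labels == label

    def area_um2(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.pixel_size**2


@dataclass
class VectorField:
    """2-D vector field on a regular rectangular grid.

    ``u``/``v`` are the x/y components, shaped ``(len(y), len(x))``;
    ``x``/``y`` are node coordinates in µm.  ``units`` tags the physical
    meaning: ``"um"`` (displacement) or ``"Pa"`` (traction).
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    units: str = "um"
    valid: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        shape = (self.y.size, self.x.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(
                f"component shape {self.u.shape} does not match grid {shape}"
            )
        if self.x.size < 2 or self.y.size < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        for ax in (self.x, self.y):
            d = np.diff(ax)
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9) or d[0] <= 0:
                raise ValueError("grid must be regular and strictly increasing")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != shape:
                raise ValueError("valid mask shape mismatch")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y.size, self.x.size)

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    def copy_with(self, u: np.ndarray, v: np.ndarray, units: str | None = None) -> "VectorField":
        return VectorField(
            self.x.copy(), self.y.copy(), u, v,
            units=self.units if units is None else units,
            valid=None if self.valid is None else self.valid.copy(),
        )

    @staticmethod
    def on_pixel_grid(shape: tuple[int, int], pixel_size: float, units: str = "um") -> "VectorField":
        """Zero field with one node per pixel centre of a raster of ``shape``."""
        ny, nx = shape
        x = np.arange(nx) * pixel_size
        y = np.arange(ny) * pixel_size
        return VectorField(x, y, np.zeros((ny, nx)), np.zeros((ny, nx)), units=units)


# permit ν = 0.5 (incompressible limit) exactly, with a little slack
_NU_MAX = 0.5 + 1e-9


@dataclass(frozen=True)
class SubstrateModel:
    """Linear-elastic half-space substrate (polyacrylamide gel).

    ``youngs_modulus`` in Pa (gels used span roughly 0.5–30 kPa),
    ``poisson_ratio`` dimensionless (0.5 = incompressible default),
    ``pixel_size`` in µm/pixel for images of this substrate.
    """

    youngs_modulus: float
    poisson_ratio: float = 0.5
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not (0.0 <= self.poisson_ratio <= _NU_MAX):
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
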