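"""File I/O helpers: TIFF rasters, vector-field / contour / track CSVs,
MTX expression matrices, JSON truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .core import ImageStack, LabelMask, RasterImage, VectorField
from .expression_scoring import ExpressionMatrix
from .shape_metrics import Contour

__all__ = [
    "read_raster",
    "write_raster",
    "read_stack",
    "write_stack",
    "read_label_mask",
    "write_label_mask",
    "read_vector_field",
    "write_vector_field",
    "read_contours",
    "write_contours",
    "read_expression_mtx",
    "write_expression_mtx",
    "write_json",
]


def write_raster(path: str | Path, image: RasterImage) -> None:
    tifffile.imwrite(path, np.asarray(image.data, dtype=np.float32))


def read_raster(path: str | Path, pixel_size: float) -> RasterImage:
    return RasterImage(tifffile.imread(path), pixel_size)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32))


def read_stack(path: str | Path, pixel_size: float, z_step: float) -> ImageStack:
    return ImageStack(tifffile.imread(path), pixel_size, z_step)


def write_label_mask(path: str | Path, mask: LabelMask) -> None:
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit output")
    tifffile.imwrite(path, mask.labels.astype(np.uint16))


def read_label_mask(path: str | Path, pixel_size: float) -> LabelMask:
    return LabelMask(tifffile.imread(path).astype(np.int32), pixel_size)


def write_vector_field(path: str | Path, field: VectorField) -> None:
    X, Y = field.meshgrid()
    valid = np.ones(field.shape, bool) if field.valid is None else field.valid
    df = pd.DataFrame(
        {
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "fx": field.u.ravel(),
            "fy": field.v.ravel(),
            "valid": valid.ravel().astype(int),
        }
    )
    df.attrs["units"] = field.units
    with open(path, "w") as fh:
        fh.write(f"# units={field.units}\n")
        df.to_csv(fh, index=False)


def read_vector_field(path: str | Path) -> VectorField:
    with open(path) as fh:
        header = fh.readline()
        units = "um"
        if header.startswith("# units="):
            units = header.strip().split("=", 1)[1]
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    x = np.unique(df["x_um"].to_numpy())
    y = np.unique(df["y_um"].to_numpy())
    shape = (y.size, x.size)
    u = df["fx"].to_numpy().reshape(shape)
    v = df["fy"].to_numpy().reshape(shape)
    valid = df["valid"].to_numpy().astype(bool).reshape(shape)
    return VectorField(x, y, u, v, units=units, valid=valid)


def write_contours(path: str | Path, contours: list[Contour]) -> None:
    rows = []
    for i, c in enumerate(contours):
        cid = c.contour_id if c.contour_id is not None else i
        for j, (x, y) in enumerate(c.vertices):
            rows.append((cid, j, x, y))
    pd.DataFrame(rows, columns=["contour_id", "vertex_index", "x_um", "y_um"]).to_csv(
        path, index=False
    )


def read_contours(path: str | Path) -> list[Contour]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("contour_id"):
        grp = grp.sort_values("vertex_index")
        out.append(Contour(grp[["x_um", "y_um"]].to_numpy(), contour_id=int(cid)))
    return out


def write_expression_mtx(prefix: str | Path, matrix: ExpressionMatrix) -> None:
    """Write <prefix>.mtx plus <prefix>.genes.txt / <prefix>.cells.txt."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(matrix.values))
    prefix.with_suffix(".genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
    prefix.with_suffix(".cells.txt").write_text("\n".join(matrix.cell_ids) + "\n")


def read_expression_mtx(prefix: str | Path) -> ExpressionMatrix:
    prefix = Path(prefix)
    values = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    cells = prefix.with_suffix(".cells.txt").read_text().splitlines()
    return ExpressionMatrix(values, genes, cells)


def write_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
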