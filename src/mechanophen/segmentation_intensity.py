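"""Object segmentation and intensity quantification.

Threshold (global Otsu or locally adaptive mean) -> morphological
closing -> hole filling -> small-object removal -> labelling, followed
by background-subtracted mean intensities, the nuclear/cytoplasmic
ratio, and multi-plane intensity profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .core import ImageStack, LabelMask, RasterImage

__all__ = [
    "SegmentationParams",
    "IntensityResult",
    "segment_objects",
    "cytoplasm_mask",
    "mean_intensity",
    "yap_ratio",
    "plane_intensity_profile",
    "estimate_background",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Defaults are declared choices (the original scripts' parameters
    are unpublished)."""

    global_level: float | None = None  # None -> Otsu
    adaptive_block: int | None = None  # px; set to use local-mean threshold
    adaptive_offset: float = 0.0
    min_area: float = 20.0  # µm²
    closing_radius: int = 2  # px
    connectivity: int = 2  # skimage convention: 2 = 8-connected


@dataclass
class IntensityResult:
    object_id: int
    mean: float
    background: float
    background_subtracted_mean: float
    clamped: bool = False


def segment_objects(
    image: RasterImage,
    params: SegmentationParams | None = None,
) -> LabelMask:
    """Threshold and label objects in a single-channel image.

    A blank image (all intensities equal) yields an empty mask with a
    warning rather than an exception.  Border-touching objects keep
    their labels; use :func:`border_labels` to query them.
    """
    params = params or SegmentationParams()
    data = np.asarray(image.data, dtype=float)

    if params.adaptive_block is not None:
        block = params.adaptive_block
        if block % 2 == 0:
            block += 1
        local = filters.threshold_local(
            data, block_size=block, method="mean", offset=params.adaptive_offset
        )
        binary = data > local
    else:
        if params.global_level is not None:
            level = params.global_level
        else:
            if data.max() == data.min():
                warnings.warn("blank image: returning empty mask", stacklevel=2)
                return LabelMask(np.zeros(data.shape, dtype=np.int32), image.pixel_size)
            level = filters.threshold_otsu(data)
        binary = data > level

    if params.closing_radius > 0:
        binary = morphology.closing(binary, morphology.disk(params.closing_radius))
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=params.connectivity)
    min_area_px = int(round(params.min_area / image.pixel_size**2))
    if min_area_px > 1 and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area_px)
        labels[np.isin(labels, small)] = 0
        labels = measure.label(labels > 0, connectivity=params.connectivity)
    return LabelMask(labels.astype(np.int32), image.pixel_size)


def border_labels(mask: LabelMask) -> set[int]:
    """Labels of objects touching the image border (flag, not filter)."""
    edges = np.concatenate(
        [mask.labels[0, :], mask.labels[-1, :], mask.labels[:, 0], mask.labels[:, -1]]
    )
    return set(int(v) for v in np.unique(edges) if v > 0)


def cytoplasm_mask(cell: LabelMask, nucleus: LabelMask) -> LabelMask:
    """Cell support minus nucleus support, label inherited from the cell.

    Cells whose cytoplasm comes out empty (nucleus covering the whole
    cell) are flagged with a warning.
    """
    if cell.labels.shape != nucleus.labels.shape:
        raise ValueError("cell and nucleus masks have different shapes")
    cyto = np.where(nucleus.labels > 0, 0, cell.labels).astype(cell.labels.dtype)
    lost = set(cell.ids.tolist()) - set(np.unique(cyto).tolist())
    if lost:
        warnings.warn(f"empty cytoplasm for labels {sorted(lost)}", stacklevel=2)
    return LabelMask(cyto, cell.pixel_size)


def estimate_background(image: RasterImage, mask: LabelMask, dilation_px: int = 2) -> float:
    """Median intensity of the mask complement after dilating the mask
    by ``dilation_px`` (keeps object halos out of the estimate)."""
    fg = mask.labels > 0
    if dilation_px > 0:
        fg = morphology.dilation(fg, morphology.disk(dilation_px))
    bg = ~fg
    if not bg.any():
        raise ValueError("mask covers the whole image; cannot estimate background")
    return float(np.median(np.asarray(image.data)[bg]))


def mean_intensity(
    image: RasterImage,
    mask: LabelMask,
    background: float | str = "auto",
    labels: list[int] | None = None,
    clamp_negative: bool = True,
) -> list[IntensityResult]:
    """Per-label background-subtracted mean intensity.

    ``background`` is a scalar or ``"auto"`` (median of the dilated mask
    complement).  Negative subtracted means are clamped at zero with a
    warning unless ``clamp_negative`` is False.
    """
    if image.data.shape != mask.labels.shape:
        raise ValueError("image and mask shapes differ")
    if labels is None:
        labels = [int(v) for v in mask.ids]
    if not labels:
        raise ValueError("mask has no labels to measure")
    bg = estimate_background(image, mask) if background == "auto" else float(background)
    data = np.asarray(image.data, dtype=float)
    out: list[IntensityResult] = []
    for lab in labels:
        sel = mask.labels == lab
        if not sel.any():
            raise ValueError(f"label {lab} absent from mask")
        m = float(data[sel].mean())
        sub = m - bg
        clamped = False
        if sub < 0 and clamp_negative:
            warnings.warn(
                f"label {lab}: background exceeds mean; clamping at 0", stacklevel=2
            )
            sub, clamped = 0.0, True
        out.append(IntensityResult(lab, m, bg, sub, clamped))
    return out


def yap_ratio(
    image: RasterImage,
    nucleus: LabelMask,
    cytoplasm: LabelMask,
) -> dict[int, float | None]:
    """Nuclear over cytoplasmic mean intensity per object.

    Objects with zero cytoplasmic mean (or empty cytoplasm) report
    ``None`` with a warning.
    """
    data = np.asarray(image.data, dtype=float)
    ratios: dict[int, float | None] = {}
    for lab in nucleus.ids:
        nsel = nucleus.labels == lab
        csel = cytoplasm.labels == lab
        if not nsel.any():
            raise ValueError(f"label {lab} absent from nucleus mask")
        if not csel.any():
            warnings.warn(f"label {lab}: empty cytoplasm; ratio undefined", stacklevel=2)
            ratios[int(lab)] = None
            continue
        cmean = float(data[csel].mean())
        if cmean == 0:
            warnings.warn(f"label {lab}: zero cytoplasmic mean; ratio undefined", stacklevel=2)
            ratios[int(lab)] = None
            continue
        ratios[int(lab)] = float(data[nsel].mean()) / cmean
    return ratios


def plane_intensity_profile(
    stack: ImageStack,
    mask: LabelMask,
    plane_offsets_um: list[float],
    base_plane: int = 0,
) -> float:
    """Mean over the mask of the per-plane masked means at the requested
    z offsets (nearest slice to each offset)."""
    if not plane_offsets_um:
        raise ValueError("no plane offsets requested")
    sel = mask.labels > 0
    if not sel.any():
        raise ValueError("empty mask")
    means = []
    for off in plane_offsets_um:
        z = base_plane + int(round(off / stack.z_step))
        if not 0 <= z < stack.n_slices:
            raise ValueError(f"offset {off} µm falls outside the stack")
        means.append(float(np.asarray(stack.data[z], dtype=float)[sel].mean()))
    return float(np.mean(means))
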