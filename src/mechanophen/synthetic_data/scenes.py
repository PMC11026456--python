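"""Multi-channel cell/cluster scenes with exact ground-truth masks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import LabelMask

__all__ = ["ObjectSpec", "CellScene", "SceneTruth", "gen_cell_scene"]


@dataclass(frozen=True)
class ObjectSpec:
    """One rendered object: an ellipse (disk when axes equal).

    ``intensity`` maps channel name -> added intensity over the object
    support.  ``nucleus_*`` optionally place a concentric elliptical
    nucleus with its own intensities; nucleus pixels get the nucleus
    intensity INSTEAD of the cell intensity in channels where both are
    given (so intensity ratios are exact by construction).
    """

    center: tuple[float, float]  # (x, y) µm
    semi_axes: tuple[float, float]  # (a, b) µm
    intensity: dict[str, float] = field(default_factory=dict)
    orientation: float = 0.0  # degrees
    nucleus_fraction: float = 0.0  # nucleus semi-axes as fraction of cell's
    nucleus_intensity: dict[str, float] = field(default_factory=dict)


@dataclass
class SceneTruth:
    """Ground-truth masks (per class) and per-object intensities."""

    masks: dict[str, LabelMask]
    intensities: dict[str, dict[int, dict[str, float]]]  # class -> label -> channel -> value
    background: float


@dataclass
class CellScene:
    """Rendered multi-channel image; all channels share the pixel grid."""

    channels: dict[str, np.ndarray]
    pixel_size: float

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


def _ellipse_mask(
    shape: tuple[int, int], ps: float, spec: ObjectSpec, scale: float = 1.0
) -> np.ndarray:
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    x = xx * ps - spec.center[0]
    y = yy * ps - spec.center[1]
    th = np.deg2rad(spec.orientation)
    c, s = np.cos(th), np.sin(th)
    xr = c * x + s * y
    yr = -s * x + c * y
    a, b = spec.semi_axes[0] * scale, spec.semi_axes[1] * scale
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def gen_cell_scene(
    spec: list[ObjectSpec],
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.5,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    channels: tuple[str, ...] | None = None,
    require_disjoint: bool = True,
) -> tuple[CellScene, SceneTruth]:
    """Render cells (and optional nuclei) into a noisy multi-channel image.

    Ground-truth masks exactly match the rendered supports before noise.
    Objects of the same class must not overlap when ``require_disjoint``.
    """
    if any(v < 0 for o in spec for v in o.intensity.values()):
        raise ValueError("intensities must be non-negative")
    rng = np.random.default_rng(seed)
    if channels is None:
        names: list[str] = []
        for o in spec:
            names.extend(o.intensity)
            names.extend(o.nucleus_intensity)
        channels = tuple(dict.fromkeys(names)) or ("ch0",)

    cell_labels = np.zeros(shape, dtype=np.int32)
    nuc_labels = np.zeros(shape, dtype=np.int32)
    imgs = {ch: np.full(shape, float(background)) for ch in channels}
    intensities: dict[str, dict[int, dict[str, float]]] = {"cell": {}, "nucleus": {}}

    for i, obj in enumerate(spec, start=1):
        cmask = _ellipse_mask(shape, pixel_size, obj)
        if require_disjoint and np.any(cell_labels[cmask] > 0):
            raise ValueError(f"object {i} overlaps a previous object of the same class")
        cell_labels[cmask] = i
        nmask = None
        if obj.nucleus_fraction > 0:
            nmask = _ellipse_mask(shape, pixel_size, obj, scale=obj.nucleus_fraction)
            nuc_labels[nmask] = i
        intensities["cell"][i] = dict(obj.intensity)
        if nmask is not None:
            intensities["nucleus"][i] = dict(obj.nucleus_intensity)
        for ch in channels:
            if ch in obj.intensity:
                imgs[ch][cmask] = background + obj.intensity[ch]
            if nmask is not None and ch in obj.nucleus_intensity:
                imgs[ch][nmask] = background + obj.nucleus_intensity[ch]

    if noise_sd > 0:
        for ch in channels:
            imgs[ch] = imgs[ch] + rng.normal(0.0, noise_sd, size=shape)

    scene = CellScene(channels=imgs, pixel_size=pixel_size)
    truth = SceneTruth(
        masks={
            "cell": LabelMask(cell_labels, pixel_size),
            "nucleus": LabelMask(nuc_labels, pixel_size),
        },
        intensities=intensities,
        background=float(background),
    )
    return scene, truth
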