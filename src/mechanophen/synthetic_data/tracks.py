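"""Synthetic centroid time series with closed-form velocity truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrackTruth", "gen_tracks"]


@dataclass
class TrackTruth:
    object_id: int
    motion: str
    velocity_um_per_min: float  # accumulated path / total time


def gen_tracks(
    n_objects: int,
    motion: str = "linear",
    step: float = 5.0,  # µm per frame transition
    n_frames: int = 10,
    frame_interval: float = 20.0,  # min
    seed: int = 0,
    *,
    spacing: float = 200.0,  # µm between object start points
) -> tuple[pd.DataFrame, list[TrackTruth]]:
    """Generate per-frame centroid tables plus ground-truth velocities.

    Truth velocity is accumulated path length over total elapsed time,
    i.e. ``(n_frames - 1) * step / ((n_frames - 1) * frame_interval)``
    for the constant-step motions.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if step < 0:
        raise ValueError("step must be non-negative")
    if motion not in ("stationary", "linear", "random_walk"):
        raise ValueError(f"unknown motion {motion!r}")
    rng = np.random.default_rng(seed)

    starts = np.column_stack(
        [np.arange(n_objects) * spacing, np.zeros(n_objects)]
    ) + rng.uniform(0, spacing / 10, size=(n_objects, 2))

    rows = []
    truths: list[TrackTruth] = []
    for oid in range(n_objects):
        pos = starts[oid].copy()
        if motion == "linear":
            ang = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.cos(ang), np.sin(ang)])
        path = 0.0
        rows.append((0, oid, pos[0], pos[1]))
        for f in range(1, n_frames):
            if motion == "stationary":
                d = np.zeros(2)
            elif motion == "linear":
                d = step * direction
            else:
                ang = rng.uniform(0, 2 * np.pi)
                d = step * np.array([np.cos(ang), np.sin(ang)])
            pos = pos + d
            path += float(np.linalg.norm(d))
            rows.append((f, oid, pos[0], pos[1]))
        total_time = (n_frames - 1) * frame_interval
        truths.append(
            TrackTruth(object_id=oid, motion=motion, velocity_um_per_min=path / total_time)
        )
    table = pd.DataFrame(rows, columns=["frame", "object_id", "x_um", "y_um"])
    return table, truths
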