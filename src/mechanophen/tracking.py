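"""Proximity-based centroid linking and accumulated-distance velocity.

Trajectories are built frame to frame by greedy mutually-nearest-pair
assignment; velocity is accumulated path length divided by total
elapsed time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "link_centroids", "velocity", "velocity_table"]

MAX_LINK_DEFAULT = 30.0  # µm
MIN_TRACK_FRAMES_DEFAULT = 5


@dataclass
class Trajectory:
    track_id: int
    frames: list[int] = field(default_factory=list)
    x: list[float] = field(default_factory=list)
    y: list[float] = field(default_factory=list)
    frame_interval: float = 1.0  # min
    flags: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def _frames_dict(frames: pd.DataFrame | dict) -> dict[int, np.ndarray]:
    if isinstance(frames, pd.DataFrame):
        out = {}
        for f, grp in frames.groupby("frame"):
            out[int(f)] = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        return out
    return {int(f): np.asarray(pts, dtype=float).reshape(-1, 2) for f, pts in frames.items()}


def link_centroids(
    frames: pd.DataFrame | dict,
    max_link_distance: float = MAX_LINK_DEFAULT,
    frame_interval: float = 1.0,
) -> list[Trajectory]:
    """Link per-frame centroids into trajectories by proximity.

    Greedy globally-nearest-pair assignment per frame transition (ties
    broken toward the smaller track id); candidate links beyond
    ``max_link_distance`` are rejected and start new trajectories.
    ``frames`` is a DataFrame with columns frame, x_um, y_um (object_id
    optional, ignored) or a dict frame -> (n, 2) array.
    """
    per_frame = _frames_dict(frames)
    if len(per_frame) < 2:
        raise ValueError("need at least 2 frames to link")
    frame_ids = sorted(per_frame)

    tracks: list[Trajectory] = []
    active: dict[int, int] = {}  # track index -> last position row in its lists

    def new_track(f: int, x: float, y: float) -> int:
        t = Trajectory(track_id=len(tracks), frame_interval=frame_interval)
        t.frames.append(f)
        t.x.append(x)
        t.y.append(y)
        tracks.append(t)
        return t.track_id

    first = frame_ids[0]
    pts0 = per_frame[first]
    if len(pts0) != len(np.unique(pts0, axis=0)):
        warnings.warn("duplicate centroids in one frame", stacklevel=2)
    current = [new_track(first, px, py) for px, py in pts0]

    for f in frame_ids[1:]:
        pts = per_frame[f]
        if len(pts) and len(pts) != len(np.unique(pts, axis=0)):
            warnings.warn(f"duplicate centroids in frame {f}", stacklevel=2)
        prev_ids = list(current)
        prev_pos = np.array(
            [[tracks[t].x[-1], tracks[t].y[-1]] for t in prev_ids]
        ).reshape(-1, 2)
        n_prev, n_new = len(prev_ids), len(pts)
        assigned_prev = set()
        assigned_new = set()
        if n_prev and n_new:
            d = np.linalg.norm(prev_pos[:, None, :] - pts[None, :, :], axis=2)
            # greedy global nearest pair; ties toward the smaller track id
            order = sorted(
                ((d[i, j], tracks[prev_ids[i]].track_id, i, j)
                 for i in range(n_prev) for j in range(n_new)),
                key=lambda t: (t[0], t[1], t[3]),
            )
            for dist, _tid, i, j in order:
                if dist > max_link_distance:
                    break
                if i in assigned_prev or j in assigned_new:
                    continue
                assigned_prev.add(i)
                assigned_new.add(j)
                t = tracks[prev_ids[i]]
                t.frames.append(f)
                t.x.append(float(pts[j, 0]))
                t.y.append(float(pts[j, 1]))
        current = [prev_ids[i] for i in sorted(assigned_prev)]
        for j in range(n_new):
            if j not in assigned_new:
                current.append(new_track(f, float(pts[j, 0]), float(pts[j, 1])))

    for t in tracks:
        if len(t.frames) == len(set(t.frames)) and (np.diff(t.frames) == 1).all():
            pass
        else:
            t.flags.append("gapped")
    return tracks


def velocity(track: Trajectory, mode: str = "accumulated") -> float | None:
    """Migration speed in µm/min: accumulated path length over total
    elapsed time.  Returns None (missing) for single-point tracks.
    """
    if mode != "accumulated":
        raise ValueError(f"unknown mode {mode!r}")
    if track.n_frames < 2:
        warnings.warn("single-point trajectory: velocity undefined", stacklevel=2)
        return None
    pos = track.positions()
    path = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())
    total_time = (track.frames[-1] - track.frames[0]) * track.frame_interval
    return path / total_time


def velocity_table(
    tracks: list[Trajectory],
    min_frames: int = MIN_TRACK_FRAMES_DEFAULT,
) -> pd.DataFrame:
    """Per-track velocities; tracks shorter than ``min_frames`` are kept
    in the table but flagged excluded (the automated stand-in for manual
    track curation)."""
    rows = []
    for t in tracks:
        v = velocity(t) if t.n_frames >= 2 else None
        rows.append(
            {
                "track_id": t.track_id,
                "n_frames": t.n_frames,
                "velocity_um_per_min": v,
                "excluded": t.n_frames < min_frames,
            }
        )
    return pd.DataFrame(rows)
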