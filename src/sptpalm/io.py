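"""File formats: TIFF movies and masks (with JSON sidecars), CSV tables.

Movies and images are plain TIFF; masks are 8-bit {0, 255} TIFF with a
JSON sidecar (same path + '.json') holding pixel_nm, origin and label so
grids stay registered to the shared nm frame. Localization tables use the
bit-stable column order frame,x_nm,y_nm,sigma_nm,intensity,background,
precision_nm; trajectory tables prepend trajectory_id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from sptpalm.localize import LOC_COLUMNS
from sptpalm.mapping import MaskImage
from sptpalm.simulate import MovieStack
from sptpalm.track import Trajectory

__all__ = [
    "save_movie",
    "load_movie",
    "save_mask",
    "load_mask",
    "save_localizations",
    "load_localizations",
    "save_trajectories",
    "load_trajectories",
]

TRAJ_COLUMNS = ["trajectory_id"] + LOC_COLUMNS


def save_movie(path, movie: MovieStack) -> None:
    tifffile.imwrite(
        path,
        movie.frames.astype(np.float32),
        photometric="minisblack",
        metadata={
            "pixel_size_nm": movie.pixel_size_nm,
            "frame_interval_s": movie.frame_interval_s,
        },
    )


def load_movie(path, pixel_size_nm=None, frame_interval_s=None) -> MovieStack:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    return MovieStack(
        frames,
        pixel_size_nm or meta.get("pixel_size_nm", 1.0),
        frame_interval_s or meta.get("frame_interval_s", 0.02),
    )


def save_mask(path, mask: MaskImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, (mask.data.astype(np.uint8)) * 255)
    sidecar = {
        "pixel_nm": mask.pixel_nm,
        "origin_nm": list(mask.origin_nm),
        "label": mask.label,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_mask(path) -> MaskImage:
    path = Path(path)
    data = tifffile.imread(path) > 0
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return MaskImage(
        data,
        meta.get("pixel_nm", 1.0),
        tuple(meta.get("origin_nm", (0.0, 0.0))),
        meta.get("label", "mask"),
    )


def save_localizations(path, locs: pd.DataFrame) -> None:
    locs[LOC_COLUMNS].to_csv(path, index=False)


def load_localizations(path) -> pd.DataFrame:
    return pd.read_csv(path)[LOC_COLUMNS]


def save_trajectories(path, trajs: list[Trajectory]) -> None:
    rows = []
    for t in trajs:
        for k in range(t.n_points):
            rows.append(
                (t.trajectory_id, t.frames[k], t.x_nm[k], t.y_nm[k], np.nan, np.nan, np.nan,
                 t.precision_nm[k])
            )
    df = pd.DataFrame(rows, columns=TRAJ_COLUMNS[:4] + ["sigma_nm", "intensity", "background", "precision_nm"])
    df.to_csv(path, index=False)


def load_trajectories(path, dt_s: float = 0.02) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for tid, sub in df.groupby("trajectory_id", sort=True):
        sub = sub.sort_values("frame")
        out.append(
            Trajectory(
                trajectory_id=int(tid),
                frames=sub["frame"].to_numpy(dtype=int),
                x_nm=sub["x_nm"].to_numpy(),
                y_nm=sub["y_nm"].to_numpy(),
                precision_nm=sub["precision_nm"].to_numpy(),
                dt_s=dt_s,
            )
        )
    return out
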