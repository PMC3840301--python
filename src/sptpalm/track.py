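"""Trajectory building: frame-to-frame linking of localizations.

Consecutive frames are linked by an optimal bipartite assignment that
minimizes total squared displacement, with links beyond a maximum
displacement gate rejected (the gate also acts as the cost of leaving a
localization unlinked, the standard construction in single-particle
tracking). With irreversible bleaching and no blinking correction the
default allows no frame gaps; unmatched localizations start new
trajectories, so every localization belongs to exactly one trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["Trajectory", "link_localizations", "filter_trajectories", "default_max_disp_nm"]

logger = logging.getLogger(__name__)

_BIG = 1e12  # forbidden-link cost


@dataclass
class Trajectory:
    """One tracked molecule: ordered localizations of a single emitter."""

    trajectory_id: int
    frames: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    precision_nm: np.ndarray
    dt_s: float = 0.02

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        self.precision_nm = np.asarray(self.precision_nm, dtype=float)
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("trajectory frames must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        return max(self.n_points - 1, 0)


def default_max_disp_nm(d_max_um2s: float = 0.5, dt_s: float = 0.02) -> float:
    """Linking gate: 4 sd of the expected frame-to-frame displacement.

    ``4 * sqrt(4 * D_max * dt)`` comfortably covers the fastest plausible
    Brownian steps (D_max defaults to 0.5 um^2/s, several-fold above
    typical membrane-receptor medians).
    """
    return 4.0 * np.sqrt(4.0 * d_max_um2s * 1e6 * dt_s)


def link_localizations(
    locs: pd.DataFrame,
    max_disp_nm: float | None = None,
    max_gap: int = 0,
    dt_s: float = 0.02,
) -> list[Trajectory]:
    """Link a localization table into trajectories.

    For each consecutive frame pair, active trajectory ends and new-frame
    detections are matched by minimum total squared displacement
    (rectangular assignment with per-item opt-out at cost
    ``max_disp_nm**2``); links longer than ``max_disp_nm`` are impossible.
    Unmatched detections seed new trajectories; trajectories unmatched for
    more than ``max_gap`` frames are closed. Singletons are kept, so the
    output partitions the input.
    """
    if max_disp_nm is None:
        max_disp_nm = default_max_disp_nm(dt_s=dt_s)
    if max_disp_nm <= 0:
        raise ValueError("max_disp_nm must be positive")
    if len(locs) == 0:
        return []
    cols_extra = "precision_nm" in locs.columns
    # canonical within-frame order makes output invariant to input row order
    locs = locs.sort_values(["frame", "x_nm", "y_nm"], kind="stable").reset_index(drop=True)
    frames_present = locs["frame"].to_numpy()
    gate2 = max_disp_nm**2

    next_id = 0
    active: list[dict] = []  # id, last (x, y), last_frame, rows (list of row idx)
    done: list[dict] = []

    for f in range(int(frames_present.min()), int(frames_present.max()) + 1):
        idx = np.flatnonzero(frames_present == f)
        # retire trajectories that exceeded the gap tolerance
        still, retired = [], []
        for tr in active:
            (still if f - tr["last_frame"] <= max_gap + 1 else retired).append(tr)
        done.extend(retired)
        active = still
        if idx.size == 0:
            continue
        xs = locs["x_nm"].to_numpy()[idx]
        ys = locs["y_nm"].to_numpy()[idx]
        na, nd = len(active), idx.size
        assigned_det = np.full(nd, -1)
        if na and nd:
            ax = np.array([tr["x"] for tr in active])
            ay = np.array([tr["y"] for tr in active])
            d2 = (ax[:, None] - xs[None, :]) ** 2 + (ay[:, None] - ys[None, :]) ** 2
            cost = np.full((na + nd, nd + na), 0.0)
            cost[:na, :nd] = np.where(d2 <= gate2, d2, _BIG)
            cost[:na, nd:] = _BIG
            cost[np.arange(na), nd + np.arange(na)] = gate2  # trajectory stays unlinked
            cost[na:, :nd] = _BIG
            cost[na + np.arange(nd), np.arange(nd)] = gate2  # detection starts a track
            rr, cc = linear_sum_assignment(cost)
            for r, c in zip(rr, cc):
                if r < na and c < nd and cost[r, c] < _BIG:
                    active[r]["rows"].append(idx[c])
                    active[r]["x"], active[r]["y"] = xs[c], ys[c]
                    active[r]["last_frame"] = f
                    assigned_det[c] = r
        for j in range(nd):
            if assigned_det[j] < 0:
                active.append(
                    {"id": next_id, "x": xs[j], "y": ys[j], "last_frame": f, "rows": [idx[j]]}
                )
                next_id += 1
    done.extend(active)
    done.sort(key=lambda tr: tr["id"])

    out = []
    fr = locs["frame"].to_numpy()
    x = locs["x_nm"].to_numpy()
    y = locs["y_nm"].to_numpy()
    prec = locs["precision_nm"].to_numpy() if cols_extra else np.zeros(len(locs))
    for tr in done:
        rows = np.array(tr["rows"], dtype=int)
        out.append(
            Trajectory(
                trajectory_id=tr["id"],
                frames=fr[rows],
                x_nm=x[rows],
                y_nm=y[rows],
                precision_nm=prec[rows],
                dt_s=dt_s,
            )
        )
    logger.info("link_localizations: %d localizations -> %d trajectories", len(locs), len(out))
    return out


def filter_trajectories(trajs: list[Trajectory], min_points: int) -> list[Trajectory]:
    """Keep trajectories with at least ``min_points`` localizations.

    Short trajectories carry large MSD estimation error; diffusion analyses
    conventionally keep >=10-point trajectories (>=5 for the area-explored
    statistic).
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    kept = [t for t in trajs if t.n_points >= min_points]
    logger.info(
        "filter_trajectories: kept %d / %d (min_points=%d)", len(kept), len(trajs), min_points
    )
    return kept
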