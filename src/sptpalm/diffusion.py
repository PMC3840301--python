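"""Per-trajectory diffusion quantification and mask-based classification.

The time-averaged mean squared displacement of a trajectory of N+1 points is

    MSD(n*dt) = (N - n)^-1 * sum_{i=1}^{N-n} [(x_{i+n} - x_i)^2 + (y_{i+n} - y_i)^2]

with dt the frame interval and n the lag index. For 2-D Brownian motion
with localization noise, MSD(t) = 4*D*t + 4*sigma_x^2, so an ordinary
least-squares fit of the early MSD points (lags 2-5 by default, hence the
field's D_{2-5}) gives the diffusion coefficient from the slope and the
localization accuracy sigma_x from the intercept.

Confinement is additionally quantified by the area explored per step
(convex-hull area of the trajectory divided by its number of steps, in
camera-pixel^2 units), a trajectory-length-independent statistic, and by
classifying each trajectory against a synaptic mask (synaptic vs
extra-synaptic) and a nanocluster mask (trapped vs free).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from sptpalm.mapping import MaskImage
from sptpalm.track import Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "DiffusionRecord",
    "compute_msd",
    "fit_diffusion_coefficient",
    "area_explored_per_step",
    "classify_trajectory",
    "analyze_trajectories",
    "records_to_dataframe",
    "ensemble_msd",
]


@dataclass
class MSDCurve:
    """Time-averaged MSD of one trajectory, in um^2 per lag."""

    lag_index: np.ndarray  # n = 1..n_max
    lag_time_s: np.ndarray  # n * dt
    msd_um2: np.ndarray
    n_pairs: np.ndarray  # N - n displacement pairs averaged at each lag

    @property
    def n_max(self) -> int:
        return len(self.lag_index)


@dataclass
class DiffusionFit:
    """MSD line fit: D from the slope, localization accuracy from the intercept."""

    D_um2s: float
    sigma_x_nm: float
    fit_r2: float
    flags: tuple[str, ...] = ()


@dataclass
class DiffusionRecord:
    """Pooled per-trajectory row of the statistical analysis."""

    trajectory_id: int
    D_um2s: float
    sigma_x_nm: float
    fit_r2: float
    n_points: int
    area_per_step_px: float
    synaptic_label: str = "unassigned"  # synaptic | extra-synaptic | unassigned
    cluster_label: str = "unassigned"  # trapped | free | unassigned
    condition: str = ""
    flags: tuple[str, ...] = ()


def compute_msd(traj: Trajectory, n_max: int | None = None) -> MSDCurve:
    """Time-averaged MSD over lags 1..n_max (default N - 1).

    Requires a gap-free trajectory (consecutive frames); ``n_max`` must be
    at most N = n_steps.
    """
    N = traj.n_steps
    if N < 1:
        raise ValueError("trajectory must have at least 2 points")
    if np.any(np.diff(traj.frames) != 1):
        raise ValueError("MSD requires a gap-free trajectory (max_gap=0 upstream)")
    if n_max is None:
        n_max = N
    if n_max < 1 or n_max > N:
        raise ValueError(f"n_max must be in [1, {N}]")
    x = traj.x_nm / 1000.0  # um
    y = traj.y_nm / 1000.0
    lags = np.arange(1, n_max + 1)
    msd = np.empty(n_max)
    for k, n in enumerate(lags):
        dx = x[n:] - x[:-n]
        dy = y[n:] - y[:-n]
        msd[k] = np.mean(dx**2 + dy**2)
    return MSDCurve(
        lag_index=lags,
        lag_time_s=lags * traj.dt_s,
        msd_um2=msd,
        n_pairs=traj.n_points - lags,  # (i, i+n) pairs available at lag n
    )


def fit_diffusion_coefficient(
    msd: MSDCurve, fit_lags: tuple[int, ...] = (2, 3, 4, 5)
) -> DiffusionFit:
    """OLS fit of MSD(t) = 4*D*t + 4*sigma_x^2 over the chosen lags.

    Default lags 2-5 (the D_{2-5} convention). A negative fitted slope is
    retained in D and flagged rather than clamped, so pooled medians are
    not biased; a negative intercept maps to sigma_x = 0 with a flag.
    """
    fit_lags = tuple(fit_lags)
    if msd.n_max < max(fit_lags):
        raise ValueError(f"MSD curve has {msd.n_max} lags; need {max(fit_lags)}")
    sel = np.isin(msd.lag_index, fit_lags)
    if sel.sum() != len(fit_lags):
        raise ValueError("requested fit lags missing from curve")
    t = msd.lag_time_s[sel]
    y = msd.msd_um2[sel]
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    flags = []
    D = slope / 4.0
    if D < 0:
        flags.append("negative_D")
    if intercept < 0:
        flags.append("negative_intercept")
    sigma_x_um = np.sqrt(max(intercept, 0.0) / 4.0)
    return DiffusionFit(float(D), float(sigma_x_um * 1000.0), float(r2), tuple(flags))


def area_explored_per_step(traj: Trajectory, camera_pixel_nm: float) -> float:
    """Convex-hull area of the trajectory per step, in camera-pixel^2.

    The total surface covered by the trajectory (its convex hull) divided
    by the number of steps; collinear trajectories have zero hull area.
    Needs at least 3 points (>=5 in conventional use).
    """
    if traj.n_points < 3:
        raise ValueError("area explored needs at least 3 points")
    if camera_pixel_nm <= 0:
        raise ValueError("camera_pixel_nm must be positive")
    pts = np.column_stack([traj.x_nm, traj.y_nm])
    try:
        area_nm2 = ConvexHull(pts).volume  # 2-D: volume is the area
    except QhullError:
        area_nm2 = 0.0  # degenerate (collinear) point set
    return float(area_nm2 / camera_pixel_nm**2 / traj.n_steps)


def classify_trajectory(
    traj: Trajectory,
    synapse_mask: MaskImage | None,
    cluster_mask: MaskImage | None,
    overlap_fraction: float = 0.5,
) -> tuple[str, str]:
    """Label a trajectory against the synaptic and nanocluster masks.

    A trajectory is synaptic (resp. trapped) if at least
    ``overlap_fraction`` of its localizations fall inside the synapse
    (resp. nanocluster) mask; the two labels are independent. A missing
    mask yields "unassigned" for its label.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")

    def frac_inside(mask: MaskImage) -> float:
        return float(mask.contains(traj.x_nm, traj.y_nm).mean())

    if synapse_mask is None:
        syn = "unassigned"
    else:
        syn = "synaptic" if frac_inside(synapse_mask) >= overlap_fraction else "extra-synaptic"
    if cluster_mask is None:
        clu = "unassigned"
    else:
        clu = "trapped" if frac_inside(cluster_mask) >= overlap_fraction else "free"
    return syn, clu


def analyze_trajectories(
    trajs: list[Trajectory],
    camera_pixel_nm: float,
    synapse_mask: MaskImage | None = None,
    cluster_mask: MaskImage | None = None,
    fit_lags: tuple[int, ...] = (2, 3, 4, 5),
    overlap_fraction: float = 0.5,
    condition: str = "",
) -> tuple[list[DiffusionRecord], dict[int, MSDCurve]]:
    """Run the full per-trajectory analysis.

    For each trajectory: MSD, D_{2-5} fit, area explored per step (NaN
    below 3 points) and mask classification. Returns the record list and
    the MSD curves keyed by trajectory id. Trajectories too short for the
    MSD fit are skipped.
    """
    records: list[DiffusionRecord] = []
    curves: dict[int, MSDCurve] = {}
    need = max(fit_lags) + 1
    for traj in trajs:
        if traj.n_points < need:
            continue
        curve = compute_msd(traj)
        fit = fit_diffusion_coefficient(curve, fit_lags)
        try:
            area = area_explored_per_step(traj, camera_pixel_nm)
        except ValueError:
            area = float("nan")
        syn, clu = classify_trajectory(traj, synapse_mask, cluster_mask, overlap_fraction)
        curves[traj.trajectory_id] = curve
        records.append(
            DiffusionRecord(
                trajectory_id=traj.trajectory_id,
                D_um2s=fit.D_um2s,
                sigma_x_nm=fit.sigma_x_nm,
                fit_r2=fit.fit_r2,
                n_points=traj.n_points,
                area_per_step_px=area,
                synaptic_label=syn,
                cluster_label=clu,
                condition=condition,
                flags=fit.flags,
            )
        )
    return records, curves


def records_to_dataframe(records: list[DiffusionRecord]) -> pd.DataFrame:
    """Flatten records into the pooled analysis table."""
    return pd.DataFrame(
        {
            "trajectory_id": [r.trajectory_id for r in records],
            "D_um2s": [r.D_um2s for r in records],
            "sigma_x_nm": [r.sigma_x_nm for r in records],
            "fit_r2": [r.fit_r2 for r in records],
            "n_points": [r.n_points for r in records],
            "area_per_step_px": [r.area_per_step_px for r in records],
            "synaptic_label": [r.synaptic_label for r in records],
            "cluster_label": [r.cluster_label for r in records],
            "condition": [r.condition for r in records],
        }
    )


def ensemble_msd(
    curves_by_group: dict[str, list[MSDCurve]], n_lags: int | None = None
) -> dict[str, pd.DataFrame]:
    """Pointwise mean +/- SEM of per-trajectory MSD curves per group.

    Each group's output holds, for every lag up to ``n_lags`` (default: the
    longest lag reached by >= 2 of the group's curves), the mean MSD, its
    standard error over trajectories and the number of curves contributing.
    Groups with fewer than 2 curves are omitted with a warning.
    """
    out: dict[str, pd.DataFrame] = {}
    for group, curves in curves_by_group.items():
        if len(curves) < 2:
            warnings.warn(f"group '{group}' has < 2 trajectories; omitted")
            continue
        lengths = sorted(c.n_max for c in curves)
        max_lag = lengths[-2]  # longest lag with >= 2 contributing curves
        if n_lags is not None:
            max_lag = min(max_lag, n_lags)
        dt = curves[0].lag_time_s[0] / curves[0].lag_index[0]
        rows = []
        for n in range(1, max_lag + 1):
            vals = np.array([c.msd_um2[n - 1] for c in curves if c.n_max >= n])
            if len(vals) < 2:
                break
            rows.append(
                (n, n * dt, vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals)), len(vals))
            )
        out[group] = pd.DataFrame(
            rows, columns=["lag_index", "lag_time_s", "mean_msd_um2", "sem_msd_um2", "n_traj"]
        )
    return out
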