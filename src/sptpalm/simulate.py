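"""Ground-truthed synthetic sptPALM acquisitions.

Emulates a live-cell sptPALM experiment on a membrane receptor fused to a
green-to-red photoconvertible protein (Dendra2-like): a sparse subset of
molecules is stochastically photoconverted, each stays on for a geometric
number of frames before irreversibly bleaching, and while on it diffuses in
the plane — either freely (Brownian) or trapped inside a ~105 nm nanodomain
modeled as a hard reflecting disc. The EMCCD camera model integrates a 2-D
Gaussian PSF over 106.7 nm pixels, applies Poisson shot noise, a
multiplicative gain and Gaussian read noise.

Defaults reproduce the acquisition geometry of the emulated experiment:
16 um camera pixels behind 100x * 1.5x magnification (106.7 nm in sample
plane), 20 ms frames (50 Hz), free diffusion ~0.09 um^2/s versus trapped
~0.04 um^2/s with ~35% of molecules confined in 105 nm nanodomains.

The ground truth (true positions, motion regime, photophysical state, true
nanodomain and synapse masks) is retained so every downstream stage can be
validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from sptpalm.mapping import MaskImage, RenderedImage

__all__ = [
    "SimConfig",
    "GroundTruthTracks",
    "MovieStack",
    "simulate_motion",
    "simulate_photophysics",
    "render_movie",
    "make_reference_images",
    "simulate_acquisition",
]

# photophysical states
UNCONVERTED, ON, BLEACHED = 0, 1, 2


@dataclass
class SimConfig:
    """All knobs of the synthetic acquisition.

    Rates are per-frame probabilities; distances nm unless suffixed;
    diffusion coefficients um^2/s.
    """

    field_size_px: int = 64
    pixel_size_nm: float = 16000.0 / 150.0  # 16 um pixel / (100x objective * 1.5x lens)
    frame_interval_s: float = 0.02  # 50 Hz
    n_frames: int = 1600
    n_emitters: int = 120
    conversion_rate_per_frame: float = 0.004
    bleach_rate_per_frame: float = 0.05
    d_free_um2s: float = 0.09
    d_trapped_um2s: float = 0.04
    trapped_fraction: float = 0.35
    n_clusters: int = 12
    cluster_diameter_nm: float = 105.0
    n_synapses: int = 4
    synapse_diameter_nm: float = 500.0
    psf_sigma_nm: float = 130.0
    photons_per_frame: float = 300.0
    background_photons: float = 10.0
    read_noise_e: float = 1.0
    em_gain: float = 1.0
    mask_pixel_nm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_rate_per_frame", "bleach_rate_per_frame", "trapped_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.n_frames <= 0 or self.n_emitters <= 0:
            raise ValueError("n_frames and n_emitters must be positive")
        if self.d_free_um2s < 0 or self.d_trapped_um2s < 0:
            raise ValueError("diffusion coefficients must be nonnegative")

    @property
    def field_size_nm(self) -> float:
        return self.field_size_px * self.pixel_size_nm

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class GroundTruthTracks:
    """Per-emitter truth: motion regime, positions and photostate per frame.

    ``x_nm``/``y_nm`` have shape (n_emitters, n_frames); ``photostate`` holds
    0 = unconverted, 1 = on, 2 = bleached and is monotone per emitter
    (conversion and bleaching are irreversible).
    """

    regime: np.ndarray  # 'free' | 'trapped', shape (n_emitters,)
    cluster_id: np.ndarray  # int, -1 for free emitters
    x_nm: np.ndarray
    y_nm: np.ndarray
    photostate: np.ndarray  # int8 (n_emitters, n_frames); all UNCONVERTED until photophysics runs
    cluster_centers_nm: np.ndarray  # (n_clusters, 2) x, y
    synapse_centers_nm: np.ndarray  # (n_synapses, 2)

    @property
    def n_emitters(self) -> int:
        return self.x_nm.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x_nm.shape[1]

    def on_frames(self, i: int) -> np.ndarray:
        """Frame indices in which emitter ``i`` is fluorescent."""
        return np.flatnonzero(self.photostate[i] == ON)


@dataclass
class MovieStack:
    """Rendered acquisition: (frame, row, col) intensities plus calibration."""

    frames: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent substreams per stage so stages can be re-run in isolation
    return np.random.default_rng([config.seed, stream])


def _place_discs(
    rng: np.random.Generator,
    n: int,
    radius_nm: float,
    field_nm: float,
    existing: list[tuple[float, float, float]],
    max_tries: int = 2000,
) -> np.ndarray:
    """Uniformly place ``n`` disc centers, discs fully in-field and
    non-overlapping with each other or ``existing`` (center, radius) discs."""
    centers = []
    for _ in range(n):
        for attempt in range(max_tries):
            c = rng.uniform(radius_nm, field_nm - radius_nm, size=2)
            ok = all(
                np.hypot(c[0] - ex, c[1] - ey) > radius_nm + er
                for ex, ey, er in existing
            )
            if ok:
                centers.append(c)
                existing.append((c[0], c[1], radius_nm))
                break
        else:
            raise RuntimeError(
                f"could not place {n} non-overlapping discs of radius {radius_nm} nm "
                f"in a {field_nm:.0f} nm field after {max_tries} tries"
            )
    return np.array(centers).reshape(n, 2)


def place_domains(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (per seed) placement of nanocluster and synapse centers.

    Shared by :func:`simulate_motion` and :func:`make_reference_images` so
    that tracks and reference masks agree on the same ground-truth geometry.
    """
    rng = _rng(config, 0)
    occupied: list[tuple[float, float, float]] = []
    synapses = _place_discs(
        rng, config.n_synapses, config.synapse_diameter_nm / 2, config.field_size_nm, occupied
    )
    clusters = _place_discs(
        rng, config.n_clusters, config.cluster_diameter_nm / 2, config.field_size_nm, occupied
    )
    return clusters, synapses


def _reflect_interval(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi] by specular reflection."""
    span = hi - lo
    x = np.mod(x - lo, 2 * span)
    x = np.where(x > span, 2 * span - x, x)
    return x + lo


#: substeps per frame for confined walks; keeps the discrete reflection
#: scheme close to continuous reflected diffusion when the per-frame step
#: is comparable to the domain radius
_N_SUB = 10


def _reflected_disc_walk(
    rng: np.random.Generator, n_walkers: int, n_frames: int, sd_frame: float, radius: float
) -> np.ndarray:
    """Brownian walks reflected at a disc of ``radius`` centered at the origin.

    Starts uniform in the disc; each frame step is split into ``_N_SUB``
    substeps, reflecting radially at the boundary after each. Returns
    positions of shape (n_walkers, n_frames, 2).
    """
    r = radius * np.sqrt(rng.random(n_walkers))
    th = rng.uniform(0, 2 * np.pi, n_walkers)
    pos = np.column_stack([r * np.cos(th), r * np.sin(th)])
    out = np.empty((n_walkers, n_frames, 2))
    out[:, 0] = pos
    sd_sub = sd_frame / np.sqrt(_N_SUB)
    for t in range(1, n_frames):
        for _ in range(_N_SUB):
            pos = pos + rng.normal(0.0, sd_sub, size=pos.shape)
            rr = np.hypot(pos[:, 0], pos[:, 1])
            while np.any(rr > radius):
                outside = rr > radius
                scale = (2 * radius - rr[outside]) / rr[outside]
                pos[outside] *= scale[:, None]
                rr[outside] = np.abs(2 * radius - rr[outside])
        out[:, t] = pos
    return out


def simulate_motion(config: SimConfig) -> GroundTruthTracks:
    """Simulate 2-D Brownian motion for free and nanodomain-trapped emitters.

    Free emitters take Gaussian steps of per-axis variance ``2*D_free*dt``
    and reflect at the field edges. Trapped emitters are assigned to a
    nanocluster, start uniformly inside its disc and reflect at the disc
    boundary (hard confinement, no escape). Regime assignment is Bernoulli
    with ``trapped_fraction``.
    """
    rng = _rng(config, 1)
    clusters, synapses = place_domains(config)
    n, T = config.n_emitters, config.n_frames
    field = config.field_size_nm
    dt = config.frame_interval_s

    trapped = rng.random(n) < config.trapped_fraction
    if config.n_clusters == 0:
        trapped[:] = False
    cluster_id = np.where(trapped, rng.integers(0, max(config.n_clusters, 1), size=n), -1)

    x = np.empty((n, T))
    y = np.empty((n, T))

    # free emitters: reflected Brownian motion in the field
    free_idx = np.flatnonzero(~trapped)
    if free_idx.size:
        sd = np.sqrt(2.0 * config.d_free_um2s * 1e6 * dt)  # nm per axis per step
        x0 = rng.uniform(0, field, size=free_idx.size)
        y0 = rng.uniform(0, field, size=free_idx.size)
        dx = rng.normal(0.0, sd, size=(free_idx.size, T - 1)) if T > 1 else np.empty((free_idx.size, 0))
        dy = rng.normal(0.0, sd, size=(free_idx.size, T - 1)) if T > 1 else np.empty((free_idx.size, 0))
        xs = np.cumsum(np.hstack([x0[:, None], dx]), axis=1)
        ys = np.cumsum(np.hstack([y0[:, None], dy]), axis=1)
        x[free_idx] = _reflect_interval(xs, 0.0, field)
        y[free_idx] = _reflect_interval(ys, 0.0, field)

    # trapped emitters: reflecting disc boundary around their cluster center
    trap_idx = np.flatnonzero(trapped)
    if trap_idx.size:
        R = config.cluster_diameter_nm / 2.0
        sd_t = np.sqrt(2.0 * config.d_trapped_um2s * 1e6 * dt)
        walk = _reflected_disc_walk(rng, trap_idx.size, T, sd_t, R)
        centers = clusters[cluster_id[trap_idx]]
        x[trap_idx] = walk[:, :, 0] + centers[:, 0:1]
        y[trap_idx] = walk[:, :, 1] + centers[:, 1:2]

    regime = np.where(trapped, "trapped", "free")
    return GroundTruthTracks(
        regime=regime,
        cluster_id=cluster_id,
        x_nm=x,
        y_nm=y,
        photostate=np.full((n, T), UNCONVERTED, dtype=np.int8),
        cluster_centers_nm=clusters,
        synapse_centers_nm=synapses,
    )


def simulate_photophysics(tracks: GroundTruthTracks, config: SimConfig) -> GroundTruthTracks:
    """Assign stochastic photoconversion and irreversible bleaching.

    Each emitter photoconverts after a geometric waiting time with the
    per-frame conversion probability, stays on for a geometric number of
    frames (mean ``1/bleach_rate``), then is bleached for good; the "on"
    run is contiguous by construction.
    """
    rng = _rng(config, 2)
    n, T = tracks.n_emitters, tracks.n_frames
    pc = config.conversion_rate_per_frame
    pb = config.bleach_rate_per_frame
    state = np.full((n, T), UNCONVERTED, dtype=np.int8)
    if pc > 0:
        t_on = rng.geometric(pc, size=n) - 1  # frame of conversion, 0-based
        dur = rng.geometric(pb, size=n) if pb > 0 else np.full(n, T, dtype=int)
        frames = np.arange(T)[None, :]
        on = (frames >= t_on[:, None]) & (frames < (t_on + dur)[:, None])
        state[on] = ON
        state[frames >= (t_on + dur)[:, None]] = BLEACHED
    tracks.photostate = state
    return tracks


def _integrated_psf(
    lam: np.ndarray, x: float, y: float, photons: float, sigma_nm: float, pixel_nm: float
) -> None:
    """Add one emitter's expected photon counts (integrated Gaussian) to ``lam``."""
    nr, nc = lam.shape
    rad = 5.0 * sigma_nm
    s = sigma_nm * np.sqrt(2.0)
    c0 = max(int(np.floor((x - rad) / pixel_nm)), 0)
    c1 = min(int(np.floor((x + rad) / pixel_nm)) + 1, nc)
    r0 = max(int(np.floor((y - rad) / pixel_nm)), 0)
    r1 = min(int(np.floor((y + rad) / pixel_nm)) + 1, nr)
    if c0 >= c1 or r0 >= r1:
        return
    ex = np.arange(c0, c1 + 1) * pixel_nm
    ey = np.arange(r0, r1 + 1) * pixel_nm
    fx = 0.5 * np.diff(erf((ex - x) / s))
    fy = 0.5 * np.diff(erf((ey - y) / s))
    lam[r0:r1, c0:c1] += photons * np.outer(fy, fx)


def render_movie(
    tracks: GroundTruthTracks, config: SimConfig, shot_noise: bool = True
) -> MovieStack:
    """Render the camera movie from tracks and photostates.

    Each "on" emitter deposits ``photons_per_frame`` expected photons as an
    integrated 2-D Gaussian PSF; pixel values are Poisson draws over signal
    plus uniform background, multiplied by the EM gain, plus Gaussian read
    noise, clipped at zero. With ``shot_noise=False`` the noiseless expected
    image (times gain) is returned — useful as an oracle.
    """
    if config.psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be positive")
    rng = _rng(config, 3)
    n_px = config.field_size_px
    T = tracks.n_frames
    movie = np.empty((T, n_px, n_px), dtype=float)
    for t in range(T):
        lam = np.full((n_px, n_px), float(config.background_photons))
        for i in np.flatnonzero(tracks.photostate[:, t] == ON):
            _integrated_psf(
                lam,
                tracks.x_nm[i, t],
                tracks.y_nm[i, t],
                config.photons_per_frame,
                config.psf_sigma_nm,
                config.pixel_size_nm,
            )
        if shot_noise:
            frame = rng.poisson(lam).astype(float) * config.em_gain
        else:
            frame = lam * config.em_gain
        if config.read_noise_e > 0:
            frame = frame + rng.normal(0.0, config.read_noise_e, size=lam.shape)
        movie[t] = np.clip(frame, 0.0, None)
    return MovieStack(movie, config.pixel_size_nm, config.frame_interval_s)


def _disc_mask(
    centers: np.ndarray, radius_nm: float, field_nm: float, pixel_nm: float, label: str
) -> MaskImage:
    n = int(np.ceil(field_nm / pixel_nm))
    mask = np.zeros((n, n), dtype=bool)
    if len(centers):
        coords = (np.arange(n) + 0.5) * pixel_nm
        xx, yy = np.meshgrid(coords, coords)
        for cx, cy in centers:
            mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_nm**2
    return MaskImage(mask, pixel_nm, label=label)


def make_reference_images(
    config: SimConfig,
) -> tuple[RenderedImage, MaskImage, MaskImage]:
    """Ground-truth reference images for classification and validation.

    Returns the diffraction-limited synapse-label image (Gaussian puncta of
    sd ``psf_sigma_nm`` on the camera grid, emulating an FM4-64-like stain),
    plus the true nanocluster and true synapse masks (binary discs at the
    ground-truth centers, rasterized at ``mask_pixel_nm``).
    """
    clusters, synapses = place_domains(config)
    n_px = config.field_size_px
    img = np.zeros((n_px, n_px), dtype=float)
    for cx, cy in synapses:
        # bright diffraction-limited punctum; amplitude is arbitrary (a.u.)
        _integrated_psf(img, cx, cy, 1000.0, config.psf_sigma_nm, config.pixel_size_nm)
    synapse_image = RenderedImage(img, config.pixel_size_nm)
    cluster_mask = _disc_mask(
        clusters, config.cluster_diameter_nm / 2, config.field_size_nm,
        config.mask_pixel_nm, "ground-truth",
    )
    synapse_mask = _disc_mask(
        synapses, config.synapse_diameter_nm / 2, config.field_size_nm,
        config.mask_pixel_nm, "ground-truth",
    )
    return synapse_image, cluster_mask, synapse_mask


def simulate_trajectories(
    n_traj: int,
    n_points: int,
    d_um2s: float,
    dt_s: float = 0.02,
    sigma_loc_nm: float = 0.0,
    confinement_radius_nm: float | None = None,
    seed: int = 0,
):
    """Directly simulate ready-made trajectories (no camera, no linking).

    Brownian motion at ``d_um2s``; if ``confinement_radius_nm`` is given the
    walk reflects at that disc boundary (hard nanodomain confinement,
    started uniformly in the disc). Independent Gaussian localization noise
    of sd ``sigma_loc_nm`` per axis is added to every point. Useful for
    estimator-calibration studies where ground-truth motion, not the
    imaging chain, is under test.
    """
    from sptpalm.track import Trajectory

    rng = np.random.default_rng(seed)
    sd = np.sqrt(2.0 * d_um2s * 1e6 * dt_s)
    if confinement_radius_nm is None:
        steps = rng.normal(0.0, sd, size=(n_traj, n_points - 1, 2))
        walks = np.concatenate(
            [np.zeros((n_traj, 1, 2)), np.cumsum(steps, axis=1)], axis=1
        )
    else:
        walks = _reflected_disc_walk(rng, n_traj, n_points, sd, confinement_radius_nm)
    walks = walks + rng.normal(0.0, sigma_loc_nm, size=walks.shape)
    out = []
    for i in range(n_traj):
        noisy = walks[i]
        out.append(
            Trajectory(
                trajectory_id=i,
                frames=np.arange(n_points),
                x_nm=noisy[:, 0],
                y_nm=noisy[:, 1],
                precision_nm=np.full(n_points, sigma_loc_nm),
                dt_s=dt_s,
            )
        )
    return out


def simulate_acquisition(
    config: SimConfig,
) -> tuple[GroundTruthTracks, MovieStack, RenderedImage, MaskImage, MaskImage]:
    """Full synthetic acquisition: tracks, movie and reference images."""
    tracks = simulate_photophysics(simulate_motion(config), config)
    movie = render_movie(tracks, config)
    synapse_image, cluster_mask, synapse_mask = make_reference_images(config)
    return tracks, movie, synapse_image, cluster_mask, synapse_mask
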