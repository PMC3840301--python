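"""Single-molecule detection and sub-pixel 2-D Gaussian fitting.

Per frame, candidate spots are found as local maxima of a
difference-of-Gaussians bandpass tuned to the PSF width, thresholded at a
multiple of the robust background noise. Each candidate's ROI is fitted by
nonlinear least squares with an integrated symmetric 2-D Gaussian plus a
constant background, giving the sub-pixel position, PSF width, integrated
photon count and a closed-form (Thompson/Mortensen-style) localization
precision. The concatenated per-frame fits form the localization table that
all downstream stages (rendering, tracking, diffusion) consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf
from skimage.feature import peak_local_max

from sptpalm.simulate import MovieStack

__all__ = ["LocalizeParams", "FitResult", "detect_spots", "fit_gaussian_2d", "localize_movie", "LOC_COLUMNS"]

logger = logging.getLogger(__name__)

#: bit-stable column order of the localization table
LOC_COLUMNS = ["frame", "x_nm", "y_nm", "sigma_nm", "intensity", "background", "precision_nm"]


@dataclass
class LocalizeParams:
    """Detection and fitting parameters.

    ``k_sigma`` scales the detection threshold in units of the robust
    (MAD-based) standard deviation of the bandpassed frame; ``roi_half``
    gives a (2*roi_half+1)^2 fitting window, ~3 PSF sd on each side at the
    default camera pitch.
    """

    pixel_size_nm: float = 16000.0 / 150.0
    psf_sigma_nm: float = 130.0
    k_sigma: float = 5.0
    roi_half: int = 3
    max_sigma_factor: float = 3.0  # reject fits with sigma outside [1/f, f] * psf_sigma


@dataclass
class FitResult:
    """Outcome of a single-spot fit; ``ok`` is False for rejected fits."""

    x_nm: float
    y_nm: float
    sigma_nm: float
    intensity: float
    background: float
    precision_nm: float
    ok: bool
    reason: str = ""


def _robust_sd(img: np.ndarray) -> float:
    med = np.median(img)
    sd = 1.4826 * np.median(np.abs(img - med))
    return sd if sd > 0 else float(img.std())


def detect_spots(
    frame_image: np.ndarray,
    detect_threshold: float | None = None,
    psf_sigma_px: float = 1.22,
    k_sigma: float = 5.0,
) -> np.ndarray:
    """Find candidate spot pixels in one frame.

    The frame is bandpassed with a difference of Gaussians (sd equal to the
    PSF sd and twice that), then local maxima above threshold are kept with
    a minimum separation of one PSF FWHM (brightest wins). If
    ``detect_threshold`` is None it is set to ``k_sigma`` times the robust
    noise sd of the bandpassed frame.

    Returns an (n, 2) array of (row, col) candidate pixels.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D frame")
    if np.any(img < 0):
        raise ValueError("expected a nonnegative image")
    if detect_threshold is not None and detect_threshold <= 0:
        raise ValueError("detect_threshold must be positive")
    bp = ndimage.gaussian_filter(img, psf_sigma_px) - ndimage.gaussian_filter(img, 2.0 * psf_sigma_px)
    if detect_threshold is None:
        detect_threshold = k_sigma * _robust_sd(bp)
        if detect_threshold <= 0:  # perfectly flat frame
            return np.empty((0, 2), dtype=int)
    fwhm = int(np.ceil(2.3548 * psf_sigma_px))
    peaks = peak_local_max(
        bp, min_distance=max(fwhm, 1), threshold_abs=detect_threshold, exclude_border=False
    )
    return peaks.astype(int)


def _integrated_gaussian_model(params, xe, ye):
    """Expected counts per ROI pixel for an integrated Gaussian + offset."""
    x0, y0, sigma, n_phot, bg = params
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * np.diff(erf((xe - x0) / s))
    fy = 0.5 * np.diff(erf((ye - y0) / s))
    return n_phot * np.outer(fy, fx) + bg


def fit_gaussian_2d(
    roi: np.ndarray,
    initial_center_px: tuple[float, float],
    pixel_size_nm: float,
    psf_sigma_nm: float = 130.0,
    roi_origin_px: tuple[int, int] = (0, 0),
    max_sigma_factor: float = 3.0,
    em_excess_noise: bool = False,
) -> FitResult:
    """Least-squares fit of one spot ROI with an integrated 2-D Gaussian.

    ``initial_center_px`` is the candidate (row, col) in frame pixel
    coordinates; ``roi_origin_px`` is the (row, col) of the ROI's first
    pixel, so returned coordinates are in the frame's nm system. The
    localization precision uses the Mortensen closed form for least-squares
    fitting,

        var = sa^2/N * (16/9 + 8*pi*sa^2*b / (N*a^2)),   sa^2 = sigma^2 + a^2/12

    with N fitted photons, b background variance per pixel, a the pixel
    size (doubled when ``em_excess_noise`` is set, for EM-amplified
    cameras). Fits that fail to converge, land outside the ROI, or return a
    degenerate amplitude or width are flagged rejected rather than dropped.
    """
    roi = np.asarray(roi, dtype=float)
    nr, nc = roi.shape
    r0, c0 = roi_origin_px
    a = pixel_size_nm
    # pixel edges of the ROI in nm (frame coordinates)
    xe = (np.arange(c0, c0 + nc + 1)) * a
    ye = (np.arange(r0, r0 + nr + 1)) * a
    bg0 = float(roi.min())
    n0 = max(float(roi.sum() - bg0 * roi.size), 1.0)
    x0 = (initial_center_px[1] + 0.5) * a
    y0 = (initial_center_px[0] + 0.5) * a
    p0 = [x0, y0, psf_sigma_nm, n0, bg0]
    lo = [xe[0], ye[0], psf_sigma_nm / max_sigma_factor / 2, 0.0, 0.0]
    hi = [xe[-1], ye[-1], psf_sigma_nm * max_sigma_factor * 2, np.inf, np.inf]

    def resid(p):
        return (_integrated_gaussian_model(p, xe, ye) - roi).ravel()

    try:
        res = least_squares(resid, p0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10)
    except Exception as exc:  # pragma: no cover - defensive
        return FitResult(x0, y0, psf_sigma_nm, 0.0, bg0, np.inf, ok=False, reason=str(exc))
    x, y, sigma, n_phot, bg = res.x
    reason = ""
    ok = bool(res.success)
    if not ok:
        reason = "no convergence"
    elif n_phot < 1.0:
        ok, reason = False, "no signal"
    elif not (xe[0] <= x <= xe[-1] and ye[0] <= y <= ye[-1]):
        ok, reason = False, "center outside ROI"
    elif not (psf_sigma_nm / max_sigma_factor <= sigma <= psf_sigma_nm * max_sigma_factor):
        ok, reason = False, "implausible width"
    sa2 = sigma**2 + a**2 / 12.0
    if em_excess_noise:
        sa2_eff = 2.0 * sa2  # excess-noise factor doubles the variance
    else:
        sa2_eff = sa2
    if n_phot >= 1.0:
        var = sa2_eff / n_phot * (16.0 / 9.0 + 8.0 * np.pi * sa2 * max(bg, 0.0) / (n_phot * a**2))
        precision = float(np.sqrt(var))
    else:
        precision = np.inf
    return FitResult(float(x), float(y), float(sigma), float(n_phot), float(bg), precision, ok, reason)


def localize_movie(movie: MovieStack | np.ndarray, params: LocalizeParams | None = None) -> pd.DataFrame:
    """Detect and fit every frame of a movie into a localization table.

    Returns a DataFrame with columns ``frame, x_nm, y_nm, sigma_nm,
    intensity, background, precision_nm`` sorted by (frame, x_nm).
    Per-frame detection/rejection counts are logged at info level. An empty
    movie yields an empty (but well-formed) table.
    """
    if params is None:
        params = LocalizeParams()
    frames = movie.frames if isinstance(movie, MovieStack) else np.asarray(movie, dtype=float)
    psf_sigma_px = params.psf_sigma_nm / params.pixel_size_nm
    rows: list[tuple] = []
    n_det = n_fit = n_rej = 0
    half = params.roi_half
    for t in range(frames.shape[0]):
        img = frames[t]
        peaks = detect_spots(img, psf_sigma_px=psf_sigma_px, k_sigma=params.k_sigma)
        for pr, pc in peaks:
            n_det += 1
            # ROI is clipped at the frame border rather than skipped, so
            # near-edge molecules are still fitted (on fewer pixels)
            r0, r1 = max(pr - half, 0), min(pr + half + 1, img.shape[0])
            c0, c1 = max(pc - half, 0), min(pc + half + 1, img.shape[1])
            if r1 - r0 < half + 2 or c1 - c0 < half + 2:
                n_rej += 1
                continue
            roi = img[r0:r1, c0:c1]
            fit = fit_gaussian_2d(
                roi,
                (pr, pc),
                params.pixel_size_nm,
                psf_sigma_nm=params.psf_sigma_nm,
                roi_origin_px=(r0, c0),
                max_sigma_factor=params.max_sigma_factor,
            )
            if fit.ok:
                n_fit += 1
                rows.append(
                    (t, fit.x_nm, fit.y_nm, fit.sigma_nm, fit.intensity, fit.background, fit.precision_nm)
                )
            else:
                n_rej += 1
    logger.info("localize_movie: %d detected, %d fitted, %d rejected", n_det, n_fit, n_rej)
    table = pd.DataFrame(rows, columns=LOC_COLUMNS)
    table["frame"] = table["frame"].astype(int) if len(table) else table["frame"]
    return table.sort_values(["frame", "x_nm"], kind="stable").reset_index(drop=True)
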