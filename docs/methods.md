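# Methods

## Coordinate convention

All positions are continuous, in nanometres. Pixel `(0, 0)` of any grid
spans `[0, p) × [0, p)` with `p` the pixel pitch; a pixel's center sits at
`+0.5 p`; array row = y, column = x. Camera images (106.7 nm pitch),
rendered images (5 nm) and masks (5 nm for true masks) all register to
this single frame via their `pixel_nm` and origin offset — never by array
index. This is what makes trajectory-vs-mask classification across grids
unambiguous.

## Simulator

The generator emulates a live-cell sptPALM acquisition of a membrane
receptor carrying a Dendra2-like photoconvertible tag.

**Geometry and camera.** 64 × 64 pixels of 16 µm / (100× · 1.5×) =
106.7 nm (a cut-out of a 512 × 512 sensor), 20 ms frames (50 Hz), PSF
standard deviation 130 nm, EMCCD modeled as Poisson(signal + background) ×
gain + Gaussian read noise, clipped at zero. EM excess noise is not
modeled; it would scale all noise by ~√2 without changing any pipeline
logic (the fit-precision formula exposes an `em_excess_noise` switch).

**Motion.** Free molecules take Gaussian steps of per-axis variance
`2 D dt` (default D = 0.09 µm²/s) and reflect at the field edges. Trapped
molecules (default 35%) are confined to 105 nm-diameter discs by hard
radial reflection; exchange between the populations is out of scope, the
two regimes being treated as distinct states. Each frame step of a
confined walk is split into 10 substeps with reflection after each:
with a single step per frame (step sd ≈ 40 nm vs R = 52.5 nm) the
discrete reflection biases the stationary density inward and the ensemble
MSD plateau lands ~17% below its continuous-diffusion limit R²; with
substepping it is within ~4%. Confined defaults use D = 0.04 µm²/s —
note that the *apparent* D₂₋₅ fitted from a confined trajectory is much
smaller than this microscopic coefficient, because the MSD saturates at
the domain size within one or two lags.

**Photophysics.** Conversion and bleaching are geometric waiting times
(memoryless per-frame probabilities); the on-run is contiguous and
transitions are irreversible (unconverted → on → bleached), matching
green-to-red photoconversion followed by terminal bleaching. Defaults:
conversion 0.004/frame, bleach 0.05/frame (mean on-time 20 frames = 0.4 s),
120 molecules over 1600 frames — a desk-scale version of a several-minute,
5000–6000-frame acquisition. The conversion rate is deliberately low: at
0.008/frame, two fluorophores in the same 105 nm nanocluster are
simultaneously on often enough that their overlapping PSFs fuse into one
detection whose fitted position wanders off both molecules, degrading
trapped/free classification; 0.004 realizes the "sparse activation"
regime an experimenter tunes for (~1.5 on-molecules/frame here,
~0.03–0.04 per µm² per frame).

**References.** Nanocluster and synapse disc centers are placed uniformly,
non-overlapping, fully in-field, from a placement RNG stream shared by the
track generator and the reference-image generator, so tracks and true
masks always agree. The synapse-label image (an FM4-64-like stain) is a
noiseless sum of PSF-sized Gaussian puncta on the camera grid: such
ensemble-label images are bright and effectively noise-free compared to
single-molecule frames.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: stage drift, PSF aberrations/astigmatism,
fluorophore blinking (re-activation), EM excess noise, regime exchange,
heterogeneous cluster sizes, and out-of-focus background from deeper
structures. Tests validate the estimators and the chain's bookkeeping
under the stated model, not robustness to these effects.

## Localization

Detection: difference-of-Gaussians bandpass (sd = PSF sd and 2× that),
threshold at 5× the robust (1.4826·MAD) noise sd of the filtered frame,
local maxima separated by at least one PSF FWHM (brightest wins). Fitting:
least-squares of an integrated symmetric 2-D Gaussian plus constant offset
on a 7 × 7-pixel ROI (clipped at frame borders rather than skipped, so
edge molecules are still fitted); fits that do not converge, leave the
ROI, or return a degenerate amplitude/width are flagged rejected, never
silently dropped. Precision is the Mortensen closed form
`var = sa²/N·(16/9 + 8π sa² b/(N a²))`, `sa² = σ² + a²/12`, reported per
axis. On simulated data the true radial RMS error stays within 1.5× of
√2 × the reported per-axis value.

## Rendering and segmentation

Pointillist images are plain 2-D histograms (binning, never merging).
Rendered images deposit one unit-mass integrated Gaussian per
localization, sd 10 nm (the conventional choice: the measured localization
accuracy) on 5 nm pixels, kernels truncated at 5σ (mass error < 1e-5).

Nanocluster masks come from the à-trous (undecimated) B3-spline wavelet
transform: keep plane `w_j = c_{j-1} − c_j`, threshold at `k` × the
plane's robust sd, remove components below 10 pixels, fill holes. Because
the threshold is relative to the plane's own spread, the mask is invariant
to intensity rescaling. Defaults `j = 3`, `k = 2.5` were tuned on planted
ground truth at the standard rendering settings: a 105 nm disc spans ~21
render pixels, which plane 2 (scale ~4 px) fragments and undersizes by
~35%, while plane 3 recovers a mean equivalent diameter within ~6%;
`k = 2.5` keeps the masked fraction of a pure-noise image at ~0.2%
(k = 2.0 lets through ~2% because the plane is spatially correlated). The
synapse image is thresholded with the same machinery at `j = 2` — on the
camera grid a diffraction-limited punctum is only a few pixels wide.

Cluster area is mask pixel count × pixel area; no sub-pixel boundary
refinement (quantization error at 5 nm pixels is a one-pixel band around
the perimeter, ≈ 1650 nm² for a 105 nm disc, comparable to biological
spread but unbiased in the mean). Components use 8-connectivity —
conservative against splitting one cluster into two. The
circular-equivalent diameter is `2·√(A/π)`.

## Tracking

Per consecutive frame pair, active trajectory ends and new detections are
matched by minimum total squared displacement (Jonker–Volgenant
assignment) with per-item opt-out cost `max_disp²`; links longer than
`max_disp` are forbidden outright. The default gate is
`4·√(4·D_max·dt)` with D_max = 0.5 µm²/s, ≈ 800 nm at 50 Hz — ≥ 4 sd above
the fastest plausible membrane-receptor steps. No gap closing by default
(`max_gap = 0`): bleaching is terminal and no blinking correction is
modeled; a `max_gap` parameter exists for robustness studies, but
downstream MSD requires gap-free trajectories (lag-aware pair counting is
not implemented). No motion-model prediction is used; at the simulator's
operating density (~0.04 on-molecules/µm²/frame) linked steps connect
same-molecule localizations ≥ 99% of the time, dropping to ~92% toward
0.08/µm²/frame — a maximum-likelihood tracker with a diffusion prior
would be needed to do better at high density.

## Diffusion quantification

MSD is the time-averaged formula above, exact (validated against a naive
double loop), with `N − n` pairs at lag `n`. D is fitted by OLS over lags
{2, 3, 4, 5} — the reading of "first 2–5 points" consistent with the
D₂₋₅ subscript; lags {1..4} are available via `fit_lags`. The intercept
estimates `4σₓ²`; a negative slope is kept (and flagged) so pooled medians
are not biased upward, and a negative intercept maps to σₓ = 0 with a
flag. Trajectories shorter than 10 points are excluded from D analysis by
convention (5 points suffice for the area statistic).

Area explored per step is the convex-hull area of the trajectory divided
by its step count, reported in camera-pixel² (hull area / 106.7² nm²). The
hull reading of "total surface covered", and pixel² units, match the
magnitudes this statistic is reported in; an occupied-render-pixel variant
was considered and rejected as resolution-dependent. Collinear
trajectories get area 0.

Classification is a majority rule: a trajectory is synaptic (resp.
trapped) when ≥ 50% of its localizations fall inside the synapse (resp.
nanocluster) mask, the two labels independent, so trapped + free and
synaptic + extra-synaptic each partition the trajectory set. The 50%
default avoids labeling a trajectory trapped on a single grazing point;
`overlap_fraction` can be set near 0 for an any-overlap rule.

## Statistics

Group summaries report median and 25th/75th percentiles (linear
interpolation between order statistics) of pooled per-trajectory D, plus
group proportions. Distributions are compared with the two-sample
two-sided Kolmogorov–Smirnov test — exact p for samples of ≤ 25,
asymptotic otherwise — starred at 0.05/0.01/0.001 per comparison, with no
multiple-testing correction (stars are per-comparison descriptors, not a
family-wise claim). Under a simulated null the 5% rejection rate is
verified to hold within ±2%.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with stable statistics: 500 trajectories of 30 points for
estimator recovery, 300 of 60 points for the confinement plateau, one
full 1600-frame/120-emitter acquisition for end-to-end classification,
20 seeds × 4 planted clusters for segmentation recovery, and 1000
replicates for KS calibration.

## Known limitations

- Hard-disc confinement with no escape: no partitioning between trapped
  and free within one trajectory, no corral hopping.
- The linker claims no equivalence with maximum-likelihood multi-target
  trackers; above ~0.08 on-molecules/µm²/frame its purity degrades.
- The MSD contract requires gap-free trajectories; blinking-tolerant
  analysis would need lag-aware pair counting.
- Apparent D of confined molecules depends on the lag window relative to
  the domain size; D₂₋₅ values for trapped populations are descriptive
  ranks, not estimates of the microscopic coefficient.
- The precision formula assumes a shot-noise-limited symmetric Gaussian
  PSF; with EM excess noise enabled it doubles the variance but still
  ignores pixel correlations.
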