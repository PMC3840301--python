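# sptpalm

Single-particle tracking PALM (sptPALM) analysis for membrane-receptor
micro-organization, with a fully ground-truthed simulator.

In an sptPALM experiment a receptor is fused to a green-to-red
photoconvertible protein (Dendra2-like). Weak 405 nm activation converts a
sparse, random subset of molecules; each is imaged at 50 Hz until it
irreversibly bleaches, localized to ~10–50 nm by fitting its point-spread
function, and tracked frame to frame. Pooled over thousands of short
trajectories, this reveals both the nanoscale map of the receptor
(nanoclusters of ~100 nm) and its mobility: molecules diffusing freely in
the membrane versus molecules trapped inside nanodomains or synapses.

`sptpalm` implements that entire chain as a tested Python library:

- **simulate** — ground-truthed synthetic acquisitions: Brownian motion
  (free, or confined to reflecting 105 nm discs), geometric
  photoconversion/bleaching, an EMCCD camera model (integrated Gaussian
  PSF, Poisson shot noise, gain, read noise), a diffraction-limited
  synapse-label image, and true masks.
- **localize** — difference-of-Gaussians spot detection plus integrated
  2-D Gaussian least-squares fitting with a Mortensen-style closed-form
  precision estimate.
- **mapping** — pointillist and Gaussian-rendered super-resolution images,
  à-trous B3-spline wavelet segmentation into background-free masks, and
  per-nanocluster quantification (area, circular-equivalent diameter
  `2·√(A/π)`, detection time-traces).
- **track** — optimal per-frame-pair assignment linking (minimum total
  squared displacement with a maximum-displacement gate) and
  minimum-length filtering.
- **diffusion** — the time-averaged mean squared displacement

  `MSD(n·dt) = (N−n)⁻¹ Σᵢ [(xᵢ₊ₙ−xᵢ)² + (yᵢ₊ₙ−yᵢ)²]`,

  the diffusion coefficient from `MSD(t) = 4·D₂₋₅·t + 4σₓ²` fitted over
  lags 2–5 (σₓ = localization accuracy), the convex-hull area explored per
  step, mask-based classification (trapped/free, synaptic/extra-synaptic)
  and per-group ensemble MSD curves.
- **report** — pooled medians/quartiles, group proportions, two-sample
  Kolmogorov–Smirnov comparisons with significance stars, and
  condition-comparison tables.

## Worked example

`examples/diffusion_analysis.py` simulates a full acquisition (1600 frames,
50 Hz, 120 emitters, 35% trapped in 105 nm nanodomains), localizes and
tracks it, and pools the per-trajectory diffusion records:

```
free    : n =  37 (61.7%), median D = 0.0753 [0.0492-0.1125] um^2/s
trapped : n =  23 (38.3%), median D = 0.0016 [0.0004-0.0037] um^2/s
ensemble MSD(free) at lag 5 (0.1 s): 35293 nm^2
ensemble MSD(trapped) at lag 5 (0.1 s): 3936 nm^2
KS free vs trapped: statistic 0.93, p = 1.5e-16 ***
```

The free median recovers the simulated 0.09 µm²/s to within estimator
noise; trapped trajectories never leave their 52.5 nm-radius domain, so
their ensemble MSD saturates near the confinement plateau R² = 2756 nm²
and their apparent D₂₋₅ collapses — the signature separating trapped from
free receptors. `examples/nanocluster_mapping.py` closes the loop on the
map side: wavelet segmentation of the rendered image recovers the planted
nanoclusters at a mean area of 8185 nm², i.e. an equivalent diameter of
101.9 nm for 105 nm ground truth.

The other examples cover simulation (`simulate_acquisition.py`),
localization/tracking accuracy (`localize_and_track.py`) and two-condition
statistics (`two_condition_comparison.py`). A thin CLI wraps the same
functions for shell use: `sptpalm run-all --seed 1 --out run/` (see
`sptpalm --help`).

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions and known limitations.
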