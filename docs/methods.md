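# Methods

This note documents the models, estimators and numerical choices behind
`ciliamotion`, including the assumptions a user should know before
interpreting output on real data.

## Coordinate system and segments

Trajectories are recorded in image coordinates (μm) and transposed onto a
cilium spline: a natural cubic curve through ordered hand-drawn control
points, parameterised by chordal arclength and densely resampled (default
10 nm) for nearest-point search. The parallel coordinate s\_// is the
arclength of the nearest sample minus a user offset (convention: 0 at the
PCMC/TZ boundary); the perpendicular coordinate d\_⊥ is the signed distance
to that sample, positive to the left of the direction of increasing
arclength. The sign convention is arbitrary — only magnitudes matter
downstream. Points farther than 2 μm from the spline are flagged as
outliers, and |d\_⊥| > 0.5 μm raises a sanity flag; neither is dropped
silently.

The parallel axis is partitioned into half-open, lower-inclusive segments
(μm): dendrite (< −0.8), PCMC [−0.8, 0), TZ [0, 0.8), PS [0.8, 3.5),
DS [3.5, 6.5), Tip [≥ 6.5). The PCMC's cup shape is flattened onto the
single spline curve; no attempt is made to model its 3D geometry.

## Sliding-window MSD estimation

For every run of 15 consecutive localizations (stride 1) the
time-averaged MSD over overlapping pairs is computed for lags 1–6 and fit
by OLS in log₁₀–log₁₀ space to MSD(τ) = 2 Γ τ^α: α is the slope and
Γ = 10^intercept / 2. Fitting in ln space would give identical α and Γ.
The six lags are unweighted. Windows containing a zero or negative MSD
value among the fitted lags are marked invalid per axis rather than
raising, so a degenerate perpendicular series (e.g. zero motion) does not
discard a good parallel estimate. Each estimate is anchored to the
window's mean parallel position and central frame.

Small-sample caveat: for pure Brownian motion the 15-point window α
estimator is broadly distributed (s.d. ≈ 0.4) with median slightly below
1; this bias is a property of short-window TA-MSD fits and is covered by
a regression test, not corrected. The perpendicular exponent and
diffusion coefficient inherit a projection caveat: imaging collapses one
of the two perpendicular axes, which can underestimate D\_⊥ by up to about
a factor of 2; this is documented, not corrected.

## Motion classification

The pooled α\_// sample is histogrammed (default bin width 0.1) and fit by
a sum of two Gaussians (six free parameters, `scipy.optimize.curve_fit`
with non-negative amplitude bounds; initializations from an 80%-quantile
split, then a median split, then a fixed guess). Component fractions are
area fractions (amplitude × σ), components ordered by mean, widths stored
as FWHM (σ = FWHM / (2√(2 ln 2))). A raw-sample two-component EM fit
(scikit-learn) is provided as an independent cross-check utility; the
histogram fit is the primary method.

Classification uses a fixed threshold α = 1.4 by default (boundary
inclusive: α = 1.4 is directed); a computed component-intersection
threshold is exposed as an alternative, because with area-normalized
components the intersection of a fitted mixture need not fall exactly at
the fixed constant. Diffusive windows with α < 1.0 carry a
"subdiffusive" sub-label.

## Velocity and diffusion profiles

Displacements inside directed windows give apparent velocities
v_app = Δs\_///dt, split into anterograde (positive) and retrograde runs
and locally averaged with a centred running mean over 10 displacements
within a track (never across tracks). Displacements inside diffusive
windows (α ≤ 1.1 on the relevant axis; default taken from the looser of
the two stated cutoffs, both exposed as parameters) give apparent
diffusion coefficients D = (Δr)²/dt, locally averaged over 60
displacements; perpendicular samples additionally require α\_// < 1.4 so
that D\_⊥ is never measured during active transport.

The single-displacement estimator (Δr)²/dt has expectation 2D for 1D
Brownian motion, while the MSD convention above implies Γ = D with the
factor 2 explicit. The estimator is implemented exactly as stated under
the default "as-printed" convention; an "msd-consistent" convention
divides by 2. The discrepancy is surfaced via the convention flag rather
than silently corrected, and both convergences (2D and D) are covered by
tests. Profiles are binned at 0.25 μm (half-open, lower-inclusive bins)
with mean, s.e.m. and count per bin.

Near segment boundaries the running mean deliberately mixes displacements
from adjacent segments; profile values within half a smoothing window of
a boundary should be read accordingly.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with full ground truth:

- **Modes.** Every `mode_hold` frames (default 15, matching the analysis
  window) a mode is drawn from the local segment's parameters: directed
  with probability `p_ift` (anterograde with `p_antero`), otherwise
  subdiffusive with probability `p_sub`, else diffusive. Directed frames
  step v·dt (speed re-evaluated each frame from the local segment);
  diffusive frames take Gaussian steps of s.d. √(2 D dt).
- **Subdiffusion** is fractional Brownian motion with Hurst exponent
  α_sub/2, scaled so TA-MSD(τ) ≈ 2 D τ^α_sub, generated as exact
  fractional Gaussian noise by Davies–Harte circulant embedding (Cholesky
  fallback). fBm was chosen over obstructed-diffusion lattice models
  because it is parameterised directly by the exponent the analysis
  estimates. Each mode window holds one fBm realisation; correlations do
  not persist across windows.
- **Noise and bleaching.** Independent Gaussian localization noise
  (default 20 nm — typical single-EGFP precision; an assumption, not a
  measured value) and a geometric photobleaching draw (per-frame survival
  probability) truncating tracks.
- **Perpendicular motion** is confined diffusion between reflecting walls
  at ±0.1 μm, bounding the ≤200 nm membrane diameter.
- **FRAP traces** follow a single-exponential recovery with configurable
  mobile fraction, recovery time, bleach depth, background and noise.
- **Imaging.** Molecules render as isotropic Gaussian PSFs with Poisson
  shot noise on a constant background; no EM-gain or depth effects.

What passing tests on these data do *not* show: robustness to non-Gaussian
localization errors, drift, blinking-induced linking errors, spline
misplacement, or motion models outside the directed/Brownian/fBm family.

## Detection and linking

Spot candidates are local maxima above an intensity threshold, refined by
least-squares fits of an isotropic 2D Gaussian plus constant background in
an ROI (half-width 4 px). Non-converging or out-of-ROI fits are flagged,
not dropped. Linking is greedy mutual-nearest-neighbour between
consecutive frames with a maximum link distance (default 0.5 μm ≈ the
largest plausible per-frame IFT step plus noise) and a gap memory
(default 1 frame); ties break by smallest distance, then lowest detection
index. A global (Hungarian) assignment was deliberately not used: in
bleach-down single-molecule data detections are sparse and there is no
cost model to optimize. All linking parameters are recorded in the run
log for provenance. Super-resolution reconstructions are 2D histograms of
fitted centres; the rendered mass equals the detection count.

## Steady-state transport simulation

The cilium is one-dimensional (the 200 nm cylinder diameter is metadata
only; membrane-area weighting is out of scope). 50 molecules start at
each micrometre from 0 to 7 (inclusive — 400 molecules; the count is
configurable) and run 5000 steps of 0.1 s. Modes are redrawn every 15
frames from the local segment's `p_ift`; directed bouts are anterograde
with probability 1/3 and retrograde 2/3, reflecting the anterograde /
retrograde IFT-train frequency asymmetry. Segment parameters are
re-evaluated every frame; the drawn mode only at window boundaries.

Boundary model: the dendrite (x < −0.8, simulated down to x = −1.5) is
pure active transport at 1.5 μm/s — a molecule whose drawn mode is
diffusive is overridden to anterograde (import) while inside the
dendrite, so every dendrite frame moves at exactly the dendrite speed;
retrograde bouts pass through and exit. A molecule crossing the dendrite
end is removed and one is injected at that end (drawn mode diffusive; the
override carries it inward), conserving the count exactly at every step.
With IFT off everywhere this override is the only import mechanism, and
no directed mode is ever drawn, so the ciliary region contains zero
directed steps. The tip end at 7.5 μm reflects. With the alternative
reflecting lower boundary (used for calibration runs), the dendrite
override is disabled and the simulator reduces to a plain mode-switching
random walk.

Space-dependent diffusion is handled in the Itô sense: each diffusive
step uses the D of the segment at the current position with no
spurious-drift correction. The resulting accumulation of density in
low-D regions is an intended feature of the model — it is what produces
the PCMC peak.

The default per-segment table (IFT probability, speeds, D) is
illustrative: it is reconstructed from the qualitative location-resolved
results this model is meant to reproduce (directed fraction high in the
TZ, low in PS, slightly higher in DS, zero at the Tip; anterograde speed
≈ 0.5 μm/s near the TZ rising beyond 1 μm/s distally; D\_// ≈ 0.03 μm²/s
along the cilium, ≈ 0.01 in the TZ, PCMC taking the TZ-boundary value).
With these defaults the grand-average steady-state density (3-s window
histograms between 180 and 390 s) shows local maxima at the PCMC, at the
start of the PS and at the tip; setting every `p_ift` to zero removes the
PS-start and tip peaks, mimicking loss of cargo–IFT coupling.

Peak detection smooths the profile (3-bin moving average), pads with the
profile minimum so maxima at the domain ends are eligible, and accepts
peaks with prominence ≥ 20% of the mean density and width at half
prominence ≤ 2 μm. The width cap separates genuine accumulation peaks
from broad monotone gradients, such as the slow equilibration tail toward
the tip in IFT-off runs.

## FRAP

Traces are background-subtracted using a neighbouring ROI and normalized
by the pre-bleach mean (all pre-bleach frames). The mobile fraction is
(I(t_eval) − floor) / (1 − floor) with t_eval measured from the bleach
(default 120 s, averaged over ±2 frames). The floor defaults to the mean
of the first 3 post-bleach frames, which is unbiased under noise; the
post-bleach minimum is available as an option and coincides with the
default on noiseless monotone recoveries (the minimum over many noisy
frames is biased low by the extreme-value effect, which would inflate the
fraction). The raw normalized intensity at t_eval is exported alongside,
since floor-relative and raw readouts differ when the bleach is
incomplete. An optional linear-decay correction for acquisition
photobleaching divides by the pre-bleach trend; corrected curves are
qualitative.

## Problem sizes and reproducibility

Validation runs use 1000-track ensembles for Brownian/fBm recovery, the
full 400-molecule × 5000-step configuration for the simulator, and
7237-sample draws for the mixture fit. Every stochastic component takes a
`numpy` `Generator` or integer seed; populations spawn per-track
generators from a `SeedSequence`, so results are bit-reproducible and
independent of track order.

## Known limitations

- 2D analysis of a 3D object: D\_⊥ underestimation (≤ ~2×) is documented,
  not corrected.
- No drift correction, no MLE localization with camera noise models, no
  HMM/change-point motion segmentation.
- The simulator's default ciliary parameters are illustrative
  reconstructions, not fitted constants; conclusions from it are
  qualitative (peak structure), not quantitative densities.
- The mixture fit assumes exactly two Gaussian components; strongly
  skewed or multi-modal diffusive pools bias the weights.
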