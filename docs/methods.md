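# Methods

## Scientific problem

Single-particle tracking of membrane proteins in rod-shaped bacteria measures
2-D apparent positions of individual fluorophores at camera frame rates from
tens of hertz to 1 kHz.  Two instrumental artifacts make naive interpretation
of mean-square-displacement (MSD) curves unreliable at these scales: the cell
surface is strongly curved (a ~1 μm-diameter cylinder capped by hemispheres,
viewed in orthographic projection), and the camera integrates the fluorophore
position over the whole exposure (motion blur), which for free diffusion
shrinks the one-frame MSD by a factor (1 − 1/3).  This package analyzes such
data the way the source study does: it simulates confined Brownian motion on
an idealized cell surface through an explicit camera model, and infers the
microscopic diffusion coefficient `D`, the confinement radius `R`, and
two-population mixture fractions by comparing simulated and observed combined
MSD curves.

## Surface model and dynamics

The cell is a cylinder of radius `r` (default 0.5 μm) and length `L` (default
`2r`) with hemispherical caps; coordinates are in μm and seconds throughout,
with `x` along the cell axis and the camera recording `(x, y)`.  The walker's
dynamics are integrated in the tangent chart centered on its initial position:
Gaussian increments with per-axis variance `2·D·dt` (internal step
`dt = 0.5 ms`; an alternative |half-normal|-length/uniform-direction step
model with the same mean-square step `4·D·dt` is selectable), reflected
specularly off the circular confinement boundary of radius `R`.  The radial
reflection is evaluated in closed form as a triangle-wave fold of the radius
with period `4R` (a negative fold value encodes passage through the center),
which is exactly equivalent to iterated mirroring about the circle.

Chart displacements are mapped to the surface by the exponential map at the
origin: exact isometric unrolling on the cylinder, great-circle advance on the
caps, with the unused arc length transferred across the cylinder/cap junction
preserving the intrinsic direction (the two surfaces meet tangentially, so
geodesics pass smoothly).  In cylinder-only mode the axial coordinate reflects
specularly off the cylinder ends.  Two approximations are documented rather
than removed: (i) confinement is enforced in the origin chart, which is exact
on the cylinder and an exponential-map approximation when the disc spans a
junction or lies on a cap — acceptable because fitted confinement radii
(≤ 0.27 μm) are small against the 0.5 μm cell radius; (ii) for origins on the
cylinder whose chart point overflows an end, the circumferential coordinate is
carried at the origin's latitude.

The camera model averages `n_sub = round(period/dt)` consecutive projected
positions per frame (the substep is rescaled to `period/n_sub` so a frame
always averages an integer number of samples), then adds isotropic Gaussian
localization noise of per-axis width `σ` (default 0 for model curves, 0.05 μm
for pseudo-experiments).  Orthographic projection drops the optical-axis
coordinate; circumferential motion is foreshortened by `cos(azimuth)`, so
even unconfined motion on the cylinder produces a camera-plane MSD below the
intrinsic one — the curvature artifact the fitting procedure corrects for.

Validated oracles: free planar diffusion reproduces the blurred-MSD law
`MSD(nΔ) = 4DΔ(n − 1/3) + 4σ²` to within Monte Carlo error; a confined chart
simulation equilibrates to the uniform distribution on the disc with MSD
plateau `R²`; a stationary particle shows the `4σ²` noise floor.

## MSD analysis

Per-track MSDs are time-averaged over all start frames; ensembles are
unweighted means across tracks with standard errors from the inter-track
scatter.  Each track contributes delays up to one third of its own length
(variance control for time-averaged MSDs); because photobleach-limited tracks
are heterogeneous in duration, the ensemble keeps a delay when at least 8
tracks contribute, up to a cap of 20 frame delays per rate.  Tracks shorter
than 10 frames are rejected at the analysis stage.  Rates below 60 Hz are
ingested but excluded from fitting.
The combined multi-rate curve anchors the fastest rate by the ordinary
least-squares intercept of its first six points and shifts each successively
slower curve by the constant that best matches the already-combined curve on
overlapping delays (linear interpolation); all shifts are recorded in the
curve's metadata so the raw per-rate levels can be restored.

The quick-look confinement estimator applies the printed square-domain
relation `L = sqrt(3 × plateau)`, `R = L/2`, with the plateau taken as the
mean of the last quartile of points and a plateau declared only when the
last-quartile rise is below 15% of its level.  Note this relation is exact
for square domains of side `L`; for the circular domains this package
simulates, the equilibrium plateau is `R²`, so the rule systematically
reports `√3/2 ≈ 0.87` of the true disc radius.  It is retained as the field's
standard back-of-envelope formula; quantitative inference uses the
simulation-based fit, which has no such bias.

## Confinement fitting

`grid_fit` evaluates a reduced chi-squared between the observed combined MSD
and simulated model curves (1000 noise-free trajectories per rate, one fixed
seed shared by all grid points so the surface is smooth — common random
numbers) over a coarse grid of ~20% multiplicative steps in `D` (1–46 μm²/s)
and 0.02 μm steps in `R` (0.10–0.34 μm), then refines around the coarse
minimum (±20% in `D` over 9 log steps, ±0.02 μm in `R` over 11 steps); the
fine grid is re-centered while its minimum lands on the fine-grid boundary,
up to four stages, so the reported optimum is interior whenever one exists
nearby.
Degrees of freedom subtract the free offsets and the two model parameters.
Asymmetric parameter bounds are the extremes of the unreduced
`chi² ≤ min + 1` region projected on each axis; a minimum on the grid
boundary is flagged.

Two offset conventions are implemented.  The classical choice frees one
vertical shift per frame rate (each with the closed-form sem⁻²-weighted mean
residual).  The package's default for grid fitting is instead a single offset
common to all rates, applied after restoring each observed rate segment to
its raw (pre-stitching) level.  The scientific argument: the acquisition
holds localization precision approximately constant across rates (~50 nm, by
adjusting illumination to fixed spot signal-to-noise), so the unknown noise
floor `4σ²` is one number, not one per rate.  The practical argument is
identifiability: for fast, tightly confined motion (the outer-membrane
transporter regime, `D ≈ 21 μm²/s`, `R ≈ 0.18 μm`) the MSD saturates below
the first observable delay at every rate, and with fully free per-rate shifts
the only remaining signal is the small residual rise, which is constant along
a ridge of `(D, R)` combinations — recovery then fails by construction.  The
blur-driven differences in apparent plateau level *between* rates break this
ridge, and the common-offset objective is what preserves them.  Both modes
are exposed (`shift_mode="common" | "per_rate"`).

## Mixture decomposition

An observed curve is decomposed as `f·A + (1 − f)·B` between two standard
curves by weighted least squares on the common delay grid, with `f`
constrained to [0, 1] and its uncertainty taken from the `Δchi² = 1` interval
with nuisance parameters profiled out.  By default the fit includes a free
vertical offset common to all rates and compares de-stitched raw-level
segments, for the same reasons as above; without the offset, the anchoring
noise of the observed curve (coherent across all its points) must be absorbed
by the fraction and roughly doubles its replicate-to-replicate scatter.  The
plain anchored weighted-average fit is available via
`fit_offset=False, use_raw_levels=False`.

The mixture fit uses a 10-frame-delay window per rate with every accepted
track contributing (per-track statistics are dense there, so each point's
standard error is well characterized); the confinement grid fit instead uses
the longer 20-delay window, whose extra plateau-level points sharpen `(D, R)`
but whose sparsely-populated long delays would only add noise to the fraction
estimate.

With 70 tracks per rate, the fraction estimate carries an irreducible
binomial component: the realized composition of the sample itself has
standard deviation `sqrt(w(1−w)/70) ≈ 0.057` per rate (≈ 0.026 after pooling
five rates), before any curve-fitting noise.  Replicate scatter of the full
estimator is ~0.035–0.05 at the reference operating points.

## Pseudo-experiments

The synthetic-data generator emulates the study's acquisition: a battery of
frame rates {60, 120, 260, 400, 1000} Hz, 70 trajectories per rate, per-axis
localization noise 0.05 μm constant across rates, photobleach-limited track
durations drawn from a geometric law with mean 30 frames truncated below at
the 10-frame acceptance floor, and populations optionally mixed across
components with true labels recorded.  Model-curve simulations use 30 frames
per track and 1000 trajectories per rate.  Features of real data it does not
emulate: detection/tracking failures, blinking, drift, depth-of-focus loss of
off-equator molecules, EMCCD gain noise, and cell-to-cell variability in size
or domain structure.  Passing recovery tests therefore demonstrates
self-consistency of the inference at realistic noise levels, not robustness
to those unmodeled effects.

The spot utilities render integrated-Gaussian fluorescent spots with Poisson
(or matched-variance Gaussian) noise and compute the box-sum signal-to-noise
ratio `SNR = (I_s − I_b)/sqrt(σ_s² + σ_b²)` over 9×9-pixel boxes; with a
single frame the box-sum variances are propagated from shot noise (variance =
sum of counts), with an image stack they are estimated empirically across
frames.  The study's per-rate illumination powers are not mapped to absolute
photon counts, so SNR targets are self-consistency checks (an SNR ≈ 2 spot
re-measures near 2), not radiometric calibration.

## Numerical and reproducibility choices

All randomness flows from integer seeds through `numpy` `SeedSequence`
spawning (one independent stream per frame rate), so every stage is exactly
reproducible and conditions differing only in `(D, R)` share their underlying
normal draws.  Observed standard errors are floored at 1e-6 μm² in weights.
Degenerate inputs (identical mixture standards, non-overlapping rate windows,
zero variance in SNR boxes, sub-curvature-scale steps) raise informative
errors rather than returning numbers.  Problem sizes used by the acceptance
batteries — 10 replicates per condition, 70 tracks per rate observed, 1000
per rate for model curves, coarse-then-fine grid — are the package's standard
operating point for a desk-scale reanalysis.

## Known limitations

- The `Δchi² = 1` parameter bounds treat MSD points as independent; because
  time-averaged MSD values at nearby delays share tracks and are strongly
  correlated, the reduced chi-squared at the minimum is typically well below
  1 and the bounds are optimistic.  Replicate-based intervals (as in the
  recovery batteries) are the more honest uncertainty.
- Whole-surface confined runs place some origins on caps, where the
  origin-chart disc is an exponential-map approximation of the true geodesic
  disc.
- The quick-look plateau estimator inherits the square-domain bias described
  above by design.
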