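# Methods

## Coordinate conventions

Images are indexed `(i, j)` = (row, column) = (y, x) with the origin at the
top-left corner. Pixel `(i, j)` covers `[j·a, (j+1)·a) × [i·a, (i+1)·a)` nm
(pixel pitch `a`), so its center is at `((j+0.5)a, (i+0.5)a)`. All
localization coordinates are 0-based nanometres. The default object-plane
pixel pitch is 100 nm and is configurable everywhere; it is a typical value
for an EMCCD behind ~160× effective magnification and must be set to the
calibrated value of a given instrument.

## Camera model

Counts relate to photons through three numbers: `offset_counts` (baseline,
default 100), `counts_per_photon` (EM gain × AD conversion lumped into one
factor, default 10) and `read_noise_counts` (Gaussian σ, default 10).
Conversion to photons clips at zero: `max(0, counts − offset)/g`. The
excess-noise factor of the EM register is *not* modelled; the Gaussian
readout term is the only non-Poisson noise. This slightly flatters the
shot-noise statistics relative to a real EMCCD (real variance is ~2× the
Poisson value at high gain); the precision formula's background term is
correspondingly conservative (it uses the fitted background level `b`, not
its square root, as the per-pixel noise scale).

## Emission / blinking model

The simulator is deliberately memoryless: each emitter turns on in each
frame independently with probability `p_on_per_frame` (default 0.01 in the
pipeline config), with at most one event per emitter per frame and no
explicit on/off dwell-state kinetics. Photon yields per event are
exponential with configurable mean, truncated from below (default floor
10 photons; by memorylessness the truncated draw is `floor + Exp(mean)`).
This is the simplest model that exercises a differential-stack detector;
consecutive-frame re-activations of the same emitter are rare at the
default `p_on` and are the main deviation from real photoswitching
kinetics. Defaults emulate a 3000-frame acquisition at 50 ms integration;
the shipped test and demo configurations use 200–500 frames to keep runs
in seconds-to-minutes, which changes only the number of events, not the
per-event statistics.

The PSF is a symmetric Gaussian (default s = 130 nm, appropriate for
~600 nm emission at NA ≈ 1.4) integrated over each pixel's area — the
forward model therefore matches the fitting model exactly. Not modelled:
3D defocus, dipole orientation effects, drift, chromatic offsets.

## Localization engine

* Detection operates on the positive part of the differential frame
  `D[t] = F[t] − F[t+1]`: local maxima at least `threshold` above the frame
  median, non-maximum-suppressed to one candidate per fit window
  (7 px default). The automatic threshold is 5× the robust (MAD-based) σ of
  the *signed* differential frame — the positive part alone is half-clipped
  and would underestimate the noise.
* A positive peak in `D[t]` means the emission ended with frame `t`; the
  event is assigned frame `t` and fitted **on the original photon frame
  `F[t]`**, not on the signed differential image. Fitting the differential
  image would subtract an adjacent noisy frame into the window (doubling
  the background variance and introducing negative lobes); the differential
  stack is used only to decide *where and when* to fit. Negative peaks are
  redundant mirrors of the same on-periods and are ignored.
* The fit is Levenberg–Marquardt least squares of a pixel-integrated
  symmetric Gaussian with parameters (x₀, y₀, s, N, b), capped at 100
  iterations; a fit is rejected when the optimizer fails, the center leaves
  the window, s leaves [50, 250] nm, or N ≤ 0. A plain sampled-Gaussian
  model is available (`model="sampled"`) but the integrated model is the
  default because it conserves photons exactly on noiseless data.
* Quality filters: N ≥ 100 photons, σ_loc ≤ 25 nm (both configurable).
  On noise-only stacks at these defaults the false-localization rate is
  below 1 per 100 frames.
* σ_loc follows the standard photon-statistics formula
  `(s² + a²/12)/N + 8π s⁴ b²/(a² N²)`. Empirically the per-axis RMSE
  against ground truth runs ~1.3–1.4× this prediction (least squares is
  not efficient in the presence of background, and the formula ignores
  window truncation); the validation suite asserts the 1.5× bound and the
  1/√N scaling. RMSE is measured per axis (pooled x and y errors), the
  scale on which σ_loc is defined.

## Rendering

Gaussian mode deposits a unit-mass kernel with σ equal to each event's own
σ_loc, integrated over 10 nm target pixels (≈ the typical 10–15 nm
localization accuracy of cellular data); kernels are truncated at 4σ
(≤ 0.013% mass loss) and the raster is padded by the largest kernel so the
image sum equals the number of localizations. Histogram mode bins unit
counts. Wide-field overlays are resampled onto the SR grid by bilinear
interpolation on pixel centers.

## Cluster analysis

The neighbour criterion (≥ k neighbours within r, the center point
excluded) is read so that the implied critical density is `(k+1)/(πr²)`:
with k = 5 this reproduces exactly 132 molecules/µm² at r = 120 nm and
530/µm² at r = 60 nm, tying the two printed parameterizations to one
formula — which is why "five neighbours" is interpreted as excluding the
center. Both presets ship (`results`: 120 nm; `methods`: 60 nm); the
default is `results`. The two radii are *different analyses*, not a single
resolved value; callers choose explicitly.

Labelling is deterministic and order-invariant: clusters are connected
components of core points (KD-tree radius queries), border points attach to
their **nearest** core point (classic DBSCAN attaches them to whichever
cluster reaches them first, which depends on scan order), and cluster ids
are assigned by smallest member index. Cluster diameter is the maximum
pairwise member distance; `diameter_mode="gyration"` (2× radius of
gyration) is available as a less outlier-sensitive alternative. Internal
density treats the cluster as a disc of that diameter; coincident-point
clusters yield NaN density rather than infinity.

The CSR test uses the clustered fraction as its statistic — it is directly
tied to the quantity of interest (how much of the pattern the density
criterion captures) — with the add-one Monte-Carlo p-value
`(1 + #{S_sim ≥ S_obs})/(n_sim + 1)`; with n_sim = 99 the smallest
attainable p is 0.01. Patterns with fewer than k+1 points return p = 1
with a warning. Note that repeated blinking of a single fluorophore
produces genuine micro-clusters of localizations; the CSR test on raw
localization tables therefore tests molecular clustering *and* blinking
multiplicity, as in any SMLM cluster analysis that does not merge repeats.

## Segmentation and co-localization

Region masks are integer label images (0 extracellular, 1 nucleus,
2 cytoplasm+membrane) with a nm georeference; point lookup is by containing
pixel, and anything outside the footprint is extracellular, so compartment
counts always partition the table. Mask upscaling interpolates each
label's indicator bilinearly and takes the argmax (ties to the lower
label). Interactive region drawing is out of scope — masks arrive from
files or from the simulator's ellipse generator.

Exosome detection thresholds the GFP channel at median + 5 robust σ,
takes 8-connected components of ≥ 4 px, and records intensity-weighted
centroids and equivalent-circle radii. A localization co-localizes with a
spot when within `spot radius + match_radius` of its center
(`match_radius` default 50 nm ≈ vesicle radius plus localization error);
each localization goes to the nearest qualifying spot, and the headline
number is the total co-localized count divided by the number of detected
exosomes.

## Nanoruler validation

The resolution of the whole chain is validated on a simulated DNA-origami
standard: 100 fluorophore pairs at a 35 nm design separation, anchors kept
≥ 5 separations apart, random orientations, ≥ 1000 photons per event,
500 frames, default camera. After localization, repeated blinks are
collapsed by density-grouping at 15 nm (well below the pair separation,
well above the ~3–5 nm precision of these bright events; groups need ≥ 2
events) and the collapsed positions are paired by mutual nearest
neighbour; distances beyond 3× the design separation are discarded as
cross-anchor mispairings, which genuine pairs cannot produce given the
anchor exclusion distance. The mean recovered separation lands within a
few tenths of a nm of the design value (the ~2 nm per-fluorophore
averaging error inflates the mean separation by ≈ +0.1 nm, far inside the
±5 nm manufacturing tolerance of the standard).

## What the simulations do and do not show

Passing tests demonstrate that the chain is self-consistent: the engine
inverts the simulator's forward model within theoretical error bounds, the
cluster statistics match an independent brute-force reference, and the
conservation laws hold exactly. They do not certify performance on real
data, where EM excess noise, drift, non-Gaussian PSFs, out-of-focus
background, label stoichiometry and multi-frame blinking all degrade the
idealized behaviour. Biological quantities (per-cell molecule tallies,
cluster counts per cell line, exosome fraction profiles) depend on the
specimen and are report formats here, not reproducible targets.

## Problem sizes

Default validation runs use 80–100 px fields, 200–500 frames and a few
hundred to ~2000 points per pattern; the CSR calibration uses 200
replicates of n = 300 with 99 simulations each. These sizes give
Monte-Carlo error comfortably inside every asserted band while keeping the
full suite under a minute of compute for the unit tests and a few minutes
for the validation suite.
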