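# Methods

This note documents the models implemented in `patchbooth`, the defaults
and numerical choices behind them, what the synthetic rigs do and do not
emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Colorimetry core

Colors are plain float arrays; spectra live on uniform wavelength grids
(internal working band 380–780 nm at 1 nm; instrument data at 5 or 10 nm
pitch is resampled on ingestion, linearly or with an Akima spline).
Tristimulus integration is rectangle (bin-width) summation — at 1 nm
pitch the difference from ASTM-style weighted tables is negligible for
the smooth spectra handled here. Emissive normalization anchors the
session's reference illuminant at Y = 100; reflective colorimetry weights
reflectance by the reference illuminant (D65 by default, 2° observer).

The CIE 1931 2° color-matching functions are evaluated from the
multi-lobe piecewise-Gaussian analytic fit of Wyman, Sloan & Shirley
(JCGT 2013) rather than shipped as a table. The fit's deviation from the
tabulated CMFs is well under 1 % of peak per function; every quantity the
package reports compares two stimuli through the *same* observer, so this
approximation cancels to first order (the computed D65 white point lands
at xy = (0.3127, 0.3291), checked in the tests). V(λ) is the ȳ lobe of
the same fit; illuminant A uses its exact Planckian formula; D65 is the
standard 10 nm relative-SPD table interpolated to 1 nm.

CIEDE2000 is implemented in vectorized form with parametric factors
kL = kC = kH = 1 (never varied here). It is verified against the 34
published verification pairs to 4 decimals and cross-checked against an
independent implementation (`skimage.color.deltaE_ciede2000`) on random
pairs to 1e-10.

## The tabulated (ΔE00-uniform) color space

**Model.** A lattice of Lab nodes indexed by integer offsets (i, j, k)
from a pinned center, Lab (50, 0, 0) by default, constructed so the
CIEDE2000 between axis neighbors equals `step_de` (default 0.5). In the
lattice's continuous index coordinates ("tab coordinates"), Euclidean
distance × `step_de` approximates ΔE00 locally, which is what makes
sphere packings and isotropic random offsets meaningful.

**Construction.** Nodes are seeded by separable marching — 1-D ΔE00
marching along the lightness axis (truncated with a warning if L* would
leave [0, 100]) and radial ΔE00 marching in the chroma plane — then
relaxed by Adam gradient descent (finite-difference gradients, cosine
learning-rate decay, stop at max move < 1e-4 or 500 sweeps) on a weighted
sum of squared distance residuals. Two constraint families enter the
objective:

- axis neighbors at `step_de` (weight 1) — the defining contract;
- face diagonals at √2·`step_de` (weight 0.3).

The diagonal terms are essential, not cosmetic: the axis contract alone
is under-determined and leaves lattice *shear* modes completely free — a
sheared lattice keeps all six neighbor distances exact while oblique
distances drift by tens of percent. With the diagonal terms the local
Euclidean ≈ ΔE00 equivalence holds to ~1 % (median) for pairs up to two
cells apart, while the axis-neighbor residuals stay within ±0.03 of the
step at desk scale (radius 10 nodes per axis; mean 0.500). Both
properties are asserted in the tests; the acceptance script recomputes
the mean neighbor distance from a freshly built grid.

**Conversions.** Tab → Lab is trilinear interpolation on the node array
(exact at nodes, continuous across cells). Lab → tab locates the
containing tetrahedron in the 6-per-cube split (all six tetrahedra share
the cube's main diagonal; ties broken by fixed cell-scan order), carries
the barycentric weights to index space, then polishes with a few Newton
steps against the trilinear map so the round trip Lab → tab → Lab closes
below 1e-6 (measured ~1e-11). Near the achromatic axis the relaxed
lattice's trilinear map can fold slightly, so a Lab color may have more
than one tab preimage; the inverse deterministically returns one exact
preimage, which is all downstream consumers need.

**Scale.** The desk-scale default extent is radius 40 nodes per axis;
tests and the acceptance run use radius 5–10. A full-gamut grid at step
0.5 (order 10⁷ nodes) is the production-scale computation and is out of
scope here; tab-space gamut meshes therefore accept an RGB sub-cube
restriction, and "printable in tab space" is implemented as grid coverage
∧ CIELAB-gamut membership.

## Printer characterization

**Forward model.** Polyharmonic spline per output dimension with an
affine polynomial tail and side conditions Σwᵢ = 0, Σwᵢxᵢ = 0, solved as
one augmented linear system. Kernels: r, r³, r² log r (φ(0) = 0 for the
thin-plate kernel, its limit value). The scalar smoothing factor s is
applied as s·n added to the kernel-matrix diagonal — the standard
thin-plate regularization reading of a bare "smoothing factor"; s = 0
gives exact interpolation, and the training residual is nondecreasing in
s (asserted). Targets may be CIEXYZ (converted to Lab under D65 after
prediction) or CIELAB directly; model selection exhaustively scores
3 kernels × 2 target spaces × a smoothing grid
{0, 1e-4, 2.5e-4, 1e-3, 2.5e-3, 1e-2, 2.5e-2, 1e-1} by test-chart mean
ΔE00 and keeps the full score table (mean/max/95th percentile for both
ΔE76 and ΔE00). An independent RBF implementation
(`scipy.interpolate.RBFInterpolator`) serves as a second-implementation
oracle in the tests.

**Backward model and gamut.** One fine RGB lattice (default 33³) is
pushed through the forward model and cut into 6 tetrahedra per cube; the
same structure answers color → RGB queries (point location + barycentric
transfer, out-of-gamut raising a distinct error) and in-gamut tests
(boundary counts as inside). The round-trip error is bounded by the
lattice pitch (≤ 2/(n−1) per RGB component, asserted). RGB is treated as
continuous [0, 1]³; 8-bit values appear only in exported manifests.

**Charts and profile.** Training 6³ = 216, test 5³ = 125, both including
the cube corners; the profile file stores all 341 (RGB, XYZ, Lab)
records plus hyperparameters, and XYZ↔Lab consistency is re-verified on
load.

## Patch design

**Reference selection.** FCC lattice (realized as the even-parity integer
lattice scaled by D/√2) — the densest packing, 12 equidistant neighbors
per interior point; HCP would satisfy the same neighbor property, FCC was
chosen for shell enumerability. The largest spacing D keeping N stack
points in gamut is found by bisection (tolerance 1e-3), halving down from
a ceiling (the gamut bounding-box diagonal) to the first feasible
spacing; the stack's shell count is capped so infeasibly small probes
never materialize huge lattices. The N references are the in-gamut stack
points nearest the center (ties: distance, then lexicographic). The stack
center defaults to the centroid of the usable region (deterministic
rejection sampling), falling back to the tab origin.

**Pair generation.** In tab space: lightness index held equal to the
reference, chromatic offset of Euclidean magnitude ρ/`step_de` in a
uniform random direction, ρ ~ N(0.6, 0.4²) redrawn while ρ ≤ 0 (a
distance cannot be nonpositive; ~6.7 % of draws). The rejection biases
the offset mean upward by σφ(α)/(1−Φ(α)) with α = −μ/σ (+0.0555 at the
defaults); the closed-form correction is implemented, verified against a
Monte-Carlo oracle, and applied wherever the configured mean is
estimated from draws. Out-of-gamut draws are rejected and redrawn
(bounded retries). Measurement aggregation is the unweighted mean over
the 3-consecutive × 5-location scheme (for a balanced design the nested
mean equals the grand mean — asserted algebraically). Banding uses
measured ΔE00 with bins <1, 1–1.5, 1.5–2, >2; pairs above 2 are removed
as outliers. Stimulus geometry: patch side = 2d·tan(θ/2) (2° at 40 cm →
1.4 cm).

## LED panel stabilization

**Model.** Linear superposition of per-channel full-drive spectra at the
reference temperature (30 °C), drives in [0, 1]. Thermal drift per
channel: intensity offset dI and wavelength offset dλ, with the drifted
channel modeled as (I + dI)·S(λ + dλ) (effective drive clipped at 0 when
predicting; |dλ| ≤ 10 nm). Objectives integrate over 380–780 nm at 1 nm;
5 nm instrument readings are upsampled with an Akima spline, which
restores peak curvature much better than linear segments.

**Drive solving.** Box-constrained linear least squares (BVLS). The
mean-absolute alternative is an exact L1 linear program (HiGHS); the
squared-error objective is the default.

**Deviation estimation** (from a single measurement) is a nonconvex
search in dλ with many local minima when neighboring channels overlap —
one channel's shift is readily absorbed by its neighbors' amplitudes.
The implemented scheme:

1. *Common-mode stage*: one shared shift offset applied to all active
   channels is scanned first (±5 nm at 0.5 nm). Thermal drift moves all
   affected channels the same way, and this stage steps over the
   misattribution minima that trap purely per-channel searches.
2. *Per-channel refinement*: block-coordinate descent; each candidate
   shift (coarse 1 nm scan over ±10 nm, then 0.1 nm around the winner) is
   scored by a joint nonnegative least-squares refit of all channel
   amplitudes, so every accepted move lowers the true residual. In a
   closed-loop run the search warm-starts from the previous estimate
   with a ±2 nm trust region (per-step drift in the standard scenario is
   ~0.6 nm), which keeps channel attribution consistent; channels at
   zero drive are excluded from the fit and carry their last known shift
   forward. A tiny ε·dλ² bias keeps degenerate (nearly unconstrained)
   channels at zero shift.

Recovery on a spectrally isolated channel is within 0.005 (dI) and
0.2 nm (dλ) of an injected truth (asserted); with strongly overlapping
channels attribution degrades gracefully — the fitted model never
explains the measurement worse than assuming no deviation.

**Closed loop.** Per iteration: measure → estimate deviation → re-solve
drives against the target under the deviated model → apply; metrics
(ΔE00, ΔE76, illuminance ratio, spectral MSE) are recorded per iteration
plus one final post-correction measurement. Color metrics anchor both
spectra's XYZ to the target (target Y = 100) and use the target as the
adapted white, so the target maps to Lab (100, 0, 0) and intensity loss
appears in L*. The standard drifting scenario ramps 30 → 45 °C linearly
over 10 control steps.

**Known limitations.**

- *Additive-offset extrapolation.* The estimated dI is exact only at the
  drives it was measured at; physically the attenuation is a gain, so
  raising a heavily attenuated channel under-compensates by about
  attenuation × drive change. The loop re-estimates every iteration and
  contracts onto the target anyway (the daylight scenario settles around
  0.1 ΔE00), but a red-heavy incandescent-metamer target under the same
  harsh scaled-down ramp plateaus near 0.7 — dominated by this bias plus
  red-channel overlap. (A multiplicative-gain update was tried and is
  *unstable* in closed loop: gain errors compound; the additive form is
  kept.)
- *Objective equivalence.* Squared-error and absolute-error objectives
  stabilize within 0.1 ΔE00 of each other at per-step drift comparable
  to a realistic ~1 s control cadence (tested at 0.4 °C/step). On the
  harsh 1.67 °C/step ramp they separate (~0.15–0.3): the quadratic
  objective spreads residual across the spectrum in a way ΔE00 favors.

## Synthetic rigs

- **Virtual printer**: reflectance = paper-white(λ) · Π_c
  (1 − amount_c·absorb_c(λ))^γ with cyan/magenta/yellow-like Gaussian
  absorption bands, γ = 1.8, amount = 1 − RGB channel; multiplicative
  measurement noise (default 0.2 %), seeded. It is smooth, monotone and
  printer-like, which is all the characterization pipeline needs — it is
  *not* a physical ink model (no halftoning, no ink limits, no
  fluorescence), so characterization accuracy on it bounds model
  fidelity, not real-printer behavior.
- **Virtual panel**: 19 channels with measured peak wavelengths
  (406–777 nm), amplitude attenuations (1–30 %) and categorical peak
  shifts at 45 °C; attenuation and shift scale linearly in (T − 30)/15.
  Channel shapes are Gaussian surrogates — FWHM 22 nm for narrow
  emitters, 70 nm for the three broad ones — because the real spectra
  are not tabulated; the shift categories are mapped to 0 / 3 / 5 nm
  ("no" / "<10" / gradual), a modeling choice. Drive response is exactly
  linear. Consequently, passing tests demonstrate the *algorithms* under
  a faithful drift structure, not the detailed spectra of any specific
  luminaire.
- **Virtual spectroradiometer**: 350–1000 nm capability, default band
  380–780 nm at 5 nm; a reading averages 3 consecutive captures with
  0.3 % multiplicative noise per capture (the same 3-consecutive
  convention used when measuring printed patches). Panel
  characterization sweeps measure over the full instrument range so
  thermally shifted red-edge channels are not clipped, and the
  summarized attenuations round-trip to the configured values at 1e-6.

A single top-level seed pins every synthetic output bit-exactly for a
fixed call sequence.

## Problem sizes used by tests and the acceptance run

Tabulated grids at radius 5–10 nodes per axis (desk scale; the full
production grid is ~10⁷ nodes); backward/gamut lattices at 9–33³;
500-point held-out evaluations; 10-step thermal ramps; 10⁵-draw sampler
checks. These sizes were chosen so the complete suite exercises every
stage end-to-end in a couple of minutes while leaving each statistical
check enough power (3-standard-error bands where sampling is involved).
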