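# Methods

This note records the models, conventions and numerical choices behind
`dosekit`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the tests do and do not demonstrate.

## Units and calibration algebra

Canonical internal units are MBq (activity), hours (time), seconds
(acquisition durations only), grams (mass), Gy (dose) and mm (length);
all I/O converts at the boundary.  One MBq·h corresponds to 3.6×10⁹
nuclear transformations.

A calibration factor links reconstructed image counts to activity and is
meaningful only together with the total acquisition duration
T = n_projections × seconds_per_projection of the scan it was measured on:
the same activity accumulates proportionally more counts in a longer scan.
The four unit kinds in clinical use are related exactly by

    sensitivity [cps/MBq] = 1 / (factor [MBq/count] × T [s])

with Bq·count⁻¹ = 10⁻⁶ MBq·count⁻¹ and Bq·intensity⁻¹ treated as a synonym
of Bq·count⁻¹ ("intensity" being a vendor name for reconstructed voxel
counts).  Conversions round-trip to ≤10⁻¹² relative error, and re-expressing
a count-based factor for a different protocol multiplies it by
T_calibration / T_patient, leaving the sensitivity invariant — both are
property-tested.  Per-time-point factors are supported by rescaling one
factor to each acquisition's duration.

The radionuclide registry ships the ¹⁷⁷Lu physical half-life (159.53 h).
The locally deposited energy per decay E_local (J) — the electron/beta
energy assumed absorbed where emitted — is deliberately *not* bundled: it
must come from the user's decay-data compilation (examples use
2.37×10⁻¹⁴ J ≈ 148 keV per decay, the typical tabulated electron +
conversion-electron energy for ¹⁷⁷Lu).  The decay constant is always
derived as ln 2 / T₁/₂, never stored.

## Synthetic phantom

The generator emulates a quantitative SPECT/CT dosimetry series: a
128×128×96 grid of 4.42 mm isotropic voxels, four time points at
4/24/72/192 h post injection of A₀ = 7200 MBq, acquisitions of
60 projections × 45 s, and a system sensitivity of 9.67 cps·MBq⁻¹ (the
value implied by a 38.3×10⁻⁶ MBq·count⁻¹ factor over 2700 s).  Organs are
non-overlapping axis-aligned ellipsoids — liver and spleen at
1.06 g·cm⁻³, kidneys at 1.05 g·cm⁻³ — with uptake-fraction kinetics
A(t) = A₀ Σᵢ fᵢ e^(−λᵢ t) (one term mono-, two terms bi-exponential).
Default fractions and effective rates were chosen once so organ masses
(~1 kg liver, ~176 g spleen, ~132 g per kidney) and TIACs (~10 h liver,
~0.9 h spleen, ~1.5 h both kidneys) sit inside published
¹⁷⁷Lu-DOTATATE patient ranges; the background holds 30 % of A₀ clearing at
0.05 h⁻¹, the remainder representing excreted activity.

Counts are generated directly in image space by the forward quantification
model counts = activity × sensitivity × duration, uniformly within each
organ, optionally Poisson-distributed per voxel (fully reproducible from
one seed).  **Not** modelled: projection/reconstruction physics, scatter,
attenuation, collimator response, partial-volume blurring, organ motion,
and non-uniform uptake.  Passing round-trip tests therefore demonstrates
the correctness of the analysis chain's algebra and estimators, not
robustness to reconstruction artefacts of real SPECT.  An optional integer
translation per time point exercises the registration step; it is off by
default, so phantom series are perfectly aligned.

Ground truth is analytic: mass = voxel count × voxel volume × density
(voxelized, so quantification round-trips exactly), TIA = A₀ Σ fᵢ/λᵢ,
TIAC = TIA/A₀, and the LED mean dose = TIA × 3.6×10⁹ × E_local / mass.

## Quantification

Volumes of interest come from one label map (conceptually drawn on the
reference time point) and are propagated rigidly, so organ volume and mass
are constant across time points.  Registration is translation-only: an
exhaustive search over the (2r+1)³ integer-shift cube (default r = 5
voxels) maximizing the normalized cross-correlation over the overlap
region; ties prefer the smaller |shift|, and constant volumes return a
zero shift flagged degenerate.  The returned vector is the displacement of
the moving volume *relative to* the reference (moving ≈ reference content
translated by +d); negating it aligns.  Rotation is out of scope — inputs
are assumed approximately aligned, as the phantom guarantees.  Densities
come from the label catalogue, not from CT numbers; no partial-volume
correction is applied anywhere.  Voxel indices are 0-based with a
voxel-center convention at (i + ½)·spacing.

VOI activity is (Σ counts in VOI) × MBq-per-count, with the factor
rescaled to the acquisition's duration; the result is provably independent
of the unit kind and additive over disjoint VOIs.

## Time–activity models and integration

All fits minimize unweighted least squares on the activity scale (fitting
A(t) rather than A(t)/A₀ is equivalent for TIAC).  Fits are deterministic:
no random restarts.

* **Mono-exponential** A e^(−λt): initialized by log-linear regression,
  refined by bounded least squares (λ > 0).  TIA = A/λ.  Non-decaying data
  return a flagged fit with λ clamped at the lower bound.
* **Bi-exponential** A₁e^(−λ₁t) + A₂e^(−λ₂t): damped least squares
  initialized by peeling the slow component off the last two points and
  the fast component off the early residual; if the slow component already
  explains the curve the second term starts at zero amplitude, which makes
  the degenerate (single-rate) case exact.  Amplitudes are non-negative by
  default; a wash-in option frees A₁'s sign.  TIA = A₁/λ₁ + A₂/λ₂.
* **Power-exponential** A t^b e^(−c t^d) (c, d > 0, b > −1 for
  integrability at 0): initialized from the mono-exponential fit at
  (b = 0, d = 1), which the family nests exactly; a fitted b ≤ −1 is
  rejected.  TIA by adaptive quadrature on (0, t_last) + (t_last, ∞) at
  10⁻¹⁰ relative tolerance.
* **Trapezoid + tail**: head = ½·t₁·A₁ (zero-line) or t₁·A₁ (constant at
  the first sample — the interpretation chosen for the "constant from time
  zero" convention, whose constant is not otherwise defined); trapezoids
  between samples; tail = A_last/λ analytically.  The default tail rate is
  physical decay only (¹⁷⁷Lu), configurable to effective rates.  The same
  integral runs vectorized per voxel to produce TIA maps.

TIAC = TIA/A₀ holds to machine precision by construction.  Goodness of fit
is the Spearman rank correlation between observed and fitted values
(1 for any exact monotone fit; NaN for single-point curves) plus the
residual sum of squares.

**Automatic selection** compares converged parametric candidates by AICc
with the small-sample denominator clamped, AICc = n ln(RSS/n) + 2k +
2k(k+1)/max(n−k−1, 1): the clamp keeps the criterion finite for the
common 4-point/4-parameter bi-exponential case while still penalizing it
heavily, so parsimony wins unless the extra component is decisively
better.  RSS is floored at n·(10⁻¹²·max|ŷ|)² so exact fits compare by
parameter count rather than floating-point noise; remaining ties break
toward fewer parameters.  If no parametric candidate converges (or only
one point exists) the trapezoid+tail integral is returned with a warning.

## Dose engines

* **S values**: D(target) = Σ_sources A₀ × TIAC(source) × S(target←source)
  × adj.  Patient-mass adjustment multiplies the *self-dose* term by
  m_ref/m_patient (inverse-mass scaling of local absorption); cross terms
  are unscaled by default and the scaling is configurable, since published
  implementations differ by generation.  Tables are pluggable CSV
  (`source,target,S_Gy_per_MBqh,ref_mass_g`); no proprietary values are
  bundled and every (source, target) pair used must be present explicitly.
* **LED**: dose = TIA × 3.6×10⁹ × E_local / (density × voxel volume), a
  per-voxel division by the relative density (zero density under nonzero
  TIA is a hard error naming the voxel).
* **DVK**: zero-padded *linear* convolution (FFT-based; no periodic
  wrap-around) of the TIA map with a water kernel of identical spacing —
  a spacing mismatch is a hard error, no resampling is implied.  Optional
  first-order density correction divides each voxel by its relative
  density; heterogeneous transport is out of scope.  Energy is conserved
  over the padded field to ≤10⁻⁶ relative; doses deposited outside the
  stored grid are cropped, so conservation checks keep a source-free
  margin of at least the kernel radius.

Kernels are built from an isotropic radial deposition profile (default
exponential).  Each voxel receives the profile's integral over its volume
by midpoint subsampling (≥7³ points per voxel, refined automatically for
sub-voxel profiles), normalized by the same quadrature extended over a
grid covering essentially all of the profile — so the quadrature bias
cancels and the stored energy fractions sum to ≤1 exactly.  The truncation
1 − Σ must stay within tolerance (default 0.5 %), otherwise construction
fails.  The default scale of 0.3 mm reflects the sub-voxel electron range
of ¹⁷⁷Lu at 4.42 mm sampling, which concentrates ~99 % of the energy in
the source voxel; the radius-0 kernel *is* the LED model in water, and the
two engines share that code path so they agree bit-for-bit there.  With the
default profile, LED and DVK organ means agree within 2 % for uniform
organs ≥15 voxels across (a numerical-consistency statement about interior
dominance, not a clinical claim).

DVHs are cumulative (fraction of VOI ≥ dose) on 0.01 Gy bins by default,
starting at 1.0 and monotone non-increasing; mean doses are computed from
the dose map, never from the histogram.

## Pipeline

A YAML config fully determines a run (inputs or phantom preset,
calibration, nuclide, fit and engine choices, seed); sanity checks
(shared geometry, increasing unique time points, positive durations,
usable calibration, complete label catalogue) must pass before any
computation.  Each stage (calibrated → quantified → fitted → dosed)
writes a JSON checkpoint keyed on a hash of the config+seed, so runs can
be resumed or truncated at stage boundaries and re-runs are byte-identical.
Dispersion across engine/model variants is summarized per organ as mean,
range, sample standard deviation (n−1 denominator) and relative SD — the
statistics used in multi-platform comparisons.

## Problem sizes and limitations

Unit tests run on small grids (≈32³); end-to-end and acceptance runs use
the full 128×128×96 phantom, with 100 seeded Poisson studies for the noisy
recovery experiment and 100 replicates for noisy-fit statistics — sizes
chosen to keep a complete run at desk scale (about a minute) while leaving
Monte-Carlo standard errors far below the tolerances tested.

Known limitations: no tomographic reconstruction or its corrections; no
rotation or deformable registration; no partial-volume correction; no
tumor or bone-marrow dosimetry; no radiobiological indices (BED/EQD2); no
decay-chain daughters or cross-organ photon transport beyond what an
S-value table encodes; uncertainty propagation through the chain is not
implemented.
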