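# Methods

This note documents the models implemented in `sersvoc`, the
parameters that matter, the design decisions taken where the problem
was genuinely open, and what the synthetic-data experiments do and do
not demonstrate.

## Spectral data model

A spectrum is a strictly increasing Raman-shift axis (cm⁻¹) with one
intensity per point (arbitrary counts). The default axis spans
1000–2300 cm⁻¹ at 648 points (≈ 2.01 cm⁻¹ per step), matching the
acquisition window of the sensing experiment the pipeline models.
Spectra are exchanged as two-column CSV (`raman_shift_cm1,intensity`,
comma delimiter, decimal point, mandatory header) and collections via
a manifest CSV (`path,label,concentration_vv,replicate`); empty
manifest fields denote absent metadata, so unlabeled spectra flow
through quantification unchanged. Values are serialized at 17
significant digits, making the write→read round trip exact. The CSV
dialect is a package convention — vendor formats (SPC, WDF, JCAMP-DX)
are out of scope.

Concentrations are dimensionless volume fractions; helpers
`PPM = 1e-6`, `PPB = 1e-9`, `PPT = 1e-12` convert the mixed notations
common in gas-sensing work.

## Synthetic spectrum generator

No public corpus of trace-aldehyde SERS spectra exists for this
sensing chemistry, so the generator is a first-class, tested component
that emulates the structure the analysis assumes:

* **Shared reporter bands** from the 4-ATP capture layer at 1141,
  1179 and 1593 cm⁻¹ (amplitudes 3.0, 2.5, 0.5) and the
  phenylacetylene internal standard at 1985 cm⁻¹ (amplitude 3.0).
  All amplitudes are package conventions — peak intensities are never
  published for this system. The 1593 band is kept weak so the
  1545–1800 cm⁻¹ region stays diagnostic of the analyte; the
  internal-standard amplitude sets the absolute scale of the
  concentration-responsive line (see below) and 3.0 keeps that line
  dominant in its band at the 100 ppb study concentration.
* **Class-specific lines.** The C=N (Schiff-base) stretches at
  benzaldehyde 1625, oxalaldehyde 1632, glutaraldehyde 1627,
  salicylaldehyde 1610 and 4-nitrobenzaldehyde 1652 cm⁻¹, and C−C
  stretches in 1558–1589 cm⁻¹ (with split doublets for salicylaldehyde
  and 4-nitrobenzaldehyde), follow the published band assignments.
  Formaldehyde forms no observable C=N line; its C−C band at
  1585 cm⁻¹ is its analyte-responsive line.
* **Fingerprint lines.** Each class carries two additional peaks in
  the 1100–1500 cm⁻¹ C−H/C−C/C−S deformation region, where real
  aldehyde spectra differ most. Their positions (e.g. benzaldehyde
  1205/1311, 4-nitrobenzaldehyde 1268/1341 cm⁻¹) are synthetic
  conventions chosen to be mutually distinct, not literature values.
  Without them a single band would carry all class information and
  the 12-feature encoding could not support the documented easy-preset
  recovery; with them the class signal is redundantly spread over
  three bands, which is also how practitioners describe real spectra
  of these analytes.
* **Nuisance structure.** Per-peak center jitter ~ N(0, σ_jitter);
  Poisson-many "miscellaneous" peaks placed uniformly in
  1100–1500 cm⁻¹ with uniform amplitudes; a degree-≤2 polynomial
  baseline in the reduced coordinate (x−1000)/1300 (default
  coefficients 0.3, 0.4, −0.2); i.i.d. Gaussian noise per point.
  Peaks are Lorentzian by default (the natural Raman line shape,
  FWHM 12 cm⁻¹) with a Gaussian option.

Two presets encode the two spectral-quality regimes studied:

| preset | jitter (cm⁻¹) | noise sd | misc rate | misc amplitude |
|--------|---------------|----------|-----------|----------------|
| easy (ppb-like) | 1 | 1 % of max amplitude (0.03) | 1 | 0.2–0.8 |
| hard (ppt-like) | 4 | 10 % (0.3) | 5 | 0.4–1.5 |

The experiment reports no per-spectrum noise statistics, so these are
package conventions fixed once; "hard" deliberately pushes the
interferent amplitudes past the fingerprint lines so that band
argmaxes are sometimes captured by interferents.

**Concentration response.** The analyte line's amplitude is not set
nominally: it is solved (Brent root-finding, cached per class and
concentration) so that the package's *own* ratiometric measurement of
the noise-free spectrum equals the configured law
max(0, k·log₁₀(c) + b), defaults k = 0.5 per decade, b = 4. This
calibrates the generator against the measurement operator, so that in
the noise-free limit the measured ratio reproduces the law exactly
rather than up to peak-overlap contamination; amplitudes are clipped
at zero because the Schiff-base signal cannot be negative. Blanks
(c = 0) contain no analyte line at all.

**Determinism.** Every spectrum draws from an independent stream
spawned from the root seed keyed by (class index, sample index), so
enlarging one class never perturbs another class's draws, and
identical (config, seed) yields bit-identical datasets. The default
dataset is 108 spectra per class × 6 classes = 648 spectra at
10⁻⁷ v/v (100 ppb), replicate ids cycling over 4 batches, emulating
four independent measurement runs.

## Ratiometric quantification

`peak_intensity` reads a band as the maximum intensity inside a
±10 cm⁻¹ window minus a straight "edge line" interpolated between the
window's two boundary samples, floored at zero. The window half-width
is a package choice (no window is published): wider than the center
jitter, narrower than the band spacing. The edge-line baseline is
local and linear — adequate for the generator's degree-≤2 baselines
and transparent to test; it undercuts an isolated Lorentzian by < 2 %
(the edge line rides on the peak's own tails), a bias that cancels in
the ratio of two same-shaped peaks.

The calibration is ordinary least squares of the ratio on log₁₀
concentration (base 10 throughout, matching decade-spaced series);
R² = 1 − SS_res/SS_tot and the residual sd uses n−2 degrees of
freedom. At least three distinct concentrations are required. Because
numerator and denominator windows scale jointly under a global
intensity change, the fit is invariant to laser-power drift — the
internal-standard rationale, asserted to 1e-10 in the tests.

The limit of detection back-projects the blank-ratio distribution
through the line at signal-to-noise 3:1:

    LOD = 10^((blank_mean + 3·blank_sd − intercept)/slope).

Whether the original analysis used blank replicates or residual noise
is not stated; this package defines the LOD through blank replicates,
and flags LOD ≥ 1 v/v as "at/above calibration range". The LOD is
strictly increasing in blank noise and requires a positive slope.

## Band features

The 13 band edges are 1000, 1030, 1152, 1174, 1195, 1280, 1350, 1410,
1450, 1522, 1545, 1800, 2300 cm⁻¹ — the eleven published interior
edges inside the published acquisition limits. Bands are half-open
[eᵢ, eᵢ₊₁) with the last closed at 2300; edge membership is not
specified anywhere, so the half-open convention is fixed and tested
(1800.0 belongs to the last band). The feature is the shift of the
per-band intensity maximum, ties broken toward the lowest shift
(arbitrary but fixed). Positions are invariant to global intensity
gain and additive offsets. For network training each position is
min-max scaled to [0, 1] within its band; whether the original
encoding was absolute shift, band-relative offset or point index is
unstated, and the normalized band-relative offset is this package's
choice (it equalizes the dynamic range of narrow and wide bands).

## Classifier

A fully connected network with 12 inputs, one hidden layer of 6
units, and a 6-way softmax output, trained by full-batch gradient
descent on mean categorical cross-entropy with analytically
back-propagated gradients (verified against central finite
differences to 1e-6 relative error). The published description of the
activation ("nonlinear softmax") is ambiguous — softmax on a hidden
layer is unusual — so the hidden activation defaults to sigmoid with
tanh/relu switches. Initialization is Glorot-uniform
(±√(6/(fan_in+fan_out))) with zero biases, reproducible by seed;
softmax uses max-subtraction and the cross-entropy floors
probabilities at 1e-12. Training is deterministic given (data, seed)
and invariant to sample order (full batch).

No optimizer, learning rate, epoch count or batch size is published.
Defaults are learning rate 0.5 for 5000 epochs: at 0.1 the descent is
still far from converged at 5000 epochs on the easy-preset task
(held-out accuracy ≈ 0.93), while 0.5 converges comfortably inside
the same epoch budget; the loss trajectory remains monotone and
finite at either setting.

The 540/108 train/test split is stratified by class (18 test spectra
per class), with per-class counts apportioned by largest remainder so
uneven datasets split exactly; the original description says only
"randomly separated", so stratification is a documented choice.
Prediction is the probability argmax with ties to the lowest class
index in the canonical class order.

## Evaluation

The confusion matrix counts true class (rows) against predicted class
(columns); the row-normalized diagonal is per-class recall, the
reading adopted for "per-class prediction accuracy" (precision is the
other possible reading; it is not used). ROC curves sweep thresholds
over the unique scores of a one-vs-rest probability column;
AUC is the trapezoidal area and equals the Mann–Whitney pair
statistic with ties credited 0.5 — asserted exactly, including tied
scores, against brute-force pair counting. Macro AUC is the
unweighted mean of the per-class AUCs; micro AUC pools all
(probability, indicator) pairs across classes before computing one
curve. The PCA baseline column-centers the raw intensity matrix and
takes the top right singular vectors; each component is oriented so
its largest-magnitude loading is positive, making score signs
reproducible; explained-variance ratios are squared singular values
over their total.

## Transport models

**Diffusion/retention.** Fick's second law in one dimension is solved
by the explicit central-difference (FTCS) scheme with the stability
bound D_a·Δt/Δx² ≤ ½ enforced (violations raise an error naming the
maximum admissible Δt). Closed boundaries are reflecting and conserve
the trapezoidal mass to machine precision; the "inlet–outlet" mode
holds the inlet at c₀ during injection (then at 0, a carrier purge)
and the outlet at 0. The outlet is absorbing rather than
zero-gradient: a zero-gradient outlet admits no diffusive outflow at
all, which would make "passed through the array" meaningless in a
purely diffusive model. Retained fraction is the trapezoidal mass in
a region over the total injected mass (flux-accounted at the inlet;
initial mass for closed runs), clipped to [0, 1] against the small
flux-discretization error.

The multiphysics geometry, boundary conditions and diffusivities
behind the original retention simulation are unpublished, so the
defaults are a transparent 1D abstraction fixed once: a 1 mm domain,
101 grid points, Δt = 1 ms, continuous unit-concentration inlet, and
a 100:1 diffusivity contrast (10⁻⁸ m²/s for the open substrate,
10⁻¹⁰ m²/s for the shell-confined one). At the 120 s reference time
the slow run retains essentially all injected mass while the fast run
retains ≈ 33 % — the qualitative ordering is the claim, not the
numbers. The solver itself is verified quantitatively: a Gaussian
pulse matches the heat-kernel closed form (variance σ² + 2D_a t) to
≤ 10⁻³ relative L2 at 401 grid points, with the expected second-order
error reduction under grid refinement.

**Penetration depth.** The evanescent decay length of the plasmonic
field into the medium is Z = (λ/2π)·√((ε′_medium − ε′_Ag)/ε′_Ag²),
with ε′_Ag < 0 required. The printed source formula ends in an
ambiguous "]/2", read here as a ½ exponent — the standard
evanescent-decay form. Z is strictly increasing in ε′_medium, so a
MOF shell (ε′ = 1.34) always deepens the field relative to air
(ε′ = 1.0003); the real part of silver's permittivity at 633 nm is
not printed in the source, so tests assert the inequality across a
literature-plausible range (−60 to −2) and the worked example uses
ε′_Ag = −18, a representative literature-scale value.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate that the pipeline's machinery is correct
and self-consistent: features equal an exhaustive oracle, gradients
equal finite differences, AUC equals pair counting, the calibration
recovers a known law, the solver matches closed forms, and the
classifier separates what is separable. They do **not** certify
performance on laboratory spectra: the generator's line shapes,
amplitudes, fingerprint positions, noise and interferent statistics
are conventions, real SERS backgrounds are not degree-2 polynomials,
real peak intensities covary with surface chemistry, and the
published headline accuracies (84.2 % / 80.9 %), R² = 0.993, LOD and
per-class AUCs were measured on an undeposited experimental dataset
that this package cannot reproduce. The hard-preset degradation is a
qualitative analogue of the ppb→ppt quality loss, not a quantitative
reproduction. Problem sizes throughout (648 spectra, 5 seeds for the
hard regime, 100-replicate Monte-Carlo, 401-point solver grids) are
the package's own choices balancing statistical resolution against a
suite that runs in well under a minute per module.

## Degenerate inputs and numerical conventions

Zero-length spectra, non-increasing axes and non-finite values are
rejected at construction with the offending row named. An all-zero
intensity window makes the internal standard "absent" (error) rather
than silently dividing by zero. A non-positive calibration slope
makes the LOD undefined (error). Empty feature bands (axis not
covering a band) raise rather than emitting placeholder positions.
All tie-breaks (feature argmax, prediction argmax) go to the lowest
index and are tested.
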