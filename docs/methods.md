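# Methods

This note documents the models behind `af4saxs`, the choices made where
the methodology was genuinely open, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Scope and data model

The pipeline operates on a *fractogram*: a strictly time-ordered series
of elution frames, each carrying a reduced 1D SAXS curve (q [nm⁻¹],
I(q) [arbitrary units, linear in concentration], σ(I)), a UV₍₂₆₀₎
absorbance value, and a set of (angle, excess Rayleigh ratio) MALS
records. All SAXS frames share one q-grid; frames read from disk are
interpolated onto the first frame's grid only when per-point deviations
are below 1%, otherwise the run is rejected. Units are fixed package-wide
(q in nm⁻¹, distances in nm, concentrations in mg/mL, molar masses in Da
with MW estimates reported in kDa, densities in g/mL); all conversions go
through the constants in `af4saxs.units` (1 nm³ = 10⁻²¹ mL,
1 mg = 10⁻³ g, N_A = 6.02214076×10²³ mol⁻¹).

## Frame processing

**Buffer selection.** The "auto" rule estimates the baseline level from
the first fifth of the run (the pre-elution region): median, and a robust
σ = 1.4826 × MAD. The buffer window is the longest contiguous run of at
least 10 frames whose 5-frame rolling-median integrated intensity stays
within 2σ of that baseline. Two deliberate robustness choices: the MAD is
rescaled to a normal-consistent σ because a raw 2-MAD band keeps only
~82% of genuine baseline frames and essentially never admits a 10-frame
run on noisy data; and membership is judged on a rolling median so
single-frame noise cannot fragment a genuine baseline. If the baseline σ
exceeds 10% of the signal span the pre-elution region is not flat and an
explicit window is required.

**Subtraction and averaging.** The buffer is the pointwise mean of the
selected frames; uncertainties propagate in quadrature
(σ′² = σ² + σ_buf²/n). Frame averaging is inverse-variance weighted
(falling back, flagged, to an unweighted mean when any σ is zero).
Time- and q-integrals are trapezoidal throughout.

## Single-curve analyses

**Guinier.** Weighted linear fit of ln I vs q², grown self-consistently
from the lowest usable q until q·Rg reaches the limit (default 1.3, the
community convention for globular scatterers). The truncation bias of
this estimator is model-dependent and was quantified on exact forms: a
Debye coil fitted to q·Rg = 1.0 reads Rg ≈ 3.5% low (1.3% at 0.6); a
solid sphere fitted to 1.3 reads ≈1.9% high (0.7% at 0.8). Validation
tests therefore fit coils to q·Rg ≤ 0.65 and spheres to ≤ 0.7; users
analysing extended or flexible species should do likewise.

**Porod exponent.** Weighted log-log linear fit of I = I₀·q⁻ˣ over a
caller-chosen window; 4 for a smooth sharp interface, lower for rough or
fractal surfaces. The window must avoid the Bragg region: an interior
local maximum inside the window raises a flag (not an error).

**Volume of correlation MW.** Vc = I(0)/∫qI dq with the integral taken
from q = 0 (Guinier model below the first measured point) to
q = 3 nm⁻¹ = 0.3 Å⁻¹, the cutoff of the published calibration protocol;
QR = Vc²/Rg, and MW = QR/0.1231 (protein) or (QR/0.00934)^0.808 (RNA) in
Da with Ångström-unit QR. The calibration constants are empirical,
derived from real macromolecules; on idealised analytic shapes the route
is systematically off (a uniform hard sphere at protein density reads
0.61× its true mass, independent of radius, because its sharp-interface
Porod tail carries more ∫qI than a real protein's). Expect ±15–40%
on toy models and the published ±~10% only on realistic curves.

**p(r) inversion.** Indirect Fourier transform on a 50-point r-grid over
[0, Dmax] with p(0) = p(Dmax) = 0 pinned, non-negativity enforced
(bounded-variable least squares), and a second-difference smoothness
penalty. The penalty weight is the largest multiplier whose data misfit
stays within 5% of the unregularized optimum (an L-curve-style rule);
Dmax is the smallest candidate in a scan around the user's guess whose
residual is within 5% of the best candidate's. Rg(real) comes from the
second moment of p(r). On a noiseless sphere this reproduces Dmax = 2R
within ~5% and the closed-form sphere p(r) with correlation > 0.99.

## Bragg-peak analysis

The Lorentzian model I(q) = I₀ + (2A/π)·w/(4(q−q_c)² + w²) is fitted by
weighted nonlinear least squares inside a window (default 0.7–1.4 nm⁻¹
around the ~1 nm⁻¹ lamellar peak). w is the FWHM, which fixes the
correlation-length convention ξ = 2/w; d = 2π/q_c. Initialisation:
q_c from the *detrended* window maximum — lipoplex curves sit on a steep
power-law decay, so the raw argmax can be the window edge even when a
clear interior peak exists; the trend is a straight line through the
window edges in log-log space (linear in q when intensities are not all
positive), and a peak is accepted only if the detrended maximum is
interior and exceeds 3× the median σ. The default baseline for real LPX
work is the additive power law c·q⁻ˣ with x co-fitted in [3, 4]; a
constant baseline (the textbook form) is available and adequate only
when the peak strongly dominates the local background. Across a series,
failed frames carry NaN rather than aborting, preserving the elution
axis for quantification.

## MALS (Berry) analysis

q_LS = (4πn₀/λ₀)·sin(θ/2) (defaults λ₀ = 658 nm, n₀ = 1.33); a straight
line fitted to √(Kc/R(θ)) vs q_LS² gives MW = 1/b² from the intercept
and Rg = √(6m/b) from the slope. Forward angles are dropped greedily
while doing so improves r² (and at least `min_angles` = 9 remain),
mirroring the practice of limiting forward angles when large particles
dominate; a non-positive slope yields Rg = 0 with a low-signal flag.
Frames whose median Rayleigh ratio is below 3× the baseline MAD are
excluded. For frames where the Berry fit is unreliable (very large
particles), Rg can be filled by a polynomial fit of Rg vs elution time
(default degree 2), explicitly marked as extrapolated. Rg is independent
of the Kc scale; MW scales inversely with it, so an uncalibrated Kc
leaves the size analysis intact.

## Quantification

Stoichiometry: one nucleotide charge (330 Da) binds one DOTMA (635 Da)
plus its share of DOPE at the 2:1 molar ratio (740/2 Da), i.e. 1005 Da
of lipid per charge and a 1335 Da complex per nucleotide. ρ_LPX follows
mass-fraction volume additivity, 1/ρ = f_RNA/ρ_RNA + f_lipid/ρ_lipid
with f_RNA = 330/1335, giving 1.111 g/mL from ρ_RNA ≈ 1.68 and
ρ_lipid ≈ 1.0 g/mL — the rule was chosen because it reproduces the
reference density from the component values. Free mRNA is quantified
*only* from the separated mRNA UV peak (ε = 0.025 mL·µg⁻¹·cm⁻¹ default);
the LPX UV peak is never used quantitatively because particle scattering
contaminates it. The Bragg-area trace is normalized to c_LPXtotal —
frames are treated per-frame and optionally rebinned into 10 equal-Rg
bins. Number concentrations follow the solid-sphere model
(R = √(5/3)·Rg); the I(0)-based mass route is deliberately not
implemented, because forward scattering under-represents large particles
when the Guinier region is inaccessible, whereas the Bragg area measures
ordered mass at any size. D-values interpolate the cumulative
distribution linearly between bin midpoints.

## The synthetic-data generator

The generator is first-class code: it forward-simulates everything the
analysis assumes, so every stage can be tested by parameter recovery.

* **Elution**: each population elutes as a Gaussian in time, truncated at
  ±4σ and renormalized so its trapezoid time-integral equals the injected
  mass concentration exactly. Truncation reflects finite elution bands; an
  unbounded tail of a ~10⁶ kDa particle population would otherwise
  dominate light scattering far outside its own peak. Real AF4 peaks are
  asymmetric; no tailing is modelled.
* **Coils** scatter as the Debye function I = i₀·(2/u²)(u−1+e⁻ᵘ),
  u = (qRg)².
* **Lipoplex-like particles** scatter as polydisperse solid spheres (10%
  Gaussian radius polydispersity — small enough that a per-frame Guinier
  fit is meaningful, large enough to damp the sphere minima) multiplied
  by the ratio of two smooth Guinier/power-law crossover envelopes: the
  target envelope with the requested exponent x at the requested ensemble
  Rg, over the ensemble's own q⁻⁴ envelope at its scattering-weighted
  apparent Rg. This imposes the mid-q exponent exactly by construction
  (giving the Porod tests an exact ground truth), preserves the requested
  ensemble Rg in the Guinier region, and keeps realistic damped sphere
  oscillations. The radius quadrature scales its node count with q·σ to
  keep the oscillatory integral resolved for large particles. A
  Lorentzian Bragg term with area proportional to the frame's mass
  concentration is added on top — the constant-internal-stoichiometry
  premise the quantification rests on.
* **Intensity scale**: forward intensity per frame is K·c·MW (counts-like
  arbitrary units), the Bragg area is K_B·c; all downstream analysis is
  scale-free or normalized, so these constants carry no physical claim.
* **Detectors**: SAXS frames get Gaussian noise of sd = noise_scale·√I
  (counting-like; default 1%) on top of a smooth instrument background
  removed by buffer subtraction; UV is Beer–Lambert absorbance of the
  RNA content plus a turbidity term proportional to forward light
  scattering (the particle UV signal is deliberately contaminated, which
  is why the pipeline never uses it quantitatively); MALS records come
  from the *inverse* first-order Berry relation at 9 angles (35–145°)
  with 1% multiplicative noise, so the Berry fit is exact at zero noise
  by construction. Rayleigh ratios of co-eluting populations add.
* **Reference scenario** (`paper_like_scenario`): free mRNA 0.045 mg/mL
  (Rg 25 nm, 450 kDa) centred at 18 min (σ = 1.5 min); LPX 0.425 mg/mL
  with ensemble Rg ramping linearly 80→470 nm over 30–55 min (AF4 normal
  mode, σ = 4.5 min, centre 40 min); Bragg q_c = 1.047 nm⁻¹ (d = 6.0 nm),
  FWHM 0.08 nm⁻¹ (ξ = 25 nm); envelope exponent 3.63; q-grid 0.02–2.0
  nm⁻¹ (400 points), frames every 0.25 min over 0–65 min. These sizes
  keep the full pipeline (260 frames, ~100 Lorentzian and ~260 Berry
  fits) at ~10 s per run.

What passing tests on this generator do **not** show: robustness to
asymmetric/tailing elution bands, inter-detector band broadening and
delay volumes (frames are taken as pre-aligned; the wider SAXS flow cell
broadens its trace in reality and no deconvolution is applied),
instrumental smearing of the Bragg peak, capillary fouling, emergent (as
opposed to imposed) Porod behaviour, and absolute-intensity calibration —
synthetic intensities are arbitrary-unit and only ratios are analysed.

## Numerical and policy choices

* Guinier window limit q·Rg ≤ 1.3 by default; oracle tests use tighter
  windows per the bias table above.
* Lorentzian fits: bounded trust-region least squares; q_c bounded to the
  window, w to (0, window span], A ≥ 0; power-law exponent bounded to
  [3, 4].
* Missing-value (NaN) policy across per-frame series everywhere —
  a failed frame never aborts a run; quantification renormalizes over the
  frames that did fit.
* Determinism: a single integer seed drives every noise source; the same
  seed yields bitwise-identical fractograms, and the pipeline writes
  byte-identical run directories (provenance headers carry a hash of the
  scientific configuration, excluding which stages were executed, so
  cached-stage reruns remain identical).
* Free-mRNA elution-trace integration assumes the manifest times are
  injected-equivalent (flow calibration factor defaults to 1); a real
  instrument requires the injection/flow calibration in
  `flow_calibration`.

## Known limitations

* The sphere model maps Rg to mass as a compact uniform body; hollow or
  strongly non-spherical particles would need a different V(Rg).
* The Vc-MW calibration constants are documented defaults, not
  instrument truths; see the accuracy discussion above.
* Berry fits beyond q·Rg ≈ 0.5 rely on the generator's exact inverse
  model; on real data the first-order fit degrades for the largest
  particles and the polynomial Rg extrapolation (flagged) takes over.
* D-values for the largest sizes inherit the Rg extrapolation's
  uncertainty.
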