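# Methods

## Forward model

The single-fiber reflectance model composes three pieces, all evaluated
pointwise in wavelength on a working grid of 450–900 nm (2 nm default
spacing, linear interpolation wherever grids must be merged):

1. **Reduced scattering.** μs′(λ) = a₈₀₀ (λ/800 nm)^(−b), with a₈₀₀ in
   mm⁻¹ and b dimensionless. The 800 nm anchor is the convention for
   reporting tissue scattering amplitudes; it is configurable on
   `ScatteringParams`.
2. **Reflectance in the absence of absorption.**
   R_SF0(x) = η_lim (1 + p₆ e^(−p₄x)) x^(p₅)/(p₄ + x^(p₅)) with
   x = μs′·d_f. The constants [p₄, p₅, p₆] = [6.82, 0.969, 1.55] and
   η_lim = 0.027 are fixed, Monte-Carlo-derived coefficients of the
   published model family; R_SF0 rises from 0 at x = 0 through a weakly
   non-monotone-slope regime (the e^(−p₄x) background-scattering term) and
   saturates at η_lim, the diffusion-limit collection efficiency for a
   0.22-NA fiber in tissue-like refractive index.
3. **Modified Beer–Lambert attenuation.** R_SF = R_SF0 e^(−μa·L_SFR) with
   L_SFR/d_f = C_PF p₁ x^(−p₂)/(p₃ + (μa·d_f)^(p₃)),
   [C_PF, p₁, p₂, p₃] = [0.944, 1.54, 0.18, 0.64]. The printed source of
   this path-length expression is typographically ambiguous about the
   exponent signs; we implement the dimensionally consistent form in which
   the effective path length strictly decreases with both absorption and
   scattering, as the single-fiber literature requires, and expose the
   exponent signs on `SFRModelConstants` for sensitivity work.

Absorption is a two-chromophore whole-blood mixture,
μa(λ) = BVF·[StO₂·μa,HbO₂(λ) + (1−StO₂)·μa,Hb(λ)], with no
vessel-packing correction and the water term off by default. The packaged
chromophore tables are **synthetic**: smooth Gaussian-band curves with the
qualitative features of whole-blood absorption (Soret edge, 542/577 nm oxy
double peak, 555 nm deoxy band, 760 nm deoxy shoulder, a near-infrared
crossing) at whole-blood magnitudes for 150 g/L hemoglobin. They make the
pipeline self-contained and exactly invertible in its own model family;
quantitative work on real tissue should substitute measured tables via
`ChromophoreLibrary.from_files`. The phase-function parameter γ is carried
as metadata only and never fitted: the model constants above are
phase-function-averaged, and γ-resolved coefficient tables are out of
scope.

## Calibration

The two-phantom transform
R_SF = R_cal_sim · (I_meas − I_water)/(I_cal − I_water) cancels every
multiplicative instrument factor (lamp, fiber tree, probe coupling,
spectrometer sensitivity) that is common to the measurement and the
calibration, and the water subtraction removes the internal specular
back-reflection. R_cal_sim — the absolute reflectance of the 2% intralipid
standard — is computed with the forward model on the phantom's nominal
properties (a₈₀₀ = 3.0 mm⁻¹, b = 2.4, no blood) rather than by Monte Carlo
photon transport; this keeps the package dependency-free and exact within
the same model family the inversion uses, at the cost of inheriting the
forward model's approximation error in any absolute-accuracy statement
about real phantoms.

Wavelengths where the calibration denominator falls below 10⁻⁶ of its
maximum are masked as NaN rather than clipped, so downstream fits simply
drop them; a calibration masked everywhere raises. The integrating-sphere
correction equalises spectrometer channels against a reference channel
(the small-diameter channel by convention) before any cross-channel
merging; applied uniformly it cancels inside the two-phantom ratio, which
is why the pipeline remains correct whether or not sphere spectra are
available.

**SNR statistic.** Calibration quality is the mean over the closed
675–725 nm band of (replicate mean / replicate sample standard deviation)
of the intralipid signal, computed across replicate acquisitions at each
wavelength. The standard deviation is taken across replicates (not across
time frames or across the band, two readings the definition would also
admit) because replicate acquisitions are what every calibration produces.
With n replicates at relative noise σ the statistic estimates 1/σ; at
small n it runs high (about 20% at n = 5) because E[1/s] > 1/σ for the
sample standard deviation — a property of the statistic as defined, which
disappears by n ≈ 200 and cancels in all within-study comparisons, which
use a common replicate count.

## Inversion

The joint two-diameter fit minimises the stacked pointwise residuals of
both spectra over (a₈₀₀, b, BVF, StO₂) with bounded least squares
(trust-region reflective), bounds a₈₀₀ ∈ [10⁻³, 20] mm⁻¹, b ∈ [0, 4],
BVF and StO₂ ∈ [0, 1], from the deterministic skin-like start
(2 mm⁻¹, 1.2, 0.02, 0.7); an optional seeded multi-start mode perturbs the
start multiplicatively, with ties broken by lowest cost then lowest b.
Convergence failures return a flagged result with infinite residual,
never silently.

- **Residual statistic**: Σ_λ |measured − fitted| × 100 (percent
  reflectance) over the working grid — an "absolute residual" whose
  magnitude on a ~450-point grid makes 25 a meaningful threshold.
- **Confidence intervals**: 95% half-widths from the local linearisation
  (residual variance times the pseudo-inverse of JᵀJ). In
  scattering-dominated spectra (BVF → 0) StO₂ is weakly identified and its
  CI inflates accordingly — which is exactly what the third exclusion
  criterion keys on.
- **Exclusions**: residual > 25; BVF > 0.40; StO₂ CI half-width above the
  batch mean plus three batch standard deviations (the value-based
  reading, StO₂ itself three SD from the batch mean, is available via
  `sto2_rule="value"`). Flagging is pure, order-preserving and idempotent.
- **Aggregation**: repeated measurements are combined by inverse-variance
  weights w = 1/(hw/1.96)²; excluded or nonfinite entries are dropped,
  zero half-widths dominate exactly.

## Synthetic data

Raw counts are modelled as
lamp(λ) × probe_factor × tree_factor × (R(λ) + back_reflection) × (1 + ε):
a smooth halogen-like lamp peaking at 600 nm, wavelength-flat probe and
fiber-tree sensitivities, the true reflectance of whatever faces the
probe, a small internal back-reflection (5 × 10⁻⁴ equivalent reflectance)
that the water measurement isolates, and i.i.d. Gaussian replicate noise
(default relative σ = 0.02; an optional shot-noise mode anchors the
variance to the detector full scale so transmission losses lower the SNR
like photon statistics). The back-reflection enters the tissue counts for
the same reason it enters the phantom counts — it is an instrument
property — and the water subtraction therefore cancels it exactly; the
default replicate count is five, matching routine calibration practice.

**What the generator does and does not emulate.** It reproduces the
multiplicative structure that makes the calibration transform exact, the
replicate statistics behind the SNR, and the mechanism by which
calibration defects propagate into tissue fits. It does not model
wavelength-dependent probe aging, detector nonlinearity or saturation,
pressure and contact effects of a hand-held probe, melanin or other
non-blood chromophores, or real intralipid microphysics. Passing tests
therefore certify the processing chain — not the biological accuracy of
any recovered parameter on real skin.

**Contamination model.** A degraded phantom is modelled as a loss of
effective scatterer concentration: its true scattering amplitude is
scaled by (1 − severity), severity growing linearly with shelf age to a
maximum at 20 weeks, while R_cal_sim continues to assume the nominal
phantom; replicate noise also inflates with severity (gain 1.5). The
scattering-loss choice, rather than a wavelength-flat transmission loss,
is deliberate: a flat loss either cancels in the ratio statistics or, via
the saturation curve's slope profile over the skin regime, biases the
fitted power-law exponent upward, whereas a scattering deficit produces a
signal shortfall that grows toward long wavelengths (where the phantom
sits lower on the saturation curve) and hence biases tissue fits toward
higher a₈₀₀ and lower b — the behaviour a degraded lipid standard is
observed to produce. The true microphysics of a contaminated phantom is
unknown; this is the simplest mechanism with the right signature.

## Statistics

Group comparisons always report the parametric and the rank-based test
side by side (Welch t with Mann–Whitney for two groups, one-way ANOVA
with Kruskal–Wallis for more) instead of automating a normality
gatekeeper; a Holm-adjusted column accompanies the raw p-values but no
correction is applied to the primary decisions. Variability uses the
sample (n−1) standard deviation, CV = 100·SD/mean. Drift is ordinary
least squares of SNR on time with a two-sided zero-slope test; a
perfectly constant series is reported as slope 0, p = 1. All tests use
α = 0.05 two-sided.

## Problem sizes and numerics

The simulated phantom study runs five probes × ten phantoms × five
calibrations with five skin fits each (250 calibrations, 1250 joint
fits, about half a minute); the clinical-style study runs four probes ×
21 monthly calibrations. Fits use xtol = ftol = gtol = 10⁻¹⁴ and converge
in about 10 ms per joint fit on the 226-point default grid; noiseless
round-trips recover parameters to ~10⁻¹² relative. Seeds derive from
`numpy.random.default_rng` with explicit (seed, stream) tuples, so every
scenario is reproducible and distinct streams (calibration, skin, truth
draws) never collide.

## Known limitations

- The forward model doubles as the source of R_cal_sim, so absolute
  reflectance accuracy on real instruments is bounded by that model, not
  checked by it.
- Synthetic chromophore tables preclude quantitative BVF/StO₂ claims on
  real spectra (swap in measured tables for that).
- γ is not estimated; tissues whose phase function departs strongly from
  the calibration family will show model misfit in the residual, not in a
  recovered parameter.
- The exclusion thresholds (25, 40%, 3 SD) are conventions carried from
  clinical practice; they are configurable but not re-derived here.
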