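# mdsfr

Multidiameter single-fiber reflectance (MDSFR) spectroscopy in Python:
calibration of raw fiber-probe spectra into absolute reflectance, the
semi-empirical single-fiber reflectance model, inversion for tissue optical
properties, and the quality-control statistics used to keep a clinical
MDSFR system honest over months of use.

## The problem

A single optical fiber of effective diameter *d*<sub>f</sub> both delivers
white light to tissue and collects the reflected fraction. The measured
reflectance depends on the dimensionless products
μ<sub>s</sub>′·*d*<sub>f</sub> (reduced scattering) and
μ<sub>a</sub>·*d*<sub>f</sub> (absorption):

- **R**<sub>SF0</sub>, the reflectance in the absence of absorption, follows
  a saturating law in *x* = μ<sub>s</sub>′·*d*<sub>f</sub>:

  R<sub>SF0</sub> = η<sub>lim</sub> (1 + p₆ e^(−p₄x)) · x^(p₅) / (p₄ + x^(p₅)),

  approaching the diffusion-limit collection efficiency
  η<sub>lim</sub> = 2.7% (NA 0.22, n = 1.38) as x → ∞;
- absorption attenuates it through a modified Beer–Lambert law,
  R<sub>SF</sub> = R<sub>SF0</sub> e^(−μ<sub>a</sub> L<sub>SFR</sub>), with an
  effective path length
  L<sub>SFR</sub>/*d*<sub>f</sub> = C<sub>PF</sub> p₁ x^(−p₂) / (p₃ + (μ<sub>a</sub>*d*<sub>f</sub>)^(p₃))
  that shrinks as either scattering or absorption grows.

The model constants are [C<sub>PF</sub>, p₁, p₂, p₃] = [0.944, 1.54, 0.18, 0.64]
and [p₄, p₅, p₆] = [6.82, 0.969, 1.55]. Tissue spectra are parameterised by a
scattering power law μ<sub>s</sub>′(λ) = a₈₀₀ (λ/800 nm)^(−b) and a whole-blood
absorption mixture (blood volume fraction BVF, oxygen saturation StO₂).
Acquiring the same site at two fiber diameters (470 and 1100 μm) makes the
scattering law identifiable; the joint fit shares one parameter vector across
both diameters.

Raw detector counts become absolute reflectance through a two-phantom
calibration against a 2% intralipid standard of model-computed reflectance
R<sub>cal</sub><sup>sim</sup> and a dark water measurement:

R<sub>SF</sub> = R<sub>cal</sub><sup>sim</sup> · (I<sub>meas</sub> − I<sub>water</sub>) / (I<sub>cal</sub> − I<sub>water</sub>).

Calibration quality is tracked as the mean signal-to-noise ratio of the
intralipid replicates over a 50 nm band centred on 700 nm, and skin fits are
screened by three exclusion criteria (absolute residual > 25, BVF > 40%, and
an StO₂ confidence interval more than three standard deviations from the
batch mean) before repeated measurements are averaged with inverse-variance
weights.

A synthetic-data module emulates the instrument — lamp shape, probe and
fiber-tree sensitivities, replicate noise, phantom contamination — so every
stage is testable without hardware.

## Worked example

```python
from mdsfr import (
    FiberGeometry, ScenarioConfig, apply_calibration, make_calibration_set,
    make_skin_measurement, mdsfr_fit, sample_skin_params, snr_quality,
)

geom = FiberGeometry()                # 470 um and 1100 um fibers
cfg = ScenarioConfig(seed=42)         # 2% replicate noise, 5 replicates

cal = make_calibration_set(cfg, phantom_age_weeks=0.0)
print(f"calibration SNR (675-725 nm): {snr_quality(cal.intralipid['small']).snr:.1f}")

sc_true, ab_true = sample_skin_params(cfg)
small, large = make_skin_measurement(cfg, sc_true, ab_true, geom)
fit = mdsfr_fit(
    apply_calibration(small, cal, "small"),
    apply_calibration(large, cal, "large"),
    geom,
)
print(f"a_800 : fit {fit.sc.a_800:.3f} mm^-1  (truth {sc_true.a_800:.3f})")
print(f"b     : fit {fit.sc.b:.3f}          (truth {sc_true.b:.3f})")
```

prints

```
calibration SNR (675-725 nm): 60.2
a_800 : fit 1.458 mm^-1  (truth 1.463)
b     : fit 1.304          (truth 1.290)
```

The SNR of about 60 is what five replicates at 2% multiplicative noise
support (the small-sample ratio statistic runs slightly above 1/σ = 50);
the joint two-diameter fit recovers the scattering amplitude at 800 nm and
the power-law exponent to better than 2% at this noise level.

## Analysis drivers

Numbered scripts under `analysis/` rerun the package's two simulated
studies end to end and write tables under `results/`:

1. `01_simulate_phantom_study.py` — five probes × ten phantoms (one
   contaminated) × five calibrations, each followed by five skin fits;
2. `02_calibration_quality.py` — intra-/inter-phantom SNR variability and
   probe comparisons (the contaminated phantom is the only one whose SNR
   separates from the fresh reference, for all five probes);
3. `03_skin_properties.py` — exclusions, CI-weighted means, and the
   contaminated-calibration bias on skin scattering (a₈₀₀ up, b down);
4. `04_drift_trees_and_users.py` — 21 months of monthly calibrations:
   no probe drift, a clear old-versus-new fiber-tree effect, no tripod
   effect.

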