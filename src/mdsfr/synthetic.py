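"""Synthetic instrument data: calibration sets and skin measurements.

Every raw spectrum the pipeline consumes is modelled as

    counts(lambda) = lamp(lambda) * probe_factor * tree_factor
                     * (R(lambda) + back_reflection) * (1 + eps),

where ``lamp`` is a smooth positive halogen-like emission curve peaking
near 600 nm, the probe and fiber-tree factors are wavelength-flat
multiplicative sensitivities, ``R`` is the true single-fiber reflectance
of whatever is in front of the probe (intralipid phantom, water, skin),
``back_reflection`` is the small internal specular return that the water
measurement isolates, and ``eps`` is i.i.d. Gaussian replicate noise.

Because the same back-reflection enters the tissue and the phantom
acquisitions, the two-phantom calibration transform cancels it exactly,
together with the lamp and the probe/tree factors — which is precisely
why the real instrument is calibrated this way, and why a *mismatch*
between the factors in the calibration and in the measurement (degraded
fiber tree, contaminated phantom) propagates into the recovered optical
properties.

Contamination model
-------------------
A degraded intralipid phantom is modelled as a loss of effective
scatterer concentration: the phantom's true reduced-scattering amplitude
is scaled by ``(1 - severity)`` while the simulated reference
``R_cal_sim`` keeps assuming the nominal phantom.  Because the
single-fiber reflectance saturates with dimensionless scattering, the
resulting signal deficit is wavelength dependent (larger at long
wavelengths, where the phantom sits lower on the saturation curve),
which biases subsequent tissue fits toward a higher scattering amplitude
and a shallower power-law exponent.  Contamination also inflates the
replicate noise, lowering the calibration-quality SNR.  Severity grows
linearly with phantom shelf age up to 20 weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .calibration import CalibrationSet, reference_reflectance
from .chromophores import ChromophoreLibrary, default_library
from .model import (
    AbsorptionParams,
    FiberGeometry,
    ScatteringParams,
    SFRModelConstants,
    forward_reflectance,
)
from .spectrum import Spectrum

__all__ = [
    "ScenarioConfig",
    "make_calibration_set",
    "make_skin_measurement",
    "sample_skin_params",
]

#: Nominal optical properties of the 2% intralipid calibration phantom:
#: reduced scattering ~3 mm^-1 at 800 nm with the steep lambda^-2.4
#: wavelength dependence characteristic of the lipid emulsion; no blood.
INTRALIPID_SCATTERING = ScatteringParams(a_800=3.0, b=2.4)
INTRALIPID_ABSORPTION = AbsorptionParams(bvf=0.0, sto2=0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated acquisition scenario; fixed seed => byte-identical data.

    Parameters
    ----------
    seed
        Base seed of the scenario; all draws derive from it.
    grid_nm
        (start, stop, step) of the detector wavelength grid in nm.
    lamp_peak_nm, lamp_width_nm, lamp_counts
        Smooth halogen-like lamp curve: Gaussian bump of the given width
        on a 15% pedestal, scaled to ``lamp_counts`` at the peak.
    probe_factor, tree_factor
        Wavelength-flat multiplicative sensitivities of the probe and the
        fiber tree (1.0 = nominal).
    contamination
        Phantom degradation severity knob in [0, 1]; effective severity is
        ``contamination * min(age_weeks / 20, 1)``.
    contamination_noise_gain
        Replicate-noise inflation per unit effective severity.
    noise_rel
        Relative standard deviation of the i.i.d. replicate noise.
    shot_noise
        If True, noise variance scales with the signal (sqrt law) instead
        of being purely multiplicative.
    n_replicates
        Intralipid replicate acquisitions per calibration.
    back_reflection
        Internal specular return as an equivalent reflectance, added to
        every through-probe acquisition and isolated by the water
        measurement.
    skin_* ranges
        Uniform sampling ranges for skin ground-truth parameters; the
        low default BVF range keeps spectra scattering dominated.
    """

    seed: int = 0
    grid_nm: tuple[float, float, float] = (450.0, 900.0, 2.0)
    lamp_peak_nm: float = 600.0
    lamp_width_nm: float = 120.0
    lamp_counts: float = 40000.0
    probe_factor: float = 1.0
    tree_factor: float = 1.0
    contamination: float = 0.0
    contamination_noise_gain: float = 1.5
    noise_rel: float = 0.02
    noiseless: bool = False  # skip noise application entirely (oracle runs)
    shot_noise: bool = False
    n_replicates: int = 5
    back_reflection: float = 5e-4
    water_noise_rel: float = 0.005
    channel_sensitivities: Mapping[str, float] = field(
        default_factory=lambda: {"small": 1.0, "large": 0.85}
    )
    intralipid_sc: ScatteringParams = INTRALIPID_SCATTERING
    intralipid_ab: AbsorptionParams = INTRALIPID_ABSORPTION
    skin_a800_range: tuple[float, float] = (1.2, 2.4)
    skin_b_range: tuple[float, float] = (0.9, 1.6)
    skin_bvf_range: tuple[float, float] = (0.005, 0.05)
    skin_sto2_range: tuple[float, float] = (0.4, 0.9)
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.noise_rel <= 0.5:
            raise ValueError("noise_rel must lie in (0, 0.5]")
        if self.contamination < 0:
            raise ValueError("contamination must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        object.__setattr__(self, "meta", dict(self.meta))
        object.__setattr__(
            self, "channel_sensitivities", dict(self.channel_sensitivities)
        )

    def grid(self) -> np.ndarray:
        start, stop, step = self.grid_nm
        n = int(np.floor((stop - start) / step)) + 1
        return start + step * np.arange(n)

    def lamp(self, grid: np.ndarray) -> np.ndarray:
        bump = np.exp(-0.5 * ((grid - self.lamp_peak_nm) / self.lamp_width_nm) ** 2)
        return self.lamp_counts * (bump + 0.15) / 1.15

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def severity(contamination: float, age_weeks: float) -> float:
    """Effective degradation severity of a phantom of the given shelf age."""
    return float(contamination * np.clip(age_weeks / 20.0, 0.0, 1.0))


def _noisy(
    clean: np.ndarray,
    rel: float,
    rng: np.random.Generator,
    shot: bool,
    noiseless: bool = False,
    full_scale: float = 1.0,
) -> np.ndarray:
    if noiseless:
        return clean.copy()
    if shot:
        # signal-proportional variance anchored at the detector full scale:
        # `rel` is the relative sigma of a signal filling the full scale, so
        # transmission losses lower the SNR like real photon statistics
        scale = rel * np.sqrt(np.clip(clean, 0, None) * full_scale)
        return clean + rng.normal(0.0, 1.0, clean.shape) * scale
    return clean * (1.0 + rng.normal(0.0, rel, clean.shape))


def make_calibration_set(
    cfg: ScenarioConfig,
    phantom_age_weeks: float = 0.0,
    geometry: FiberGeometry = FiberGeometry(),
    k: SFRModelConstants = SFRModelConstants(),
    lib: ChromophoreLibrary | None = None,
    meta: Mapping[str, object] | None = None,
) -> CalibrationSet:
    """Simulate one complete calibration: intralipid replicates, water and
    sphere acquisitions, plus the model-based reference reflectance.

    The reference ``r_cal_sim`` always assumes the *nominal* phantom; a
    contaminated phantom's actual scattering amplitude is reduced by the
    effective severity, so reference and reality drift apart exactly the
    way a degraded standard corrupts a real calibration.
    """
    if lib is None:
        lib = default_library()
    grid = cfg.grid()
    lamp = cfg.lamp(grid)
    sev = severity(cfg.contamination, phantom_age_weeks)
    noise = cfg.noise_rel * (1.0 + cfg.contamination_noise_gain * sev)
    gain = cfg.probe_factor * cfg.tree_factor
    rng = cfg.rng(stream=1)
    set_meta = {**cfg.meta, **(meta or {}), "phantom_age_weeks": phantom_age_weeks}

    actual_sc = replace(cfg.intralipid_sc, a_800=cfg.intralipid_sc.a_800 * (1.0 - sev))
    intralipid: dict[str, list[Spectrum]] = {}
    water: dict[str, Spectrum] = {}
    r_cal_sim: dict[str, Spectrum] = {}
    for label in ("small", "large"):
        d_f = geometry.diameter(label)
        r_actual = forward_reflectance(grid, actual_sc, cfg.intralipid_ab, d_f, k, lib).values
        clean = lamp * gain * (r_actual + cfg.back_reflection)
        intralipid[label] = [
            Spectrum(
                grid,
                _noisy(clean, noise, rng, cfg.shot_noise, cfg.noiseless, cfg.lamp_counts),
                units="counts",
                meta={**set_meta, "diameter_label": label, "source": "intralipid", "replicate": i},
            )
            for i in range(cfg.n_replicates)
        ]
        water_clean = lamp * gain * cfg.back_reflection
        water[label] = Spectrum(
            grid,
            _noisy(water_clean, cfg.water_noise_rel, rng, cfg.shot_noise, cfg.noiseless, cfg.lamp_counts),
            units="counts",
            meta={**set_meta, "diameter_label": label, "source": "water"},
        )
        r_cal_sim[label] = reference_reflectance(
            label, geometry, cfg.intralipid_sc, cfg.intralipid_ab, k, grid, lib
        )

    sphere = {
        channel: Spectrum(
            grid,
            lamp * sens,
            units="counts",
            meta={**set_meta, "channel": channel, "source": "sphere"},
        )
        for channel, sens in cfg.channel_sensitivities.items()
    }
    return CalibrationSet(
        intralipid=intralipid, water=water, r_cal_sim=r_cal_sim, sphere=sphere, meta=set_meta
    )


def make_skin_measurement(
    cfg: ScenarioConfig,
    sc_true: ScatteringParams,
    ab_true: AbsorptionParams,
    geometry: FiberGeometry = FiberGeometry(),
    k: SFRModelConstants = SFRModelConstants(),
    lib: ChromophoreLibrary | None = None,
    stream: int = 2,
) -> tuple[Spectrum, Spectrum]:
    """Simulate one two-diameter skin acquisition in raw counts.

    The ground-truth parameters travel in each spectrum's metadata so
    recovery experiments can close the loop without side channels.
    """
    if lib is None:
        lib = default_library()
    grid = cfg.grid()
    lamp = cfg.lamp(grid)
    gain = cfg.probe_factor * cfg.tree_factor
    rng = cfg.rng(stream=stream)
    out = []
    truth = {
        "true_a_800": sc_true.a_800,
        "true_b": sc_true.b,
        "true_bvf": ab_true.bvf,
        "true_sto2": ab_true.sto2,
    }
    for label in ("small", "large"):
        d_f = geometry.diameter(label)
        r_true = forward_reflectance(grid, sc_true, ab_true, d_f, k, lib).values
        clean = lamp * gain * (r_true + cfg.back_reflection)
        out.append(
            Spectrum(
                grid,
                _noisy(clean, cfg.noise_rel, rng, cfg.shot_noise, cfg.noiseless, cfg.lamp_counts),
                units="counts",
                meta={**cfg.meta, **truth, "diameter_label": label, "source": "skin"},
            )
        )
    return out[0], out[1]


def sample_skin_params(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[ScatteringParams, AbsorptionParams]:
    """Draw skin ground truth uniformly from the scenario's ranges."""
    if rng is None:
        rng = cfg.rng(stream=3)
    sc = ScatteringParams(
        a_800=float(rng.uniform(*cfg.skin_a800_range)),
        b=float(rng.uniform(*cfg.skin_b_range)),
    )
    ab = AbsorptionParams(
        bvf=float(rng.uniform(*cfg.skin_bvf_range)),
        sto2=float(rng.uniform(*cfg.skin_sto2_range)),
    )
    return sc, ab
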