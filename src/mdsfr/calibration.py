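"""Calibration of raw detector spectra into absolute single-fiber reflectance.

The instrument chain (lamp shape, fiber-tree transmission, probe coupling,
spectrometer sensitivity) multiplies every raw spectrum by an unknown smooth
curve.  The two-phantom transform cancels it: with an intralipid scattering
standard of known simulated reflectance ``R_cal_sim`` and a dark water
measurement capturing internal back-reflections,

    R_SF(lambda) = R_cal_sim * (I_meas - I_water) / (I_cal - I_water).

This module also provides the integrating-sphere channel correction (which
equalises spectrometer channels against a reference channel before merging)
and the calibration-quality statistic: the mean, over a 50 nm band centred
on 700 nm, of the per-wavelength replicate mean over replicate standard
deviation of the intralipid signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .model import (
    AbsorptionParams,
    FiberGeometry,
    ScatteringParams,
    SFRModelConstants,
    forward_reflectance,
)
from .spectrum import Spectrum, common_grid

__all__ = [
    "CalibrationSet",
    "QualityReport",
    "CalibrationError",
    "IncompatibleGridsError",
    "UnusableCalibrationError",
    "InsufficientReplicatesError",
    "DegenerateReplicatesError",
    "sphere_correction",
    "apply_calibration",
    "reference_reflectance",
    "snr_quality",
    "DEFAULT_SNR_BAND_NM",
]

DEFAULT_SNR_BAND_NM = (675.0, 725.0)

#: Wavelengths are masked where the calibration denominator falls below this
#: fraction of its in-band maximum, to avoid silent division blow-ups at
#: spectrum edges.
DENOMINATOR_FLOOR_FRACTION = 1e-6


class CalibrationError(ValueError):
    """Base class for calibration failures."""


class IncompatibleGridsError(CalibrationError):
    """Spectra share no overlapping wavelength range."""


class UnusableCalibrationError(CalibrationError):
    """The calibration denominator is below the floor everywhere."""


class InsufficientReplicatesError(CalibrationError):
    """Fewer replicate acquisitions than the SNR statistic requires."""


class DegenerateReplicatesError(CalibrationError):
    """Replicates are identical (zero standard deviation) in the SNR band."""


@dataclass
class CalibrationSet:
    """Everything the two-phantom transform needs, per effective diameter.

    Attributes
    ----------
    intralipid
        Per diameter label, a list of replicate intralipid acquisitions
        (counts); at least one replicate per diameter present.
    water
        Per diameter label, the dark water acquisition (counts).
    r_cal_sim
        Per diameter label, the reference absolute reflectance of the
        intralipid phantom.
    sphere
        Per spectrometer channel, the integrating-sphere acquisition.
    meta
        probe_id, fiber_tree_id, user_id, date, tripod flag ...
    """

    intralipid: Mapping[str, Sequence[Spectrum]]
    water: Mapping[str, Spectrum]
    r_cal_sim: Mapping[str, Spectrum]
    sphere: Mapping[str, Spectrum] = field(default_factory=dict)
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intralipid = {k: list(v) for k, v in self.intralipid.items()}
        for label, reps in self.intralipid.items():
            if not reps:
                raise ValueError(f"no intralipid replicates for diameter {label!r}")
            if label not in self.water or label not in self.r_cal_sim:
                raise ValueError(f"water/r_cal_sim missing for diameter {label!r}")
        self.meta = dict(self.meta)

    def diameters(self) -> list[str]:
        return list(self.intralipid)

    def mean_intralipid(self, label: str) -> Spectrum:
        """Replicate-averaged intralipid spectrum on the replicates' grid."""
        reps = self.intralipid[label]
        grid = common_grid(reps)
        stack = np.stack([r.resample(grid).values for r in reps])
        return Spectrum(grid, stack.mean(axis=0), units="counts", meta=self.meta)

    def is_defective(self, label: str, band_nm: tuple[float, float] | None = None) -> bool:
        """Flag sets whose intralipid signal does not exceed the water signal
        on average over the working band — a physically impossible situation
        that indicates a swapped or failed acquisition."""
        il = self.mean_intralipid(label)
        grid = common_grid([il, self.water[label]])
        il_v = il.resample(grid).values
        w_v = self.water[label].resample(grid).values
        if band_nm is not None:
            m = (grid >= band_nm[0]) & (grid <= band_nm[1])
            il_v, w_v = il_v[m], w_v[m]
        return float(il_v.mean()) < float(w_v.mean())


@dataclass(frozen=True)
class QualityReport:
    """The calibration-quality SNR with its grouping keys."""

    snr: float
    band_nm: tuple[float, float]
    n_replicates: int
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.snr > 0):
            raise ValueError("SNR must be strictly positive when defined")
        object.__setattr__(self, "meta", dict(self.meta))

    def row(self) -> dict[str, Any]:
        """Flat dict for tabular export."""
        out = dict(self.meta)
        out.update(
            snr=self.snr,
            band_lo_nm=self.band_nm[0],
            band_hi_nm=self.band_nm[1],
            n_replicates=self.n_replicates,
        )
        return out


def sphere_correction(
    channels: Mapping[str, Spectrum], reference: str | None = None
) -> dict[str, Spectrum]:
    """Per-channel multiplicative correction curves from sphere spectra.

    Under uniform integrating-sphere illumination every channel sees the
    same radiance, so channel ratios expose relative sensitivity.  The
    returned curve for channel ``c`` is ``reference / c`` on the common
    grid; multiplying a channel's spectra by its curve maps them onto the
    reference channel's sensitivity.  The reference channel's correction
    is identically 1.
    """
    if len(channels) < 2:
        raise ValueError("need at least two channels to correct")
    if reference is None:
        reference = next(iter(channels))
    if reference not in channels:
        raise KeyError(f"reference channel {reference!r} not among channels")
    try:
        grid = common_grid(channels.values())
    except ValueError as exc:
        raise IncompatibleGridsError(str(exc)) from exc
    ref_vals = channels[reference].resample(grid).values
    if np.any(ref_vals <= 0):
        raise CalibrationError("reference sphere spectrum must be strictly positive")
    out: dict[str, Spectrum] = {}
    for cid, spec in channels.items():
        vals = spec.resample(grid).values
        if np.any(vals <= 0):
            raise CalibrationError(f"sphere spectrum for channel {cid!r} must be positive")
        out[cid] = Spectrum(
            grid, ref_vals / vals, units="reflectance", meta={"channel": cid, "role": "sphere_correction"}
        )
    return out


def apply_calibration(
    i_meas: Spectrum,
    cal: CalibrationSet,
    diameter_label: str,
    floor_fraction: float = DENOMINATOR_FLOOR_FRACTION,
) -> Spectrum:
    """Calibrate a raw measurement into absolute reflectance (the two-phantom
    transform).

    Wavelengths where the intralipid-minus-water denominator falls below
    ``floor_fraction`` times its maximum are masked with NaN rather than
    silently clipped.  Raises :class:`UnusableCalibrationError` if the whole
    band is masked.
    """
    if diameter_label not in cal.intralipid:
        raise KeyError(f"calibration set holds no diameter {diameter_label!r}")
    i_cal = cal.mean_intralipid(diameter_label)
    i_water = cal.water[diameter_label]
    r_sim = cal.r_cal_sim[diameter_label]
    try:
        grid = common_grid([i_meas, i_cal, i_water, r_sim])
    except ValueError as exc:
        raise IncompatibleGridsError(str(exc)) from exc
    meas = i_meas.resample(grid).values
    calv = i_cal.resample(grid).values
    wat = i_water.resample(grid).values
    sim = r_sim.resample(grid).values

    denom = calv - wat
    floor = floor_fraction * np.max(denom)
    usable = denom > max(floor, 0.0)
    if not usable.any():
        raise UnusableCalibrationError(
            "calibration denominator below floor at every wavelength"
        )
    r_sf = np.full_like(denom, np.nan)
    r_sf[usable] = sim[usable] * (meas[usable] - wat[usable]) / denom[usable]
    meta = dict(i_meas.meta)
    meta.update(diameter_label=diameter_label, calibrated_with=cal.meta.get("probe_id"))
    return Spectrum(grid, r_sf, units="reflectance", meta=meta)


def reference_reflectance(
    diameter_label: str,
    geometry: FiberGeometry,
    intralipid_scattering: ScatteringParams,
    intralipid_absorption: AbsorptionParams = AbsorptionParams(bvf=0.0, sto2=0.0),
    k: SFRModelConstants = SFRModelConstants(),
    grid_nm=None,
    lib=None,
) -> Spectrum:
    """Reference reflectance R_cal_sim of the intralipid calibration phantom.

    Computed with the forward reflectance model on the phantom's nominal
    optical properties.  (The original processing chain used a Monte Carlo
    simulation of the phantom here; the forward model keeps the pipeline
    self-contained and is exact in the same parameter family it is later
    inverted in.)
    """
    if grid_nm is None:
        grid_nm = np.arange(450.0, 901.0, 2.0)
    d_f = geometry.diameter(diameter_label)
    spec = forward_reflectance(
        grid_nm,
        intralipid_scattering,
        intralipid_absorption,
        d_f,
        k,
        lib,
        meta={"role": "r_cal_sim", "diameter_label": diameter_label},
    )
    return spec


def snr_quality(
    replicates: Sequence[Spectrum],
    band_nm: tuple[float, float] = DEFAULT_SNR_BAND_NM,
    meta: Mapping[str, Any] | None = None,
) -> QualityReport:
    """Calibration-quality SNR from replicate intralipid acquisitions.

    Per wavelength in the closed band, SNR(lambda) = mean over replicates /
    sample standard deviation over replicates; the reported SNR is the mean
    of that ratio across the band.  Needs >= 3 replicates; identical
    replicates (zero standard deviation anywhere in the band) raise
    :class:`DegenerateReplicatesError`.
    """
    replicates = list(replicates)
    if len(replicates) < 3:
        raise InsufficientReplicatesError(
            f"SNR needs >= 3 replicates, got {len(replicates)}"
        )
    grid = common_grid(replicates)
    lo, hi = band_nm
    band_mask = (grid >= lo) & (grid <= hi)
    if band_mask.sum() < 2:
        raise ValueError(f"band [{lo}, {hi}] nm not covered by the replicates")
    stack = np.stack([r.resample(grid).values[band_mask] for r in replicates])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1)
    if np.any(std == 0):
        raise DegenerateReplicatesError(
            "zero replicate standard deviation in the SNR band (identical spectra?)"
        )
    snr = float(np.mean(mean / std))
    base = dict(meta or {})
    for key in ("probe_id", "fiber_tree_id", "user_id", "date", "tripod", "phantom_id"):
        if replicates[0].meta.get(key) is not None and key not in base:
            base[key] = replicates[0].meta[key]
    return QualityReport(snr=snr, band_nm=(lo, hi), n_replicates=len(replicates), meta=base)
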