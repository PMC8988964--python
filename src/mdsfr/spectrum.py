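"""Wavelength-resolved spectra: the carrier object passed between pipeline stages.

A :class:`Spectrum` pairs a strictly increasing wavelength grid (nm) with
aligned intensity values and a small metadata mapping.  The unit tag records
whether the values are raw detector ``counts`` or dimensionless absolute
``reflectance``; calibration is the only stage allowed to change the tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np

__all__ = ["Spectrum", "common_grid"]

_VALID_UNITS = ("counts", "reflectance")


@dataclass(frozen=True)
class Spectrum:
    """An intensity spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Wavelengths in nanometres, strictly increasing.
    values
        Intensity per wavelength; detector counts or dimensionless
        reflectance depending on ``units``.
    units
        Either ``"counts"`` or ``"reflectance"``.
    meta
        Free-form acquisition metadata (probe id, diameter label,
        timestamp, source tag ...). Never participates in arithmetic.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    units: str = "counts"
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {vals.size} values"
            )
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelengths must be finite")
        if self.units not in _VALID_UNITS:
            raise ValueError(f"units must be one of {_VALID_UNITS}, got {self.units!r}")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "meta", dict(self.meta))

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def resample(self, grid_nm: np.ndarray) -> "Spectrum":
        """Linearly interpolate onto ``grid_nm``.

        The target grid must lie inside the spectrum's coverage;
        extrapolation is refused because detector edges are unreliable.
        """
        grid = np.asarray(grid_nm, dtype=float)
        lo, hi = self.range_nm
        if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
            raise ValueError(
                f"target grid [{grid[0]}, {grid[-1]}] nm outside coverage [{lo}, {hi}] nm"
            )
        vals = np.interp(grid, self.wavelengths_nm, self.values)
        return Spectrum(grid, vals, units=self.units, meta=self.meta)

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Spectrum":
        return Spectrum(
            self.wavelengths_nm, values, units=units or self.units, meta=self.meta
        )

    def band(self, lo_nm: float, hi_nm: float) -> "Spectrum":
        """Restrict to wavelengths in the closed band [lo_nm, hi_nm]."""
        mask = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        if mask.sum() < 2:
            raise ValueError(f"band [{lo_nm}, {hi_nm}] nm holds <2 grid points")
        return Spectrum(
            self.wavelengths_nm[mask], self.values[mask], units=self.units, meta=self.meta
        )


def common_grid(spectra: Iterable[Spectrum], step_nm: float | None = None) -> np.ndarray:
    """Build a shared wavelength grid over the overlap of several spectra.

    The grid spans the intersection of coverages with ``step_nm`` spacing
    (default: the coarsest native spacing among the inputs).
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra given")
    lo = max(s.range_nm[0] for s in spectra)
    hi = min(s.range_nm[1] for s in spectra)
    if hi <= lo:
        raise ValueError("spectra share no overlapping wavelength range")
    if step_nm is None:
        step_nm = max(float(np.median(np.diff(s.wavelengths_nm))) for s in spectra)
    n = int(np.floor((hi - lo) / step_nm)) + 1
    return lo + step_nm * np.arange(n)
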