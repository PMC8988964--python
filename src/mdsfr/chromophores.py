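"""Chromophore absorption tables for spectral unmixing.

Tissue absorption in the visible/NIR is modelled as whole blood — a mixture
of oxy- and deoxyhemoglobin scaled by the blood volume fraction (BVF) and
the hemoglobin oxygen saturation (StO2).  The library stores tabulated
whole-blood absorption coefficients mu_a(lambda) in mm^-1 for fully
oxygenated and fully deoxygenated blood at a stated reference hemoglobin
concentration, and interpolates them onto arbitrary grids inside coverage.

The tables shipped with the package (``data/*_synthetic.tsv``) are
*synthetic*: smooth Gaussian-band curves that reproduce the qualitative
features of whole-blood absorption (Soret edge below 450 nm, the oxy
double peak near 542/577 nm, the deoxy band near 555 nm and its 760 nm
shoulder, an isosbestic crossing near 800 nm) at whole-blood magnitudes
for 150 g/L total hemoglobin.  They are not digitised literature data;
swap in measured tables via :meth:`ChromophoreLibrary.from_files` for
quantitative work on real tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["ChromophoreLibrary", "default_library"]


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Tabulated whole-blood absorption spectra, interpolable inside coverage.

    Attributes
    ----------
    wavelengths_nm
        Strictly increasing tabulation grid covering at least 400-900 nm.
    mu_a_hbo2, mu_a_hb
        Whole-blood absorption (mm^-1) for fully oxygenated and fully
        deoxygenated blood at ``hb_concentration_g_per_l``.
    mu_a_water
        Optional water absorption (mm^-1); ``None`` disables the water term.
    """

    wavelengths_nm: np.ndarray
    mu_a_hbo2: np.ndarray
    mu_a_hb: np.ndarray
    mu_a_water: np.ndarray | None = None
    hb_concentration_g_per_l: float = 150.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        oxy = np.asarray(self.mu_a_hbo2, dtype=float)
        deoxy = np.asarray(self.mu_a_hb, dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise ValueError("tabulation grid must be strictly increasing")
        if wl.size != oxy.size or wl.size != deoxy.size:
            raise ValueError("chromophore tables must share the tabulation grid")
        if np.any(oxy < 0) or np.any(deoxy < 0):
            raise ValueError("absorption coefficients must be nonnegative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "mu_a_hbo2", oxy)
        object.__setattr__(self, "mu_a_hb", deoxy)

    @property
    def coverage_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def _check_coverage(self, lambda_nm: np.ndarray) -> None:
        lo, hi = self.coverage_nm
        lam = np.asarray(lambda_nm, dtype=float)
        if np.any(lam < lo - 1e-9) or np.any(lam > hi + 1e-9):
            raise ValueError(
                f"wavelength outside library coverage [{lo}, {hi}] nm"
            )

    def hbo2(self, lambda_nm):
        """mu_a of fully oxygenated whole blood (mm^-1) at lambda_nm."""
        self._check_coverage(lambda_nm)
        return np.interp(lambda_nm, self.wavelengths_nm, self.mu_a_hbo2)

    def hb(self, lambda_nm):
        """mu_a of fully deoxygenated whole blood (mm^-1) at lambda_nm."""
        self._check_coverage(lambda_nm)
        return np.interp(lambda_nm, self.wavelengths_nm, self.mu_a_hb)

    def water(self, lambda_nm):
        if self.mu_a_water is None:
            return np.zeros_like(np.asarray(lambda_nm, dtype=float))
        self._check_coverage(lambda_nm)
        return np.interp(lambda_nm, self.wavelengths_nm, self.mu_a_water)

    @classmethod
    def from_files(
        cls,
        hbo2_path: str | Path,
        hb_path: str | Path,
        water_path: str | Path | None = None,
        hb_concentration_g_per_l: float = 150.0,
    ) -> "ChromophoreLibrary":
        """Load two-column tables ``wavelength_nm <tab-or-comma> mu_a_mm^-1``.

        Lines starting with ``#`` are comments.  All files are resampled
        onto the oxyhemoglobin file's grid.
        """
        wl, oxy = _read_table(hbo2_path)
        wl_d, deoxy = _read_table(hb_path)
        deoxy = np.interp(wl, wl_d, deoxy)
        water = None
        if water_path is not None:
            wl_w, w = _read_table(water_path)
            water = np.interp(wl, wl_w, w)
        return cls(wl, oxy, deoxy, water, hb_concentration_g_per_l)


def _read_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, comments="#", delimiter=None)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, mu_a_mm^-1)")
    order = np.argsort(data[:, 0])
    return data[order, 0], data[order, 1]


def default_library() -> ChromophoreLibrary:
    """The packaged synthetic whole-blood library (400-900 nm, 150 g/L Hb)."""
    pkg = resources.files("mdsfr") / "data"
    return ChromophoreLibrary.from_files(
        str(pkg / "hbo2_whole_blood_synthetic.tsv"),
        str(pkg / "hb_whole_blood_synthetic.tsv"),
    )


def synthetic_whole_blood_tables(
    grid_nm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic generator behind the packaged synthetic tables.

    Returns ``(wavelengths_nm, mu_a_hbo2, mu_a_hb)`` in mm^-1 for whole
    blood at 150 g/L hemoglobin.  Gaussian bands are placed at the known
    feature positions with whole-blood peak magnitudes; the curves are
    smooth, strictly positive, and cross near 800 nm like the real
    isosbestic point.
    """
    if grid_nm is None:
        grid_nm = np.arange(400.0, 901.0, 2.0)
    lam = np.asarray(grid_nm, dtype=float)

    def band(center, amplitude, sigma):
        return amplitude * np.exp(-0.5 * ((lam - center) / sigma) ** 2)

    # Oxyhemoglobin: Soret edge, Q-bands at 542/577 nm, weak NIR floor.
    oxy = (
        band(415.0, 260.0, 22.0)
        + band(542.0, 27.0, 13.0)
        + band(577.0, 31.0, 10.0)
        + 0.35 * np.exp((lam - 900.0) / 280.0)  # gentle NIR rise, ~0.45 at 900
        + 0.08
    )
    # Deoxyhemoglobin: Soret edge, single 555 nm band, 760 nm shoulder,
    # falling NIR tail so the curves cross near 800 nm.
    deoxy = (
        band(430.0, 300.0, 24.0)
        + band(555.0, 29.0, 20.0)
        + band(760.0, 0.45, 28.0)
        + 1.1 * np.exp(-np.clip(lam - 600.0, 0.0, None) / 110.0)
        + 0.25
    )
    return lam, oxy, deoxy
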