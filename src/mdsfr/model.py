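"""Forward single-fiber reflectance (SFR) model.

A single fiber of effective diameter ``d_f`` both delivers and collects
light, so its reflectance depends on the dimensionless products
``mu_s' * d_f`` (reduced scattering) and ``mu_a * d_f`` (absorption).
The model composes three pieces:

* a power-law reduced scattering spectrum anchored at 800 nm,
  ``mu_s'(lambda) = a_800 * (lambda / 800)**(-b)``;
* the semi-empirical reflectance in the absence of absorption,
  ``R_SF0(x) = eta_lim * (1 + p6 * exp(-p4 * x)) * x**p5 / (p4 + x**p5)``
  with ``x = mu_s' * d_f``, which saturates at the diffusion-limit
  collection efficiency ``eta_lim`` (2.7% for NA 0.22 in n = 1.38);
* a modified Beer-Lambert attenuation ``exp(-mu_a * L_SFR)`` with the
  effective photon path length
  ``L_SFR / d_f = C_PF * p1 * x**(-p2) / (p3 + (mu_a * d_f)**p3)``,
  which shortens as either scattering or absorption grows.

The coefficient sets [C_PF, p1, p2, p3] = [0.944, 1.54, 0.18, 0.64] and
[p4, p5, p6] = [6.82, 0.969, 1.55] are Monte-Carlo-derived constants of
the published model and are treated as fixed; the phase-function
parameter gamma is carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .chromophores import ChromophoreLibrary
from .spectrum import Spectrum

__all__ = [
    "SFRModelConstants",
    "ScatteringParams",
    "AbsorptionParams",
    "FiberGeometry",
    "reduced_scattering",
    "absorption_coefficient",
    "path_length",
    "rsf0",
    "forward_reflectance",
]


@dataclass(frozen=True)
class SFRModelConstants:
    """Fixed coefficients of the SFR reflectance and path-length models.

    ``path_exp_scat`` and ``path_exp_abs`` expose the sign/magnitude of the
    path-length exponents for sensitivity studies; the defaults give the
    dimensionally consistent published form in which L_SFR decreases with
    both ``mu_s'`` and ``mu_a``.
    """

    c_pf: float = 0.944
    p1: float = 1.54
    p2: float = 0.18
    p3: float = 0.64
    p4: float = 6.82
    p5: float = 0.969
    p6: float = 1.55
    eta_lim: float = 0.027
    path_exp_scat: float = -1.0  # multiplies p2 in (mu_s'*d_f)**(path_exp_scat*p2)
    path_exp_abs: float = 1.0    # multiplies p3 in (mu_a*d_f)**(path_exp_abs*p3)

    def __post_init__(self) -> None:
        for name in ("c_pf", "p1", "p2", "p3", "p4", "p5", "p6", "eta_lim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"model constant {name} must be strictly positive")

    @property
    def rsf0_max(self) -> float:
        """Upper bound of R_SF0: eta_lim * (1 + p6)."""
        return self.eta_lim * (1.0 + self.p6)


@dataclass(frozen=True)
class ScatteringParams:
    """Power-law reduced scattering: amplitude at the reference wavelength
    (mm^-1) and dimensionless decay exponent b.  gamma, the phase-function
    parameter, is metadata only — it is never fitted here."""

    a_800: float
    b: float
    gamma: float | None = None
    reference_nm: float = 800.0

    def __post_init__(self) -> None:
        if not (self.a_800 > 0 and np.isfinite(self.a_800)):
            raise ValueError("a_800 must be strictly positive and finite")
        if not np.isfinite(self.b):
            raise ValueError("power-law exponent b must be finite")
        if self.reference_nm <= 0:
            raise ValueError("reference wavelength must be positive")


@dataclass(frozen=True)
class AbsorptionParams:
    """Blood volume fraction and hemoglobin oxygen saturation, both in [0, 1]."""

    bvf: float
    sto2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.bvf <= 1.0:
            raise ValueError(f"bvf must lie in [0, 1], got {self.bvf}")
        if not 0.0 <= self.sto2 <= 1.0:
            raise ValueError(f"sto2 must lie in [0, 1], got {self.sto2}")


@dataclass(frozen=True)
class FiberGeometry:
    """Effective fiber diameters of the two-diameter probe, in mm."""

    d_small: float = 0.470
    d_large: float = 1.100

    def __post_init__(self) -> None:
        if not 0 < self.d_small < self.d_large:
            raise ValueError("need 0 < d_small < d_large")

    def diameter(self, label: str) -> float:
        if label == "small":
            return self.d_small
        if label == "large":
            return self.d_large
        raise KeyError(f"unknown diameter label {label!r}; use 'small' or 'large'")


def reduced_scattering(lambda_nm, sc: ScatteringParams):
    """mu_s'(lambda) = a_800 * (lambda / reference)**(-b), in mm^-1."""
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be strictly positive")
    out = sc.a_800 * (lam / sc.reference_nm) ** (-sc.b)
    return out if out.ndim else float(out)


def absorption_coefficient(lambda_nm, ab: AbsorptionParams, lib: ChromophoreLibrary):
    """Whole-blood mixture absorption, mm^-1.

    mu_a(lambda) = bvf * [sto2 * mu_a_HbO2(lambda) + (1 - sto2) * mu_a_Hb(lambda)]
    """
    lam = np.asarray(lambda_nm, dtype=float)
    out = ab.bvf * (ab.sto2 * lib.hbo2(lam) + (1.0 - ab.sto2) * lib.hb(lam))
    return out if out.ndim else float(out)


def path_length(mu_a, mu_s_prime, d_f: float, k: SFRModelConstants = SFRModelConstants()):
    """Effective SFR photon path length L_SFR in mm.

    L_SFR = d_f * C_PF * p1 * (mu_s'*d_f)**(-p2) / (p3 + (mu_a*d_f)**p3).
    Strictly positive; strictly decreasing in both mu_a and mu_s'.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s = np.asarray(mu_s_prime, dtype=float)
    if d_f <= 0:
        raise ValueError("fiber diameter must be strictly positive")
    if np.any(mu_s <= 0):
        raise ValueError("mu_s_prime must be strictly positive")
    if np.any(mu_a < 0):
        raise ValueError("mu_a must be nonnegative")
    x = mu_s * d_f
    y = mu_a * d_f
    out = (
        d_f
        * k.c_pf
        * k.p1
        * x ** (k.path_exp_scat * k.p2)
        / (k.p3 + y ** (k.path_exp_abs * k.p3))
    )
    return out if out.ndim else float(out)


def rsf0(mu_s_prime, d_f: float = 1.0, k: SFRModelConstants = SFRModelConstants()):
    """Single-fiber reflectance in the absence of absorption (dimensionless).

    R_SF0 = eta_lim * (1 + p6 * exp(-p4 * x)) * x**p5 / (p4 + x**p5),
    x = mu_s' * d_f.  Zero at x = 0; saturates at eta_lim as x -> infinity.
    """
    mu_s = np.asarray(mu_s_prime, dtype=float)
    if d_f <= 0:
        raise ValueError("fiber diameter must be strictly positive")
    if np.any(mu_s < 0):
        raise ValueError("mu_s_prime must be nonnegative")
    x = mu_s * d_f
    xp = x**k.p5
    out = k.eta_lim * (1.0 + k.p6 * np.exp(-k.p4 * x)) * xp / (k.p4 + xp)
    return out if out.ndim else float(out)


def forward_reflectance(
    grid_nm,
    sc: ScatteringParams,
    ab: AbsorptionParams,
    d_f: float,
    k: SFRModelConstants = SFRModelConstants(),
    lib: ChromophoreLibrary | None = None,
    meta: Mapping[str, Any] | None = None,
) -> Spectrum:
    """Model reflectance spectrum R_SF(lambda) for one fiber diameter.

    R_SF = R_SF0(mu_s'(lambda), d_f) * exp(-mu_a(lambda) * L_SFR).
    With bvf = 0 this reduces to R_SF0 pointwise.
    """
    if lib is None:
        from .chromophores import default_library

        lib = default_library()
    grid = np.asarray(grid_nm, dtype=float)
    mu_s = reduced_scattering(grid, sc)
    mu_a = absorption_coefficient(grid, ab, lib)
    r0 = rsf0(mu_s, d_f, k)
    attenuation = np.exp(-mu_a * path_length(mu_a, mu_s, d_f, k))
    return Spectrum(grid, r0 * attenuation, units="reflectance", meta=dict(meta or {}))
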