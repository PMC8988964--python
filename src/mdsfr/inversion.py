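"""Inversion of calibrated reflectance spectra for tissue optical properties.

A single-diameter fit is underdetermined in the scattering amplitude /
phase-function direction; acquiring the same site at two effective fiber
diameters (``d_small``, ``d_large``) constrains the reduced scattering
power law.  The joint fit shares one parameter vector
``(a_800, b, bvf, sto2)`` across both diameters, each evaluated with its
own ``d_f`` in the forward model, and minimises the stacked pointwise
residuals by bounded least squares.

Downstream utilities implement the three exclusion criteria applied to
skin spectra (absolute residual > 25, blood volume fraction > 40%, and an
StO2 confidence interval more than three standard deviations from the
batch mean) and the inverse-variance aggregation of repeated measurements
by their individual confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .chromophores import ChromophoreLibrary, default_library
from .model import (
    AbsorptionParams,
    FiberGeometry,
    ScatteringParams,
    SFRModelConstants,
    absorption_coefficient,
    forward_reflectance,
    path_length,
    reduced_scattering,
)
from .spectrum import Spectrum, common_grid

__all__ = [
    "FitBounds",
    "FitInit",
    "MDSFRResult",
    "ExclusionFlags",
    "WeightedSummary",
    "EmptySummaryError",
    "fit_sfr_spectrum",
    "mdsfr_fit",
    "apply_exclusions",
    "weighted_mean",
    "RESIDUAL_THRESHOLD",
    "BVF_THRESHOLD",
]

RESIDUAL_THRESHOLD = 25.0
BVF_THRESHOLD = 0.40

_PARAM_NAMES = ("a_800", "b", "bvf", "sto2")


class EmptySummaryError(ValueError):
    """Every entry of a weighted summary was dropped."""


@dataclass(frozen=True)
class FitBounds:
    """Box constraints of the least-squares fit."""

    a_800: tuple[float, float] = (1e-3, 20.0)
    b: tuple[float, float] = (0.0, 4.0)
    bvf: tuple[float, float] = (0.0, 1.0)
    sto2: tuple[float, float] = (0.0, 1.0)

    def lower(self) -> np.ndarray:
        return np.array([self.a_800[0], self.b[0], self.bvf[0], self.sto2[0]])

    def upper(self) -> np.ndarray:
        return np.array([self.a_800[1], self.b[1], self.bvf[1], self.sto2[1]])


@dataclass(frozen=True)
class FitInit:
    """Deterministic starting point (skin-like defaults)."""

    a_800: float = 2.0
    b: float = 1.2
    bvf: float = 0.02
    sto2: float = 0.7

    def vector(self) -> np.ndarray:
        return np.array([self.a_800, self.b, self.bvf, self.sto2])


@dataclass(frozen=True)
class ExclusionFlags:
    residual_exceeded: bool = False
    bvf_exceeded: bool = False
    sto2_ci_outlier: bool = False

    @property
    def excluded(self) -> bool:
        return self.residual_exceeded or self.bvf_exceeded or self.sto2_ci_outlier


@dataclass(frozen=True)
class MDSFRResult:
    """Fitted parameters, uncertainties and diagnostics of one (joint) fit.

    ``residual`` is the absolute residual statistic used by the exclusion
    filter: sum over the working grid of |measured - fitted| expressed in
    percent reflectance (x100).  ``ci`` maps parameter name to the 95%
    confidence half-width from the local linearisation of the fit.
    """

    sc: ScatteringParams
    ab: AbsorptionParams
    ci: Mapping[str, float]
    residual: float
    per_diameter_rsf0: Mapping[str, Spectrum]
    flags: ExclusionFlags = ExclusionFlags()
    converged: bool = True
    n_points: int = 0
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be nonnegative")
        object.__setattr__(self, "ci", dict(self.ci))
        object.__setattr__(self, "meta", dict(self.meta))

    def params(self) -> dict[str, float]:
        return {
            "a_800": self.sc.a_800,
            "b": self.sc.b,
            "bvf": self.ab.bvf,
            "sto2": self.ab.sto2,
        }

    def row(self) -> dict[str, object]:
        out: dict[str, object] = dict(self.meta)
        out.update(self.params())
        out.update({f"ci_{k}": v for k, v in self.ci.items()})
        out.update(
            residual=self.residual,
            converged=self.converged,
            excluded=self.flags.excluded,
            residual_exceeded=self.flags.residual_exceeded,
            bvf_exceeded=self.flags.bvf_exceeded,
            sto2_ci_outlier=self.flags.sto2_ci_outlier,
        )
        return out


@dataclass(frozen=True)
class WeightedSummary:
    """Inverse-variance weighted mean of one parameter across repeats."""

    parameter: str
    weighted_mean: float
    n_used: int
    weight_rule: str = "inverse_variance_95ci"


def _model_stack(
    theta: np.ndarray,
    grids: Sequence[np.ndarray],
    diameters: Sequence[float],
    k: SFRModelConstants,
    lib: ChromophoreLibrary,
) -> np.ndarray:
    a800, b, bvf, sto2 = theta
    sc = ScatteringParams(a_800=a800, b=b)
    ab = AbsorptionParams(bvf=bvf, sto2=sto2)
    parts = [
        forward_reflectance(g, sc, ab, d, k, lib).values
        for g, d in zip(grids, diameters)
    ]
    return np.concatenate(parts)


def _run_fit(
    spectra: Sequence[Spectrum],
    diameters: Sequence[float],
    k: SFRModelConstants,
    lib: ChromophoreLibrary,
    bounds: FitBounds,
    init: FitInit,
    n_starts: int,
    seed: int,
    meta: Mapping[str, object],
) -> MDSFRResult:
    grids, targets = [], []
    for spec in spectra:
        mask = np.isfinite(spec.values)
        if mask.sum() < 8:
            raise ValueError("too few usable wavelengths to fit")
        grids.append(spec.wavelengths_nm[mask])
        targets.append(spec.values[mask])
    target = np.concatenate(targets)
    n_points = target.size

    def residual_vec(theta: np.ndarray) -> np.ndarray:
        return _model_stack(theta, grids, diameters, k, lib) - target

    lower, upper = bounds.lower(), bounds.upper()
    starts = [np.clip(init.vector(), lower, upper)]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            jitter = starts[0] * rng.uniform(0.5, 1.5, size=4)
            starts.append(np.clip(jitter, lower, upper))

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residual_vec,
                x0,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        # ties broken by lowest cost, then lowest power-law exponent b
        key = (sol.cost, sol.x[1])
        if best is None or key < best[0]:
            best = (key, sol)

    if best is None:
        # non-convergence: flagged result, residual = +inf, never silent
        sc = ScatteringParams(a_800=init.a_800, b=init.b)
        ab = AbsorptionParams(bvf=init.bvf, sto2=init.sto2)
        return MDSFRResult(
            sc=sc,
            ab=ab,
            ci={p: np.inf for p in _PARAM_NAMES},
            residual=np.inf,
            per_diameter_rsf0={},
            converged=False,
            n_points=n_points,
            meta=meta,
        )

    sol = best[1]
    a800, b, bvf, sto2 = sol.x
    sc = ScatteringParams(a_800=float(a800), b=float(b))
    ab = AbsorptionParams(bvf=float(np.clip(bvf, 0, 1)), sto2=float(np.clip(sto2, 0, 1)))

    residual_stat = float(np.sum(np.abs(sol.fun)) * 100.0)
    ci = _confidence_half_widths(sol, n_points)

    per_diameter: dict[str, Spectrum] = {}
    labels = [s.meta.get("diameter_label", f"d{i}") for i, s in enumerate(spectra)]
    for label, spec, d_f in zip(labels, spectra, diameters):
        mask = np.isfinite(spec.values)
        grid = spec.wavelengths_nm[mask]
        mu_s = reduced_scattering(grid, sc)
        mu_a = absorption_coefficient(grid, ab, lib)
        beer = np.exp(-mu_a * path_length(mu_a, mu_s, d_f, k))
        per_diameter[str(label)] = Spectrum(
            grid, spec.values[mask] / beer, units="reflectance",
            meta={**spec.meta, "role": "rsf0_extracted"},
        )

    return MDSFRResult(
        sc=sc,
        ab=ab,
        ci=ci,
        residual=residual_stat,
        per_diameter_rsf0=per_diameter,
        converged=True,
        n_points=n_points,
        meta=meta,
    )


def _confidence_half_widths(sol, n_points: int) -> dict[str, float]:
    """95% half-widths from the local linearisation of the least-squares fit."""
    n_params = sol.x.size
    dof = max(n_points - n_params, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.pinv(jtj)
        var = np.clip(np.diag(cov), 0.0, None)
        hw = 1.96 * np.sqrt(var)
    except np.linalg.LinAlgError:
        hw = np.full(n_params, np.inf)
    return dict(zip(_PARAM_NAMES, (float(h) for h in hw)))


def fit_sfr_spectrum(
    r_sf: Spectrum,
    d_f: float,
    k: SFRModelConstants = SFRModelConstants(),
    lib: ChromophoreLibrary | None = None,
    bounds: FitBounds = FitBounds(),
    init: FitInit = FitInit(),
    n_starts: int = 1,
    seed: int = 0,
) -> MDSFRResult:
    """Fit the forward model to one calibrated single-diameter spectrum.

    Deterministic given data, init and seed.  ``n_starts > 1`` adds seeded
    multiplicative perturbations of the initial point.
    """
    if lib is None:
        lib = default_library()
    return _run_fit([r_sf], [d_f], k, lib, bounds, init, n_starts, seed, dict(r_sf.meta))


def mdsfr_fit(
    r_small: Spectrum,
    r_large: Spectrum,
    geom: FiberGeometry = FiberGeometry(),
    k: SFRModelConstants = SFRModelConstants(),
    lib: ChromophoreLibrary | None = None,
    bounds: FitBounds = FitBounds(),
    init: FitInit = FitInit(),
    n_starts: int = 1,
    seed: int = 0,
) -> MDSFRResult:
    """Joint two-diameter fit sharing one (a_800, b, bvf, sto2) vector.

    Residuals of the two diameters are stacked; each diameter uses its own
    effective diameter in the forward model.
    """
    if lib is None:
        lib = default_library()
    r_small = replace_label(r_small, "small")
    r_large = replace_label(r_large, "large")
    meta = {**r_small.meta}
    meta.pop("diameter_label", None)
    return _run_fit(
        [r_small, r_large],
        [geom.d_small, geom.d_large],
        k,
        lib,
        bounds,
        init,
        n_starts,
        seed,
        meta,
    )


def replace_label(spec: Spectrum, label: str) -> Spectrum:
    if spec.meta.get("diameter_label") == label:
        return spec
    meta = dict(spec.meta)
    meta["diameter_label"] = label
    return Spectrum(spec.wavelengths_nm, spec.values, units=spec.units, meta=meta)


def apply_exclusions(
    results: Sequence[MDSFRResult],
    residual_threshold: float = RESIDUAL_THRESHOLD,
    bvf_threshold: float = BVF_THRESHOLD,
    sto2_rule: str = "ci_halfwidth",
) -> list[MDSFRResult]:
    """Set the three exclusion flags on a batch of fit results.

    1. absolute residual > ``residual_threshold`` (default 25);
    2. blood volume fraction > ``bvf_threshold`` (default 0.40);
    3. StO2 confidence-interval outlier relative to the batch:
       with ``sto2_rule="ci_halfwidth"`` (default) a record is flagged when
       its StO2 95%-CI half-width exceeds the batch mean half-width plus
       three batch standard deviations; ``sto2_rule="value"`` instead flags
       StO2 values more than three standard deviations from the batch mean.

    Pure flagging: input order preserved, idempotent, criteria 1-2 are
    per-record, criterion 3 depends only on the batch's set of values.
    Criterion 3 needs >= 2 records with finite inputs; otherwise it is left
    unset.
    """
    if sto2_rule not in ("ci_halfwidth", "value"):
        raise ValueError("sto2_rule must be 'ci_halfwidth' or 'value'")
    if sto2_rule == "ci_halfwidth":
        batch = np.array([r.ci.get("sto2", np.inf) for r in results])
    else:
        batch = np.array([r.ab.sto2 for r in results])
    finite = np.isfinite(batch)
    cutoff_hi = cutoff_lo = None
    if finite.sum() >= 2:
        mean = batch[finite].mean()
        sd = batch[finite].std(ddof=1)
        cutoff_hi = mean + 3.0 * sd
        cutoff_lo = mean - 3.0 * sd

    out: list[MDSFRResult] = []
    for r, value, is_finite in zip(results, batch, finite):
        sto2_flag = False
        if cutoff_hi is not None:
            if not is_finite:
                sto2_flag = True
            elif sto2_rule == "ci_halfwidth":
                sto2_flag = value > cutoff_hi
            else:
                sto2_flag = value > cutoff_hi or value < cutoff_lo
        flags = ExclusionFlags(
            residual_exceeded=bool(r.residual > residual_threshold),
            bvf_exceeded=bool(r.ab.bvf > bvf_threshold),
            sto2_ci_outlier=bool(sto2_flag),
        )
        out.append(replace(r, flags=flags))
    return out


def weighted_mean(
    values: Sequence[float],
    ci_half_widths: Sequence[float],
    excluded: Sequence[bool] | None = None,
    parameter: str = "value",
) -> WeightedSummary:
    """Inverse-variance weighted mean using 95%-CI half-widths as weights.

    Each half-width is converted to a standard error sigma = hw / 1.96 and
    weighted w = 1/sigma^2.  Entries flagged excluded or with nonfinite
    half-widths are dropped (``n_used`` reflects that).  Zero half-widths
    carry infinite weight: if any are present the summary averages exactly
    those entries.
    """
    vals = np.asarray(values, dtype=float)
    hws = np.asarray(ci_half_widths, dtype=float)
    if vals.shape != hws.shape:
        raise ValueError("values and ci_half_widths must have equal length")
    if np.any(hws < 0):
        raise ValueError("confidence half-widths must be nonnegative")
    keep = np.isfinite(vals) & np.isfinite(hws)
    if excluded is not None:
        keep &= ~np.asarray(excluded, dtype=bool)
    if not keep.any():
        raise EmptySummaryError("all entries dropped; nothing to average")
    vals, hws = vals[keep], hws[keep]
    if np.any(hws == 0.0):
        exact = hws == 0.0
        mean = float(vals[exact].mean())
        n_used = int(exact.sum())
    else:
        sigma = hws / 1.96
        w = 1.0 / sigma**2
        mean = float(np.sum(w * vals) / np.sum(w))
        n_used = int(vals.size)
    return WeightedSummary(parameter=parameter, weighted_mean=mean, n_used=n_used)
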