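"""Plain-text readers and writers for spectra and calibration manifests.

Spectral files are delimited text with a header row
``wavelength_nm,intensity[,intensity...]``; extra intensity columns are
replicate acquisitions.  A calibration-set manifest is a YAML block naming
the sphere/intralipid/water files per diameter plus the metadata keys.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationSet, QualityReport
from .spectrum import Spectrum

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_calibration_manifest",
    "write_reports",
]


def read_spectra(
    path: str | Path, units: str = "counts", meta: Mapping[str, Any] | None = None
) -> list[Spectrum]:
    """Read one spectral file; one Spectrum per intensity column."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavelength column plus >=1 intensity column")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    out = []
    for i, col in enumerate(df.columns[1:]):
        m = dict(meta or {})
        m.setdefault("source_file", str(path))
        m.setdefault("column", str(col))
        m.setdefault("replicate", i)
        out.append(Spectrum(wl, df[col].to_numpy(dtype=float), units=units, meta=m))
    return out


def write_spectra(path: str | Path, spectra: Sequence[Spectrum]) -> None:
    """Write spectra sharing a grid as one delimited file."""
    spectra = list(spectra)
    wl = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths_nm, wl):
            raise ValueError("spectra must share the wavelength grid to co-write")
    data = {"wavelength_nm": wl}
    for i, s in enumerate(spectra):
        data[str(s.meta.get("column", f"intensity_{i}"))] = s.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_calibration_manifest(path: str | Path) -> CalibrationSet:
    """Build a CalibrationSet from a YAML manifest.

    Expected layout::

        meta: {probe_id: P1, fiber_tree_id: T1, user_id: U1,
               date: 2021-01-01, tripod: true}
        diameters:
          small:
            intralipid: intralipid_small.csv   # replicates as extra columns
            water: water_small.csv
            r_cal_sim: rcalsim_small.csv
          large: {...}
        sphere:
          ch_small: sphere_small.csv
          ch_large: sphere_large.csv

    Relative file paths resolve against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = path.parent
    meta = dict(doc.get("meta", {}))

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    intralipid: dict[str, list[Spectrum]] = {}
    water: dict[str, Spectrum] = {}
    r_cal_sim: dict[str, Spectrum] = {}
    for label, files in doc["diameters"].items():
        m = {**meta, "diameter_label": label}
        intralipid[label] = read_spectra(_resolve(files["intralipid"]), "counts", m)
        water[label] = read_spectra(_resolve(files["water"]), "counts", m)[0]
        r_cal_sim[label] = read_spectra(_resolve(files["r_cal_sim"]), "reflectance", m)[0]
    sphere = {
        cid: read_spectra(_resolve(f), "counts", {**meta, "channel": cid})[0]
        for cid, f in doc.get("sphere", {}).items()
    }
    return CalibrationSet(
        intralipid=intralipid, water=water, r_cal_sim=r_cal_sim, sphere=sphere, meta=meta
    )


def write_reports(path: str | Path, reports: Sequence[QualityReport]) -> pd.DataFrame:
    """Write QualityReports as one CSV row each; returns the frame."""
    df = pd.DataFrame([r.row() for r in reports])
    df.to_csv(path, index=False)
    return df
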