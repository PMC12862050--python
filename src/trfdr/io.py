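"""Serialization: HDF5 cohort container, JSON look-up table, CSV tables.

Cohort layout:

    /patients/<id>/<sample>/trf          float32 [39 x 11 x T]
    /patients/<id>/<sample>/trf_time     float64 [T]
    /patients/<id>/<sample>/dr           float64 [3 x n_lambda] (raw, background, standard)
    /patients/<id>/<sample>/dr_wavelengths
    /annotations                          one row per measured cell
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import Cohort, PhantomLUT
from .types import DRMeasurement, TRFMeasurement

__all__ = ["save_cohort", "load_annotations", "load_measurement",
           "save_lut", "load_lut", "save_features", "load_features"]

ANNOTATION_COLUMNS = ["patient_id", "sample", "row", "col",
                      "p_tumor", "p_fibro", "p_adipose", "label"]


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write annotations and all raw measurements (streamed, one cell at
    a time) into a single HDF5 container."""
    ann = cohort.annotations()
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = cohort.seed
        f.attrs["n_patients"] = cohort.config.n_patients
        g = f.create_group("annotations")
        for col in ANNOTATION_COLUMNS:
            data = ann[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        for roi, trf, dr in cohort.iter_measurements():
            grp = f.require_group(f"patients/{roi.patient_id}/{roi.sample_kind}")
            cell = grp.require_group(f"r{roi.row:02d}c{roi.col:02d}")
            cell.create_dataset("trf", data=trf.decays.astype(np.float32))
            cell.create_dataset("trf_time", data=trf.time_ns)
            cell.create_dataset("trf_wavelengths", data=trf.wavelengths)
            cell.create_dataset("dr", data=np.vstack([dr.raw, dr.background, dr.standard]))
            cell.create_dataset("dr_wavelengths", data=dr.wavelengths)


def load_annotations(path: str | Path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        g = f["annotations"]
        data = {}
        for col in ANNOTATION_COLUMNS:
            arr = g[col][...]
            if arr.dtype.kind == "S":
                arr = arr.astype(str)
            data[col] = arr
    return pd.DataFrame(data)


def load_measurement(path: str | Path, patient_id: str, sample: str,
                     row: int, col: int) -> tuple[TRFMeasurement, DRMeasurement]:
    with h5py.File(path, "r") as f:
        cell = f[f"patients/{patient_id}/{sample}/r{row:02d}c{col:02d}"]
        trf = TRFMeasurement(cell["trf_wavelengths"][...], cell["trf_time"][...],
                             cell["trf"][...].astype(float))
        spectra = cell["dr"][...]
        dr = DRMeasurement(cell["dr_wavelengths"][...], spectra[0], spectra[1], spectra[2])
    return trf, dr


def save_lut(lut: PhantomLUT, path: str | Path) -> None:
    payload = {
        "rho": lut.rho,
        "mu_a_grid": lut.mu_a_grid.tolist(),
        "mu_s_grid": lut.mu_s_grid.tolist(),
        "reflectance": lut.reflectance.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_lut(path: str | Path) -> PhantomLUT:
    payload = json.loads(Path(path).read_text())
    return PhantomLUT(
        np.array(payload["mu_a_grid"]),
        np.array(payload["mu_s_grid"]),
        np.array(payload["reflectance"]),
        rho=float(payload["rho"]),
    )


def save_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def load_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
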