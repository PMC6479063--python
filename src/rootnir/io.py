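"""Readers/writers for spectra, reference and survey tables, plus run plumbing.

The interchange contract is plain CSV:

* spectra CSV — first column ``sample_id``, remaining headers are wavelengths
  (nm by default; a leading ``# unit: cm-1`` comment line switches the header
  to wavenumbers, converted on read via lambda[nm] = 1e7 / nu[cm^-1]);
* reference CSV — columns ``sample_id, lignin_pct``;
* survey CSV — one row per case study, blank cells meaning "not reported".
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import SpectraMatrix


class DataError(ValueError):
    """Malformed input data (bad grid, non-positive transmission, ...)."""


# ---------------------------------------------------------------------------
# transmission -> absorbance
# ---------------------------------------------------------------------------

def to_absorbance(transmission: SpectraMatrix) -> SpectraMatrix:
    """Convert transmission T in (0, 1] to absorbance A = log10(1/T).

    Values above 1 are physically suspect but tolerated with a warning;
    values <= 0 have no defined absorbance and raise, naming the first
    offending sample/band.
    """
    T = transmission.values
    bad = T <= 0
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"non-positive transmission {T[i, j]!r} for sample "
            f"{transmission.ids[i]!r} at {transmission.wavelengths[j]:.1f} nm"
        )
    if np.any(T > 1):
        n = int(np.sum(T > 1))
        warnings.warn(f"{n} transmission values exceed 1; absorbance will be negative")
    out = transmission.copy()
    out.values = np.log10(1.0 / T)
    out.meta["converted"] = "absorbance"
    return out


def average_replicate_spectra(replicates: SpectraMatrix,
                              expected_reps: int = 5) -> SpectraMatrix:
    """Band-wise mean of replicate spectra sharing a sample id.

    Rows with the same id are averaged; order of first appearance is kept.
    A warning is issued for samples whose replicate count differs from the
    instrument protocol (5 scans per sample).
    """
    order: list = []
    groups: dict = {}
    for row, sid in enumerate(replicates.ids):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(row)
    means = np.empty((len(order), replicates.n_bands))
    counts = {}
    for k, sid in enumerate(order):
        rows = groups[sid]
        counts[sid] = len(rows)
        means[k] = replicates.values[rows].mean(axis=0)
        if len(rows) != expected_reps:
            warnings.warn(
                f"sample {sid!r} has {len(rows)} replicate spectra "
                f"(expected {expected_reps})"
            )
    return SpectraMatrix(order, replicates.wavelengths.copy(), means,
                         {"replicate_counts": counts})


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------

def write_spectra(spectra: SpectraMatrix, path) -> None:
    """Write the spectra CSV (full float precision, nm header)."""
    df = pd.DataFrame(spectra.values,
                      columns=[repr(float(w)) for w in spectra.wavelengths])
    df.insert(0, "sample_id", spectra.ids)
    df.to_csv(path, index=False)


def read_spectra(path) -> SpectraMatrix:
    """Read a spectra CSV; see module docstring for the dialect."""
    path = Path(path)
    unit = "nm"
    header = None
    n_skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            n_skip += 1
            if line.startswith("#"):
                if "unit" in line and ("cm-1" in line or "cm^-1" in line):
                    unit = "cm-1"
                continue
            header = line.rstrip("\n").split(",")
            break
    if not header:
        raise DataError("empty spectra CSV")
    if header[0] != "sample_id":
        raise DataError("first column of a spectra CSV must be 'sample_id'")
    try:
        grid = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise DataError(f"non-numeric wavelength header: {exc}") from exc
    df = pd.read_csv(path, skiprows=n_skip, header=None,
                     float_precision="round_trip")
    if df.shape[1] != len(header):
        raise DataError("ragged spectra CSV: row width differs from header")
    if unit == "cm-1":
        grid = 1e7 / grid
    if len(set(np.round(grid, 9))) != grid.size:
        raise DataError("duplicated wavelength columns in spectra CSV")
    if np.any(np.diff(grid) < 0):
        raise DataError(
            "wavelength header must be increasing in nm "
            "(descending grids are rejected: re-sort the columns, or declare "
            "'# unit: cm-1' for a wavenumber header)"
        )
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"spectra CSV contains non-numeric cells: {exc}") from exc
    if np.any(pd.isna(values)):
        raise DataError("spectra CSV contains missing cells")
    return SpectraMatrix(df.iloc[:, 0].astype(str).tolist(), grid, values)


def write_reference(reference: pd.DataFrame, path) -> None:
    reference.loc[:, ["sample_id", "lignin_pct"]].to_csv(path, index=False)


def read_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("sample_id", "lignin_pct"):
        if col not in df.columns:
            raise DataError(f"reference CSV is missing column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_survey(path) -> pd.DataFrame:
    """Literature-survey CSV; blank cells are missing values."""
    return pd.read_csv(path)


def read_wetchem_replicates(path) -> pd.DataFrame:
    """Replicate-level UV readings: sample_id, replicate_id, OD_S, OD_B, W_d_mg, F."""
    df = pd.read_csv(path)
    needed = {"sample_id", "replicate_id", "OD_S", "OD_B", "W_d_mg", "F"}
    missing = needed - set(df.columns)
    if missing:
        raise DataError(f"wet-chem replicates CSV is missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# config + manifest plumbing
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataError("run config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, *, seed: int, config: dict, extra: dict | None = None) -> None:
    """Record everything needed to replay a run: seed, config and its hash."""
    manifest = {"seed": seed, "config_hash": config_hash(config), "config": config}
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
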