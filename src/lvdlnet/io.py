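"""Plain-text persistence for paired spectral datasets.

Layout of a dataset directory::

    libs.csv       first row = LIBS wavelengths (nm), then one row per spectrum
    vnir.csv       first row = VNIR wavelengths (nm), then one row per spectrum
    labels.csv     columns label,fraction, one row per sample
    manifest.yaml  generator parameters, spectra-per-level, seed, provenance

Everything is comma-separated text at full double precision (%.17g, which
round-trips IEEE doubles exactly), so fixtures stay inspectable and the
write -> read pair is the identity.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import (
    DatasetManifest,
    Modality,
    SpectraDataset,
    WavelengthAxis,
)

__all__ = ["write_dataset", "read_dataset"]

_FILES = ("libs.csv", "vnir.csv", "labels.csv", "manifest.yaml")
_FMT = "%.17g"


def _write_matrix(path: Path, axis: np.ndarray, X: np.ndarray) -> None:
    np.savetxt(path, np.vstack([axis[None, :], X]), fmt=_FMT, delimiter=",")


def write_dataset(ds: SpectraDataset, path: str | os.PathLike) -> None:
    """Write a validated dataset to ``path`` (created if missing)."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    _write_matrix(out / "libs.csv", ds.libs_axis.values, ds.libs)
    _write_matrix(out / "vnir.csv", ds.vnir_axis.values, ds.vnir)
    pd.DataFrame({"label": ds.labels, "fraction": ds.fractions}).to_csv(
        out / "labels.csv", index=False, float_format="%.6g"
    )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(ds.manifest.to_dict(), fh, sort_keys=False)


def read_dataset(path: str | os.PathLike) -> SpectraDataset:
    """Read a dataset directory; all invariants are re-validated on load."""
    root = Path(path)
    missing = [f for f in _FILES if not (root / f).exists()]
    if missing:
        raise FileNotFoundError(f"dataset at {root} is missing {missing}")

    raw_libs = np.loadtxt(root / "libs.csv", delimiter=",", ndmin=2)
    raw_vnir = np.loadtxt(root / "vnir.csv", delimiter=",", ndmin=2)
    libs_axis = WavelengthAxis(raw_libs[0], Modality.LIBS)
    vnir_axis = WavelengthAxis(raw_vnir[0], Modality.VNIR)

    labels_df = pd.read_csv(root / "labels.csv")
    with open(root / "manifest.yaml") as fh:
        manifest = DatasetManifest.from_dict(yaml.safe_load(fh))

    return SpectraDataset(
        libs=raw_libs[1:],
        vnir=raw_vnir[1:],
        labels=labels_df["label"].to_numpy(),
        fractions=labels_df["fraction"].to_numpy(),
        libs_axis=libs_axis,
        vnir_axis=vnir_axis,
        manifest=manifest,
    )
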