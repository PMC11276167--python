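"""Canonical in-memory containers for paired LIBS / VNIR spectral datasets.

Every other module consumes these types: a shared wavelength axis per
modality, single spectra, and the paired dataset with adulteration labels.
Invariants are enforced at construction so violations never propagate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np

__all__ = [
    "Modality",
    "WavelengthAxis",
    "Spectrum",
    "DatasetManifest",
    "SpectraDataset",
    "FRACTIONS",
    "N_CLASSES",
]

#: The six adulteration weight fractions (omega/omega) defining the classes.
FRACTIONS = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
N_CLASSES = 6

_SPANS = {"LIBS": (196.0, 874.0), "VNIR": (350.0, 1100.0)}


class Modality(str, Enum):
    LIBS = "LIBS"
    VNIR = "VNIR"


@dataclass(frozen=True)
class WavelengthAxis:
    """A strictly increasing wavelength grid (nm) tagged by modality.

    LIBS axes must lie within 196-874 nm (the broadband echelle range),
    VNIR axes within 350-1100 nm.
    """

    values: np.ndarray
    modality: Modality

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "modality", Modality(self.modality))
        if values.ndim != 1 or values.size == 0:
            raise ValueError("wavelength axis must be a non-empty 1-D vector")
        if not np.all(np.isfinite(values)):
            raise ValueError("wavelength axis contains non-finite values")
        if np.any(values <= 0):
            raise ValueError("wavelengths must be positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        lo, hi = _SPANS[self.modality.value]
        if values[0] < lo - 1e-9 or values[-1] > hi + 1e-9:
            raise ValueError(
                f"{self.modality.value} axis [{values[0]:.2f}, {values[-1]:.2f}]"
                f" nm outside allowed span [{lo}, {hi}] nm"
            )

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class Spectrum:
    """One intensity vector on a shared :class:`WavelengthAxis`."""

    axis: WavelengthAxis
    intensities: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", y)
        if y.ndim != 1 or y.size != len(self.axis):
            raise ValueError(
                f"intensity vector length {y.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")

    @property
    def modality(self) -> Modality:
        return self.axis.modality


@dataclass
class DatasetManifest:
    """Provenance of a generated dataset: seed, sizes, generator parameters."""

    spectra_per_level: int
    seed: int
    generator_params: dict[str, Any] = field(default_factory=dict)
    preset: str | None = None
    provenance: str = "lvdlnet synthetic paired-spectrum generator"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DatasetManifest":
        return cls(
            spectra_per_level=int(d["spectra_per_level"]),
            seed=int(d["seed"]),
            generator_params=d.get("generator_params", {}),
            preset=d.get("preset"),
            provenance=d.get("provenance", ""),
        )


class SpectraDataset:
    """Paired LIBS/VNIR spectra with adulteration-level labels.

    Row ``i`` of ``libs`` and ``vnir`` describe the same physical sample.
    ``labels`` are class indices 0..5 and ``fractions`` the corresponding
    adulteration weight fractions in {0, 0.2, ..., 1.0}; consistency
    (label == round(5 * fraction)) is enforced.
    """

    def __init__(
        self,
        libs: np.ndarray,
        vnir: np.ndarray,
        labels: np.ndarray,
        fractions: np.ndarray,
        libs_axis: WavelengthAxis,
        vnir_axis: WavelengthAxis,
        manifest: DatasetManifest,
    ) -> None:
        libs = np.asarray(libs, dtype=float)
        vnir = np.asarray(vnir, dtype=float)
        labels = np.asarray(labels, dtype=int)
        fractions = np.asarray(fractions, dtype=float)
        if libs.ndim != 2 or vnir.ndim != 2:
            raise ValueError("libs and vnir must be 2-D matrices")
        if libs.shape[0] != vnir.shape[0]:
            raise ValueError(
                f"libs has {libs.shape[0]} rows but vnir has {vnir.shape[0]};"
                " rows must be paired"
            )
        n = libs.shape[0]
        if labels.shape != (n,) or fractions.shape != (n,):
            raise ValueError("labels/fractions length must match row count")
        if libs.shape[1] != len(libs_axis):
            raise ValueError("libs column count != LIBS axis length")
        if vnir.shape[1] != len(vnir_axis):
            raise ValueError("vnir column count != VNIR axis length")
        if libs_axis.modality is not Modality.LIBS:
            raise ValueError("libs_axis must have LIBS modality")
        if vnir_axis.modality is not Modality.VNIR:
            raise ValueError("vnir_axis must have VNIR modality")
        if not (np.all(np.isfinite(libs)) and np.all(np.isfinite(vnir))):
            raise ValueError("spectra contain non-finite values")
        if np.any(labels < 0) or np.any(labels >= N_CLASSES):
            raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
        if not np.array_equal(np.round(5.0 * fractions).astype(int), labels):
            raise ValueError("labels inconsistent with fractions (label != round(5 f))")
        if manifest.spectra_per_level * N_CLASSES != n:
            raise ValueError(
                f"manifest says {manifest.spectra_per_level} spectra/level"
                f" x {N_CLASSES} levels, but dataset has {n} rows"
            )
        self.libs = libs
        self.vnir = vnir
        self.labels = labels
        self.fractions = fractions
        self.libs_axis = libs_axis
        self.vnir_axis = vnir_axis
        self.manifest = manifest

    @property
    def n_samples(self) -> int:
        return int(self.libs.shape[0])

    def libs_spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.libs_axis, self.libs[i])

    def vnir_spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.vnir_axis, self.vnir[i])

    def equals(self, other: "SpectraDataset", atol: float = 1e-12) -> bool:
        """Equality on labels/fractions (exact) and intensities (within atol)."""
        return (
            self.n_samples == other.n_samples
            and np.array_equal(self.labels, other.labels)
            and np.allclose(self.fractions, other.fractions, atol=1e-12)
            and np.allclose(self.libs_axis.values, other.libs_axis.values, atol=1e-12)
            and np.allclose(self.vnir_axis.values, other.vnir_axis.values, atol=1e-12)
            and np.allclose(self.libs, other.libs, atol=atol, rtol=0)
            and np.allclose(self.vnir, other.vnir, atol=atol, rtol=0)
        )
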