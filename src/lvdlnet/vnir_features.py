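"""VNIR interval selection and first-derivative (slope) features.

Five wavebands bracketing the informative absorption features (chlorophyll
near 670 nm, O-H stretching overtones near 920 and 970 nm, and the
short-wavelength pigment edge) are cut from the 997-point reflectance
spectrum, keeping 375 of the points. Within each band the first derivative is
taken as forward differences divided by the local wavelength spacing, giving
a slope vector of length 370 (one fewer slope than points per band, never
crossing a band boundary). Slopes are insensitive to additive baseline
offsets, which is the point of the representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .spectra import Modality, Spectrum, WavelengthAxis

__all__ = [
    "VnirInterval",
    "VnirIntervalSet",
    "default_interval_set",
    "select_vnir_points",
    "interval_slopes",
    "slope_features",
    "full_spectrum_features",
]


@dataclass(frozen=True)
class VnirInterval:
    lower: float
    upper: float
    points: int

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError("interval lower bound must be below upper bound")
        if self.points < 2:
            raise ValueError("interval must expect at least 2 points")


class VnirIntervalSet:
    """Ordered, non-overlapping waveband selection."""

    def __init__(self, intervals: list[VnirInterval]):
        if not intervals:
            raise ValueError("interval set must be non-empty")
        for a, b in zip(intervals, intervals[1:]):
            if b.lower <= a.upper:
                raise ValueError("intervals must be non-overlapping and increasing")
        self.intervals = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i: int) -> VnirInterval:
        return self.intervals[i]

    @property
    def total_points(self) -> int:
        return sum(iv.points for iv in self.intervals)

    @property
    def n_slopes(self) -> int:
        return sum(iv.points - 1 for iv in self.intervals)

    @classmethod
    def from_yaml(cls, path_or_stream) -> "VnirIntervalSet":
        if hasattr(path_or_stream, "read"):
            doc = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream, "r") as fh:
                doc = yaml.safe_load(fh)
        return cls([VnirInterval(**row) for row in doc["intervals"]])


def default_interval_set() -> VnirIntervalSet:
    """The packaged five-band selection (63 + 67 + 136 + 27 + 82 = 375 points)."""
    ref = resources.files("lvdlnet.data").joinpath("vnir_intervals.yaml")
    with ref.open("r") as fh:
        return VnirIntervalSet.from_yaml(fh)


def _interval_indices(axis: WavelengthAxis, iv: VnirInterval) -> np.ndarray:
    values = axis.values
    if iv.lower < values[0] or iv.upper > values[-1]:
        raise ValueError(
            f"interval [{iv.lower}, {iv.upper}] nm outside axis span"
            f" [{values[0]:.2f}, {values[-1]:.2f}] nm"
        )
    lo = int(np.searchsorted(values, iv.lower, side="left"))
    hi = int(np.searchsorted(values, iv.upper, side="right"))
    return np.arange(lo, hi)


def select_vnir_points(
    s: Spectrum, interval_set: VnirIntervalSet | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-band ``(wavelengths, intensities)`` segments, in band order."""
    if s.modality is not Modality.VNIR:
        raise ValueError("waveband selection is defined for VNIR spectra")
    interval_set = interval_set or default_interval_set()
    segments = []
    for iv in interval_set:
        idx = _interval_indices(s.axis, iv)
        segments.append((s.axis.values[idx], s.intensities[idx]))
    return segments


def interval_slopes(segments: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Concatenated within-band first derivatives d(reflectance)/d(lambda)."""
    out = []
    for lam, y in segments:
        lam = np.asarray(lam, dtype=float)
        y = np.asarray(y, dtype=float)
        if lam.size < 2:
            raise ValueError("each segment needs at least 2 points for a slope")
        out.append(np.diff(y) / np.diff(lam))
    return np.concatenate(out)


def slope_features(
    s: Spectrum, interval_set: VnirIntervalSet | None = None
) -> np.ndarray:
    """Convenience: selection followed by differentiation (length 370 default)."""
    return interval_slopes(select_vnir_points(s, interval_set))


def full_spectrum_features(s: Spectrum) -> np.ndarray:
    """The raw reflectance vector, unchanged (full-spectrum baseline input)."""
    if s.modality is not Modality.VNIR:
        raise ValueError("full-spectrum features are defined for VNIR spectra")
    return s.intensities


def batch_slope_features(
    X: np.ndarray, axis: WavelengthAxis, interval_set: VnirIntervalSet | None = None
) -> np.ndarray:
    """Vectorized :func:`slope_features` over rows of ``X`` -> ``(n, 370)``."""
    interval_set = interval_set or default_interval_set()
    parts = []
    for iv in interval_set:
        idx = _interval_indices(axis, iv)
        lam = axis.values[idx]
        parts.append(np.diff(X[:, idx], axis=1) / np.diff(lam)[None, :])
    return np.concatenate(parts, axis=1)
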