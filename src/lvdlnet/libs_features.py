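"""LIBS line-interval feature extraction.

A broadband LIBS spectrum (24,564 points, 196-874 nm) is reduced to an
18 x 14 matrix: one row per registered elemental emission line, each row the
line's profile interval standardized to exactly 14 points. Three operators
perform the standardization depending on how many raw axis points fall inside
the line's interval:

* ``zero_padding`` (n < 14): the n values are centered among zeros, the extra
  zero going to the right when the deficit is odd;
* ``retention`` (n == 14): the values pass through unchanged;
* ``interception`` (n > 14): the central 14 values are kept, starting at left
  offset ``floor((n - 14) / 2)`` (one extra point dropped on the right when
  the overflow is odd).

The 14-point window is chosen to exceed the FWHM of every registered line, so
the standardized row carries the full profile (wings included), not just the
peak. A peak-only extractor is provided for baseline comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .spectra import Modality, Spectrum, WavelengthAxis

__all__ = [
    "TARGET_POINTS",
    "LineInterval",
    "LineRegistry",
    "default_registry",
    "standardize_interval",
    "locate_interval",
    "extract_line_features",
    "extract_peak_features",
]

#: Standardized number of points per line interval (also the convolution
#: kernel width of the downstream model).
TARGET_POINTS = 14

_OPERATIONS = ("zero_padding", "retention", "interception")


@dataclass(frozen=True)
class LineInterval:
    """One registered emission line: center, interval bounds, operator."""

    element: str
    center: float
    lower: float
    upper: float
    points: int
    operation: str

    def __post_init__(self) -> None:
        if not (self.lower < self.center < self.upper):
            raise ValueError(
                f"{self.element} {self.center}: center must lie strictly inside"
                f" ({self.lower}, {self.upper})"
            )
        if self.operation not in _OPERATIONS:
            raise ValueError(f"unknown operation {self.operation!r}")
        expected = (
            "zero_padding"
            if self.points < TARGET_POINTS
            else "retention"
            if self.points == TARGET_POINTS
            else "interception"
        )
        if self.operation != expected:
            raise ValueError(
                f"{self.element} {self.center}: {self.points} points requires"
                f" operation {expected!r}, got {self.operation!r}"
            )


class LineRegistry:
    """Ordered collection of :class:`LineInterval` entries (wavelength order)."""

    def __init__(self, lines: list[LineInterval]):
        if len(lines) == 0:
            raise ValueError("registry must contain at least one line")
        centers = [li.center for li in lines]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("line centers must be strictly increasing")
        for a, b in zip(lines, lines[1:]):
            if b.lower <= a.upper:
                raise ValueError(
                    f"intervals of {a.element} {a.center} and {b.element}"
                    f" {b.center} overlap"
                )
        self.lines = list(lines)

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self):
        return iter(self.lines)

    def __getitem__(self, i: int) -> LineInterval:
        return self.lines[i]

    @property
    def centers(self) -> np.ndarray:
        return np.array([li.center for li in self.lines])

    @classmethod
    def from_yaml(cls, path_or_stream) -> "LineRegistry":
        if hasattr(path_or_stream, "read"):
            doc = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream, "r") as fh:
                doc = yaml.safe_load(fh)
        return cls([LineInterval(**row) for row in doc["lines"]])


def default_registry() -> LineRegistry:
    """The packaged 18-line registry (C, Mg, Si, Al, Ca, Na, N, K, O lines)."""
    ref = resources.files("lvdlnet.data").joinpath("libs_lines.yaml")
    with ref.open("r") as fh:
        return LineRegistry.from_yaml(fh)


def standardize_interval(values: np.ndarray, target: int = TARGET_POINTS) -> np.ndarray:
    """Map an interval's raw values to exactly ``target`` points.

    See the module docstring for the three operators and their tie-breaks.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("interval values must be a non-empty 1-D vector")
    n = values.size
    if n == target:
        return values.copy()
    if n < target:
        left = (target - n) // 2
        out = np.zeros(target, dtype=float)
        out[left : left + n] = values
        return out
    offset = (n - target) // 2
    return values[offset : offset + target].copy()


def locate_interval(axis: WavelengthAxis, li: LineInterval) -> np.ndarray:
    """Indices of axis points with ``lower <= lambda <= upper`` (closed)."""
    values = axis.values
    if li.lower < values[0] or li.upper > values[-1]:
        raise ValueError(
            f"interval [{li.lower}, {li.upper}] nm outside axis span"
            f" [{values[0]:.2f}, {values[-1]:.2f}] nm"
        )
    lo = int(np.searchsorted(values, li.lower, side="left"))
    hi = int(np.searchsorted(values, li.upper, side="right"))
    if hi <= lo:
        raise ValueError(f"no axis points inside [{li.lower}, {li.upper}] nm")
    return np.arange(lo, hi)


def extract_line_features(
    s: Spectrum, registry: LineRegistry | None = None
) -> np.ndarray:
    """Standardized line-interval matrix, shape ``(len(registry), 14)``."""
    if s.modality is not Modality.LIBS:
        raise ValueError("line features are defined for LIBS spectra")
    registry = registry or default_registry()
    rows = [
        standardize_interval(s.intensities[locate_interval(s.axis, li)])
        for li in registry
    ]
    return np.vstack(rows)


def extract_peak_features(
    s: Spectrum, registry: LineRegistry | None = None
) -> np.ndarray:
    """Peak-maximum per registered line, shape ``(len(registry),)``.

    The peak-only representation discards the line wings and FWHM and is the
    weaker baseline input in the feature-input comparison.
    """
    if s.modality is not Modality.LIBS:
        raise ValueError("peak features are defined for LIBS spectra")
    registry = registry or default_registry()
    return np.array(
        [float(np.max(s.intensities[locate_interval(s.axis, li)])) for li in registry]
    )


def batch_line_features(
    X: np.ndarray, axis: WavelengthAxis, registry: LineRegistry | None = None
) -> np.ndarray:
    """Vectorized :func:`extract_line_features` over rows of ``X``.

    Returns an array of shape ``(n, len(registry), 14)``.
    """
    registry = registry or default_registry()
    n = X.shape[0]
    out = np.zeros((n, len(registry), TARGET_POINTS))
    for i, li in enumerate(registry):
        idx = locate_interval(axis, li)
        m = idx.size
        if m == TARGET_POINTS:
            out[:, i, :] = X[:, idx]
        elif m < TARGET_POINTS:
            left = (TARGET_POINTS - m) // 2
            out[:, i, left : left + m] = X[:, idx]
        else:
            off = (m - TARGET_POINTS) // 2
            out[:, i, :] = X[:, idx[off : off + TARGET_POINTS]]
    return out


def batch_peak_features(
    X: np.ndarray, axis: WavelengthAxis, registry: LineRegistry | None = None
) -> np.ndarray:
    """Vectorized :func:`extract_peak_features` over rows of ``X``."""
    registry = registry or default_registry()
    cols = [X[:, locate_interval(axis, li)].max(axis=1) for li in registry]
    return np.column_stack(cols)
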