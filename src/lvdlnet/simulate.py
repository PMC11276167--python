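"""Paired LIBS/VNIR spectrum simulator.

The generator emulates the statistical structure of adulterated powdered
plant material measured by the two instruments: every class shows the *same*
emission lines and absorption bands, and only intensities move with the
adulteration fraction ``f``.

LIBS model (per spectrum)::

    I(lambda) = baseline + (1 + eps) * sum_e (a_e + b_e f) L(lambda; c_e, gamma_e)
                + N(0, sigma_add)  per point

with ``L`` a unit-peak Lorentzian (Stark-broadened emission line) and ``eps``
a single zero-mean Gaussian draw per spectrum modelling shot-to-shot
pulse-energy fluctuation (it scales all lines together).

VNIR model (per spectrum)::

    R(lambda) = baseline(lambda) - sum_b (d0_b + d1_b f) G(lambda; c_b, w_b)
                + N(0, sigma_add)  per point

with ``G`` a unit-peak Gaussian absorption band and ``baseline`` a smooth
monotone-segment interpolation through configured control points.

Both wavelength axes are built piecewise so that every registered line /
waveband interval contains exactly its reference number of points (real
multi-channel spectrometers have non-uniform dispersion, so a uniform grid
cannot reproduce those counts).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator

from .libs_features import LineRegistry, default_registry
from .spectra import (
    FRACTIONS,
    N_CLASSES,
    DatasetManifest,
    Modality,
    SpectraDataset,
    Spectrum,
    WavelengthAxis,
)
from .vnir_features import VnirIntervalSet, default_interval_set

__all__ = [
    "LIBS_AXIS_POINTS",
    "VNIR_AXIS_POINTS",
    "LibsSimParams",
    "VnirSimParams",
    "make_libs_axis",
    "make_vnir_axis",
    "simulate_libs_spectrum",
    "simulate_vnir_spectrum",
    "generate_paired_dataset",
    "load_preset",
    "available_presets",
]

LIBS_AXIS_POINTS = 24_564
VNIR_AXIS_POINTS = 997

_PRESETS = ("easy", "hard", "complementary", "null")


# ---------------------------------------------------------------------------
# Axes


def _piecewise_axis(
    total: int, span: tuple[float, float], windows: list[tuple[float, float, int]]
) -> np.ndarray:
    """Strictly increasing grid with exact point counts inside each window.

    ``windows`` are disjoint ``(lower, upper, count)`` triples inside ``span``;
    each contributes ``linspace(lower, upper, count)`` (closed interval, exact
    endpoints). The remaining points are apportioned to the gaps by length
    (largest-remainder rule) and placed strictly outside every window; the
    span endpoints are included.
    """
    lo, hi = span
    windows = sorted(windows)
    fixed = sum(c for *_, c in windows)
    free = total - fixed
    if free < len(windows) + 1:
        raise ValueError("not enough free points to fill the gaps")
    # gap boundaries: (start, end); first gap includes lo, last includes hi
    bounds = [lo] + [b for w in windows for b in (w[0], w[1])] + [hi]
    gaps = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(len(windows) + 1)]
    lengths = np.array([b - a for a, b in gaps])
    quota = free * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    remainder = free - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    # an edge gap of zero length is fine when the window itself supplies the
    # span endpoint; otherwise the endpoint needs at least one grid point
    if (counts[0] < 1 and lengths[0] > 0) or (counts[-1] < 1 and lengths[-1] > 0):
        raise ValueError("span endpoints could not be placed")
    if lengths[0] == 0 and counts[0] > 0:
        raise ValueError("cannot place points in a zero-length leading gap")

    pieces: list[np.ndarray] = []
    for i, (a, b) in enumerate(gaps):
        m = int(counts[i])
        if i == 0:
            pieces.append(np.linspace(a, b, m, endpoint=False))
        elif i == len(gaps) - 1:
            pieces.append(np.linspace(a, b, m + 1)[1:])
        else:
            pieces.append(np.linspace(a, b, m + 2)[1:-1])
        if i < len(windows):
            wl, wu, wc = windows[i]
            pieces.append(np.linspace(wl, wu, wc))
    axis = np.concatenate(pieces)
    assert axis.size == total
    return axis


def make_libs_axis(registry: LineRegistry | None = None) -> WavelengthAxis:
    """Reference LIBS axis: 24,564 points over 196-874 nm, honoring the
    registered per-line interval point counts exactly."""
    registry = registry or default_registry()
    windows = [(li.lower, li.upper, li.points) for li in registry]
    values = _piecewise_axis(LIBS_AXIS_POINTS, (196.0, 874.0), windows)
    return WavelengthAxis(values, Modality.LIBS)


def make_vnir_axis(interval_set: VnirIntervalSet | None = None) -> WavelengthAxis:
    """Reference VNIR axis: 997 points over 350-1100 nm, honoring the
    selected-waveband point counts exactly."""
    interval_set = interval_set or default_interval_set()
    windows = [(iv.lower, iv.upper, iv.points) for iv in interval_set]
    values = _piecewise_axis(VNIR_AXIS_POINTS, (350.0, 1100.0), windows)
    return WavelengthAxis(values, Modality.VNIR)


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class LibsSimParams:
    """Emission-line amplitudes and noise levels for the LIBS channel.

    ``base_amp[e] + frac_coef[e] * f`` is the noiseless peak height of line
    ``e`` above baseline at adulteration fraction ``f``; it must stay
    non-negative over f in [0, 1].
    """

    base_amp: np.ndarray
    frac_coef: np.ndarray
    gamma: np.ndarray
    baseline: float = 50.0
    sigma_mult: float = 0.0
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        self.base_amp = np.asarray(self.base_amp, dtype=float)
        self.frac_coef = np.asarray(self.frac_coef, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        if gamma.ndim == 0:
            gamma = np.full(self.base_amp.shape, float(gamma))
        self.gamma = gamma
        if not (self.base_amp.shape == self.frac_coef.shape == self.gamma.shape):
            raise ValueError("base_amp, frac_coef and gamma must share one shape")
        if np.any(self.gamma <= 0):
            raise ValueError("Lorentzian half-widths must be positive")
        if self.sigma_mult < 0 or self.sigma_add < 0:
            raise ValueError("noise standard deviations must be non-negative")
        # amplitude linear in f: checking both endpoints covers all f in [0,1]
        for f in (0.0, 1.0):
            if np.any(self.base_amp + self.frac_coef * f < 0):
                raise ValueError("line amplitude a_e + b_e f must be >= 0 on [0,1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}


@dataclass
class VnirSimParams:
    """Absorption-band depths and noise level for the VNIR channel.

    Band ``b`` subtracts ``(depth0[b] + depth_slope[b] * f) * G`` from the
    smooth baseline; the noiseless reflectance must stay in (0, 1.2] over
    f in [0, 1].
    """

    band_centers: np.ndarray
    depth0: np.ndarray
    depth_slope: np.ndarray
    widths: np.ndarray
    baseline_knots: list[tuple[float, float]] = field(default_factory=list)
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        for name in ("band_centers", "depth0", "depth_slope", "widths"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        shapes = {
            self.band_centers.shape,
            self.depth0.shape,
            self.depth_slope.shape,
            self.widths.shape,
        }
        if len(shapes) != 1:
            raise ValueError("band parameter arrays must share one shape")
        if np.any(self.widths <= 0):
            raise ValueError("band widths must be positive")
        if self.sigma_add < 0:
            raise ValueError("noise standard deviation must be non-negative")
        if len(self.baseline_knots) < 2:
            raise ValueError("baseline needs at least two control points")

    def baseline_fn(self) -> PchipInterpolator:
        knots = np.asarray(self.baseline_knots, dtype=float)
        return PchipInterpolator(knots[:, 0], knots[:, 1])

    def validate_reflectance(self, axis: WavelengthAxis) -> None:
        """Check the noiseless template stays in (0, 1.2] at f = 0 and f = 1."""
        for f in (0.0, 1.0):
            r = _vnir_template(axis.values, self, f)
            if np.any(r <= 0) or np.any(r > 1.2):
                raise ValueError(
                    f"noiseless reflectance leaves (0, 1.2] at f={f}"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        out = {}
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            elif k == "baseline_knots":
                out[k] = [[float(a), float(b)] for a, b in v]
            else:
                out[k] = v
        return out


# ---------------------------------------------------------------------------
# Templates


def _lorentz_profiles(lam: np.ndarray, centers: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Unit-peak Lorentzians, shape (n_lines, n_points)."""
    d = lam[None, :] - centers[:, None]
    g2 = (gamma**2)[:, None]
    return g2 / (d**2 + g2)


def _gauss_profiles(lam: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    d = lam[None, :] - centers[:, None]
    return np.exp(-0.5 * (d / widths[:, None]) ** 2)


def _vnir_template(lam: np.ndarray, params: VnirSimParams, f: float) -> np.ndarray:
    base = params.baseline_fn()(lam)
    depths = params.depth0 + params.depth_slope * f
    return base - depths @ _gauss_profiles(lam, params.band_centers, params.widths)


# ---------------------------------------------------------------------------
# Single-spectrum simulation


def _check_fraction(f: float) -> float:
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"adulteration fraction must lie in [0, 1], got {f}")
    return f


def simulate_libs_spectrum(
    f: float,
    params: LibsSimParams,
    rng: np.random.Generator,
    axis: WavelengthAxis | None = None,
    registry: LineRegistry | None = None,
    _profiles: np.ndarray | None = None,
) -> Spectrum:
    """One noisy LIBS spectrum at adulteration fraction ``f``.

    ``_profiles`` lets batch callers reuse the (n_lines, n_points) Lorentzian
    template matrix; it does not change the result.
    """
    f = _check_fraction(f)
    registry = registry or default_registry()
    axis = axis or make_libs_axis(registry)
    if params.base_amp.size != len(registry):
        raise ValueError("params must provide one amplitude per registered line")
    profiles = (
        _profiles
        if _profiles is not None
        else _lorentz_profiles(axis.values, registry.centers, params.gamma)
    )
    amps = (params.base_amp + params.frac_coef * f) * (
        1.0 + rng.normal(0.0, params.sigma_mult)
    )
    y = params.baseline + amps @ profiles
    if params.sigma_add > 0:
        y = y + rng.normal(0.0, params.sigma_add, size=y.shape)
    return Spectrum(axis, y)


def simulate_vnir_spectrum(
    f: float,
    params: VnirSimParams,
    rng: np.random.Generator,
    axis: WavelengthAxis | None = None,
) -> Spectrum:
    """One noisy VNIR reflectance spectrum at adulteration fraction ``f``."""
    f = _check_fraction(f)
    axis = axis or make_vnir_axis()
    r = _vnir_template(axis.values, params, f)
    if params.sigma_add > 0:
        r = r + rng.normal(0.0, params.sigma_add, size=r.shape)
    return Spectrum(axis, r)


# ---------------------------------------------------------------------------
# Dataset generation


def generate_paired_dataset(
    spectra_per_level: int,
    libs_params: LibsSimParams,
    vnir_params: VnirSimParams,
    seed: int,
    preset: str | None = None,
    registry: LineRegistry | None = None,
) -> SpectraDataset:
    """Six levels x ``spectra_per_level`` paired spectra.

    One seed sequence is spawned deterministically per sample (two child
    streams, LIBS then VNIR), so the same seed always regenerates the same
    dataset and individual samples are independently reproducible.
    """
    if spectra_per_level < 1:
        raise ValueError("spectra_per_level must be >= 1")
    registry = registry or default_registry()
    libs_axis = make_libs_axis(registry)
    vnir_axis = make_vnir_axis()
    vnir_params.validate_reflectance(vnir_axis)

    n = spectra_per_level * N_CLASSES
    libs = np.empty((n, len(libs_axis)))
    vnir = np.empty((n, len(vnir_axis)))
    labels = np.repeat(np.arange(N_CLASSES), spectra_per_level)
    fractions = FRACTIONS[labels]

    profiles = _lorentz_profiles(
        libs_axis.values, registry.centers, libs_params.gamma
    )
    root = np.random.SeedSequence(seed)
    children = root.spawn(n)
    for i in range(n):
        ss_libs, ss_vnir = children[i].spawn(2)
        libs[i] = simulate_libs_spectrum(
            fractions[i],
            libs_params,
            np.random.default_rng(ss_libs),
            axis=libs_axis,
            registry=registry,
            _profiles=profiles,
        ).intensities
        vnir[i] = simulate_vnir_spectrum(
            fractions[i], vnir_params, np.random.default_rng(ss_vnir), axis=vnir_axis
        ).intensities

    manifest = DatasetManifest(
        spectra_per_level=spectra_per_level,
        seed=int(seed),
        generator_params={
            "libs": libs_params.to_dict(),
            "vnir": vnir_params.to_dict(),
        },
        preset=preset,
    )
    return SpectraDataset(libs, vnir, labels, fractions, libs_axis, vnir_axis, manifest)


# ---------------------------------------------------------------------------
# Presets


def available_presets() -> tuple[str, ...]:
    return _PRESETS


def load_preset(name: str) -> tuple[LibsSimParams, VnirSimParams]:
    """Load a packaged parameter preset (``easy``, ``hard``, ``complementary``,
    ``null``) as a (LIBS, VNIR) parameter pair."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {_PRESETS}")
    ref = resources.files("lvdlnet.data").joinpath(f"preset_{name}.yaml")
    with ref.open("r") as fh:
        doc = yaml.safe_load(fh)
    lp = doc["libs"]
    libs = LibsSimParams(
        base_amp=lp["base_amp"],
        frac_coef=lp["frac_coef"],
        gamma=lp["gamma"],
        baseline=lp["baseline"],
        sigma_mult=lp["sigma_mult"],
        sigma_add=lp["sigma_add"],
    )
    vp = doc["vnir"]
    bands = vp["bands"]
    vnir = VnirSimParams(
        band_centers=[b["center"] for b in bands],
        depth0=[b["depth0"] for b in bands],
        depth_slope=[b["depth_slope"] for b in bands],
        widths=[b["width"] for b in bands],
        baseline_knots=[tuple(k) for k in vp["baseline_knots"]],
        sigma_add=vp["sigma_add"],
    )
    return libs, vnir


def generate_preset_dataset(
    preset: str, spectra_per_level: int, seed: int
) -> SpectraDataset:
    """Shortcut: :func:`load_preset` + :func:`generate_paired_dataset`."""
    libs_p, vnir_p = load_preset(preset)
    return generate_paired_dataset(
        spectra_per_level, libs_p, vnir_p, seed, preset=preset
    )
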