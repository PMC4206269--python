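"""Acoustic media, scatterer phantoms and travel-time geometry.

Coordinate frame (right-handed): ``x`` lateral (along the array), ``e``
elevational (out of the imaging plane), ``z`` axial (depth, 0 at the probe
face).  The imaging mid-plane is ``e = 0``.  All internal quantities are SI
(meters, seconds, Hz).

A :class:`Medium` is an ordered stack of layers along ``z``; rays propagate
straight (refraction at layer boundaries is deliberately ignored — the
layered-medium effects of interest here are pure timing effects).  The
scanner converts round-trip time to displayed depth with the *assumed* speed
of sound, which is how a fast inclusion (e.g. an aluminum plate) makes a
target appear shallower than it is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, GeometryError

__all__ = [
    "Layer",
    "Medium",
    "ScattererField",
    "Scene",
    "Inclusion",
    "PhantomSpec",
    "WATER_C",
    "TISSUE_C",
    "water",
    "make_phantom",
    "one_way_time",
    "apparent_depth",
]

WATER_C = 1480.0  #: speed of sound in water at ~20 C, m/s
TISSUE_C = 1540.0  #: conventional soft-tissue average, m/s


@dataclass(frozen=True)
class Layer:
    """One axial slab of a layered medium.

    Parameters
    ----------
    thickness:
        Extent along ``z`` in meters; ``None`` marks the last, unbounded layer.
    c:
        Speed of sound in m/s.
    attenuation:
        Amplitude attenuation coefficient in dB/(cm MHz).
    """

    thickness: float | None
    c: float
    attenuation: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness is not None and not self.thickness > 0:
            raise ConfigError(f"layer thickness must be > 0, got {self.thickness}")
        if not self.c > 0:
            raise ConfigError(f"speed of sound must be > 0, got {self.c}")
        if self.attenuation < 0:
            raise ConfigError(f"attenuation must be >= 0, got {self.attenuation}")


@dataclass(frozen=True)
class Medium:
    """Ordered layer stack plus the scanner's display speed of sound."""

    layers: tuple[Layer, ...]
    assumed_c: float = TISSUE_C

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigError("medium needs at least one layer")
        if not self.assumed_c > 0:
            raise ConfigError("assumed_c must be > 0")
        for lay in self.layers[:-1]:
            if lay.thickness is None:
                raise ConfigError("only the last layer may be unbounded")

    @property
    def c0(self) -> float:
        """Speed of sound of the first (probe-contact) layer."""
        return self.layers[0].c

    def _breaks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Depth breakpoints, cumulative one-way times and cumulative
        attenuation (dB per MHz) at each boundary."""
        zb = [0.0]
        tb = [0.0]
        ab = [0.0]
        for lay in self.layers:
            if lay.thickness is None:
                break
            zb.append(zb[-1] + lay.thickness)
            tb.append(tb[-1] + lay.thickness / lay.c)
            ab.append(ab[-1] + lay.attenuation * lay.thickness * 100.0)
        return np.asarray(zb), np.asarray(tb), np.asarray(ab)

    @property
    def bounded_depth(self) -> float:
        """Total depth covered by bounded layers (inf if the last is open)."""
        if self.layers[-1].thickness is None:
            return np.inf
        return float(sum(lay.thickness for lay in self.layers))

    def amp_factor(self, z, f_hz: float):
        """One-way frequency-dependent amplitude attenuation factor.

        ``10**(-alpha * f_MHz * path_cm / 20)`` accumulated over traversed
        layers.  Vectorized over ``z``.
        """
        z = np.asarray(z, dtype=float)
        zb, _, ab = self._breaks()
        last = self.layers[-1]
        # dB per MHz accumulated to depth z
        db_per_mhz = np.interp(z, zb, ab)
        if last.thickness is None:
            over = np.clip(z - zb[-1], 0.0, None)
            db_per_mhz = db_per_mhz + last.attenuation * over * 100.0
        return 10.0 ** (-(db_per_mhz * f_hz * 1e-6) / 20.0)


def water(assumed_c: float | None = None) -> Medium:
    """A single unbounded water layer (the default bench-test medium)."""
    return Medium(
        layers=(Layer(None, WATER_C, 0.0),),
        assumed_c=WATER_C if assumed_c is None else assumed_c,
    )


def one_way_time(z, medium: Medium):
    """One-way axial travel time from the probe face to depth ``z``.

    Sum over traversed layers of (path in layer) / (layer speed of sound).
    Vectorized over ``z``; a single-layer medium reduces to ``z / c``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise GeometryError("depth must be >= 0")
    if np.any(z > medium.bounded_depth):
        raise GeometryError(
            f"depth {float(np.max(z)):g} m beyond modelled region "
            f"({medium.bounded_depth:g} m)"
        )
    zb, tb, _ = medium._breaks()
    t = np.interp(z, zb, tb)
    last = medium.layers[-1]
    if last.thickness is None:
        t = t + np.clip(z - zb[-1], 0.0, None) / last.c
    return t if t.ndim else float(t)


def apparent_depth(t_round_trip, medium: Medium):
    """Depth at which the scanner displays an echo received after
    ``t_round_trip`` seconds: ``assumed_c * t / 2``.

    For a homogeneous medium with ``assumed_c`` equal to the true speed this
    is the true depth; through a faster inclusion the spot appears shallower.
    """
    t = np.asarray(t_round_trip, dtype=float)
    if np.any(t < 0):
        raise ValueError("round-trip time must be >= 0")
    d = medium.assumed_c * t / 2.0
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class ScattererField:
    """Discrete point scatterers: positions (N, 3) as (x, e, z), unit-free
    non-negative reflectivities, and the seed that generated them."""

    positions: np.ndarray
    reflectivities: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        refl = np.asarray(self.reflectivities, dtype=float).reshape(-1)
        if pos.shape[0] != refl.shape[0]:
            raise ConfigError("positions and reflectivities length mismatch")
        if not np.all(np.isfinite(refl)) or np.any(refl < 0):
            raise ConfigError("reflectivities must be finite and >= 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "reflectivities", refl)

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])

    @staticmethod
    def empty(seed: int = 0) -> "ScattererField":
        return ScattererField(np.zeros((0, 3)), np.zeros(0), seed)


@dataclass(frozen=True)
class Scene:
    """Everything the scanner insonifies: a medium, a scatterer field and an
    additive receiver-noise level (RF units; 0 = noiseless)."""

    medium: Medium
    scatterers: "ScattererField"
    noise_std: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ConfigError("noise_std must be >= 0")

    @staticmethod
    def empty(medium: Medium | None = None) -> "Scene":
        return Scene(medium or water(), ScattererField.empty())


@dataclass(frozen=True)
class Inclusion:
    """Spherical bright inclusion: scatterers inside get ``amplitude``."""

    center: tuple[float, float, float]
    radius: float
    amplitude: float


@dataclass(frozen=True)
class PhantomSpec:
    """Random-phantom recipe.

    ``bounds`` are full extents (X, E, Z) in meters; scatterers are drawn
    uniformly over ``x in [-X/2, X/2]``, ``e in [-E/2, E/2]``,
    ``z in (0, Z]``.  ``density`` is scatterers per cm^3.  The reflectivity
    distribution is a named family (``rayleigh``, ``uniform`` or
    ``lognormal``) with parameters.
    """

    bounds: tuple[float, float, float]
    density: float = 0.0
    reflectivity: str = "rayleigh"
    reflectivity_params: dict = field(default_factory=dict)
    inclusions: tuple[Inclusion, ...] = ()

    def __post_init__(self) -> None:
        if any(not b > 0 for b in self.bounds):
            raise ConfigError(f"phantom extents must be > 0, got {self.bounds}")
        if self.density < 0:
            raise ConfigError("scatterer density must be >= 0")
        if self.reflectivity not in ("rayleigh", "uniform", "lognormal"):
            raise ConfigError(
                f"unknown reflectivity family {self.reflectivity!r}"
            )

    @property
    def volume_cm3(self) -> float:
        x, e, z = self.bounds
        return x * e * z * 1e6


def _draw_reflectivities(spec: PhantomSpec, n: int, rng: np.random.Generator):
    p = spec.reflectivity_params
    if spec.reflectivity == "rayleigh":
        return rng.rayleigh(scale=p.get("scale", 0.3), size=n)
    if spec.reflectivity == "uniform":
        return rng.uniform(p.get("low", 0.0), p.get("high", 1.0), size=n)
    return rng.lognormal(p.get("mean", -1.5), p.get("sigma", 0.5), size=n)


def make_phantom(spec: PhantomSpec, seed: int) -> ScattererField:
    """Draw a reproducible scatterer field from a phantom recipe.

    The scatterer count is ``round(density * volume)``; the same
    ``(spec, seed)`` always yields bit-identical arrays.
    """
    n = int(round(spec.density * spec.volume_cm3))
    rng = np.random.default_rng(seed)
    x_ext, e_ext, z_ext = spec.bounds
    pos = np.empty((n, 3))
    pos[:, 0] = rng.uniform(-x_ext / 2, x_ext / 2, size=n)
    pos[:, 1] = rng.uniform(-e_ext / 2, e_ext / 2, size=n)
    pos[:, 2] = rng.uniform(0.0, z_ext, size=n)
    # avoid z == 0 exactly (on the probe face)
    pos[:, 2] = np.maximum(pos[:, 2], 1e-6)
    refl = _draw_reflectivities(spec, n, rng)
    for inc in spec.inclusions:
        d2 = np.sum((pos - np.asarray(inc.center)) ** 2, axis=1)
        refl = np.where(d2 <= inc.radius**2, inc.amplitude, refl)
    return ScattererField(pos, refl, seed)
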