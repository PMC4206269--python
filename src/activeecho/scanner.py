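"""Linear-array B-mode acquisition and the coupled AE-device event loop.

The scanner fires one focused (or plane) transmit beam per scan line, in
order, and records one pre-beamformed RF line per event.  The transmit beam
is summarized by a separable Gaussian amplitude field (lateral and
elevational sigmas plus an on-axis peak amplitude); echo timing uses the
axial round-trip time only, so the axial position of a point target in the
image is exact by construction.

The event loop couples acquisition to the active-echo element: for every
line the beacon amplitude at the element is evaluated, the comparator is
run on the (band-passed, optionally noisy) received trace, and — if the
device mode and blink gate permit — an echo firing or the planned pattern
firings for that line are superimposed on the synthesized RF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .device import (
    AEDevice,
    Firing,
    TriggerEvent,
    blink_gate,
    frontend_filter,
    make_firing,
    receive_voltage,
    trigger_decision,
)
from .errors import ConfigError, GeometryError, PlanError
from .scene import Medium, Scene, one_way_time

__all__ = [
    "LinearProbe",
    "BeamProfile",
    "RFFrame",
    "TriggerLog",
    "MODE_PRESETS",
    "preset_probe",
    "gabor",
    "gabor_waveform",
    "line_schedule",
    "make_beam_profile",
    "beam_amplitude",
    "synthesize_rf_line",
    "acquire_frame",
    "acquire_sequence",
]


#: Imaging-mode presets: transmit center frequency, receive band, and the
#: fraction of echo energy returned at the second harmonic (band bookkeeping
#: only — harmonic generation physics is not modelled).
MODE_PRESETS: dict[str, dict] = {
    "general": {"f0_tx": 10.0e6, "rx_band": (7.0e6, 13.0e6), "harmonic": False},
    "resolution": {"f0_tx": 10.0e6, "rx_band": (8.5e6, 14.5e6), "harmonic": False},
    "penetration": {"f0_tx": 6.6e6, "rx_band": (4.0e6, 9.0e6), "harmonic": False},
    "harmonic": {"f0_tx": 5.0e6, "rx_band": (8.0e6, 12.0e6), "harmonic": True},
}


@dataclass(frozen=True)
class LinearProbe:
    """Linear-array probe and acquisition settings (SI units).

    Defaults model a 128-element, 0.3 mm pitch linear probe firing 256 lines
    per frame with a 32-element transmit aperture focused at 4 cm.
    ``focus_depth=None`` selects an unfocused (constant-width) beam.
    ``elev_sigma`` is the elevational Gaussian beam sigma (no elevation
    focusing is modelled).
    """

    n_elements: int = 128
    pitch: float = 0.3e-3
    f0_tx: float = 10.0e6
    rx_band: tuple[float, float] = (7.0e6, 13.0e6)
    fs: float = 40.0e6
    lines_per_frame: int = 256
    tx_aperture: int = 32
    focus_depth: float | None = 0.04
    tx_power: float = 1.0
    line_period: float = 200e-6
    max_depth: float = 0.05
    tx_cycles: int = 2
    elev_sigma: float = 3.0e-3
    harmonic: bool = False
    harmonic_fraction: float = 0.1
    mode: str = "general"

    def __post_init__(self) -> None:
        if self.lines_per_frame < 1:
            raise ConfigError("lines_per_frame must be >= 1")
        if not self.fs > 2 * self.rx_band[1]:
            raise ConfigError(
                f"fs={self.fs:g} must exceed twice the receive band top "
                f"({self.rx_band[1]:g} Hz)"
            )
        if self.tx_aperture > self.n_elements:
            raise ConfigError("tx_aperture cannot exceed n_elements")
        if self.tx_power < 0:
            raise ConfigError("tx_power must be >= 0")
        if self.max_depth <= 0 or self.line_period <= 0:
            raise ConfigError("max_depth and line_period must be > 0")

    @property
    def aperture_width(self) -> float:
        return self.tx_aperture * self.pitch

    @property
    def footprint(self) -> float:
        return self.n_elements * self.pitch

    @property
    def tx_pulse_duration(self) -> float:
        return self.tx_cycles / self.f0_tx

    def n_samples(self, assumed_c: float) -> int:
        return int(round(2 * self.max_depth / assumed_c * self.fs))

    def at(self, **kw) -> "LinearProbe":
        return replace(self, **kw)


def preset_probe(mode: str = "general", **overrides) -> LinearProbe:
    """Probe configured for one of the named imaging modes."""
    if mode not in MODE_PRESETS:
        raise ConfigError(
            f"unknown imaging mode {mode!r}; choose from {sorted(MODE_PRESETS)}"
        )
    kw = dict(MODE_PRESETS[mode], mode=mode)
    kw.update(overrides)
    return LinearProbe(**kw)


def gabor(t, f: float, cycles: int):
    """Gaussian-windowed cosine of unit peak amplitude.

    Duration ``T = cycles / f``; the Gaussian sigma is T/6 so the envelope
    is essentially confined to ``|t| <= T/2``.
    """
    t = np.asarray(t, dtype=float)
    sigma = cycles / f / 6.0
    return np.exp(-(t**2) / (2 * sigma**2)) * np.cos(2 * np.pi * f * t)


def gabor_waveform(f: float, cycles: int, fs: float, amplitude: float = 1.0):
    """Sampled Gabor pulse; returns (samples, center_index)."""
    half = int(math.ceil(cycles / f / 2.0 * fs))
    j = np.arange(-half, half + 1)
    return amplitude * gabor(j / fs, f, cycles), half


def line_schedule(probe: LinearProbe) -> list[tuple[int, float, float]]:
    """(line index, lateral beam center, start time) for one frame.

    Lines span the array footprint uniformly (centered on x = 0) and start
    at ``index * line_period``.
    """
    dx = probe.footprint / probe.lines_per_frame
    return [
        (i, -probe.footprint / 2 + (i + 0.5) * dx, i * probe.line_period)
        for i in range(probe.lines_per_frame)
    ]


@dataclass(frozen=True)
class BeamProfile:
    """Separable Gaussian transmit-beam summary.

    Unfocused: constant lateral sigma ``aperture_width / 4``.  Focused: a
    hyperbolic waist with minimum ``lambda * focus_depth / aperture_width``
    at the focus, opening back to the unfocused width at the probe face.
    The on-axis peak amplitude carries transmit power, aperture size and
    focusing gain (amplitude ~ 1 / lateral width, a crude energy argument).
    """

    sigma0: float
    waist: float | None
    focus_depth: float | None
    z_r: float | None
    elev_sigma_const: float
    base_amplitude: float

    def lateral_sigma(self, z):
        z = np.asarray(z, dtype=float)
        if self.waist is None or self.focus_depth is None:
            out = np.full_like(z, self.sigma0)
        else:
            out = self.waist * np.sqrt(1.0 + ((z - self.focus_depth) / self.z_r) ** 2)
        return out if out.ndim else float(out)

    def elev_sigma(self, z):
        z = np.asarray(z, dtype=float)
        out = np.full_like(z, self.elev_sigma_const)
        return out if out.ndim else float(out)

    def peak_amplitude(self, z):
        out = self.base_amplitude * self.sigma0 / np.asarray(
            self.lateral_sigma(z), dtype=float
        )
        return out if out.ndim else float(out)


def make_beam_profile(probe: LinearProbe, c: float = 1540.0) -> BeamProfile:
    """Beam summary for a probe in a medium with sound speed ``c``."""
    sigma0 = probe.aperture_width / 4.0
    base = probe.tx_power * probe.tx_aperture / 32.0
    if probe.focus_depth is None:
        return BeamProfile(sigma0, None, None, None, probe.elev_sigma, base)
    lam = c / probe.f0_tx
    waist = lam * probe.focus_depth / probe.aperture_width
    if waist >= sigma0:  # aperture too small to focus tighter than it is wide
        return BeamProfile(sigma0, None, None, None, probe.elev_sigma, base)
    z_r = probe.focus_depth / math.sqrt((sigma0 / waist) ** 2 - 1.0)
    return BeamProfile(sigma0, waist, probe.focus_depth, z_r, probe.elev_sigma, base)


def beam_amplitude(
    probe: LinearProbe,
    profile: BeamProfile,
    line_x: float,
    point,
    medium: Medium | None = None,
):
    """Transmit-field amplitude of one beam at a 3-D point (x, e, z),
    including one-way frequency-dependent attenuation when a medium is given.
    """
    x, e, z = (float(v) for v in point)
    if z <= 0:
        raise GeometryError(f"point depth must be > 0, got z={z}")
    if z > probe.max_depth:
        raise GeometryError(f"point depth {z} beyond max_depth {probe.max_depth}")
    sl = profile.lateral_sigma(z)
    se = profile.elev_sigma(z)
    amp = (
        profile.peak_amplitude(z)
        * math.exp(-((x - line_x) ** 2) / (2 * sl**2))
        * math.exp(-(e**2) / (2 * se**2))
    )
    if medium is not None:
        amp *= float(medium.amp_factor(z, probe.f0_tx))
    return amp


@dataclass(frozen=True)
class RFFrame:
    """One frame of per-line RF data."""

    samples: np.ndarray  # (lines_per_frame, n_samples)
    fs: float
    line_x: np.ndarray  # lateral beam centers, strictly increasing
    frame_start: float = 0.0
    line_period: float = 200e-6

    def __post_init__(self) -> None:
        lx = np.asarray(self.line_x, dtype=float)
        if np.any(np.diff(lx) <= 0):
            raise ConfigError("line_x must be strictly increasing")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "line_x", lx)

    @property
    def n_lines(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class TriggerLog:
    """Comparator events for one frame; at most one per line (latch rule)."""

    events: list[TriggerEvent] = field(default_factory=list)
    frame_index: int = 0

    @property
    def count(self) -> int:
        return len(self.events)

    @property
    def peak_amplitude(self) -> float:
        return max((ev.amplitude_v for ev in self.events), default=0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "line": [ev.line_index for ev in self.events],
                "time_us": [ev.t_trigger * 1e6 for ev in self.events],
                "amplitude": [ev.amplitude_v for ev in self.events],
            }
        )


def _rx_bandpass_sos(probe: LinearProbe):
    lo, hi = probe.rx_band
    hi = min(hi, 0.49 * probe.fs)
    return _sig.butter(4, [lo, hi], btype="bandpass", fs=probe.fs, output="sos")


def _add_packets(samples, fs, t_centers, amps, f, cycles):
    """Accumulate Gabor packets (vector of centers/amplitudes) into a line,
    with exact fractional-sample placement."""
    t_centers = np.atleast_1d(np.asarray(t_centers, dtype=float))
    amps = np.atleast_1d(np.asarray(amps, dtype=float))
    if t_centers.size == 0:
        return
    n = samples.shape[0]
    half = int(math.ceil(cycles / f / 2.0 * fs)) + 1
    k0 = np.round(t_centers * fs).astype(int)
    j = np.arange(-half, half + 1)
    idx = k0[:, None] + j[None, :]
    tt = idx / fs - t_centers[:, None]
    vals = amps[:, None] * gabor(tt, f, cycles)
    ok = (idx >= 0) & (idx < n)
    np.add.at(samples, idx[ok], vals[ok])


def _ae_path_time(position, line_x: float, medium: Medium) -> float:
    """Straight-ray travel time from the element to a line's aperture
    center (line_x, 0, 0), scaling the axial layered travel time by the
    oblique path-length ratio."""
    x, e, z = position
    if z <= 0:
        raise GeometryError("element must be below the probe face (z > 0)")
    d = math.sqrt((x - line_x) ** 2 + e**2 + z**2)
    return float(one_way_time(z, medium)) * (d / z)


def synthesize_rf_line(
    probe: LinearProbe,
    scene: Scene,
    line,
    ae_firings: list[Firing] = (),
    ae_position=None,
    profile: BeamProfile | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize one band-passed RF line.

    The line is the superposition of (a) scatterer echoes — a transmit-pulse
    replica at the axial round-trip time, scaled by beam amplitude,
    reflectivity and two-way attenuation — and (b) AE contributions arriving
    at ``fire_time`` plus the element-to-aperture-center travel time.
    ``line`` may be a ``(index, line_x, t_start)`` schedule entry or a bare
    lateral position.
    """
    line_x = float(line[1]) if isinstance(line, (tuple, list)) else float(line)
    medium = scene.medium
    n = probe.n_samples(medium.assumed_c)
    samples = np.zeros(n)
    if profile is None:
        profile = make_beam_profile(probe, medium.c0)

    sc = scene.scatterers
    if sc.n:
        pos = sc.positions
        z = pos[:, 2]
        in_range = (z > 0) & (z <= min(probe.max_depth, medium.bounded_depth))
        if in_range.any():
            pz = pos[in_range]
            refl = sc.reflectivities[in_range]
            zs = pz[:, 2]
            sl = np.asarray(profile.lateral_sigma(zs))
            se = np.asarray(profile.elev_sigma(zs))
            amp = (
                np.asarray(profile.peak_amplitude(zs))
                * np.exp(-((pz[:, 0] - line_x) ** 2) / (2 * sl**2))
                * np.exp(-(pz[:, 1] ** 2) / (2 * se**2))
                * np.asarray(medium.amp_factor(zs, probe.f0_tx))
            )
            f_echo = probe.f0_tx
            if probe.harmonic:
                f_echo = 2 * probe.f0_tx
                amp = amp * probe.harmonic_fraction
            amp = amp * refl * np.asarray(medium.amp_factor(zs, f_echo))
            t_echo = 2.0 * np.asarray(one_way_time(zs, medium))
            keep = amp > 1e-9 * (amp.max() if amp.size else 0.0)
            _add_packets(
                samples, probe.fs, t_echo[keep], amp[keep], f_echo, probe.tx_cycles
            )

    for fir in ae_firings:
        if not (0.0 <= fir.fire_time < probe.line_period):
            raise PlanError(
                f"firing at {fir.fire_time:.3e} s outside line window "
                f"[0, {probe.line_period:.3e})"
            )
        if ae_position is None:
            raise PlanError("ae_position required to place AE firings")
        t_arr = fir.fire_time + _ae_path_time(ae_position, line_x, medium)
        amp = fir.amplitude * float(
            scene.medium.amp_factor(ae_position[2], fir.freq)
        )
        _add_packets(samples, probe.fs, [t_arr], [amp], fir.freq, fir.cycles)

    if rng is not None and scene.noise_std > 0:
        samples += rng.normal(0.0, scene.noise_std, size=n)

    sos = _rx_bandpass_sos(probe)
    return _sig.sosfiltfilt(sos, samples)


def _plan_by_line(plan) -> dict[int, list]:
    by_line: dict[int, list] = {}
    for entry in plan.firings:
        by_line.setdefault(entry.line_index, []).append(entry)
    return by_line


def acquire_frame(
    probe: LinearProbe,
    scene: Scene,
    device: AEDevice | None = None,
    plan=None,
    frame_start: float = 0.0,
    frame_index: int = 0,
    rng: np.random.Generator | None = None,
    rf: bool = True,
):
    """Run one frame of the coupled acquisition / AE-device event loop.

    Per line, in order: beacon amplitude at the element, comparator
    decision (logged with the latch rule: at most one event per line), then
    — mode and blink gate permitting — an echo firing ``loop_delay`` after
    the beacon or the plan's firings for that line.  Returns
    ``(RFFrame | None, TriggerLog)``; pass ``rf=False`` to skip RF synthesis
    when only trigger statistics are needed (sweeps).
    """
    medium = scene.medium
    if probe.line_period < 2 * probe.max_depth / medium.assumed_c:
        raise ConfigError("line_period shorter than the round-trip listen window")
    if plan is not None:
        bad = [f.line_index for f in plan.firings if f.line_index >= probe.lines_per_frame]
        if bad:
            raise PlanError(f"plan references lines beyond the frame: {sorted(set(bad))}")

    sched = line_schedule(probe)
    profile = make_beam_profile(probe, medium.c0)
    log = TriggerLog(frame_index=frame_index)
    n = probe.n_samples(medium.assumed_c)
    lines = np.zeros((probe.lines_per_frame, n)) if rf else None
    plan_by_line = _plan_by_line(plan) if plan is not None else {}

    dev_on = device is not None and device.mode != "off"
    ref_norm = None
    if dev_on:
        # l2 norm of the front-end-filtered unit-peak beacon shape: the
        # calibration the device uses to convert packet energy to peak volts
        buf = np.zeros(512)
        _add_packets(buf, probe.fs, [256 / probe.fs], [1.0], probe.f0_tx, probe.tx_cycles)
        ref_norm = float(np.linalg.norm(frontend_filter(buf, probe.fs)))
        x_e, e_e, z_e = device.position
        if z_e <= 0 or z_e > probe.max_depth:
            raise GeometryError("device must lie inside the imaged region")
        beam_dir = np.array([0.0, 0.0, 1.0])
        axis = np.asarray(device.orientation, dtype=float)
        axis = axis / np.linalg.norm(axis)
        incidence = math.degrees(math.asin(min(1.0, abs(float(beam_dir @ axis)))))

    for i, line_x, t_line in sched:
        firings: list[Firing] = []
        if dev_on:
            p_amp = beam_amplitude(probe, profile, line_x, device.position, medium)
            v_peak = receive_voltage(p_amp, device, incidence)
            t_b = _ae_path_time(device.position, line_x, medium)
            event = None
            noisy = device.noise_std > 0
            # a line whose beacon peak is far below threshold (allowing for
            # an 8-sigma noise excursion) cannot trigger; skip its trace
            possible = v_peak >= min(
                0.5 * device.threshold,
                device.threshold - 8.0 * device.noise_std,
            )
            if possible:
                trace = np.zeros(n)
                _add_packets(
                    trace, probe.fs, [t_b], [v_peak], probe.f0_tx, probe.tx_cycles
                )
                trace = frontend_filter(trace, probe.fs)
                if noisy:
                    if rng is None:
                        rng = np.random.default_rng(0)
                    trace = trace + rng.normal(0.0, device.noise_std, size=n)
                event = trigger_decision(
                    trace,
                    device.threshold,
                    probe.fs,
                    line_index=i,
                    t_beacon=t_b,
                    ref_norm=ref_norm,
                )
            if event is not None:
                log.events.append(event)
            gate_open = blink_gate(frame_start + t_line, device)
            if device.mode == "echo" and event is not None and gate_open:
                firings.append(make_firing(event, device))
            elif device.mode == "pattern" and gate_open:
                for entry in plan_by_line.get(i, []):
                    firings.append(
                        Firing(
                            fire_time=entry.fire_time,
                            freq=device.pulse_freq,
                            cycles=device.pulse_cycles,
                            amplitude=entry.amplitude
                            * device.drive_voltage
                            / 150.0,
                        )
                    )
        if rf:
            lines[i] = synthesize_rf_line(
                probe,
                scene,
                (i, line_x, t_line),
                firings,
                ae_position=device.position if dev_on else None,
                profile=profile,
                rng=rng,
            )

    frame = None
    if rf:
        frame = RFFrame(
            samples=lines,
            fs=probe.fs,
            line_x=np.array([s[1] for s in sched]),
            frame_start=frame_start,
            line_period=probe.line_period,
        )
    return frame, log


def acquire_sequence(
    probe: LinearProbe,
    scene: Scene,
    device: AEDevice | None = None,
    n_frames: int = 1,
    frame_period: float | None = None,
    plan=None,
    rng: np.random.Generator | None = None,
    rf: bool = True,
):
    """Acquire a sequence of frames at a fixed frame period (default: the
    frame's own duration, i.e. back-to-back acquisition)."""
    if frame_period is None:
        frame_period = probe.lines_per_frame * probe.line_period
    frames, logs = [], []
    for k in range(n_frames):
        fr, log = acquire_frame(
            probe,
            scene,
            device,
            plan=plan,
            frame_start=k * frame_period,
            frame_index=k,
            rng=rng,
            rf=rf,
        )
        frames.append(fr)
        logs.append(log)
    return frames, logs
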