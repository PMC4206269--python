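"""Scenario configuration, reproducible experiment runner and fixtures.

A scenario is a YAML file describing probe, medium, phantom, device,
pattern and experiment; values accept explicit unit suffixes (``4 cm``,
``10 MHz``, ``200 us``) and are normalized to SI on load.  ``run_scenario``
executes the experiment deterministically for a fixed seed and writes an
artifact manifest with content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import yaml
from PIL import Image

from . import analysis, imaging, injection
from .device import AEDevice
from .errors import ConfigError
from .injection import BarConfig, PatternSpec, Pixel, midplane_bars, pattern_from_bitmap
from .scanner import LinearProbe, acquire_frame, acquire_sequence, preset_probe
from .scene import Inclusion, Layer, Medium, PhantomSpec, Scene, ScattererField, make_phantom

__all__ = ["Scenario", "load_scenario", "run_scenario", "make_fixtures", "FIXTURE_KINDS"]

log = logging.getLogger(__name__)

_UNIT_FACTORS = {
    "m": 1.0,
    "cm": 1e-2,
    "mm": 1e-3,
    "um": 1e-6,
    "in": 25.4e-3,
    "s": 1.0,
    "ms": 1e-3,
    "us": 1e-6,
    "ns": 1e-9,
    "hz": 1.0,
    "khz": 1e3,
    "mhz": 1e6,
    "v": 1.0,
    "db": 1.0,
    "m/s": 1.0,
}


def parse_quantity(value, key: str = "?"):
    """Number or 'number unit' string -> SI float (or None for 'none')."""
    if value is None or (isinstance(value, str) and value.strip().lower() == "none"):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split()
    try:
        num = float(parts[0])
    except ValueError as exc:
        raise ConfigError(f"cannot parse quantity for key {key!r}: {value!r}") from exc
    if len(parts) == 1:
        return num
    unit = parts[1].lower()
    if unit not in _UNIT_FACTORS:
        raise ConfigError(f"unknown unit {parts[1]!r} for key {key!r}")
    return num * _UNIT_FACTORS[unit]


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {unknown}")


@dataclass
class Scenario:
    """Fully resolved scenario: domain objects plus the raw resolved dict."""

    probe: LinearProbe
    scene: Scene
    device: AEDevice | None
    pattern: PatternSpec | None
    experiment: dict
    seed: int | None
    out_dir: Path
    resolved: dict

    def to_dict(self) -> dict:
        return self.resolved


_PROBE_KEYS = set(LinearProbe.__dataclass_fields__) | {"preset"}
_DEVICE_KEYS = set(AEDevice.__dataclass_fields__)
_TOP_KEYS = {
    "probe",
    "medium",
    "phantom",
    "device",
    "pattern",
    "experiment",
    "seed",
    "out_dir",
    "noise_std",
}
_EXPERIMENT_KINDS = {"single-frame", "sweep", "grid", "mmode", "inject", "bars", "modes"}


def _build_probe(cfg: dict) -> LinearProbe:
    cfg = dict(cfg or {})
    _check_keys(cfg, _PROBE_KEYS, "probe")
    preset = cfg.pop("preset", "general")
    quantity_keys = {
        "pitch",
        "f0_tx",
        "fs",
        "focus_depth",
        "line_period",
        "max_depth",
        "elev_sigma",
    }
    kw = {}
    for k, v in cfg.items():
        if k == "rx_band":
            kw[k] = tuple(parse_quantity(x, k) for x in v)
        elif k in quantity_keys:
            kw[k] = parse_quantity(v, k)
        else:
            kw[k] = v
    return preset_probe(preset, **kw)


def _build_medium(cfg: dict | None) -> Medium:
    if not cfg:
        from .scene import water

        return water()
    _check_keys(dict(cfg), {"layers", "assumed_c"}, "medium")
    layers = []
    for i, lay in enumerate(cfg.get("layers", [])):
        _check_keys(dict(lay), {"thickness", "c", "attenuation"}, f"medium.layers[{i}]")
        layers.append(
            Layer(
                parse_quantity(lay.get("thickness"), "thickness"),
                parse_quantity(lay["c"], "c"),
                float(lay.get("attenuation", 0.0)),
            )
        )
    return Medium(tuple(layers), assumed_c=parse_quantity(cfg.get("assumed_c", 1540.0), "assumed_c"))


def _build_phantom(cfg: dict | None, seed: int | None) -> ScattererField:
    if not cfg:
        return ScattererField.empty()
    cfg = dict(cfg)
    _check_keys(cfg, {"bounds", "density", "reflectivity", "inclusions"}, "phantom")
    refl = dict(cfg.get("reflectivity", {}) or {})
    family = refl.pop("family", "rayleigh")
    inclusions = tuple(
        Inclusion(
            tuple(parse_quantity(x, "inclusion.center") for x in inc["center"]),
            parse_quantity(inc["radius"], "inclusion.radius"),
            float(inc.get("amplitude", 1.0)),
        )
        for inc in cfg.get("inclusions", [])
    )
    spec = PhantomSpec(
        bounds=tuple(parse_quantity(x, "phantom.bounds") for x in cfg["bounds"]),
        density=float(cfg.get("density", 0.0)),
        reflectivity=family,
        reflectivity_params=refl,
        inclusions=inclusions,
    )
    if spec.density > 0 and seed is None:
        raise ConfigError("seed is required for a random phantom")
    return make_phantom(spec, 0 if seed is None else seed)


def _build_device(cfg: dict | None) -> AEDevice | None:
    if cfg is None:
        return None
    cfg = dict(cfg)
    _check_keys(cfg, _DEVICE_KEYS, "device")
    quantity_keys = {"loop_delay", "pulse_freq", "blink_period", "threshold", "drive_voltage"}
    kw = {}
    for k, v in cfg.items():
        if k in ("position", "orientation"):
            kw[k] = tuple(parse_quantity(x, k) for x in v)
        elif k in quantity_keys:
            kw[k] = parse_quantity(v, k)
        else:
            kw[k] = v
    return AEDevice(**kw)


def _build_pattern(cfg: dict | None) -> PatternSpec | None:
    if cfg is None:
        return None
    cfg = dict(cfg)
    _check_keys(
        cfg,
        {"anchor", "pixels", "bitmap", "line0", "depth0", "depth_step", "line_step"},
        "pattern",
    )
    if "bitmap" in cfg:
        return pattern_from_bitmap(
            cfg["bitmap"],
            line0=int(cfg.get("line0", 0)),
            depth0=parse_quantity(cfg.get("depth0", 0.02), "depth0"),
            depth_step=parse_quantity(cfg.get("depth_step", 1e-3), "depth_step"),
            line_step=int(cfg.get("line_step", 1)),
        )
    pixels = tuple(
        Pixel(int(p[0]), parse_quantity(p[1], "pattern.pixels"), float(p[2]) if len(p) > 2 else 1.0)
        for p in cfg.get("pixels", [])
    )
    return PatternSpec(pixels, frame_anchor=cfg.get("anchor", "absolute"))


def load_scenario(path) -> Scenario:
    """Parse and fully resolve a YAML scenario file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("scenario file must contain a mapping")
    _check_keys(raw, _TOP_KEYS, "scenario")
    seed = raw.get("seed")
    experiment = dict(raw.get("experiment", {"kind": "single-frame"}))
    kind = experiment.get("kind", "single-frame")
    if kind not in _EXPERIMENT_KINDS:
        raise ConfigError(f"unknown experiment kind {kind!r}")
    noise_std = float(raw.get("noise_std", 0.0))
    device = _build_device(raw.get("device"))
    stochastic = noise_std > 0 or (device is not None and device.noise_std > 0)
    if kind in ("sweep", "grid") or stochastic:
        if seed is None:
            raise ConfigError(f"experiment {kind!r} is stochastic; a seed is required")
    probe = _build_probe(raw.get("probe", {}))
    medium = _build_medium(raw.get("medium"))
    scatterers = _build_phantom(raw.get("phantom"), seed)
    scene = Scene(medium, scatterers, noise_std=noise_std)
    pattern = _build_pattern(raw.get("pattern"))
    return Scenario(
        probe=probe,
        scene=scene,
        device=device,
        pattern=pattern,
        experiment=experiment,
        seed=seed,
        out_dir=Path(raw.get("out_dir", "out")),
        resolved=raw,
    )


def _save_png(path: Path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels).astype(np.uint8)).save(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, files: list[Path], scenario: Scenario) -> dict:
    manifest = {
        "seed": scenario.seed,
        "experiment": scenario.experiment,
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _bmode_files(out: Path, frame, log_, sc: Scenario, stem: str = "bmode") -> list[Path]:
    img = imaging.form_bmode(frame, sc.scene.medium)
    files = []
    p = out / f"{stem}.png"
    _save_png(p, img.pixels)
    files.append(p)
    sidecar = out / f"{stem}.json"
    sidecar.write_text(
        json.dumps(
            {
                "axial_extent_m": img.axial_extent,
                "lateral_extent_m": img.lateral_extent,
                "dynamic_range_db": img.dynamic_range_db,
                "fs": img.fs,
                "assumed_c": img.assumed_c,
            },
            indent=2,
        )
    )
    files.append(sidecar)
    rf_path = out / f"{stem}_rf.npy"
    np.save(rf_path, frame.samples)
    files.append(rf_path)
    trig = out / "triggers.csv"
    log_.to_dataframe().to_csv(trig, index=False)
    files.append(trig)
    return files


def run_scenario(scenario: Scenario) -> dict:
    """Execute the scenario's experiment and write its artifacts.

    Returns the manifest (also written to ``manifest.json``); identical
    scenario + seed always produce hash-identical artifacts.
    """
    sc = scenario
    out = sc.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sc.seed if sc.seed is not None else 0)
    kind = sc.experiment.get("kind", "single-frame")
    files: list[Path] = []

    if kind == "single-frame":
        frame, log_ = acquire_frame(sc.probe, sc.scene, sc.device, rng=rng)
        files += _bmode_files(out, frame, log_, sc)
        log.info("frame acquired: %d triggers", log_.count)

    elif kind == "inject":
        dev = sc.device.at(mode="pattern")
        plan = injection.rasterize_sync(
            sc.pattern,
            sc.probe,
            dev.position,
            sc.scene.medium.c0,
            min_gap=dev.pulse_duration,
        )
        frame, log_ = acquire_frame(sc.probe, sc.scene, dev, plan=plan, rng=rng)
        files += _bmode_files(out, frame, log_, sc)
        plan_path = out / "plan.csv"
        plan.to_dataframe().to_csv(plan_path, index=False)
        files.append(plan_path)

    elif kind == "bars":
        # echo frame -> trigger count -> injected bar indicator
        _, log_ = acquire_frame(sc.probe, sc.scene, sc.device, rng=rng, rf=False)
        pattern = midplane_bars(log_.count, BarConfig())
        dev = sc.device.at(mode="pattern")
        plan = injection.rasterize_sync(
            pattern, sc.probe, dev.position, sc.scene.medium.c0,
            min_gap=dev.pulse_duration,
        )
        frame, _ = acquire_frame(sc.probe, sc.scene, dev, plan=plan, rng=rng)
        files += _bmode_files(out, frame, log_, sc)
        log.info("trigger count %d -> %d bars", log_.count, len(pattern.pixels))

    elif kind == "sweep":
        off = sc.experiment.get("offsets_mm", list(np.arange(-9.0, 9.1, 1.0)))
        offsets = np.asarray(off, dtype=float) * 1e-3
        sweep = analysis.midplane_sweep(
            sc.probe,
            sc.scene,
            sc.device,
            offsets,
            repeats=int(sc.experiment.get("repeats", 10)),
            seed=sc.seed,
        )
        csv = out / "sweep.csv"
        sweep.to_dataframe().to_csv(csv, index=False)
        files.append(csv)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.errorbar(sweep.offsets_mm, sweep.count_mean, yerr=sweep.count_std, fmt="o-")
        ax.set_xlabel("elevational offset (mm)")
        ax.set_ylabel("trigger count / frame")
        fig.tight_layout()
        png = out / "sweep.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        files.append(png)

    elif kind == "grid":
        grid = sc.experiment.get("grid") or {
            "tx_power": [0.25, 0.5, 1.0],
            "rx_gain_db": [10.0, 19.0, 25.0],
        }
        table = analysis.parameter_grid(sc.probe, sc.scene, sc.device, grid, seed=sc.seed)
        csv = out / "grid.csv"
        table.to_csv(csv, index=False)
        files.append(csv)
        names = list(grid)
        if len(names) >= 2:
            piv = table.pivot_table(
                index=names[0], columns=names[1], values="trigger_count", aggfunc="mean"
            )
            fig, ax = plt.subplots(figsize=(4.5, 3.6))
            im = ax.imshow(piv.values, origin="lower", aspect="auto", cmap="viridis")
            ax.set_xticks(range(len(piv.columns)), [str(c) for c in piv.columns])
            ax.set_yticks(range(len(piv.index)), [str(i) for i in piv.index])
            ax.set_xlabel(names[1])
            ax.set_ylabel(names[0])
            fig.colorbar(im, ax=ax, label="trigger count")
            fig.tight_layout()
            png = out / "grid.png"
            fig.savefig(png, dpi=120)
            plt.close(fig)
            files.append(png)

    elif kind == "mmode":
        n_frames = int(sc.experiment.get("n_frames", 40))
        fps = float(sc.experiment.get("fps", 20.0))
        frames, logs = acquire_sequence(
            sc.probe, sc.scene, sc.device, n_frames=n_frames, frame_period=1.0 / fps,
            rng=rng,
        )
        line_index = int(
            sc.experiment.get(
                "line_index",
                int(
                    np.argmin(
                        np.abs(frames[0].line_x - (sc.device.position[0] if sc.device else 0.0))
                    )
                ),
            )
        )
        mm = imaging.extract_mmode(frames, line_index)
        pix = imaging.log_compress(mm.columns)
        png = out / "mmode.png"
        _save_png(png, pix)
        files.append(png)
        counts = out / "frame_counts.csv"
        with counts.open("w") as fh:
            fh.write("frame,trigger_count\n")
            for lg in logs:
                fh.write(f"{lg.frame_index},{lg.count}\n")
        files.append(counts)

    elif kind == "modes":
        rows = {}
        for mode in ("harmonic", "general", "resolution", "penetration"):
            probe = _build_probe(dict(sc.resolved.get("probe", {}), preset=mode))
            on, _ = acquire_frame(probe, sc.scene, sc.device, rng=np.random.default_rng(sc.seed))
            off, _ = acquire_frame(
                probe, sc.scene, sc.device.at(mode="off"), rng=np.random.default_rng(sc.seed)
            )
            img_on = imaging.form_bmode(on, sc.scene.medium)
            img_off = imaging.form_bmode(off, sc.scene.medium)
            center = (
                int(np.argmin(np.abs(on.line_x - sc.device.position[0]))),
                img_on.depth_to_sample(sc.device.position[2]),
            )
            rep = analysis.compute_snr_cnr(img_on, img_off, center)
            rows[mode] = {"snr": rep.snr, "cnr": rep.cnr}
        metrics = out / "metrics.json"
        metrics.write_text(json.dumps(rows, indent=2, sort_keys=True))
        files.append(metrics)

    return _write_manifest(out, files, sc)


_JHU_BITMAP = "\n".join(
    [
        "JJJ  H H  U U",
        "  J  H H  U U",
        "  J  HHH  U U",
        "J J  H H  U U",
        " J   H H  UUU",
    ]
)

FIXTURE_KINDS = (
    "echo-basic",
    "jhu-pattern",
    "midplane-bars",
    "aluminum-layer",
    "deep-tissue",
    "mode-comparison",
)


def make_fixtures(kind: str, seed: int, out_dir="fixtures") -> Path:
    """Write a self-contained scenario file reproducing one of the named
    bench experiments at desk scale; returns the file path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    water_medium = {"assumed_c": 1480.0, "layers": [{"thickness": None, "c": 1480.0}]}
    phantom = {
        "bounds": ["40 mm", "12 mm", "50 mm"],
        "density": 40.0,
        "reflectivity": {"family": "rayleigh", "scale": 0.3},
    }
    device = {"position": [0.0, 0.0, "40 mm"], "mode": "echo"}

    if kind == "echo-basic":
        doc = {
            "seed": seed,
            "probe": {"preset": "general"},
            "medium": water_medium,
            "phantom": phantom,
            "device": device,
            "experiment": {"kind": "single-frame"},
        }
    elif kind == "jhu-pattern":
        doc = {
            "seed": seed,
            "probe": {"preset": "general"},
            "medium": water_medium,
            "phantom": dict(phantom, density=10.0),
            "device": dict(device, mode="pattern"),
            "pattern": {
                "bitmap": _JHU_BITMAP,
                "line0": 60,
                "depth0": "25 mm",
                "depth_step": "1.5 mm",
                "line_step": 8,
            },
            "experiment": {"kind": "inject"},
        }
    elif kind == "midplane-bars":
        doc = {
            "seed": seed,
            "probe": {"preset": "general"},
            "medium": water_medium,
            "phantom": dict(phantom, density=10.0),
            "device": dict(device, position=[0.0, "1.5 mm", "40 mm"]),
            "experiment": {"kind": "bars"},
        }
    elif kind == "aluminum-layer":
        doc = {
            "seed": seed,
            "probe": {"preset": "general", "max_depth": "70 mm"},
            "medium": {
                "assumed_c": 1480.0,
                "layers": [
                    {"thickness": "20 mm", "c": 1480.0},
                    {"thickness": "1 in", "c": 6320.0},
                    {"thickness": None, "c": 1480.0},
                ],
            },
            "phantom": None,
            "device": dict(device, position=[0.0, 0.0, "60 mm"], loop_delay=0.0),
            "experiment": {"kind": "single-frame"},
        }
    elif kind == "deep-tissue":
        doc = {
            "seed": seed,
            "probe": {"preset": "penetration", "max_depth": "90 mm", "focus_depth": "85 mm"},
            "medium": {
                "assumed_c": 1540.0,
                "layers": [{"thickness": None, "c": 1540.0, "attenuation": 0.5}],
            },
            "phantom": {
                "bounds": ["40 mm", "12 mm", "90 mm"],
                "density": 40.0,
                "reflectivity": {"family": "rayleigh", "scale": 0.3},
            },
            "device": dict(device, position=[0.0, 0.0, "85 mm"], rx_gain_db=30.0),
            "experiment": {"kind": "single-frame"},
        }
    elif kind == "mode-comparison":
        doc = {
            "seed": seed,
            "probe": {},
            "medium": {
                "assumed_c": 1540.0,
                "layers": [{"thickness": None, "c": 1540.0, "attenuation": 0.5}],
            },
            "phantom": dict(phantom, density=60.0),
            "device": device,
            "experiment": {"kind": "modes"},
        }
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")

    path = out / f"{kind}.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
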