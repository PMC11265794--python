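"""Configuration, file I/O, orchestration and provenance.

File conventions
----------------
* Raw image stacks: multi-page TIFF (16-bit integer in, 32-bit float out).
* Map series (thickness / displacement / stress): HDF5 bundles carrying the
  values, per-frame validity masks, units and sign-convention metadata; float
  maps round-trip bit-identically.
* Tables (tracks, events, latencies): CSV with header schemas; track tables
  are canonicalised (sorted by point then time) on load.
* Run configuration: a single YAML file with ``optics``, ``mechanics``,
  ``analysis`` and ``io`` blocks plus a top-level ``seed``; unknown keys are
  rejected before any computation.  Every run writes a JSON manifest with the
  config hash, input digests and per-stage parameters and timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, erism, kinematics, mechanics, optics, synthetic, warp

__all__ = [
    "ConfigError",
    "RunConfig",
    "RunManifest",
    "load_config",
    "build_layer_stack",
    "build_spectrum_grid",
    "build_mechanics",
    "build_scenario",
    "write_map_series",
    "read_map_series",
    "write_image_stack",
    "read_image_stack",
    "run_pipeline",
]

log = logging.getLogger("mechwarp")


class ConfigError(ValueError):
    """Configuration schema violation, reported with its key path."""


_ALLOWED = {
    "": {"seed", "optics", "mechanics", "analysis", "io", "scenario"},
    "optics": {
        "lambda_pair", "wavelength_grid", "thickness_range", "lookup_step",
        "layers", "ambient", "substrate", "cavity_layer_index", "materials",
    },
    "optics.wavelength_grid": {"start", "stop", "step"},
    "mechanics": {
        "youngs_modulus_pa", "poisson_ratio", "layer_thickness_nm",
        "pixel_size_um", "regularisation",
    },
    "analysis": {
        "v_on_um_s", "v_off_um_s", "min_swing_s", "contact_threshold_nm",
        "corner_fraction", "noise_floor", "probe_line", "kymo_width_px",
    },
    "io": {"out_dir", "stack", "video", "calibration", "tracks", "curve", "assume_units"},
}


def _check_keys(block: dict, path: str):
    allowed = _ALLOWED.get(path, None)
    if allowed is None:
        return
    for key in block:
        if key not in allowed:
            raise ConfigError(f"unknown config key {path + '.' if path else ''}{key}")
        if isinstance(block[key], dict):
            _check_keys(block[key], f"{path}.{key}" if path else key)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    seed: int = 0
    optics: dict = field(default_factory=dict)
    mechanics: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed, "optics": self.optics, "mechanics": self.mechanics,
                "analysis": self.analysis, "io": self.io, "scenario": self.scenario,
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(source) -> RunConfig:
    """Load and schema-validate a YAML config file (or a pre-parsed dict)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, "")
    for block in ("optics", "mechanics", "analysis", "io"):
        sub = raw.get(block, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"config block {block!r} must be a mapping")
        _check_keys(sub, block)
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        optics=raw.get("optics", {}),
        mechanics=raw.get("mechanics", {}),
        analysis=raw.get("analysis", {}),
        io=raw.get("io", {}),
        scenario=raw.get("scenario", {}),
    )


# ---------------------------------------------------------------------------
# builders


def _materials(cfg: dict) -> dict:
    mats = optics.default_materials()
    for name, spec in (cfg.get("materials") or {}).items():
        mats[name] = optics.OpticalMaterial.constant(name, float(spec["n"]), float(spec.get("k", 0.0)))
    return mats


def build_layer_stack(cfg: dict) -> optics.LayerStack:
    mats = _materials(cfg)
    if "layers" not in cfg or not cfg["layers"]:
        return optics.default_stack(mats)
    layers = tuple(
        (mats[item["material"]], float(item["thickness_nm"])) for item in cfg["layers"]
    )
    return optics.LayerStack(
        ambient=mats[cfg.get("ambient", "glass")],
        layers=layers,
        substrate=mats[cfg.get("substrate", "water")],
        cavity_layer_index=int(cfg.get("cavity_layer_index", len(layers) - 2)),
    )


def build_spectrum_grid(cfg: dict) -> optics.SpectrumGrid:
    g = cfg.get("wavelength_grid") or {}
    start = float(g.get("start", 550.0))
    stop = float(g.get("stop", 750.0))
    step = float(g.get("step", 1.0))
    return optics.SpectrumGrid(np.arange(start, stop + 0.5 * step, step))


def build_mechanics(cfg: dict, pixel_size_um: float | None = None) -> mechanics.SubstrateMechanics:
    return mechanics.SubstrateMechanics(
        youngs_modulus=float(cfg.get("youngs_modulus_pa", 28000.0)),
        poisson_ratio=float(cfg.get("poisson_ratio", 0.495)),
        layer_thickness=float(cfg.get("layer_thickness_nm", 10000.0)),
        pixel_size=float(pixel_size_um or cfg.get("pixel_size_um", 1.0)),
    )


def build_scenario(cfg: dict, seed: int | None = None) -> synthetic.CrawlScenario:
    kwargs = dict(cfg)
    for key in ("peak_depths_nm", "tripod_offset_um", "grf_area_law"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    if "shape" in kwargs:
        kwargs["shape"] = tuple(kwargs["shape"])
    if seed is not None:
        kwargs["seed"] = seed
    return synthetic.CrawlScenario(**kwargs)


def load_scenario(path) -> synthetic.CrawlScenario:
    with open(path) as fh:
        return build_scenario(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# map series and image stack I/O


def write_map_series(
    path,
    values: np.ndarray,
    valid: np.ndarray | None = None,
    units: str = "nm",
    pixel_size_um: float = 1.0,
    frame_rate: float | None = None,
    sign_convention: str = "negative = indentation",
    baseline_plane=None,
):
    """Write a (T, H, W) or (H, W) map series to an HDF5 bundle."""
    values = np.asarray(values)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=values)
        d.attrs["units"] = units
        d.attrs["sign_convention"] = sign_convention
        f.attrs["pixel_size_um"] = pixel_size_um
        f.attrs["mechwarp_version"] = __version__
        if frame_rate is not None:
            f.attrs["frame_rate"] = frame_rate
        if valid is not None:
            f.create_dataset("valid", data=np.asarray(valid, dtype=bool))
        if baseline_plane is not None:
            f.create_dataset("baseline_plane", data=np.asarray(baseline_plane, dtype=float))


def read_map_series(path, assume_units: str | None = None):
    """Read an HDF5 map bundle -> dict with values/valid/units/pixel_size/..."""
    with h5py.File(path, "r") as f:
        d = f["values"]
        units = d.attrs.get("units")
        if units is None:
            if assume_units is None:
                raise ValueError(f"{path}: no units metadata (pass assume_units to override)")
            units = assume_units
        out = {
            "values": d[()],
            "units": units,
            "pixel_size_um": float(f.attrs.get("pixel_size_um", 1.0)),
            "frame_rate": float(f.attrs["frame_rate"]) if "frame_rate" in f.attrs else None,
            "valid": f["valid"][()] if "valid" in f else None,
            "baseline_plane": tuple(f["baseline_plane"][()]) if "baseline_plane" in f else None,
        }
    return out


def write_image_stack(path, frames: np.ndarray, dtype=np.float32):
    """Write an image stack as multi-page TIFF (32-bit float by default)."""
    tifffile.imwrite(path, np.asarray(frames, dtype=dtype), photometric="minisblack")


def read_image_stack(path) -> np.ndarray:
    """Read a multi-page TIFF; integer input is preserved as integers."""
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# manifest and pipeline


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    seed: int
    inputs: dict = field(default_factory=dict)  # path -> sha256
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    failure: dict | None = None

    def to_dict(self) -> dict:
        return {
            "tool_version": self.tool_version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "inputs": self.inputs,
            "stages": self.stages,
            "outputs": self.outputs,
            "failure": self.failure,
        }

    def write(self, path):
        """Atomic JSON write (temp file + rename)."""
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        with open(tmp, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        os.replace(tmp, path)


def _sha256(path) -> str:
    hsh = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            hsh.update(chunk)
    return hsh.hexdigest()


_STAGE_ORDER = ("simulate", "erism", "warp", "stress", "footfall", "kinematics")


def run_pipeline(config: RunConfig, stages, out_dir=None) -> RunManifest:
    """Execute pipeline stages in dependency order and write a manifest.

    Supported stages: ``simulate`` (synthetic scenario -> truth + rendered
    video), ``erism`` (spectral TIFF -> thickness/displacement maps), ``warp``
    (interleaved video -> displacement series), ``stress`` (displacement ->
    stress maps + GRFs), ``footfall`` (contact areas/volumes per ROI),
    ``kinematics`` (track CSV -> footfall events).  A stage failure stops the
    run but leaves completed outputs and a failure record in the manifest.
    """
    requested = [s for s in _STAGE_ORDER if s in set(stages)]
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(out_dir or config.io.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(__version__, config.digest(), config.seed)

    ctx: dict = {}
    for name in requested:
        t0 = time.perf_counter()
        try:
            params = _run_stage(name, config, ctx, out, manifest)
        except Exception as exc:  # record and stop; completed outputs remain
            manifest.failure = {"stage": name, "error": f"{type(exc).__name__}: {exc}"}
            log.error("stage %s failed: %s", name, exc)
            break
        manifest.stages.append(
            {"name": name, "seconds": round(time.perf_counter() - t0, 3), "params": params}
        )
        log.info("stage %s done in %.2fs", name, manifest.stages[-1]["seconds"])
    manifest.write(out / "manifest.json")
    return manifest


def _run_stage(name, config, ctx, out, manifest):
    if name == "simulate":
        sc = build_scenario(config.scenario, seed=config.seed)
        bundle = synthetic.simulate_crawl(sc)
        stack = build_layer_stack(config.optics)
        video = synthetic.render_interference(
            bundle.thickness, stack, mode="two_wavelength",
            lambda_pair=tuple(config.optics.get("lambda_pair", optics.DEFAULT_LAMBDA_PAIR)),
            noise_fraction=sc.intensity_noise, seed=sc.seed,
            pixel_size_um=sc.pixel_size_um, map_rate=sc.map_rate,
            jitter_nm=sc.displacement_jitter_nm,
        )
        write_image_stack(out / "video.tif", video.frames)
        write_map_series(
            out / "truth_displacement.h5", bundle.displacement, units="nm",
            pixel_size_um=sc.pixel_size_um, frame_rate=sc.map_rate,
        )
        bundle.events.to_csv(out / "truth_events.csv", index=False)
        ctx["bundle"], ctx["video"], ctx["stack"] = bundle, video, stack
        manifest.outputs["video"] = str(out / "video.tif")
        log.info("simulate: %d frames %s px, %d protopodia",
                 len(bundle.times), bundle.displacement.shape[1:], sc.n_protopodia)
        return {"n_frames": len(bundle.times), "n_protopodia": sc.n_protopodia, "seed": sc.seed}

    if name == "erism":
        stack_img = ctx.get("spectral") or read_image_stack(
            config.io["stack"]
        )
        grid = build_spectrum_grid(config.optics)
        device = ctx.get("stack") or build_layer_stack(config.optics)
        spectral = erism.SpectralStack(
            np.asarray(stack_img, dtype=float), grid,
            float(config.mechanics.get("pixel_size_um", 1.0)),
        )
        lookup = optics.build_thickness_lookup(
            device, grid,
            tuple(config.optics.get("thickness_range", (8000.0, 12000.0))),
            float(config.optics.get("lookup_step", 1.0)),
        )
        tmap = erism.reconstruct_thickness(spectral, lookup)
        dmap = erism.subtract_reference_plane(
            tmap, float(config.analysis.get("corner_fraction", 0.05))
        )
        write_map_series(
            out / "thickness.h5", tmap.values, tmap.valid, units="nm",
            pixel_size_um=tmap.pixel_size,
        )
        write_map_series(
            out / "displacement.h5", dmap.values, dmap.valid, units="nm",
            pixel_size_um=dmap.pixel_size, baseline_plane=dmap.baseline_plane,
        )
        ctx["displacement"] = [dmap]
        ctx["pixel_size"] = dmap.pixel_size
        manifest.outputs["displacement"] = str(out / "displacement.h5")
        return {"shape": list(tmap.values.shape), "valid_fraction": float(tmap.valid.mean())}

    if name == "warp":
        if "video" in ctx:
            video = ctx["video"]
            bundle = ctx["bundle"]
            sc = bundle.scenario
            baseline = erism.ThicknessMap(
                np.full(sc.shape, sc.rest_thickness_nm), sc.pixel_size_um,
                np.ones(sc.shape, dtype=bool),
            )
            device = ctx["stack"]
            cal = _model_calibration(device, config, sc.rest_thickness_nm)
        else:
            frames = read_image_stack(config.io["video"])
            video = warp.InterleavedStack(np.asarray(frames, dtype=float), 120.0)
            base = read_map_series(config.io["calibration"])
            baseline = erism.ThicknessMap(
                base["values"], base["pixel_size_um"],
                base["valid"] if base["valid"] is not None else np.ones_like(base["values"], bool),
            )
            device = build_layer_stack(config.optics)
            cal = _model_calibration(device, config, float(np.median(base["values"])))
        maps, rate = warp.process_video(video, cal, baseline)
        write_map_series(
            out / "displacement.h5", np.stack([m.values for m in maps]),
            np.stack([m.valid for m in maps]), units="nm",
            pixel_size_um=maps[0].pixel_size, frame_rate=rate,
        )
        ctx["displacement"] = maps
        ctx["map_rate"] = rate
        ctx["pixel_size"] = maps[0].pixel_size
        manifest.outputs["displacement"] = str(out / "displacement.h5")
        return {"n_maps": len(maps), "map_rate": rate, "fsr_nm": cal.fsr_nm}

    if name == "stress":
        maps = ctx.get("displacement") or _maps_from_file(config)
        mech = build_mechanics(config.mechanics, ctx.get("pixel_size"))
        reg = float(config.mechanics.get("regularisation", 1e-3))
        stress_stack = [mechanics.stress_from_displacement(m, mech, reg) for m in maps]
        write_map_series(
            out / "stress.h5", np.stack([s.values for s in stress_stack]),
            np.stack([s.valid for s in stress_stack]), units="Pa",
            pixel_size_um=mech.pixel_size,
            sign_convention="negative = pushing into substrate",
        )
        ctx["stress"] = stress_stack
        manifest.outputs["stress"] = str(out / "stress.h5")
        if "bundle" in ctx:
            rois = ctx["bundle"].rois
            grf = np.array(
                [[mechanics.integrate_grf(s, roi) for roi in rois] for s in stress_stack]
            )
            pd.DataFrame(
                grf, columns=[f"protopodium_{i}" for i in range(rois.shape[0])]
            ).to_csv(out / "grf.csv", index=False)
            manifest.outputs["grf"] = str(out / "grf.csv")
        return {"n_maps": len(stress_stack), "regularisation": reg}

    if name == "footfall":
        maps = ctx.get("displacement") or _maps_from_file(config)
        thr = float(config.analysis.get("contact_threshold_nm", 0.0))
        rois = ctx["bundle"].rois if "bundle" in ctx else [None]
        rows = []
        for f, m in enumerate(maps):
            for i, roi in enumerate(rois):
                area, _ = mechanics.contact_area(m, roi, min(thr, 0.0))
                vol = mechanics.displaced_volume(m, roi)
                rows.append({"frame": f, "roi": i, "contact_area_um2": area,
                             "displaced_volume_um3": vol})
        pd.DataFrame(rows).to_csv(out / "footfall.csv", index=False)
        manifest.outputs["footfall"] = str(out / "footfall.csv")
        return {"n_maps": len(maps), "threshold_nm": thr}

    if name == "kinematics":
        if "tracks" in config.io:
            tracks = kinematics.TrackTable.from_csv(config.io["tracks"], 60.0)
            manifest.inputs[str(config.io["tracks"])] = _sha256(config.io["tracks"])
        elif "bundle" in ctx:
            tracks = synthetic.simulate_tracks(ctx["bundle"].scenario)
        else:
            raise ConfigError("kinematics stage needs io.tracks or a simulated bundle")
        speeds = kinematics.point_velocities(tracks)
        events = []
        for pid, g in speeds.groupby("point_id"):
            evs = kinematics.segment_footfalls(
                g["time_s"].to_numpy(), g["speed_um_s"].to_numpy(),
                float(config.analysis.get("v_on_um_s", 20.0)),
                float(config.analysis.get("v_off_um_s", 10.0)),
                float(config.analysis.get("min_swing_s", 0.0)),
                point_id=pid,
            )
            events += [
                {"point_id": pid, "si_time": e.si_time, "st_time": e.st_time} for e in evs
            ]
        pd.DataFrame(events).to_csv(out / "events.csv", index=False)
        manifest.outputs["events"] = str(out / "events.csv")
        return {"n_points": len(tracks.point_ids()), "n_events": len(events)}

    raise ConfigError(f"unknown stage {name!r}")


def _model_calibration(device, config, anchor_thickness):
    """Calibration from a model-rendered thickness ramp spanning ~1.5 FSR."""
    pair = tuple(config.optics.get("lambda_pair", optics.DEFAULT_LAMBDA_PAIR))
    n = device.cavity_index(pair[0]).real
    fsr = pair[0] / (2.0 * n)
    ramp = np.linspace(anchor_thickness - 0.75 * fsr, anchor_thickness + 0.75 * fsr, 64)
    ramp2d = np.tile(ramp, (48, 1))
    w = optics.warp_response(device, ramp2d, pair)
    tmap = erism.ThicknessMap(ramp2d, 1.0, np.ones_like(ramp2d, dtype=bool))
    return warp.calibrate(w, tmap)


def _maps_from_file(config):
    data = read_map_series(config.io["stack"], config.io.get("assume_units"))
    valid = data["valid"]
    values = data["values"]
    if values.ndim == 2:
        values = values[None]
        valid = valid[None] if valid is not None else None
    return [
        erism.DisplacementMap(
            values[i], data["pixel_size_um"], (0.0, 0.0, 0.0),
            valid[i] if valid is not None else np.ones_like(values[i], dtype=bool),
        )
        for i in range(values.shape[0])
    ]
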