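"""Configuration-driven orchestration of generate -> condition -> analyze runs.

A run is described by a YAML config (scenario name, master seed, ordered
stage list with per-stage parameters, output directory). Every stage draws
its seed deterministically from the master seed and the stage name, writes
its artifacts under the output directory, and is recorded in a manifest with
content hashes so that reruns of deterministic stages reproduce identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "WorkflowError", "run", "report", "STAGES"]


class WorkflowError(RuntimeError):
    """Raised when a stage fails; carries the partial manifest path."""

    def __init__(self, message: str, manifest_path: Path | None = None):
        super().__init__(message)
        self.manifest_path = manifest_path


@dataclass
class RunConfig:
    """Validated run configuration."""

    scenario: str
    seed: int
    stages: list[dict]
    output_dir: Path
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        errors = []
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        scenario = data.get("scenario", "run")
        seed = data.get("seed")
        if not isinstance(seed, int):
            errors.append("'seed' is required and must be an integer")
        stages = data.get("stages")
        if not isinstance(stages, list) or not stages:
            errors.append("'stages' must be a non-empty list")
        else:
            for i, st in enumerate(stages):
                if not isinstance(st, dict) or "name" not in st:
                    errors.append(f"stage {i} must be a mapping with a 'name'")
                elif st["name"] not in STAGES:
                    errors.append(
                        f"unknown stage {st['name']!r} (known: {sorted(STAGES)})"
                    )
                elif not isinstance(st.get("params", {}), dict):
                    errors.append(f"stage {st['name']}: 'params' must be a mapping")
        out = data.get("output_dir")
        if not out:
            errors.append("'output_dir' is required")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        return cls(
            scenario=scenario,
            seed=seed,
            stages=stages,
            output_dir=Path(out),
            raw=data,
        )


def stage_seed(master_seed: int, stage_name: str, index: int) -> int:
    """Stable per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{index}:{stage_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def _stage_scene_image(outdir: Path, seed: int, params: dict) -> dict:
    from . import io, synthetic_scene

    preset = params.get("preset", "post_disruption")
    hmap, truth = synthetic_scene.scene_from_preset(preset, seed=seed)
    path = outdir / f"scene_{preset}.tiff"
    io.write_height_map(path, hmap, seed=seed)
    return {"files": [path], "summary": {"preset": preset, "shape": list(hmap.shape)}}


def _stage_rms(outdir: Path, seed: int, params: dict) -> dict:
    from . import afm_image, io

    src = params.get("input")
    if src is None:  # generate both disruption presets and quantify them
        from . import synthetic_scene

        values = {}
        for preset in ("pre_disruption", "post_disruption"):
            hmap, _ = synthetic_scene.scene_from_preset(preset, seed=seed)
            values[preset] = afm_image.rms_roughness(hmap)
        payload = {"rms_nm": values}
    else:
        hmap = io.read_height_map(src, pixel_size=params.get("pixel_size"))
        payload = {"rms_nm": {Path(src).name: afm_image.rms_roughness(hmap)}}
    path = outdir / "rms.json"
    path.write_text(json.dumps(payload, indent=1))
    return {"files": [path], "summary": payload}


def _stage_spatial(outdir: Path, seed: int, params: dict) -> dict:
    from . import io, mac_spatial, synthetic_scene
    from .geometry import make_geometry

    if "pattern" in params:
        pattern = io.read_point_pattern(params["pattern"])
    else:
        geom = make_geometry(
            params.get("length_nm", 3000.0), params.get("radius_nm", 500.0)
        )
        pattern, _ = synthetic_scene.sample_mac_pattern(
            geom, params.get("density_per_um2", 100.0), seed=seed
        )
    n_reps = params.get("n_reps", 5)
    observed = mac_spatial.summarize_pattern(pattern)
    nulls = [
        mac_spatial.summarize_pattern(p)
        for p in mac_spatial.csr_replicates(pattern, n_reps=n_reps, seed=seed + 1)
    ]
    rep = mac_spatial.csr_compare(observed, nulls)
    pat_path = outdir / "pattern.csv"
    io.write_point_pattern(pat_path, pattern)
    rep_path = outdir / "spatial_report.json"
    rep_path.write_text(json.dumps(rep, indent=1))
    return {"files": [pat_path, pat_path.with_suffix(".csv.json"), rep_path], "summary": rep}


def _stage_series(outdir: Path, seed: int, params: dict) -> dict:
    from . import force_mech, io, synthetic_scene

    preset = params.get("preset", "dying")
    mech = synthetic_scene.scene_from_preset(preset)
    n_frames = params.get("n_frames", 10)
    if mech.permeation_time > n_frames - 2:  # keep a plateau segment in short runs
        mech.permeation_time = n_frames - 2
    frames, _ = synthetic_scene.simulate_timeseries(
        mech,
        n_frames=n_frames,
        seed=seed,
        grid_shape=tuple(params.get("grid_shape", (24, 24))),
    )
    series = force_mech.analyze_timeseries(frames)
    dh, de = force_mech.relative_change(series)
    path = outdir / f"series_{preset}.csv"
    io.write_series(path, series)
    payload = {
        "preset": preset,
        "height_change_fraction": dh,
        "E_change_fraction": de,
    }
    if len(series.times) >= 6:
        plateau, bp = force_mech.plateau_detect(series)
        payload["plateau"] = plateau
        payload["plateau_frame"] = bp
    jpath = outdir / f"series_{preset}.json"
    jpath.write_text(json.dumps(payload, indent=1))
    return {"files": [path, jpath], "summary": payload}


def _stage_fluor(outdir: Path, seed: int, params: dict) -> dict:
    from . import morphometrics, synthetic_scene

    preset = params.get("preset", "untreated_width")
    truth = synthetic_scene.scene_from_preset(
        preset, seed=seed, n_cells=params.get("n_cells", 50)
    )
    membrane, sytox, truth_df = synthetic_scene.render_fluor_population(
        truth, shape=tuple(params.get("shape", (1024, 1024)))
    )
    df = morphometrics.analyze_population(membrane, sytox, group=preset)
    truth_path = outdir / f"fluor_{preset}_truth.csv"
    truth_df.to_csv(truth_path, index=False)
    meas_path = outdir / f"fluor_{preset}_cells.csv"
    df.to_csv(meas_path, index=False)
    payload = {
        "preset": preset,
        "n_measured": int(len(df)),
        "mean_width_um": float(df["width_um"].mean()) if len(df) else None,
        "median_width_um": float(df["width_um"].median()) if len(df) else None,
    }
    jpath = outdir / f"fluor_{preset}.json"
    jpath.write_text(json.dumps(payload, indent=1))
    return {"files": [truth_path, meas_path, jpath], "summary": payload}


STAGES = {
    "scene_image": _stage_scene_image,
    "rms": _stage_rms,
    "spatial": _stage_spatial,
    "series": _stage_series,
    "fluor": _stage_fluor,
}


# ---------------------------------------------------------------------------
# runner


def run(config: RunConfig) -> dict:
    """Execute the configured stages and write a hashed manifest.

    Returns the manifest dict; a stage failure raises :class:`WorkflowError`
    after writing the partial manifest.
    """
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "scenario": config.scenario,
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }
    manifest_path = outdir / "manifest.json"
    for i, st in enumerate(config.stages):
        name = st["name"]
        params = st.get("params", {})
        seed = stage_seed(config.seed, name, i)
        logger.info("stage %d/%d: %s (seed %d)", i + 1, len(config.stages), name, seed)
        try:
            result = STAGES[name](outdir, seed, params)
        except Exception as exc:  # noqa: BLE001 - abort with partial manifest
            manifest["failed_stage"] = name
            manifest["error"] = str(exc)
            manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
            raise WorkflowError(f"stage {name!r} failed: {exc}", manifest_path) from exc
        manifest["stages"].append(
            {
                "name": name,
                "seed": seed,
                "artifacts": [
                    {"path": str(Path(f).relative_to(outdir)), "sha256": _sha256(Path(f))}
                    for f in result["files"]
                ],
                "summary": _jsonable(result.get("summary", {})),
            }
        )
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=_coerce))


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def report(manifest: dict | str | Path) -> str:
    """Human-readable summary of a run manifest.

    Sections degrade gracefully: stages absent from the manifest are simply
    omitted, and missing artifact files are listed, not fatal.
    """
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    lines = [
        f"Run: {manifest.get('scenario', '?')} (seed {manifest.get('seed', '?')})",
        "",
    ]
    stages = manifest.get("stages", [])
    if not stages:
        logger.warning("report: empty manifest")
        lines.append("(no completed stages)")
    for st in stages:
        lines.append(f"[{st['name']}]")
        summary = st.get("summary", {})
        for key, val in summary.items():
            if isinstance(val, dict):
                lines.append(f"  {key}:")
                for k2, v2 in val.items():
                    lines.append(f"    {k2}: {_fmt(v2)}")
            else:
                lines.append(f"  {key}: {_fmt(val)}")
        for art in st.get("artifacts", []):
            lines.append(f"  artifact: {art['path']}")
        lines.append("")
    if manifest.get("failed_stage"):
        lines.append(f"FAILED at stage {manifest['failed_stage']}: {manifest.get('error')}")
    return "\n".join(lines)


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)
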