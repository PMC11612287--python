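"""Reading and writing the package's on-disk formats.

Height maps travel as 32-bit float TIFF (values in nm, or degrees for phase)
with a JSON sidecar carrying pixel size, channel and seed; plain
whitespace-delimited text grids are also accepted. QI maps are directories
of per-pixel CSV curves (columns z_nm, force_pN) with a JSON calibration
file. Point patterns are CSVs (x_nm, y_nm) with a JSON region descriptor.
Truth tables and series go through pandas CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm_image import HeightMap
from .force_mech import ForceCurve, MechSeries, QIMap
from .geometry import CellGeometry
from .mac_spatial import CapsuleRegion, PointPattern, PolygonRegion, RectRegion

__all__ = [
    "write_height_map",
    "read_height_map",
    "write_qi_map",
    "read_qi_map",
    "write_point_pattern",
    "read_point_pattern",
    "write_series",
    "read_series",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_height_map(path, hmap: HeightMap, seed: int | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, hmap.values.astype(np.float32))
    meta = {"pixel_size_nm": hmap.pixel_size, "channel": hmap.channel, "seed": seed}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_height_map(path, pixel_size: float | None = None) -> HeightMap:
    """Read a TIFF (with sidecar) or a plain text grid (pixel_size required)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path).astype(float)
        meta = {}
        if _sidecar(path).exists():
            meta = json.loads(_sidecar(path).read_text())
        px = pixel_size or meta.get("pixel_size_nm")
        if px is None:
            raise ValueError("pixel size missing (no sidecar; pass pixel_size)")
        return HeightMap(values=values, pixel_size=px, channel=meta.get("channel", "height"))
    values = np.loadtxt(path)
    if pixel_size is None:
        raise ValueError("pixel_size is required for text grids")
    return HeightMap(values=values, pixel_size=pixel_size)


def write_qi_map(dirpath, qimap: QIMap) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    nr, nc = qimap.shape
    for i in range(nr):
        for j in range(nc):
            c = qimap.curves[i][j]
            pd.DataFrame({"z_nm": c.z, "force_pN": c.force}).to_csv(
                d / f"curve_{i:03d}_{j:03d}.csv", index=False
            )
    calib = {
        "k_N_per_m": qimap.k,
        "grid": [nr, nc],
        "pixel_size_nm": qimap.pixel_size,
        "timestamp_min": qimap.timestamp,
    }
    (d / "calibration.json").write_text(json.dumps(calib, indent=1))


def read_qi_map(dirpath) -> QIMap:
    d = Path(dirpath)
    calib = json.loads((d / "calibration.json").read_text())
    nr, nc = calib["grid"]
    curves = []
    for i in range(nr):
        row = []
        for j in range(nc):
            df = pd.read_csv(d / f"curve_{i:03d}_{j:03d}.csv")
            row.append(
                ForceCurve(
                    z=df["z_nm"].to_numpy(),
                    force=df["force_pN"].to_numpy(),
                    k=calib["k_N_per_m"],
                )
            )
        curves.append(row)
    return QIMap(
        curves=curves,
        pixel_size=calib["pixel_size_nm"],
        timestamp=calib.get("timestamp_min", 0.0),
    )


def _region_to_json(region) -> dict:
    if isinstance(region, CapsuleRegion):
        g = region.geometry
        return {
            "type": "capsule",
            "length_nm": g.length,
            "radius_nm": g.radius,
            "center_nm": list(g.center),
            "orientation_rad": g.orientation,
        }
    if isinstance(region, RectRegion):
        return {"type": "rect", "bounds_nm": [region.x0, region.x1, region.y0, region.y1]}
    if isinstance(region, PolygonRegion):
        return {"type": "polygon", "vertices_nm": region.vertices.tolist()}
    raise TypeError(f"cannot serialize region {type(region).__name__}")


def _region_from_json(spec: dict):
    kind = spec["type"]
    if kind == "capsule":
        return CapsuleRegion(
            CellGeometry(
                length=spec["length_nm"],
                radius=spec["radius_nm"],
                center=tuple(spec["center_nm"]),
                orientation=spec["orientation_rad"],
            )
        )
    if kind == "rect":
        return RectRegion(*spec["bounds_nm"])
    if kind == "polygon":
        return PolygonRegion(np.asarray(spec["vertices_nm"]))
    raise ValueError(f"unknown region type {kind!r}")


def write_point_pattern(csv_path, pattern: PointPattern) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame(pattern.points, columns=["x_nm", "y_nm"]).to_csv(csv_path, index=False)
    _sidecar(csv_path).write_text(json.dumps(_region_to_json(pattern.region), indent=1))


def read_point_pattern(csv_path) -> PointPattern:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    region = _region_from_json(json.loads(_sidecar(csv_path).read_text()))
    geometry = region.geometry if isinstance(region, CapsuleRegion) else None
    return PointPattern(
        points=df[["x_nm", "y_nm"]].to_numpy(), region=region, geometry=geometry
    )


def write_series(path, series: MechSeries) -> None:
    pd.DataFrame(
        {
            "time_min": series.times,
            "height_nm": series.heights,
            "E_kPa": series.E_values,
            "sytox": series.sytox_flags.astype(int),
        }
    ).to_csv(path, index=False)


def read_series(path) -> MechSeries:
    df = pd.read_csv(path)
    return MechSeries(
        times=df["time_min"].to_numpy(),
        heights=df["height_nm"].to_numpy(),
        E_values=df["E_kPa"].to_numpy(),
        sytox_flags=df["sytox"].to_numpy().astype(bool),
    )
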