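"""File formats: ROI polygons (CSV/JSON and ImageJ .roi), scalar series
CSV, and YAML simulation configs.

Internal coordinates are Cartesian micrometres with y increasing toward
the PSD.  ImageJ ROIs use 0-based pixel coordinates with y increasing
downward, so reading one requires an explicit ``pixel_size_um`` (no silent
default) and flips the y axis.
"""

from __future__ import annotations

import json
import struct
import zipfile
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import actin as ac
from . import membrane as mb
from . import simulate as sim
from .shape import ROIPolygon


# ---------------------------------------------------------------------------
# ROI polygons
# ---------------------------------------------------------------------------

def write_roi_csv(roi: ROIPolygon, path) -> None:
    """CSV of x,y rows plus a JSON sidecar <path>.json with the neck data."""
    path = Path(path)
    np.savetxt(path, roi.points, delimiter=",", header="x,y", comments="")
    side = {"neck_center": list(map(float, roi.neck_center))}
    if roi.neck_limits is not None:
        side["neck_limits"] = np.asarray(roi.neck_limits).tolist()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side))


def _read_csv_roi(path: Path) -> ROIPolygon:
    pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if pts.size == 0:
        raise ValueError(f"empty ROI file {path}")
    side_path = path.with_suffix(path.suffix + ".json")
    neck = [0.0, 0.0]
    limits = None
    if side_path.exists():
        side = json.loads(side_path.read_text())
        neck = side["neck_center"]
        limits = side.get("neck_limits")
    return ROIPolygon(points=pts[:, :2], neck_center=np.asarray(neck, float),
                      neck_limits=None if limits is None
                      else np.asarray(limits, float))


def _read_json_roi(path: Path) -> ROIPolygon:
    data = json.loads(path.read_text())
    if "points" not in data:
        raise ValueError(f"no 'points' field in {path}")
    return ROIPolygon(points=np.asarray(data["points"], float),
                      neck_center=np.asarray(
                          data.get("neck_center", [0.0, 0.0]), float),
                      neck_limits=(np.asarray(data["neck_limits"], float)
                                   if "neck_limits" in data else None))


_IJ_POLYGON, _IJ_FREEHAND = 0, 7


def _parse_imagej_roi(buf: bytes, pixel_size_um: float) -> np.ndarray:
    """Vertex list of an ImageJ .roi polygon/freehand record, y-up um."""
    if buf[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI file (missing 'Iout' magic)")
    roi_type = buf[6]
    if roi_type not in (_IJ_POLYGON, _IJ_FREEHAND):
        raise ValueError(
            f"unsupported ImageJ ROI type {roi_type}; only polygon (0) and "
            "freehand (7) outlines are supported")
    top, left = struct.unpack(">hh", buf[8:12])
    n = struct.unpack(">h", buf[16:18])[0]
    if n < 3:
        raise ValueError("ImageJ ROI has fewer than 3 vertices")
    xs = np.frombuffer(buf[64:64 + 2 * n], dtype=">i2").astype(float) + left
    ys = np.frombuffer(buf[64 + 2 * n:64 + 4 * n], dtype=">i2"
                       ).astype(float) + top
    # image y is down; flip to the package's y-up convention
    return np.stack([xs, -ys], axis=1) * pixel_size_um


def read_roi(path, pixel_size_um: float | None = None,
             neck_center=None) -> ROIPolygon | list[ROIPolygon]:
    """Read an ROI polygon from CSV, JSON, ImageJ .roi or RoiSet .zip.

    CSV expects an x,y header row and an optional <file>.json sidecar with
    the neck centre; JSON expects {"points": [[x, y], ...],
    "neck_center": [x, y]}.  ImageJ files require ``pixel_size_um`` and an
    explicit ``neck_center`` (in um, y-up); a RoiSet zip returns a list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return _read_csv_roi(path)
    if suffix == ".json":
        return _read_json_roi(path)
    if suffix in (".roi", ".zip"):
        if pixel_size_um is None:
            raise ValueError("reading ImageJ ROIs requires pixel_size_um")
        nc = np.asarray(neck_center if neck_center is not None
                        else [0.0, 0.0], float)
        if suffix == ".roi":
            pts = _parse_imagej_roi(path.read_bytes(), pixel_size_um)
            return ROIPolygon(points=pts, neck_center=nc)
        out = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if name.lower().endswith(".roi"):
                    pts = _parse_imagej_roi(zf.read(name), pixel_size_um)
                    out.append(ROIPolygon(points=pts, neck_center=nc.copy()))
        if not out:
            raise ValueError(f"no .roi records in {path}")
        return out
    raise ValueError(f"unsupported ROI format {suffix!r}")


# ---------------------------------------------------------------------------
# scalar series
# ---------------------------------------------------------------------------

def write_series_csv(series, path, sample_interval_s: float) -> None:
    """Single-column CSV with the sampling interval in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# sample_interval_s={sample_interval_s}\n")
        fh.write("value\n")
        for v in np.asarray(series, float):
            fh.write(f"{v!r}\n".replace("np.float64(", "").replace(")", ""))


def read_series_csv(path):
    """Returns (series, sample_interval_s or None)."""
    interval = None
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "sample_interval_s=" in line:
                    interval = float(line.split("sample_interval_s=")[1])
                continue
            try:
                vals.append(float(line))
            except ValueError:
                continue        # header row
    if not vals:
        raise ValueError(f"no numeric values in {path}")
    return np.asarray(vals), interval


# ---------------------------------------------------------------------------
# simulation configs
# ---------------------------------------------------------------------------

def config_to_dict(config: sim.SimConfig) -> dict:
    d = {
        "mechanical": asdict(config.mechanical),
        "actin": asdict(config.actin),
        "kernel": asdict(config.kernel),
        "geometry": asdict(config.geometry),
        "psd_neck_rate": config.psd_neck_rate,
        "d_mov": config.d_mov,
        "duration": config.duration,
        "sample_interval": config.sample_interval,
        "seed": config.seed,
        "feedback": config.feedback,
        "n_substeps": config.n_substeps,
        "force_mode": config.force_mode,
        "kernel_center": config.kernel_center,
        "contact_radius": config.contact_radius,
    }
    if config.ltp is not None:
        d["ltp"] = asdict(config.ltp)
    return d


def config_from_dict(d: dict) -> sim.SimConfig:
    kw = dict(d)
    if "mechanical" in kw:
        kw["mechanical"] = mb.MechanicalParams(**kw["mechanical"])
    if "actin" in kw:
        kw["actin"] = ac.ActinRates(**kw["actin"])
    if "kernel" in kw:
        kw["kernel"] = ac.KernelParams(**kw["kernel"])
    if "geometry" in kw:
        kw["geometry"] = sim.GeometryParams(**kw["geometry"])
    if "ltp" in kw and kw["ltp"] is not None:
        kw["ltp"] = sim.LTPProtocol(**kw["ltp"])
    return sim.SimConfig(**kw)


def load_config(path) -> sim.SimConfig:
    """YAML or JSON simulation config."""
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: sim.SimConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def save_trajectory(traj: sim.Trajectory, out_dir) -> None:
    """CSV series plus per-snapshot mesh CSVs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(out / "series.csv", index=False)
    traj.event_frame().to_csv(out / "events.csv", index=False)
    snaps = out / "snapshots"
    snaps.mkdir(exist_ok=True)
    for t, mesh in zip(traj.snapshot_times, traj.snapshots):
        mb.write_mesh_csv(mesh, snaps / f"mesh_{t:010.2f}s.csv")
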