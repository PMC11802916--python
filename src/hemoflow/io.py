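"""Persistence of pipeline inputs and outputs.

Flow and scalar fields, tracks and FRAP traces round-trip through CSV (one
row per node-frame or time point), with a small JSON sidecar
(``<name>.meta.json``) carrying the calibration that CSV columns cannot:
grid spacing, frame interval, units. Movies and masks use multi-page TIFF;
ground-truth records use JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    FlowField,
    GroundTruth,
    MaskSeries,
    Movie,
    ScalarField,
    Track,
)

__all__ = [
    "save_flow_field_csv",
    "load_flow_field_csv",
    "save_scalar_field_csv",
    "load_scalar_field_csv",
    "save_track_csv",
    "load_track_csv",
    "save_frap_csv",
    "load_frap_csv",
    "save_movie_tiff",
    "load_movie_tiff",
    "save_mask_tiff",
    "load_mask_tiff",
    "save_ground_truth_json",
    "load_ground_truth_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_flow_field_csv(field: FlowField, path: str | Path) -> None:
    path = Path(path)
    t_idx, y_idx, x_idx = np.indices(field.u.shape)
    corr = field.corr if field.corr is not None else np.full(field.u.shape, np.nan)
    df = pd.DataFrame(
        {
            "frame": t_idx.ravel(),
            "x_um": field.x[x_idx.ravel()],
            "y_um": field.y[y_idx.ravel()],
            "u_um_per_min": field.u.ravel(),
            "v_um_per_min": field.v.ravel(),
            "valid": field.valid.ravel().astype(int),
            "corr": corr.ravel(),
        }
    )
    df.to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps(
            {
                "grid_spacing_um": field.grid_spacing,
                "frame_interval_s": field.frame_interval,
            }
        )
    )


def load_flow_field_csv(path: str | Path) -> FlowField:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    x = np.unique(df["x_um"].to_numpy())
    y = np.unique(df["y_um"].to_numpy())
    n_t = int(df["frame"].max()) + 1
    shape = (n_t, y.size, x.size)
    xi = np.searchsorted(x, df["x_um"].to_numpy())
    yi = np.searchsorted(y, df["y_um"].to_numpy())
    ti = df["frame"].to_numpy()
    u = np.zeros(shape)
    v = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    corr = np.full(shape, np.nan)
    u[ti, yi, xi] = df["u_um_per_min"].to_numpy()
    v[ti, yi, xi] = df["v_um_per_min"].to_numpy()
    valid[ti, yi, xi] = df["valid"].to_numpy().astype(bool)
    corr[ti, yi, xi] = df["corr"].to_numpy()
    return FlowField(
        x=x,
        y=y,
        u=u,
        v=v,
        valid=valid,
        grid_spacing=float(meta["grid_spacing_um"]),
        frame_interval=float(meta["frame_interval_s"]),
        corr=corr,
    )


def save_scalar_field_csv(field: ScalarField, path: str | Path) -> None:
    path = Path(path)
    t_idx, y_idx, x_idx = np.indices(field.values.shape)
    pd.DataFrame(
        {
            "frame": t_idx.ravel(),
            "x_um": field.x[x_idx.ravel()],
            "y_um": field.y[y_idx.ravel()],
            "value": field.values.ravel(),
            "valid": field.valid.ravel().astype(int),
        }
    ).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"units": field.units}))


def load_scalar_field_csv(path: str | Path) -> ScalarField:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    x = np.unique(df["x_um"].to_numpy())
    y = np.unique(df["y_um"].to_numpy())
    n_t = int(df["frame"].max()) + 1
    xi = np.searchsorted(x, df["x_um"].to_numpy())
    yi = np.searchsorted(y, df["y_um"].to_numpy())
    ti = df["frame"].to_numpy()
    values = np.zeros((n_t, y.size, x.size))
    valid = np.zeros((n_t, y.size, x.size), dtype=bool)
    values[ti, yi, xi] = df["value"].to_numpy()
    valid[ti, yi, xi] = df["valid"].to_numpy().astype(bool)
    return ScalarField(x=x, y=y, values=values, valid=valid,
                       units=meta.get("units", ""))


def save_track_csv(track: Track, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(track.n_points),
            "time_s": track.t,
            "x_um": track.x,
            "y_um": track.y,
        }
    ).to_csv(path, index=False)


def load_track_csv(path: str | Path) -> Track:
    df = pd.read_csv(path)
    return Track(
        t=df["time_s"].to_numpy(),
        x=df["x_um"].to_numpy(),
        y=df["y_um"].to_numpy(),
    )


def save_frap_csv(series, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": series.time_s,
            "bleach": series.bleach,
            "control": series.control,
            "background": series.background,
        }
    ).to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps({"n_pre": series.n_pre, "roi_geometry": dict(series.roi_geometry)})
    )


def load_frap_csv(path: str | Path):
    from .datatypes import FRAPSeries

    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    kwargs = {}
    if "n_pre" in meta:
        kwargs["n_pre"] = int(meta["n_pre"])
    if "roi_geometry" in meta:
        kwargs["roi_geometry"] = meta["roi_geometry"]
    return FRAPSeries(
        time_s=df["time_s"].to_numpy(),
        bleach=df["bleach"].to_numpy(),
        control=df["control"].to_numpy(),
        background=df["background"].to_numpy(),
        **kwargs,
    )


def save_movie_tiff(movie: Movie, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps(
            {
                "channels": movie.channels,
                "pixel_size_um": movie.pixel_size,
                "frame_interval_s": movie.frame_interval,
            }
        )
    )


def load_movie_tiff(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    channels: list[str] | None = None,
) -> Movie:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    frame_interval = (
        frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    )
    if pixel_size is None or frame_interval is None:
        raise ValueError("pixel_size and frame_interval required (no sidecar found)")
    channels = channels or meta.get("channels")
    if channels is None:
        channels = (
            ["ch0"] if frames.ndim == 3 else [f"ch{i}" for i in range(frames.shape[1])]
        )
    return Movie(
        frames=frames,
        channels=channels,
        pixel_size=float(pixel_size),
        frame_interval=float(frame_interval),
    )


def save_mask_tiff(masks: MaskSeries | np.ndarray, path: str | Path) -> None:
    arr = masks.masks if isinstance(masks, MaskSeries) else np.asarray(masks)
    tifffile.imwrite(Path(path), (arr.astype(np.uint8)) * 255)


def load_mask_tiff(
    path: str | Path, pixel_size: float, frame_interval: float = 1.0
) -> MaskSeries:
    arr = np.asarray(tifffile.imread(Path(path)))
    if arr.ndim == 2:
        arr = arr[None]
    return MaskSeries(arr > 0, pixel_size, frame_interval)


def save_ground_truth_json(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"kind": gt.kind, "params": gt.params}, indent=2))


def load_ground_truth_json(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(kind=data["kind"], params=data["params"])
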