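"""Track- and mask-based migration metrics.

Covers nuclear centroid tracking, mean speed, walking-average persistence,
lamellar polarity relative to the direction of motion, contact-inhibition-of-
locomotion (CIL) acceleration along the collision axis, per-pixel cell-edge
extension dynamics with motion correlation, and 3D volume/sphericity.

Persistence here is the per-window ratio of net displacement to path length:
1 for perfectly straight motion, approaching 0 for erratic motion. CIL
acceleration is the x-component of the central second difference of the
focal nucleus position over (-60 s, 0, +60 s) after rotating the
focal-to-partner collision axis onto +x, so repulsion (accelerating away
from the partner) is negative.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .datatypes import (
    MaskSeries,
    ParameterizationError,
    Track,
    UndefinedResultError,
)

__all__ = [
    "CollisionEvent",
    "EdgeDynamics",
    "EdgeFrame",
    "track_centroids",
    "mean_speed",
    "persistence",
    "lamellar_polarity",
    "cil_acceleration",
    "edge_dynamics",
    "motion_extension_correlation",
    "shape_metrics",
]


@dataclasses.dataclass
class CollisionEvent:
    """A manually annotated collision between two migrating cells.

    ``collision_time`` is the absolute time (s) on the focal track at which
    contact occurs; positions are sampled at ``collision_time + offsets``.
    """

    track: Track
    partner_position: tuple[float, float]  # µm, at collision time
    collision_time: float  # s
    offsets: tuple[float, float, float] = (-60.0, 0.0, 60.0)

    def __post_init__(self) -> None:
        t = self.track.t
        for off in self.offsets:
            ts = self.collision_time + off
            if ts < t[0] or ts > t[-1]:
                raise ParameterizationError(
                    f"sample time {ts} s outside the focal track [{t[0]}, {t[-1]}]"
                )


@dataclasses.dataclass
class EdgeFrame:
    """Edge-extension measurements for one frame transition t -> t+1."""

    frame: int
    boundary_speeds: np.ndarray  # µm/s per boundary point of mask t+1, ordered
    largest_extension_speed: float  # µm/s; 0 if no extension
    all_extension_speed: float  # mean over positive boundary speeds; 0 if none
    motion_vector: tuple[float, float] | None  # µm, nucleus t -> t+1
    extension_vector: tuple[float, float] | None  # µm, nucleus t -> largest new area
    valid: bool  # False when the mask difference is empty


@dataclasses.dataclass
class EdgeDynamics:
    """Per-transition edge dynamics for a mask series."""

    frames: list[EdgeFrame]

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# tracking and track metrics
# ---------------------------------------------------------------------------

def track_centroids(nuclear_masks: MaskSeries) -> Track:
    """Centroid of the (single) nuclear mask at every time point, in µm."""
    ps = nuclear_masks.pixel_size
    xs, ys = [], []
    for f, mask in enumerate(nuclear_masks.masks):
        labels, n = ndimage.label(mask)
        if n != 1:
            raise ParameterizationError(
                f"frame {f}: expected exactly one connected component, found {n}"
            )
        row, col = ndimage.center_of_mass(mask)
        xs.append(col * ps)
        ys.append(row * ps)
    t = nuclear_masks.frame_interval * np.arange(nuclear_masks.n_frames)
    return Track(t=t, x=np.array(xs), y=np.array(ys))


def mean_speed(track: Track) -> float:
    """Mean instantaneous speed along the track, µm/min."""
    d = np.hypot(np.diff(track.x), np.diff(track.y))
    dt = np.diff(track.t)
    return float(np.mean(d / dt) * 60.0)


def persistence(track: Track, window: float = 60.0) -> tuple[np.ndarray, float]:
    """Walking-average persistence over sliding windows of ``window`` seconds.

    For each start frame, the window ends at the nearest frame whose time
    offset is >= ``window`` (frame intervals need not divide the window
    evenly). The per-window value is the start-to-end distance divided by the
    path length within the window; windows with zero path length are skipped.
    Returns the per-window values and their mean.
    """
    t = track.t
    if track.duration() < window:
        raise ParameterizationError(
            f"track duration {track.duration():.1f} s shorter than window {window} s"
        )
    pos = track.positions()
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    cum = np.concatenate([[0.0], np.cumsum(steps)])

    values = []
    for i in range(len(t)):
        j = int(np.searchsorted(t, t[i] + window, side="left"))
        if j >= len(t):
            break
        path = cum[j] - cum[i]
        if path == 0:
            continue
        net = float(np.hypot(*(pos[j] - pos[i])))
        # net <= path mathematically; clamp float round-off
        values.append(min(net / path, 1.0))
    if not values:
        raise UndefinedResultError("no window with non-zero path length")
    arr = np.asarray(values)
    return arr, float(arr.mean())


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------

def lamellar_polarity(
    cell_masks: MaskSeries, nucleus_track: Track
) -> tuple[np.ndarray, float]:
    """Front/back area ratio of the cell mask split at the nuclear centroid.

    At each frame with non-zero nuclear displacement to the next frame, the
    cell mask is halved by the line through the nuclear centroid
    perpendicular to the instantaneous direction of motion; polarity is the
    area of the half toward the motion over the area behind. Frames with zero
    displacement, or with an empty back half, are skipped. Returns per-frame
    ratios (NaN where skipped) and the mean over defined frames.
    """
    if cell_masks.n_frames != nucleus_track.n_points:
        raise ParameterizationError("masks and track must have equal frame counts")
    ps = cell_masks.pixel_size
    out = np.full(cell_masks.n_frames, np.nan)
    for f in range(cell_masks.n_frames - 1):
        mx = nucleus_track.x[f + 1] - nucleus_track.x[f]
        my = nucleus_track.y[f + 1] - nucleus_track.y[f]
        norm = math.hypot(mx, my)
        if norm == 0:
            continue
        mask = cell_masks.masks[f]
        rows, cols = np.nonzero(mask)
        # signed distance of each cell pixel along the motion direction
        s = (cols * ps - nucleus_track.x[f]) * (mx / norm) + (
            rows * ps - nucleus_track.y[f]
        ) * (my / norm)
        front = int(np.count_nonzero(s > 0))
        back = int(np.count_nonzero(s < 0))
        if back == 0:
            warnings.warn(f"frame {f}: empty back half, excluded from polarity mean")
            continue
        out[f] = front / back
    defined = out[np.isfinite(out)]
    if defined.size == 0:
        raise UndefinedResultError("no frame with defined polarity")
    return out, float(defined.mean())


# ---------------------------------------------------------------------------
# contact inhibition of locomotion
# ---------------------------------------------------------------------------

def _track_position_at(track: Track, time_s: float) -> np.ndarray:
    return np.array(
        [np.interp(time_s, track.t, track.x), np.interp(time_s, track.t, track.y)]
    )


def cil_acceleration(event: CollisionEvent) -> float:
    """Collision-axis acceleration of the focal nucleus, µm/s².

    Coordinates are rotated so the focal-to-partner axis at the collision
    time lies along +x; the returned value is the x-component of the central
    second difference of position over the event's sampling offsets
    (default ±60 s). Negative values mean the focal cell accelerates away
    from its collision partner (repulsion).
    """
    t0 = event.collision_time
    p_minus, p_zero, p_plus = (
        _track_position_at(event.track, t0 + off) for off in event.offsets
    )
    axis = np.asarray(event.partner_position) - p_zero
    norm = float(np.hypot(*axis))
    if norm == 0:
        raise UndefinedResultError(
            "focal and partner coincide at collision; axis undefined"
        )
    axis /= norm
    h = event.offsets[2] - event.offsets[1]
    if not math.isclose(h, event.offsets[1] - event.offsets[0]):
        raise ParameterizationError("sampling offsets must be symmetric")
    accel = (p_plus - 2.0 * p_zero + p_minus) / h**2
    return float(accel @ axis)


# ---------------------------------------------------------------------------
# edge dynamics
# ---------------------------------------------------------------------------

def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mask interface, px; positive outside.

    Distances from the pixel-center EDT are shifted by half a pixel toward
    the interface, which sits midway between the last inside and first
    outside pixel centers (the same 0.5-level convention used when tracing
    contours); without the shift every extension is biased a half pixel
    outward.
    """
    outside = ndimage.distance_transform_edt(~mask) - 0.5
    inside = ndimage.distance_transform_edt(mask) - 0.5
    return np.where(mask, -inside, outside)


def _largest_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise UndefinedResultError("mask has no boundary contour")
    return max(contours, key=len)


def _longest_positive_run(values: np.ndarray) -> np.ndarray:
    """Indices of the longest circular run of strictly positive values."""
    pos = values > 0
    if not pos.any():
        return np.array([], dtype=int)
    if pos.all():
        return np.arange(values.size)
    n = values.size
    ext = np.concatenate([pos, pos])
    best_start, best_len, run_start = 0, 0, None
    for i in range(2 * n):
        if ext[i]:
            if run_start is None:
                run_start = i
            if i - run_start + 1 > best_len and run_start < n:
                best_len, best_start = i - run_start + 1, run_start
        else:
            run_start = None
    best_len = min(best_len, n)
    return (best_start + np.arange(best_len)) % n


def edge_dynamics(
    cell_masks: MaskSeries, nucleus_track: Track
) -> EdgeDynamics:
    """Per-pixel edge-extension speeds along the perimeter, per transition.

    For each transition t -> t+1, boundary correspondence uses the signed
    Euclidean distance transform of mask t sampled along the traced boundary
    of mask t+1: positive where mask t+1 extends beyond mask t. Speeds are in
    µm/s. The largest extension is the longest uninterrupted positive run
    along the perimeter, reported as the maximum speed within that run; the
    mean over all positive boundary points is reported as the speed of all
    extensions. The extension direction points from the nuclear center at t
    to the centroid of the largest connected region of (mask t+1 minus
    mask t); the motion vector points to the nuclear center at t+1.
    """
    if cell_masks.n_frames < 2:
        raise ParameterizationError("need at least 2 frames")
    if cell_masks.n_frames != nucleus_track.n_points:
        raise ParameterizationError("masks and track must have equal frame counts")
    ps = cell_masks.pixel_size
    dt = cell_masks.frame_interval
    frames: list[EdgeFrame] = []
    for f in range(cell_masks.n_frames - 1):
        m0, m1 = cell_masks.masks[f], cell_masks.masks[f + 1]
        sdf = _signed_distance(m0)
        contour = _largest_contour(m1)  # (n, 2) in (row, col)
        ext_px = ndimage.map_coordinates(sdf, contour.T, order=1, mode="nearest")
        speeds = ext_px * ps / dt

        run = _longest_positive_run(speeds)
        largest_speed = float(speeds[run].max()) if run.size else 0.0
        positives = speeds[speeds > 0]
        all_speed = float(positives.mean()) if positives.size else 0.0

        motion = (
            float(nucleus_track.x[f + 1] - nucleus_track.x[f]),
            float(nucleus_track.y[f + 1] - nucleus_track.y[f]),
        )
        diff = m1 & ~m0
        labels, n = ndimage.label(diff)
        if n == 0:
            frames.append(
                EdgeFrame(f, speeds, 0.0, all_speed, motion, None, valid=False)
            )
            continue
        areas = ndimage.sum_labels(diff, labels, index=np.arange(1, n + 1))
        largest_label = int(np.argmax(areas)) + 1
        row, col = ndimage.center_of_mass(labels == largest_label)
        ext_vec = (
            float(col * ps - nucleus_track.x[f]),
            float(row * ps - nucleus_track.y[f]),
        )
        frames.append(
            EdgeFrame(f, speeds, largest_speed, all_speed, motion, ext_vec, True)
        )
    return EdgeDynamics(frames)


def motion_extension_correlation(
    dyn: EdgeDynamics, n_bins: int = 18
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Cosine similarity between motion and largest-extension directions.

    Returns (per-frame cos(theta), mean, angular histogram counts, bin edges
    in degrees). The histogram collects the angle of the extension vector in
    the motion-aligned frame (motion along 0°, counter-clockwise positive
    after the y-flip to mathematical convention), in ``n_bins`` equal bins
    spanning (-180°, 180°].
    """
    cos_vals = []
    angles = []
    for ef in dyn:
        if ef.motion_vector is None or ef.extension_vector is None:
            continue
        mx, my = ef.motion_vector
        ex, ey = ef.extension_vector
        nm, ne = math.hypot(mx, my), math.hypot(ex, ey)
        if nm == 0 or ne == 0:
            continue
        dot = (mx * ex + my * ey) / (nm * ne)
        cos_vals.append(max(-1.0, min(1.0, dot)))
        # image rows grow downward: flip y for CCW-positive angles
        cross = (mx * -ey - -my * ex) / (nm * ne)
        angles.append(math.degrees(math.atan2(cross, dot)))
    if not cos_vals:
        raise UndefinedResultError("no frame with both motion and extension vectors")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    hist, _ = np.histogram(angles, bins=edges)
    arr = np.asarray(cos_vals)
    return arr, float(arr.mean()), hist, edges


# ---------------------------------------------------------------------------
# 3D shape
# ---------------------------------------------------------------------------

def shape_metrics(
    mask3d: np.ndarray,
    voxel_size: float | Sequence[float],
    body_mask3d: np.ndarray | None = None,
) -> dict[str, float]:
    """Volume (µm³), surface area (µm²) and sphericity of a 3D binary mask.

    Volume is the voxel count times the voxel volume. Surface area comes
    from a marching-cubes iso-surface at level 0.5 after a 0.8-voxel
    Gaussian smooth (the raw voxel surface overestimates area and biases
    sphericity low; 0.8 voxels removes the staircase with sub-percent area
    error on a 20-voxel-radius sphere). Sphericity is
    pi^(1/3) * (6V)^(2/3) / A. If a cell-body
    mask is given, the lamellar volume (whole minus body) is also returned.
    """
    mask3d = np.asarray(mask3d).astype(bool)
    if not mask3d.any():
        raise ParameterizationError("empty mask")
    spacing = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    voxel_volume = float(np.prod(spacing))

    volume = float(mask3d.sum()) * voxel_volume
    padded = np.pad(mask3d, 2).astype(float)
    smoothed = ndimage.gaussian_filter(padded, sigma=0.8)
    verts, faces, _, _ = measure.marching_cubes(
        smoothed, level=0.5, spacing=tuple(spacing)
    )
    area = float(measure.mesh_surface_area(verts, faces))
    sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)

    out = {"volume_um3": volume, "surface_area_um2": area, "sphericity": sphericity}
    if body_mask3d is not None:
        body = np.asarray(body_mask3d).astype(bool)
        if (body & ~mask3d).any():
            raise ParameterizationError("body mask is not a subset of the whole mask")
        out["lamellar_volume_um3"] = volume - float(body.sum()) * voxel_volume
    return out
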