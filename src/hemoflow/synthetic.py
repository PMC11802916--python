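"""Synthetic movies, masks, traces and tracks with known ground truth.

Every generator in this module emulates one class of input the hemocyte
pipeline consumes — speckle movies advected by an analytic planar flow,
two-channel cells with a graded cortical ratio, single-exponential FRAP
recovery under acquisition photobleaching, nuclear tracks from simple motion
models, protruding cell-edge mask sequences, and voxelized ellipsoids — and
returns a :class:`~hemoflow.datatypes.GroundTruth` recording the generative
parameters so that every downstream stage can be validated against a known
answer. Fixing the seed reproduces bit-identical output.

These are deliberately idealized: additive Gaussian noise only, no PSF
convolution or shot noise. See the methods note for what that implies about
real microscope data.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import (
    FRAPSeries,
    GroundTruth,
    MaskSeries,
    Movie,
    ParameterizationError,
    Track,
)
from .morphodynamics import CollisionEvent

__all__ = [
    "MotionModel",
    "make_speckle_movie",
    "speckle_velocity_field",
    "make_two_channel_cell",
    "ring_profile",
    "make_frap_series",
    "make_track",
    "make_collision_pair",
    "make_mask_sequence",
    "make_ellipsoid_mask",
]


# ---------------------------------------------------------------------------
# speckle movies under analytic flow
# ---------------------------------------------------------------------------

_FLOW_KINDS = ("uniform", "rotation", "radial_sink")


def _analytic_velocity_px(
    flow_spec: str,
    magnitude: float,
    shape: tuple[int, int],
    direction: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity components (px/frame) of the analytic field on the pixel grid."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if flow_spec == "uniform":
        d = np.asarray(direction, dtype=float)
        norm = np.hypot(*d)
        if norm == 0:
            d = np.array([1.0, 0.0])
        else:
            d = d / norm
        u = np.full(shape, magnitude * d[0])
        v = np.full(shape, magnitude * d[1])
    elif flow_spec == "rotation":
        # solid rotation, magnitude = omega in rad/frame, CCW in image coords
        u = -magnitude * (yy - cy)
        v = magnitude * (xx - cx)
    elif flow_spec == "radial_sink":
        # v(r) = -a * r with a = magnitude in 1/frame
        u = -magnitude * (xx - cx)
        v = -magnitude * (yy - cy)
    else:
        raise ParameterizationError(
            f"flow_spec must be one of {_FLOW_KINDS}, got {flow_spec!r}"
        )
    return u, v


def speckle_velocity_field(
    gt: GroundTruth, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Re-evaluate the analytic velocity field (px/frame) a speckle movie was
    advected by, from its ground-truth record."""
    kind = gt.kind.removeprefix("speckle_")
    direction = (gt.params.get("direction_x", 1.0), gt.params.get("direction_y", 0.0))
    return _analytic_velocity_px(kind, gt.params["magnitude"], shape, direction)


def make_speckle_movie(
    flow_spec: str,
    magnitude: float,
    frame_size: tuple[int, int] = (64, 64),
    pixel_size: float = 0.1,
    n_frames: int = 10,
    frame_interval: float = 5.0,
    speckle_density: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    direction: tuple[float, float] = (1.0, 0.0),
    max_displacement_px: float | None = None,
) -> tuple[Movie, GroundTruth]:
    """Generate a speckle movie advected by a known planar flow.

    The first frame scatters Gaussian blobs (sigma 1 px) at Poisson-random
    positions covering ``speckle_density`` of the pixels. Each subsequent
    latent frame is the previous one advected by the analytic velocity field
    (semi-Lagrangian backward warp, bilinear resampling, reflective boundary);
    i.i.d. Gaussian noise is added to each emitted frame.

    Parameters
    ----------
    flow_spec
        ``uniform`` (magnitude = speed in px/frame along ``direction``),
        ``rotation`` (magnitude = angular speed in rad/frame) or
        ``radial_sink`` (magnitude = sink strength ``a`` in 1/frame,
        ``v(r) = -a r``).
    max_displacement_px
        If given, reject parameterizations whose maximum per-frame
        displacement anywhere in the frame exceeds this radius (the PIV
        search radius downstream).
    """
    if flow_spec not in _FLOW_KINDS:
        raise ParameterizationError(
            f"flow_spec must be one of {_FLOW_KINDS}, got {flow_spec!r}"
        )
    u, v = _analytic_velocity_px(flow_spec, magnitude, frame_size, direction)
    max_disp = float(np.max(np.hypot(u, v)))
    if max_displacement_px is not None and max_disp > max_displacement_px:
        raise ParameterizationError(
            f"per-frame displacement {max_disp:.2f} px exceeds the search "
            f"radius {max_displacement_px:.2f} px; reduce magnitude"
        )

    rng = np.random.default_rng(seed)
    h, w = frame_size
    n_speckles = rng.poisson(speckle_density * h * w)
    rows = rng.uniform(0, h, n_speckles)
    cols = rng.uniform(0, w, n_speckles)
    amps = rng.uniform(0.5, 1.0, n_speckles)
    impulses = np.zeros(frame_size)
    np.add.at(impulses, (rows.astype(int) % h, cols.astype(int) % w), amps)
    frame0 = ndimage.gaussian_filter(impulses, sigma=1.0, mode="reflect")

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    latent = [frame0]
    for _ in range(n_frames - 1):
        # backward warp: value at x comes from x - v(x)
        coords = np.stack([yy - v, xx - u])
        latent.append(
            ndimage.map_coordinates(latent[-1], coords, order=1, mode="reflect")
        )
    frames = np.stack(latent)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)

    params = {
        "magnitude": magnitude,
        "pixel_size": pixel_size,
        "frame_interval": frame_interval,
        "noise_sd": noise_sd,
        "speckle_density": speckle_density,
        "max_displacement_px": max_disp,
    }
    if flow_spec == "uniform":
        d = np.asarray(direction, dtype=float)
        d = d / np.hypot(*d) if np.hypot(*d) > 0 else np.array([1.0, 0.0])
        params["direction_x"], params["direction_y"] = float(d[0]), float(d[1])
        params["flow_speed_um_per_min"] = (
            abs(magnitude) * pixel_size / frame_interval * 60.0
        )
    elif flow_spec == "rotation":
        params["omega_rad_per_frame"] = magnitude
        params["omega_rad_per_min"] = magnitude / frame_interval * 60.0
    else:
        params["sink_strength_per_frame"] = magnitude
        params["divergence_per_frame"] = -2.0 * magnitude

    movie = Movie(
        frames=frames,
        channels=["speckle"],
        pixel_size=pixel_size,
        frame_interval=frame_interval,
    )
    return movie, GroundTruth(kind=f"speckle_{flow_spec}", params=params)


# ---------------------------------------------------------------------------
# two-channel cell with graded cortical ratio
# ---------------------------------------------------------------------------

def ring_profile(
    body_radius: float,
    ring_width: float,
    ring_amplitude: float = 2.0,
    baseline: float = 1.0,
    lamella_slope: float = 0.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Radial ratio profile: a Gaussian cortical ring of the given amplitude
    peaking at the cell-body edge, on a baseline, with an optional linear
    gradient over the lamella (``lamella_slope`` per µm beyond the body edge,
    emulating rearward-graded membrane-proximal actin)."""
    sigma = ring_width / 2.0

    def profile(r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        ring = (ring_amplitude - baseline) * np.exp(
            -0.5 * ((r - body_radius) / sigma) ** 2
        )
        grad = lamella_slope * np.clip(r - body_radius, 0.0, None)
        return baseline + ring + grad

    return profile


def make_two_channel_cell(
    body_radius: float = 5.0,
    lamella_extent: float = 12.0,
    ring_width: float = 2.0,
    ratio_profile: Callable[[np.ndarray], np.ndarray] | None = None,
    ring_amplitude: float = 2.0,
    pixel_size: float = 0.1,
    noise_sd: float = 0.0,
    n_frames: int = 1,
    frame_interval: float = 1.0,
    denominator_level: float = 100.0,
    seed: int = 0,
) -> tuple[Movie, MaskSeries, MaskSeries, GroundTruth]:
    """Generate a circular two-channel cell for ratiometric cortex analysis.

    The denominator channel (a uniform membrane marker) is constant inside
    the cell disk of radius ``lamella_extent``; the numerator channel is the
    denominator multiplied by a radial ratio profile (default: a cortical
    ring of amplitude ``ring_amplitude`` peaking at the cell-body edge, 1 at
    the centroid). Returns the movie, the whole-cell and cell-body mask
    series, and the ground truth holding the profile sampled every 0.5 µm.
    """
    if ring_width <= 0:
        raise ParameterizationError("ring_width must be > 0")
    if lamella_extent <= body_radius:
        raise ParameterizationError("lamella_extent must exceed body_radius")
    if ratio_profile is None:
        ratio_profile = ring_profile(body_radius, ring_width, ring_amplitude)

    rng = np.random.default_rng(seed)
    margin = 2.0  # µm of background around the cell
    half = lamella_extent + margin
    n_px = int(np.ceil(2 * half / pixel_size))
    c = (n_px - 1) / 2.0
    yy, xx = np.mgrid[0:n_px, 0:n_px].astype(float)
    r_um = np.hypot(xx - c, yy - c) * pixel_size

    cell = r_um <= lamella_extent
    body = r_um <= body_radius
    den = np.where(cell, denominator_level, 0.0)
    num = den * ratio_profile(r_um)

    frames = np.broadcast_to(
        np.stack([num, den])[None], (n_frames, 2, n_px, n_px)
    ).copy()
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)

    r_samples = np.arange(0.0, lamella_extent + 0.25, 0.5)
    profile_samples = np.asarray(ratio_profile(r_samples), dtype=float)
    params = {
        "body_radius_um": body_radius,
        "lamella_extent_um": lamella_extent,
        "ring_width_um": ring_width,
        "pixel_size": pixel_size,
        "noise_sd": noise_sd,
        "ratio_at_center": float(profile_samples[0]),
        "ratio_at_body_edge": float(ratio_profile(np.array([body_radius]))[0]),
    }
    for r, val in zip(r_samples, profile_samples):
        params[f"profile_r{r:.1f}um"] = float(val)

    movie = Movie(
        frames=frames,
        channels=["mpact", "caax"],
        pixel_size=pixel_size,
        frame_interval=frame_interval,
    )
    cell_masks = MaskSeries(
        np.broadcast_to(cell, (n_frames, n_px, n_px)).copy(), pixel_size, frame_interval
    )
    body_masks = MaskSeries(
        np.broadcast_to(body, (n_frames, n_px, n_px)).copy(), pixel_size, frame_interval
    )
    return movie, cell_masks, body_masks, GroundTruth("two_channel_cell", params)


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def make_frap_series(
    A: float = 0.6,
    k: float = 0.35,
    acq_bleach_rate: float = 0.0,
    baseline: float = 10.0,
    noise_sd: float = 0.0,
    pre_frames: int = 5,
    post_frames: int = 45,
    dt: float = 0.5,
    bleach_floor: float = 0.2,
    seed: int = 0,
) -> tuple[FRAPSeries, GroundTruth]:
    """Generate the three ROI traces of a FRAP experiment.

    The bleach-ROI signal above baseline follows a single-exponential
    recovery ``s0 + A*(1 - exp(-k t))`` from the post-bleach floor ``s0 =
    bleach_floor`` (pre-bleach signal 1), multiplied by ``exp(-beta *
    t_acq)`` acquisition photobleaching where ``t_acq`` runs from the first
    acquired (pre-bleach) frame. The control ROI carries the same
    acquisition decay on a constant signal; the background is the constant
    ``baseline``. Time 0 is the first post-bleach frame.
    """
    if k <= 0:
        raise ParameterizationError("k must be > 0")
    if not (0 < A <= 1):
        raise ParameterizationError("plateau fraction A must be in (0, 1]")
    rng = np.random.default_rng(seed)

    t_pre = -dt * np.arange(pre_frames, 0, -1)
    t_post = dt * np.arange(post_frames)
    time_s = np.concatenate([t_pre, t_post])
    t_acq = dt * np.arange(pre_frames + post_frames)  # from first acquired frame
    decay = np.exp(-acq_bleach_rate * t_acq)

    signal = np.empty_like(time_s)
    signal[:pre_frames] = 1.0
    signal[pre_frames:] = bleach_floor + A * (1.0 - np.exp(-k * t_post))

    bleach = baseline + signal * decay
    control = baseline + 1.0 * decay
    background = np.full_like(time_s, baseline)
    if noise_sd > 0:
        bleach = bleach + rng.normal(0.0, noise_sd, bleach.shape)
        control = control + rng.normal(0.0, noise_sd, control.shape)
        background = background + rng.normal(0.0, noise_sd, background.shape)

    series = FRAPSeries(
        time_s=time_s,
        bleach=bleach,
        control=control,
        background=background,
        n_pre=pre_frames,
    )
    gt = GroundTruth(
        "frap_recovery",
        {
            "A": A,
            "k_per_s": k,
            "half_life_s": float(np.log(2.0) / k),
            "acq_bleach_rate_per_s": acq_bleach_rate,
            "baseline": baseline,
            "bleach_floor": bleach_floor,
            "noise_sd": noise_sd,
            "dt_s": dt,
            # plateau of the depth-normalized trace
            "normalized_plateau": A / (1.0 - bleach_floor),
        },
    )
    return series, gt


# ---------------------------------------------------------------------------
# nuclear tracks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MotionModel:
    """Motion model for synthetic nuclear tracks.

    ``speed`` is in µm/min; ``rotational_diffusion`` (rad²/s) applies to the
    persistent random walk only; ``collision_time_index`` to colliding pairs.
    """

    name: str  # straight | persistent_random_walk | collision_pair
    speed: float = 3.0
    rotational_diffusion: float = 0.0
    collision_time_index: int | None = None

    def __post_init__(self) -> None:
        if self.name not in ("straight", "persistent_random_walk", "collision_pair"):
            raise ParameterizationError(f"unknown motion model {self.name!r}")
        if self.speed < 0:
            raise ParameterizationError("speed must be >= 0")
        if self.rotational_diffusion < 0:
            raise ParameterizationError("rotational_diffusion must be >= 0")


def make_track(
    model: MotionModel,
    n_steps: int,
    dt: float,
    seed: int = 0,
    start: tuple[float, float] = (0.0, 0.0),
    heading: float | None = None,
) -> tuple[Track, GroundTruth]:
    """Generate a single nuclear track under a motion model.

    ``straight`` yields collinear, equally spaced points along ``heading``
    (default +x). ``persistent_random_walk`` yields fixed-modulus steps whose
    heading diffuses with the stated rotational diffusion. Colliding pairs
    are produced by :func:`make_collision_pair`, which also returns the
    partner track and the collision annotation.
    """
    if n_steps < 3:
        raise ParameterizationError("n_steps must be >= 3")
    if model.name == "collision_pair":
        raise ParameterizationError(
            "use make_collision_pair for the collision_pair model"
        )
    rng = np.random.default_rng(seed)
    step = model.speed / 60.0 * dt  # µm per step
    t = dt * np.arange(n_steps + 1)

    if model.name == "straight":
        th = 0.0 if heading is None else heading
        headings = np.full(n_steps, th)
    else:
        th0 = rng.uniform(0, 2 * np.pi) if heading is None else heading
        dth = np.sqrt(2.0 * model.rotational_diffusion * dt) * rng.standard_normal(
            n_steps - 1
        )
        headings = th0 + np.concatenate([[0.0], np.cumsum(dth)])

    dx = step * np.cos(headings)
    dy = step * np.sin(headings)
    x = start[0] + np.concatenate([[0.0], np.cumsum(dx)])
    y = start[1] + np.concatenate([[0.0], np.cumsum(dy)])
    track = Track(t=t, x=x, y=y)
    gt = GroundTruth(
        f"track_{model.name}",
        {
            "speed_um_per_min": model.speed,
            "rotational_diffusion_rad2_per_s": model.rotational_diffusion,
            "dt_s": dt,
            "n_steps": n_steps,
        },
    )
    return track, gt


def make_collision_pair(
    speed: float = 3.0,
    dt: float = 10.0,
    n_steps: int = 20,
    collision_time_index: int = 10,
    reversal: float = 1.0,
    contact_distance: float = 5.0,
    seed: int = 0,
) -> tuple[Track, Track, CollisionEvent, GroundTruth]:
    """Two cells approach head-on along x, meet at ``collision_time_index``,
    and rebound with the given post-collision ``reversal`` fraction of the
    approach speed (1 = full reversal, 0 = stop). The collision annotation
    (time and partner position) is emitted by the generator, mirroring how
    collisions are marked by eye on real movies rather than detected.
    """
    if not 0 <= collision_time_index <= n_steps:
        raise ParameterizationError("collision_time_index outside the track")
    step = speed / 60.0 * dt  # µm per frame
    t = dt * np.arange(n_steps + 1)
    idx = np.arange(n_steps + 1)
    # focal approaches from the left, stops contact_distance/2 short of origin
    x_contact = -contact_distance / 2.0
    x_focal = np.where(
        idx <= collision_time_index,
        x_contact - step * (collision_time_index - idx),
        x_contact - reversal * step * (idx - collision_time_index),
    ).astype(float)
    x_partner = -x_focal
    zeros = np.zeros_like(x_focal)
    focal = Track(t=t, x=x_focal, y=zeros)
    partner = Track(t=t, x=x_partner, y=zeros.copy())
    event = CollisionEvent(
        track=focal,
        partner_position=(float(x_partner[collision_time_index]), 0.0),
        collision_time=float(t[collision_time_index]),
    )
    gt = GroundTruth(
        "track_collision_pair",
        {
            "speed_um_per_min": speed,
            "approach_speed_um_per_s": speed / 60.0,
            "reversal": reversal,
            "dt_s": dt,
            "collision_time_s": float(t[collision_time_index]),
            "contact_distance_um": contact_distance,
            # central second difference over +/-60 s for full head-on reversal
            "expected_ax_um_per_s2": -(1.0 + reversal) * (speed / 60.0) / 60.0,
        },
    )
    return focal, partner, event, gt


# ---------------------------------------------------------------------------
# protruding edge mask sequences
# ---------------------------------------------------------------------------

def make_mask_sequence(
    base_radius: float = 8.0,
    protrusions: Sequence[tuple[float, float, float]] = ((0.0, 60.0, 1.0),),
    n_frames: int = 5,
    pixel_size: float = 0.2,
    frame_interval: float = 10.0,
    seed: int = 0,
) -> tuple[MaskSeries, GroundTruth]:
    """Disk-shaped cell whose edge grows radially inside angular sectors.

    ``protrusions`` lists ``(bisector_deg, width_deg, growth_um_per_frame)``
    sectors; outside all sectors the radius stays at ``base_radius``. Angles
    follow the package convention (CCW from +x, y up). The ground truth
    records the fastest sector's bisector and its growth speed.
    """
    for _, width, growth in protrusions:
        if width <= 0 or growth < 0:
            raise ParameterizationError("sector width must be > 0 and growth >= 0")
    max_r = base_radius + max((g * (n_frames - 1) for *_ , g in protrusions), default=0)
    half = max_r + 2.0
    n_px = int(np.ceil(2 * half / pixel_size))
    c = (n_px - 1) / 2.0
    yy, xx = np.mgrid[0:n_px, 0:n_px].astype(float)
    r_um = np.hypot(xx - c, yy - c) * pixel_size
    theta = np.degrees(np.arctan2(-(yy - c), xx - c))  # y flipped: CCW, y up

    masks = np.empty((n_frames, n_px, n_px), dtype=bool)
    for f in range(n_frames):
        radius = np.full((n_px, n_px), base_radius)
        for bisector, width, growth in protrusions:
            dtheta = (theta - bisector + 180.0) % 360.0 - 180.0
            in_sector = np.abs(dtheta) <= width / 2.0
            radius = np.where(in_sector, base_radius + growth * f, radius)
        masks[f] = r_um <= radius

    largest = max(protrusions, key=lambda p: p[2], default=(0.0, 0.0, 0.0))
    gt = GroundTruth(
        "protruding_mask_sequence",
        {
            "base_radius_um": base_radius,
            "pixel_size": pixel_size,
            "frame_interval_s": frame_interval,
            "n_sectors": len(protrusions),
            "largest_sector_bisector_deg": largest[0],
            "largest_sector_width_deg": largest[1],
            "growth_um_per_frame": largest[2],
            "growth_um_per_s": largest[2] / frame_interval,
            "center_x_um": c * pixel_size,
            "center_y_um": c * pixel_size,
        },
    )
    return MaskSeries(masks, pixel_size, frame_interval), gt


# ---------------------------------------------------------------------------
# voxelized ellipsoids
# ---------------------------------------------------------------------------

def make_ellipsoid_mask(
    radii: tuple[float, float, float],
    voxel_size: float = 0.25,
) -> tuple[np.ndarray, GroundTruth]:
    """Voxelized solid ellipsoid with semi-axes ``radii`` = (a, b, c) µm
    along (x, y, z). Ground truth stores the closed-form volume 4/3·πabc and
    the analytic sphericity (Thomsen approximation for the ellipsoid surface
    area, exact for a sphere)."""
    a, b, c = radii
    if min(radii) <= 2 * voxel_size:
        raise ParameterizationError("radii must exceed 2x the voxel size")
    half = np.array([c, b, a]) + 2 * voxel_size  # (z, y, x)
    n = np.ceil(2 * half / voxel_size).astype(int)
    ctr = (n - 1) / 2.0
    zz, yy, xx = np.mgrid[0 : n[0], 0 : n[1], 0 : n[2]].astype(float)
    mask = (
        ((xx - ctr[2]) * voxel_size / a) ** 2
        + ((yy - ctr[1]) * voxel_size / b) ** 2
        + ((zz - ctr[0]) * voxel_size / c) ** 2
    ) <= 1.0

    volume = 4.0 / 3.0 * np.pi * a * b * c
    p = 1.6075  # Thomsen exponent, max error ~1.06%
    area = 4.0 * np.pi * (
        ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    ) ** (1.0 / p)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    gt = GroundTruth(
        "ellipsoid_mask",
        {
            "a_um": a,
            "b_um": b,
            "c_um": c,
            "voxel_size": voxel_size,
            "volume_um3": float(volume),
            "sphericity": float(sphericity),
        },
    )
    return mask, gt
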