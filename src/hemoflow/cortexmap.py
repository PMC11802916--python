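"""Ratiometric cortex mapping (MPAct-style analysis).

A membrane-proximal actin (MPAct) probe imaged against a uniformly
membrane-targeted (CaaX) or actin (F-tractin) reference gives, pixel by
pixel, a ratio map of membrane-associated actin. This module builds the
ratio image, summarizes it per cell, extracts lamellar line-scan
distributions along rays from the cell edge toward the cell body, and
computes the cortical-enrichment statistic (signal at the cell-body edge
over signal at the body center).

Line scans are deterministic stand-ins for an interactive line tool: each
scan samples the image by bilinear interpolation at 0.5-px steps, with the
stated thickness realized as parallel offset lines averaged per step.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, QhullError

from .datatypes import (
    Movie,
    ParameterizationError,
    ScalarField,
    UndefinedResultError,
)

__all__ = [
    "Ellipse",
    "Profile",
    "ratio_image",
    "mpact_mean",
    "mask_centroid",
    "fit_circumscribing_ellipse",
    "lamellar_profiles",
    "mpact_lamellar_distribution",
    "cortical_enrichment",
]


@dataclasses.dataclass
class Ellipse:
    """Ellipse with fixed center (µm), semi-axes (µm) and orientation (rad).

    ``orientation`` is the angle of the semi-major axis in image coordinates
    (x along columns, y along rows).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (a, b), a >= b
    orientation: float

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ParameterizationError("semi-axes must be > 0")

    def radius_along(self, direction: tuple[float, float]) -> float:
        """Distance from center to the ellipse edge along a direction."""
        dx, dy = direction
        n = math.hypot(dx, dy)
        if n == 0:
            raise ParameterizationError("direction must be non-zero")
        dx, dy = dx / n, dy / n
        cphi, sphi = math.cos(self.orientation), math.sin(self.orientation)
        dxp = dx * cphi + dy * sphi
        dyp = -dx * sphi + dy * cphi
        a, b = self.semi_axes
        return 1.0 / math.sqrt((dxp / a) ** 2 + (dyp / b) ** 2)

    def contains(self, points: np.ndarray, slack: float = 1e-9) -> np.ndarray:
        """Containment test for (n, 2) points in µm."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center)
        cphi, sphi = math.cos(self.orientation), math.sin(self.orientation)
        xp = p[:, 0] * cphi + p[:, 1] * sphi
        yp = -p[:, 0] * sphi + p[:, 1] * cphi
        a, b = self.semi_axes
        return (xp / a) ** 2 + (yp / b) ** 2 <= 1.0 + slack


@dataclasses.dataclass
class Profile:
    """Averaged line-scan profile along an aligned distance axis.

    ``anchor`` states where distance 0 sits: at the cell edge (increasing
    inward) or at the cell-body edge (lamella positive, body negative).
    """

    distance: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    anchor: str  # "cell_edge" | "body_edge"
    units: str = "px"

    def __post_init__(self) -> None:
        if np.any(self.count < 0):
            raise ParameterizationError("counts must be >= 0")
        if not np.all(np.isfinite(self.mean[self.count > 0])):
            raise ParameterizationError("mean must be finite where count > 0")


# ---------------------------------------------------------------------------
# ratio images
# ---------------------------------------------------------------------------

def ratio_image(
    movie: Movie,
    numerator: str,
    denominator: str,
    background: tuple[float, float] = (0.0, 0.0),
    min_denominator: float = 1e-3,
) -> ScalarField:
    """Per-pixel background-subtracted channel ratio.

    Pixels whose background-subtracted denominator does not exceed
    ``min_denominator`` are invalid (gated, never infinite). Returns a
    pixel-resolution scalar field in µm coordinates.
    """
    if min_denominator <= 0:
        raise ParameterizationError("min_denominator must be > 0")
    num = movie.channel(numerator) - background[0]
    den = movie.channel(denominator) - background[1]
    valid = den > min_denominator
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(valid, num / np.where(valid, den, 1.0), 0.0)
    ps = movie.pixel_size
    h, w = movie.frame_shape
    return ScalarField(
        x=np.arange(w) * ps,
        y=np.arange(h) * ps,
        values=values,
        valid=valid,
        units="ratio",
    )


def mpact_mean(ratio: ScalarField, cell_mask: np.ndarray) -> float:
    """Mean ratio over valid pixels inside the segmented cell."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    sel = ratio.valid & cell_mask[None]
    if not sel.any():
        raise UndefinedResultError("no valid ratio pixel inside the cell mask")
    return float(ratio.values[sel].mean())


def mask_centroid(mask: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Area centroid of a binary mask in µm (x, y)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterizationError("empty mask")
    row, col = ndimage.center_of_mass(mask)
    return (col * pixel_size, row * pixel_size)


# ---------------------------------------------------------------------------
# circumscribing ellipse
# ---------------------------------------------------------------------------

def _required_semi_major(pts: np.ndarray, phi: float, q: float) -> float:
    """Smallest semi-major axis so the centered ellipse (phi, b = q a)
    contains every point (pts are centered)."""
    c, s = math.cos(phi), math.sin(phi)
    xp = pts[:, 0] * c + pts[:, 1] * s
    yp = -pts[:, 0] * s + pts[:, 1] * c
    return float(np.sqrt(np.max(xp**2 + (yp / q) ** 2)))


def fit_circumscribing_ellipse(
    cell_mask: np.ndarray,
    body_centroid: tuple[float, float],
    pixel_size: float,
) -> Ellipse:
    """Minimal-area ellipse centered at the body centroid containing the cell.

    The center is fixed at ``body_centroid`` (µm); orientation and axis
    ratio are searched (coarse grid then simplex refinement) with an exact
    containment check over the mask's convex-hull pixel centers. Ties are
    broken toward smaller eccentricity, so a disk returns a circle.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ParameterizationError("empty cell mask")
    cx, cy = body_centroid
    r_idx = int(round(cy / pixel_size))
    c_idx = int(round(cx / pixel_size))
    if not (
        0 <= r_idx < cell_mask.shape[0]
        and 0 <= c_idx < cell_mask.shape[1]
        and cell_mask[r_idx, c_idx]
    ):
        raise ParameterizationError("body centroid lies outside the cell mask")

    rows, cols = np.nonzero(cell_mask)
    pts = np.column_stack([cols * pixel_size - cx, rows * pixel_size - cy])
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        pass  # degenerate (e.g. collinear) masks: keep all points

    phis = np.linspace(0.0, np.pi, 72, endpoint=False)
    qs = np.linspace(0.1, 1.0, 37)
    best = None  # (area, -q, phi, q, a)
    for phi in phis:
        for q in qs:
            a = _required_semi_major(pts, phi, q)
            area = a * a * q
            key = (area, -q)
            if best is None or key < (best[0] - 1e-12 * best[0], best[1]):
                best = (area, -q, phi, q, a)
    _, _, phi0, q0, _ = best

    def objective(x: np.ndarray) -> float:
        phi, q = x[0], min(max(x[1], 0.02), 1.0)
        a = _required_semi_major(pts, phi, q)
        return a * a * q

    res = minimize(
        objective, np.array([phi0, q0]), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400},
    )
    phi, q = res.x[0] % np.pi, min(max(res.x[1], 0.02), 1.0)
    if objective(res.x) > best[0]:
        phi, q = phi0, q0
    a = _required_semi_major(pts, phi, q) * (1.0 + 1e-9)
    ell = Ellipse(center=(cx, cy), semi_axes=(a, q * a), orientation=phi)
    if not np.all(ell.contains(pts + np.array([cx, cy]))):  # hard guarantee
        a *= 1.0 + 1e-6
        ell = Ellipse(center=(cx, cy), semi_axes=(a, q * a), orientation=phi)
    return ell


# ---------------------------------------------------------------------------
# line-scan machinery
# ---------------------------------------------------------------------------

_STEP_PX = 0.5


def _image_arrays(image: ScalarField | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(image, ScalarField):
        return image.values[0], image.valid[0]
    arr = np.asarray(image, dtype=float)
    return arr, np.isfinite(arr)


def _scan_means(
    values: np.ndarray,
    img_valid: np.ndarray,
    include_mask: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    thickness_px: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean intensity along the scan p0 -> p1 (px coords, (x, y)).

    Thickness is realized as ``thickness_px`` parallel lines offset
    perpendicular to the scan at 1-px spacing, averaged per step. Samples
    outside ``include_mask`` or the image, or at invalid pixels, are
    dropped. Interpolation is validity-normalized: each bilinear sample
    weights only valid pixels, so values never bleed across a masked
    boundary. Returns (s_px, mean, n_included) per 0.5-px step.
    """
    d = p1 - p0
    length = float(np.hypot(*d))
    if length == 0:
        return np.array([]), np.array([]), np.array([])
    d = d / length
    n_perp = np.array([-d[1], d[0]])
    s = np.arange(0.0, length + _STEP_PX / 2, _STEP_PX)
    offsets = np.arange(thickness_px) - (thickness_px - 1) / 2.0
    centers = p0[None] + s[:, None] * d[None]  # (ns, 2) in (x, y)
    pts = centers[:, None, :] + offsets[None, :, None] * n_perp[None, None]
    rows = pts[..., 1].ravel()
    cols = pts[..., 0].ravel()
    h, w = values.shape
    inb = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    samp = np.zeros(rows.size)
    ok = np.zeros(rows.size, dtype=bool)
    if inb.any():
        coords = np.stack([rows[inb], cols[inb]])
        vf = img_valid.astype(float)
        num = ndimage.map_coordinates(values * vf, coords, order=1)
        wgt = ndimage.map_coordinates(vf, coords, order=1)
        good = wgt > 0.5  # at least half the bilinear weight from valid pixels
        samp_in = np.zeros(num.size)
        samp_in[good] = num[good] / wgt[good]
        samp[inb] = samp_in
        in_region = ndimage.map_coordinates(
            include_mask.astype(np.uint8), coords, order=0
        ).astype(bool)
        ok[inb] = good & in_region
    samp = samp.reshape(s.size, thickness_px)
    ok = ok.reshape(s.size, thickness_px)
    n = ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, (samp * ok).sum(axis=1) / np.maximum(n, 1), np.nan)
    return s, mean, n


def _ellipse_edge_points(
    ellipse: Ellipse, spacing_px: float, pixel_size: float
) -> np.ndarray:
    """Points on the ellipse edge equally spaced by arc length, px coords."""
    t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    a, b = ellipse.semi_axes
    c, s = math.cos(ellipse.orientation), math.sin(ellipse.orientation)
    ex = a * np.cos(t)
    ey = b * np.sin(t)
    x = (ellipse.center[0] + ex * c - ey * s) / pixel_size
    y = (ellipse.center[1] + ex * s + ey * c) / pixel_size
    seg = np.hypot(np.diff(x, append=x[:1]), np.diff(y, append=y[:1]))
    arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    perimeter = arc[-1] + seg[-1]
    n_scans = max(int(perimeter // spacing_px), 1)
    targets = np.arange(n_scans) * spacing_px
    idx = np.searchsorted(arc, targets)
    idx = np.clip(idx, 0, t.size - 1)
    return np.column_stack([x[idx], y[idx]])


def _first_true(mask_hits: np.ndarray) -> int | None:
    idx = np.flatnonzero(mask_hits)
    return int(idx[0]) if idx.size else None


def _mask_along(
    mask: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbor mask values along the scan center line."""
    d = p1 - p0
    length = float(np.hypot(*d))
    s = np.arange(0.0, length + _STEP_PX / 2, _STEP_PX)
    pts = p0[None] + s[:, None] * (d / length)[None]
    h, w = mask.shape
    rows = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
    cols = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
    inb = (pts[:, 1] >= -0.5) & (pts[:, 1] <= h - 0.5) & (pts[:, 0] >= -0.5) & (
        pts[:, 0] <= w - 0.5
    )
    return s, mask[rows, cols] & inb


def _accumulate(bins: dict[int, list[float]], bin_idx: np.ndarray, vals: np.ndarray):
    for b, val in zip(bin_idx, vals):
        bins.setdefault(int(b), []).append(float(val))


def _bins_to_profile(
    bins: dict[int, list[float]], step: float, anchor: str, units: str, sign: int = 1
) -> Profile:
    keys = sorted(bins)
    dist = np.array([k * step * sign for k in keys])
    order = np.argsort(dist)
    dist = dist[order]
    mean = np.array([np.mean(bins[keys[i]]) for i in order])
    count = np.array([len(bins[keys[i]]) for i in order])
    return Profile(distance=dist, mean=mean, count=count, anchor=anchor, units=units)


def lamellar_profiles(
    image: ScalarField | np.ndarray,
    cell_mask: np.ndarray,
    body_mask: np.ndarray,
    ellipse: Ellipse,
    pixel_size: float,
    exclusion_mask: np.ndarray | None = None,
    spacing_px: float = 100.0,
    thickness_px: int = 10,
) -> Profile:
    """Average lamellar line-scan profile, anchored at the cell edge.

    Scans start at points spaced ``spacing_px`` apart by arc length along
    the cell-circumscribing ellipse and run toward the body centroid
    (the ellipse center), sampling mean intensity across ``thickness_px``.
    Samples are restricted to the cell mask minus the exclusion regions
    (e.g. the cell body and fiber-free lamella areas). Each scan's distance
    axis starts at 0 where it first enters the cell; the per-cell average
    over scans is returned with the distance axis in px.
    """
    values, img_valid = _image_arrays(image)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    include = cell_mask.copy()
    if exclusion_mask is not None:
        include &= ~np.asarray(exclusion_mask, dtype=bool)
    center_px = np.asarray(ellipse.center) / pixel_size
    starts = _ellipse_edge_points(ellipse, spacing_px, pixel_size)

    bins: dict[int, list[float]] = {}
    any_hit = False
    for p0 in starts:
        s_axis, in_cell = _mask_along(cell_mask, p0, center_px)
        edge = _first_true(in_cell)
        if edge is None:
            continue
        s, mean, n = _scan_means(values, img_valid, include, p0, center_px,
                                 thickness_px)
        sel = (n > 0) & (np.arange(s.size) >= edge)
        if not sel.any():
            continue
        any_hit = True
        rel = np.round((s[sel] - s_axis[edge]) / _STEP_PX).astype(int)
        _accumulate(bins, rel, mean[sel])
    if not any_hit:
        raise UndefinedResultError("no line scan intersects the cell mask")
    return _bins_to_profile(bins, _STEP_PX, anchor="cell_edge", units="px")


def mpact_lamellar_distribution(
    ratio: ScalarField | np.ndarray,
    cell_mask: np.ndarray,
    body_mask: np.ndarray,
    pixel_size: float,
    exclusion_mask: np.ndarray | None = None,
    spacing_px: float = 100.0,
    thickness_px: int = 10,
) -> Profile:
    """Lamellar ratio distribution re-anchored at the body/lamella transition.

    Same scan machinery as :func:`lamellar_profiles` (ellipse fitted here,
    centered at the body centroid and circumscribing the cell), but each
    scan's distance axis is shifted so 0 sits where the scan first enters
    the body mask: positive distances lie in the lamella, negative inside
    the body.
    """
    values, img_valid = _image_arrays(ratio)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    body_mask = np.asarray(body_mask, dtype=bool)
    include = cell_mask.copy()
    if exclusion_mask is not None:
        include &= ~np.asarray(exclusion_mask, dtype=bool)
    centroid = mask_centroid(body_mask, pixel_size)
    ellipse = fit_circumscribing_ellipse(cell_mask, centroid, pixel_size)
    center_px = np.asarray(ellipse.center) / pixel_size
    starts = _ellipse_edge_points(ellipse, spacing_px, pixel_size)

    bins: dict[int, list[float]] = {}
    any_hit = False
    for p0 in starts:
        s_axis, in_cell = _mask_along(cell_mask, p0, center_px)
        _, in_body = _mask_along(body_mask, p0, center_px)
        edge = _first_true(in_cell)
        body_edge = _first_true(in_body)
        if edge is None or body_edge is None:
            continue
        s, mean, n = _scan_means(values, img_valid, include, p0, center_px,
                                 thickness_px)
        sel = (n > 0) & (np.arange(s.size) >= edge)
        if not sel.any():
            continue
        any_hit = True
        # distance from the body boundary: positive in the lamella
        rel = np.round((s_axis[body_edge] - s[sel]) / _STEP_PX).astype(int)
        _accumulate(bins, rel, mean[sel])
    if not any_hit:
        raise UndefinedResultError("no line scan intersects the cell mask")
    return _bins_to_profile(bins, _STEP_PX, anchor="body_edge", units="px")


def cortical_enrichment(
    image: ScalarField | np.ndarray,
    body_mask: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size: float,
    probe_center_offset: float = -3.0,
    offset_units: str = "um",
    thickness_px: int = 10,
    n_scans: int = 72,
    min_coverage: float = 0.1,
) -> float:
    """Signal at the cell-body edge over signal at the body center.

    Scans of ``thickness_px`` run from the body centroid outward to the cell
    edge in ``n_scans`` directions. Each scan's axis is aligned at the
    body-circumscribing ellipse edge (x = 0; lamella positive, body
    negative). Probe values are bin means (0.5-px bins) across scans,
    requiring data from at least ``min_coverage`` of the scans at both
    probes. ``probe_center_offset`` places the body-center probe, by default
    at x = -3 µm (the axis unit is configurable: "um" or "px").
    """
    if offset_units not in ("um", "px"):
        raise ParameterizationError("offset_units must be 'um' or 'px'")
    values, img_valid = _image_arrays(image)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    body_mask = np.asarray(body_mask, dtype=bool)
    centroid = mask_centroid(body_mask, pixel_size)
    body_ellipse = fit_circumscribing_ellipse(body_mask, centroid, pixel_size)
    center_px = np.asarray(centroid) / pixel_size

    axis_scale = pixel_size if offset_units == "um" else 1.0  # px -> axis units
    bin_width = _STEP_PX * axis_scale
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    scan_hits: dict[int, int] = {}
    h, w = cell_mask.shape
    max_len = float(np.hypot(h, w))
    for i in range(n_scans):
        theta = 2 * np.pi * i / n_scans
        d = np.array([math.cos(theta), math.sin(theta)])
        p1 = center_px + d * max_len
        s_axis, in_cell = _mask_along(cell_mask, center_px, p1)
        hits = np.flatnonzero(in_cell)
        if hits.size == 0:
            continue
        end = hits[-1]  # last sample still inside the cell
        s, mean, n = _scan_means(values, img_valid, cell_mask, center_px, p1,
                                 thickness_px)
        sel = (n > 0) & (np.arange(s.size) <= end)
        if not sel.any():
            continue
        r_ell_px = body_ellipse.radius_along(tuple(d)) / pixel_size
        x = (s[sel] - r_ell_px) * axis_scale
        b_idx = np.round(x / bin_width).astype(int)
        for b, val in zip(b_idx, mean[sel]):
            sums[int(b)] = sums.get(int(b), 0.0) + float(val)
            counts[int(b)] = counts.get(int(b), 0) + 1
        for b in np.unique(b_idx):
            scan_hits[int(b)] = scan_hits.get(int(b), 0) + 1

    def probe(x_axis: float, name: str) -> float:
        b = int(round(x_axis / bin_width))
        if scan_hits.get(b, 0) < min_coverage * n_scans:
            raise UndefinedResultError(
                f"insufficient scan coverage at the {name} probe (x = {x_axis})"
            )
        return sums[b] / counts[b]

    edge_val = probe(0.0, "body-edge")
    center_val = probe(probe_center_offset, "body-center")
    if center_val == 0:
        raise UndefinedResultError("zero signal at the body-center probe")
    return edge_val / center_val
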