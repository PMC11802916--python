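"""Scalar analysis of flow fields: divergence, sink maps, regional summaries.

Negative divergence marks sinks — regions where the actin network is
compressed. Divergence is computed with a central difference scheme on the
PIV node grid (one-sided at the borders), in 1/min for µm/min velocities.
The cortical region is a ring of configurable width (default 5 µm) around
the cell body; the lamellar region is the cell minus the body and the ring.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .datatypes import (
    FlowField,
    ParameterizationError,
    ScalarField,
    UndefinedResultError,
)
from .flow import nodes_in_mask

__all__ = [
    "RegionSpec",
    "divergence",
    "negative_divergence",
    "cortical_ring",
    "lamellar_region",
    "region_mean",
    "negative_divergence_summary",
    "nodes_in_mask",
]


@dataclasses.dataclass
class RegionSpec:
    """Named analysis region: the lamella or the cortical ring around the body."""

    kind: str  # "lamellar" | "cortical"
    cortical_ring_width: float = 5.0  # µm

    def __post_init__(self) -> None:
        if self.kind not in ("lamellar", "cortical"):
            raise ParameterizationError("kind must be 'lamellar' or 'cortical'")
        if self.cortical_ring_width <= 0:
            raise ParameterizationError("ring width must be > 0")

    def resolve(
        self, cell_mask: np.ndarray, body_mask: np.ndarray, pixel_size: float
    ) -> np.ndarray:
        ring = cortical_ring(body_mask, self.cortical_ring_width, pixel_size)
        if self.kind == "cortical":
            return ring
        return lamellar_region(cell_mask, body_mask, ring)


def _stencil_valid(valid: np.ndarray, axis: int) -> np.ndarray:
    """Validity of the central-difference stencil along one axis.

    Interior nodes need both neighbors valid; border nodes (one-sided
    difference) need the two nodes the difference uses.
    """
    v = np.moveaxis(valid, axis, -1)
    out = np.empty_like(v)
    out[..., 1:-1] = v[..., :-2] & v[..., 2:]
    out[..., 0] = v[..., 0] & v[..., 1]
    out[..., -1] = v[..., -2] & v[..., -1]
    return np.moveaxis(out, -1, axis)


def divergence(field: FlowField) -> ScalarField:
    """Central-difference divergence ∂u/∂x + ∂v/∂y of the flow, 1/min.

    One-sided differences are used at grid borders. A node is invalid
    wherever any node its stencil touches is invalid.
    """
    if field.u.shape[1] < 3 or field.u.shape[2] < 3:
        raise ParameterizationError("divergence needs a grid of at least 3x3 nodes")
    h = field.grid_spacing
    dudx = np.gradient(field.u, h, axis=2)
    dvdy = np.gradient(field.v, h, axis=1)
    valid = _stencil_valid(field.valid, axis=2) & _stencil_valid(field.valid, axis=1)
    values = np.where(valid, dudx + dvdy, 0.0)
    return ScalarField(x=field.x, y=field.y, values=values, valid=valid, units="1/min")


def negative_divergence(div: ScalarField) -> ScalarField:
    """Clip a divergence field to its sinks: min(div, 0), validity preserved."""
    return ScalarField(
        x=div.x,
        y=div.y,
        values=np.minimum(div.values, 0.0),
        valid=div.valid.copy(),
        units=div.units,
    )


def cortical_ring(
    cell_body_mask: np.ndarray, width: float, pixel_size: float
) -> np.ndarray:
    """Pixels outside the body whose Euclidean distance to it is <= width µm."""
    body = np.asarray(cell_body_mask).astype(bool)
    if not body.any():
        raise ParameterizationError("empty cell-body mask")
    if width <= 0:
        raise ParameterizationError("ring width must be > 0")
    dist = ndimage.distance_transform_edt(~body) * pixel_size
    return ~body & (dist <= width)


def lamellar_region(
    cell_mask: np.ndarray, body_mask: np.ndarray, ring: np.ndarray
) -> np.ndarray:
    """Lamellar analysis region: cell minus body minus cortical ring."""
    return np.asarray(cell_mask, bool) & ~np.asarray(body_mask, bool) & ~np.asarray(
        ring, bool
    )


def region_mean(field: ScalarField, region: np.ndarray) -> float:
    """Mean of valid values at nodes inside the region, over all frames.

    ``region`` is a boolean selection on the node grid, ``(ny, nx)`` or per
    frame ``(T, ny, nx)`` (build one from pixel masks with
    :func:`nodes_in_mask`). Every valid node-frame sample weighs equally.
    """
    region = np.asarray(region, dtype=bool)
    sel = field.valid & (region if region.ndim == 3 else region[None])
    if not sel.any():
        raise UndefinedResultError("no valid node inside the region")
    return float(field.values[sel].mean())


def negative_divergence_summary(
    div: ScalarField, region: np.ndarray, estimator: str = "clipped"
) -> float:
    """Regional summary of sink strength, 1/min.

    ``clipped`` (default) averages min(div, 0) over all valid nodes in the
    region; ``negatives_only`` averages only the strictly negative nodes.
    The default is recorded so downstream outputs can state which estimator
    produced them.
    """
    if estimator == "clipped":
        return region_mean(negative_divergence(div), region)
    if estimator == "negatives_only":
        region = np.asarray(region, dtype=bool)
        sel = div.valid & (region if region.ndim == 3 else region[None])
        sel &= div.values < 0
        if not sel.any():
            raise UndefinedResultError("no negative node inside the region")
        return float(div.values[sel].mean())
    raise ParameterizationError("estimator must be 'clipped' or 'negatives_only'")
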