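"""Minimal rendering helpers: vector fields, scalar colormaps, streamlines,
rose plots. All functions draw onto a provided or fresh matplotlib Axes and
return it; saving is the caller's business."""

from __future__ import annotations

import numpy as np

from .datatypes import FlowField, ScalarField


def _get_ax(ax=None):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_flow(field: FlowField, frame: int = 0, ax=None, **quiver_kw):
    """Quiver plot of one frame of a flow field (invalid nodes omitted)."""
    ax = _get_ax(ax)
    ok = field.valid[frame]
    xx, yy = np.meshgrid(field.x, field.y)
    ax.quiver(
        xx[ok], yy[ok], field.u[frame][ok], -field.v[frame][ok],
        angles="xy", **quiver_kw,
    )
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.invert_yaxis()
    return ax


def plot_scalar(field: ScalarField, frame: int = 0, ax=None, **imshow_kw):
    """Colormap of one frame of a scalar field; invalid nodes masked out."""
    ax = _get_ax(ax)
    vals = np.ma.masked_where(~field.valid[frame], field.values[frame])
    extent = (field.x[0], field.x[-1], field.y[-1], field.y[0])
    im = ax.imshow(vals, extent=extent, **imshow_kw)
    ax.figure.colorbar(im, ax=ax, label=field.units)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    return ax


def plot_streamlines(lines, ax=None, **plot_kw):
    """Draw polylines returned by :func:`hemoflow.flow.streamlines`."""
    ax = _get_ax(ax)
    for line in lines:
        if len(line):
            ax.plot(line[:, 0], line[:, 1], **plot_kw)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    return ax


def rose_plot(hist: np.ndarray, bin_edges_deg: np.ndarray, ax=None):
    """Polar rose plot of an angular histogram (motion along 0°)."""
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.deg2rad(0.5 * (bin_edges_deg[:-1] + bin_edges_deg[1:]))
    width = np.deg2rad(np.diff(bin_edges_deg))
    ax.bar(centers, hist, width=width, bottom=0.0, alpha=0.7, edgecolor="k")
    return ax
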