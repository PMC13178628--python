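"""Polar-plot and heat-ring visualization of peripheral deformation values.

The 8 discrete per-spot values are shown as points on a polar plot with a
connecting line; the surrounding annulus ("heat ring") is a periodic cubic
spline over azimuth, resampled densely so the colour varies smoothly while
passing exactly through every knot.  Meridional asymmetry vectors are drawn
dotted and the overall asymmetry vector solid; a pre/post difference shape
can be overlaid for treatment comparisons.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib
import numpy as np
from scipy.interpolate import CubicSpline

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .core import ConfigError, SpotLayout  # noqa: E402
from .metrics import AsymmetryVector  # noqa: E402

__all__ = ["heat_ring", "polar_figure", "render_report"]

# deterministic SVG output across processes
matplotlib.rcParams["svg.hashsalt"] = "puffoct"


def heat_ring(
    values: Mapping[str, float],
    layout: SpotLayout,
    resolution_deg: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Periodic-spline ring samples over azimuth.

    Returns ``(azimuth_deg, ring_values)`` with azimuths covering [0, 360)
    once at the requested resolution.  The spline is periodic (continuous in
    value and first derivative across the 0/360 seam) and interpolates every
    knot exactly.
    """
    labels = layout.peripheral_labels
    for lab in labels:
        if lab not in values:
            raise ConfigError(f"missing value for peripheral spot {lab}")
        if not np.isfinite(values[lab]):
            raise ConfigError(f"non-finite value for peripheral spot {lab}")
    if resolution_deg <= 0 or resolution_deg > 45:
        raise ConfigError("resolution_deg must be in (0, 45]")
    azis = np.array([layout.azimuth(lab) for lab in labels])
    vals = np.array([float(values[lab]) for lab in labels])
    order = np.argsort(azis)
    azis, vals = azis[order], vals[order]
    knots = np.append(azis, azis[0] + 360.0)
    kvals = np.append(vals, vals[0])
    spline = CubicSpline(knots, kvals, bc_type="periodic")
    grid = np.arange(0.0, 360.0, resolution_deg)
    return grid, spline(azis[0] + (grid - azis[0]) % 360.0)


def _draw_vector(ax, vector: AsymmetryVector, rmax: float,
                 color: str, label: str | None = None) -> None:
    theta = np.radians(vector.azimuth_deg)
    ax.annotate(
        "", xy=(theta, vector.magnitude), xytext=(0, 0),
        arrowprops=dict(arrowstyle="-|>", color=color, lw=2),
    )
    if label:
        ax.plot([], [], color=color, lw=2, label=label)


def polar_figure(
    values: Mapping[str, float],
    layout: SpotLayout,
    vector: AsymmetryVector | None = None,
    diff_values: Mapping[str, float] | None = None,
    ring_resolution_deg: float = 1.0,
    title: str = "",
) -> "plt.Figure":
    """Polar plot with 8 spot points, heat ring, and vector overlays."""
    labels = layout.peripheral_labels
    azis = np.array([layout.azimuth(lab) for lab in labels])
    vals = np.array([float(values[lab]) for lab in labels])

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    theta = np.radians(np.append(azis, azis[0]))
    r = np.append(vals, vals[0])
    ax.plot(theta, r, "-o", color="tab:green", lw=1.5, ms=6, label="per-spot")

    rmax = float(np.max(np.abs(vals))) or 1.0
    grid_deg, ring = heat_ring(values, layout, ring_resolution_deg)
    ring_theta = np.radians(np.append(grid_deg, 360.0))
    ring_vals = np.append(ring, ring[0])
    rr = np.array([1.05 * rmax, 1.18 * rmax])
    tt, rr_grid = np.meshgrid(ring_theta, rr)
    ax.pcolormesh(tt, rr_grid, np.vstack([ring_vals, ring_vals]),
                  cmap="turbo", shading="gouraud",
                  vmin=float(ring_vals.min()), vmax=float(ring_vals.max()))

    if diff_values is not None:
        dvals = np.array([float(diff_values[lab]) for lab in labels])
        ax.plot(theta, np.append(dvals, dvals[0]), "-", color="tab:olive",
                lw=1.2, label="difference")

    if vector is not None:
        for m in vector.meridionals:
            ax.annotate("", xy=(np.radians(m.azimuth_deg), m.magnitude),
                        xytext=(0, 0),
                        arrowprops=dict(arrowstyle="-|>", color="tab:orange",
                                        lw=1.2, linestyle=":"))
        if vector.is_zero:
            ax.text(0.5, 0.5, "zero-magnitude asymmetry vector",
                    transform=ax.transAxes, ha="center", va="center",
                    fontsize=9, color="tab:blue")
        else:
            _draw_vector(ax, vector, rmax, "tab:blue", "asymmetry vector")

    ax.set_rlim(0, 1.25 * rmax)
    if title:
        ax.set_title(title)
    return fig


def render_report(
    values: Mapping[str, float],
    layout: SpotLayout,
    vector: AsymmetryVector | None,
    out_dir: str | Path,
    stem: str = "report",
    diff_values: Mapping[str, float] | None = None,
    formats: tuple[str, ...] = ("svg", "png"),
    title: str = "",
) -> dict[str, Path]:
    """Write the polar report figure as SVG and/or PNG; deterministic bytes
    for fixed inputs (SVG hash salt pinned, no timestamps embedded)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig = polar_figure(values, layout, vector, diff_values, title=title)
    paths: dict[str, Path] = {}
    try:
        for fmt in formats:
            p = out_dir / f"{stem}.{fmt}"
            fig.savefig(p, format=fmt, metadata={"Date": None}
                        if fmt == "svg" else None)
            paths[fmt] = p
    finally:
        plt.close(fig)
    return paths
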