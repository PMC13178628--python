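"""Anterior-surface tracking: M-scan images → displacement profiles.

Two routes produce a per-channel boundary series (surface row vs time, in
axial pixels):

* :func:`read_mask` / :func:`mask_boundary` — the manual workflow, where an
  operator paints the anterior surface on a mask overlay (red curve on an
  image-editor mask layer, exported as PNG) and the topmost marked pixel per
  time column is taken as the boundary;
* :func:`track_surface` — an automatic intensity tracker (threshold at
  window median + k·MAD, intensity-weighted centroid) suited to synthetic
  and clean instrument data.

:func:`to_displacement` then converts a boundary series into a
:class:`~puffoct.core.DisplacementProfile` in micrometres, zeroed on a
pre-onset baseline window, with indentation (surface moving away from the
probe, i.e. down the image) positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

from .core import (
    ConfigError,
    DisplacementProfile,
    MScan,
    MaskError,
    TrackingError,
)

__all__ = [
    "SegmentationMask",
    "read_mask",
    "mask_boundary",
    "track_surface",
    "track_all",
    "to_displacement",
]


@dataclass
class SegmentationMask:
    """Binary segmentation grid congruent with an M-scan image."""

    mask: np.ndarray          # bool, same shape as the M-scan image
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise MaskError("mask must be a 2-D grid")


def _binarize(arr: np.ndarray) -> np.ndarray:
    """RGB(A): red channel above half range; grayscale: any nonzero."""
    if arr.ndim == 3:
        red = arr[..., 0].astype(float)
        # normalise half-range for both 8- and 16-bit encodings
        half = 127.5 if arr.dtype == np.uint8 else float(arr[..., 0].max()) / 2.0
        return red > half
    return arr != 0


def read_mask(mask: str | Path | np.ndarray, mscan: MScan) -> SegmentationMask:
    """Load a painted mask overlay and validate it against an M-scan.

    Nonzero pixels (red channel above half range for RGB inputs, any nonzero
    value for grayscale) become the binary mask.  Every channel depth window
    must contain at least one marked pixel; channels with empty windows are
    reported together in the error message.
    """
    if isinstance(mask, (str, Path)):
        arr = np.asarray(Image.open(mask))
    else:
        arr = np.asarray(mask)
    binary = _binarize(arr)
    if binary.shape != mscan.image.shape:
        raise MaskError(
            f"mask shape {binary.shape} does not match M-scan image shape "
            f"{mscan.image.shape}"
        )
    empty = [lab for lab, (lo, hi) in mscan.windows.items()
             if not binary[lo:hi, :].any()]
    if empty:
        raise MaskError(
            "mask has no marked pixels in the depth window(s) of channel(s): "
            + ", ".join(empty)
        )
    return SegmentationMask(mask=binary, provenance="manual")


def mask_boundary(segmask: SegmentationMask, mscan: MScan,
                  label: str) -> np.ndarray:
    """Boundary series (absolute axial-pixel rows) of one channel's mask.

    Columns with several marked pixels keep the topmost (shallowest) one —
    the anterior surface is the first interface the beam meets.  Columns
    with no marked pixel are linearly interpolated from marked neighbours.
    """
    lo, hi = mscan.windows[label]
    window = segmask.mask[lo:hi, :]
    n_t = window.shape[1]
    marked = window.any(axis=0)
    if not marked.any():
        raise MaskError(f"mask empty in the depth window of channel {label}")
    topmost = np.argmax(window, axis=0).astype(float)  # first True per column
    cols = np.arange(n_t)
    boundary = np.interp(cols, cols[marked], topmost[marked])
    return boundary + lo


def track_surface(mscan: MScan, label: str, k_mad: float = 5.0,
                  max_fail_frac: float = 0.2,
                  search_halfwidth_px: float | None = None) -> np.ndarray:
    """Automatic boundary series of one channel, in absolute axial pixels.

    Per time column, the boundary is the intensity-weighted centroid of
    pixels above ``median + k_mad * MAD`` of the channel window (weights are
    background-subtracted, which makes the result invariant to a constant
    intensity offset).  The centroid is confined to a neighbourhood of the
    column's intensity maximum (``search_halfwidth_px``, default 4 ridge
    widths) so isolated noise pixels elsewhere in the window cannot drag it.
    Columns with no suprathreshold pixel are linearly interpolated from
    their neighbours; if more than ``max_fail_frac`` of columns fail, the
    channel is considered untrackable.
    """
    if label not in mscan.windows:
        raise ConfigError(f"unknown channel label {label!r}")
    lo, hi = mscan.windows[label]
    window = mscan.image[lo:hi, :].astype(float)
    med = float(np.median(window))
    mad = float(np.median(np.abs(window - med)))
    thr = med + k_mad * mad
    weights = np.where(window > thr, window - med, 0.0)
    if search_halfwidth_px is None:
        search_halfwidth_px = 4.0 * mscan.config.ridge_width_px
    peak_rows = np.argmax(window, axis=0)
    row_idx = np.arange(window.shape[0])[:, None]
    near_peak = np.abs(row_idx - peak_rows[None, :]) <= search_halfwidth_px
    weights = np.where(near_peak, weights, 0.0)
    colsum = weights.sum(axis=0)
    failed = colsum <= 0
    fail_frac = failed.mean()
    if fail_frac > max_fail_frac:
        raise TrackingError(
            f"channel {label}: {fail_frac:.0%} of columns have no signal above "
            f"threshold (limit {max_fail_frac:.0%})"
        )
    rows = np.arange(window.shape[0], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = (rows[:, None] * weights).sum(axis=0) / colsum
    if failed.any():
        cols = np.arange(window.shape[1])
        centroid[failed] = np.interp(
            cols[failed], cols[~failed], centroid[~failed]
        )
    return centroid + lo


def track_all(mscan: MScan, k_mad: float = 5.0,
              max_fail_frac: float = 0.2) -> dict[str, np.ndarray]:
    """Boundary series for every channel of an M-scan."""
    return {lab: track_surface(mscan, lab, k_mad, max_fail_frac)
            for lab in mscan.windows}


def to_displacement(
    boundary_px: np.ndarray,
    mscan: MScan,
    label: str = "",
    baseline_ms: tuple[float, float] = (0.0, 2.0),
) -> DisplacementProfile:
    """Convert a boundary series (axial pixels) to a displacement profile.

    displacement_µm(t) = (boundary(t) − ⟨boundary⟩_baseline) × pixel pitch,
    with indentation positive (rows grow away from the probe).  The baseline
    window must lie inside the record, precede the deformation, and contain
    at least 20 samples; its standard deviation is recorded as
    ``baseline_sigma_um``.
    """
    boundary_px = np.asarray(boundary_px, dtype=float)
    t = mscan.time_ms
    if boundary_px.shape != t.shape:
        raise ConfigError("boundary series length does not match the M-scan")
    t0, t1 = baseline_ms
    if not (0 <= t0 < t1 <= t[-1] + mscan.config.dt_ms):
        raise ConfigError(
            f"baseline window {baseline_ms} ms lies outside the record"
        )
    sel = (t >= t0) & (t < t1)
    if sel.sum() < 20:
        raise ConfigError("baseline window must contain >= 20 samples")
    pitch = mscan.config.axial_pixel_pitch_um
    base = boundary_px[sel].mean()
    disp = (boundary_px - base) * pitch
    sigma = float(np.std(boundary_px[sel] * pitch))
    return DisplacementProfile(
        time_ms=t, displacement_um=disp, label=label, baseline_sigma_um=sigma
    )


def profiles_from_mscan(
    mscan: MScan,
    mask: SegmentationMask | None = None,
    k_mad: float = 5.0,
    baseline_ms: tuple[float, float] = (0.0, 2.0),
) -> dict[str, DisplacementProfile]:
    """End-to-end: boundaries (mask or automatic) → displacement profiles."""
    out: dict[str, DisplacementProfile] = {}
    for lab in mscan.windows:
        if mask is not None:
            boundary = mask_boundary(mask, mscan, lab)
        else:
            boundary = track_surface(mscan, lab, k_mad=k_mad)
        out[lab] = to_displacement(boundary, mscan, lab, baseline_ms)
    return out
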