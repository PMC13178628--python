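"""Temporal down-sampling error analysis and repeatability statistics.

The native instrument samples displacement every 10 µs (100 kHz A-scan
rate).  :func:`downsample` emulates slower devices by decimating (integer
rate factors) or linearly interpolating (non-integer factors, e.g. 33.3 µs)
a profile onto a coarser grid, and :func:`worst_case_error` quantifies how
badly the asymmetry vector degrades in the *worst case* over all temporal
offsets of the coarse grid relative to the transient — coarse sampling can
miss the deformation peak by up to half a coarse period, biasing amplitudes
and hence both magnitude and azimuth of the vector.

:func:`repeatability` summarises repeated acquisitions of the same eye:
component-wise mean vector, circular standard deviation of the azimuths,
and (normalized) standard deviation of the magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import circmean, circstd

from .core import (
    ConfigError,
    DisplacementProfile,
    OnsetError,
    ParameterError,
    SpotLayout,
)
from .metrics import (
    AsymmetryVector,
    angular_distance,
    extract_params,
)

__all__ = [
    "DownsamplingReport",
    "RepeatabilityReport",
    "downsample",
    "worst_case_error",
    "repeatability",
]


def downsample(profile: DisplacementProfile, target_dt_us: float,
               offset_us: float = 0.0) -> DisplacementProfile:
    """Resample a profile onto a coarser uniform grid.

    Integer multiples of the native period decimate at matching indices;
    non-integer targets (e.g. 33.3 µs from a 10 µs grid) linearly
    interpolate the native profile at the coarse timestamps.  ``offset_us``
    shifts the coarse grid within one coarse period, emulating the unknown
    phase of the sampling clock relative to the transient.
    """
    native_us = profile.dt_ms * 1000.0
    if target_dt_us < native_us * (1 - 1e-9):
        raise ConfigError(
            f"target_dt {target_dt_us} us is finer than the native "
            f"{native_us} us grid"
        )
    if not 0 <= offset_us < target_dt_us:
        raise ConfigError("offset must satisfy 0 <= offset < target_dt")
    factor = target_dt_us / native_us
    if abs(factor - round(factor)) < 1e-9:
        f = int(round(factor))
        k0 = int(round(offset_us / native_us))
        t = profile.time_ms[k0::f]
        d = profile.displacement_um[k0::f]
    else:
        t0 = profile.time_ms[0] + offset_us / 1000.0
        step = target_dt_us / 1000.0
        n = int(np.floor((profile.time_ms[-1] - t0) / step)) + 1
        t = t0 + step * np.arange(n)
        d = np.interp(t, profile.time_ms, profile.displacement_um)
    if t.size < 2:
        raise ConfigError("down-sampled grid has fewer than 2 samples")
    return DisplacementProfile(
        time_ms=t, displacement_um=d, label=profile.label,
        baseline_sigma_um=profile.baseline_sigma_um,
    )


@dataclass
class DownsamplingReport:
    """Worst-case asymmetry-vector errors at one target temporal resolution.

    Magnitude errors are percentages of the reference (native-resolution)
    vector magnitude; azimuth errors are absolute degrees.  ``worst_*`` are
    the maxima over the scanned temporal offsets.  If the reference vector
    has zero magnitude the percentage is undefined (``ref_zero`` set, NaN
    reported); azimuth errors are still reported.
    """

    target_dt_us: float
    offsets_us: np.ndarray
    magnitude_error_pct: np.ndarray
    azimuth_error_deg: np.ndarray
    reference: AsymmetryVector
    ref_zero: bool = False

    @property
    def worst_magnitude_error_pct(self) -> float:
        if self.ref_zero:
            return float("nan")
        return float(np.max(self.magnitude_error_pct))

    @property
    def worst_azimuth_error_deg(self) -> float:
        return float(np.max(self.azimuth_error_deg))

    def per_offset_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset_us": self.offsets_us,
            "magnitude_error_pct": self.magnitude_error_pct,
            "azimuth_error_deg": self.azimuth_error_deg,
        })

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "target_dt_us": self.target_dt_us,
            "worst_magnitude_error_pct": self.worst_magnitude_error_pct,
            "worst_azimuth_error_deg": self.worst_azimuth_error_deg,
            "ref_zero": self.ref_zero,
            "reference": self.reference.to_dict(),
            "offsets_us": self.offsets_us.tolist(),
            "magnitude_error_pct": self.magnitude_error_pct.tolist(),
            "azimuth_error_deg": self.azimuth_error_deg.tolist(),
        }
        path.write_text(json.dumps(payload, indent=2, allow_nan=True))
        return path


def _da1_map(profiles: Mapping[str, DisplacementProfile],
             labels: Sequence[str], **extract_kwargs) -> dict[str, float]:
    """Per-spot DA1; a spot whose coarse profile yields no detectable onset
    or peak contributes 0 (the sampling grid missed the event)."""
    out: dict[str, float] = {}
    for lab in labels:
        try:
            out[lab] = extract_params(profiles[lab], **extract_kwargs).da1_um
        except (OnsetError, ParameterError):
            out[lab] = 0.0
    return out


def worst_case_error(
    profiles: Mapping[str, DisplacementProfile],
    target_dt_us: float,
    layout: SpotLayout,
    source_param: str = "DA1",
    **extract_kwargs,
) -> DownsamplingReport:
    """Worst-case asymmetry-vector error over all coarse-grid offsets.

    ``profiles`` must contain the eight peripheral spots on a common native
    grid.  For every admissible offset (all multiples of the native period
    within one coarse period), the profiles are down-sampled, onset is
    re-detected and DA1 re-extracted per spot, the asymmetry vector is
    recomputed, and its magnitude error (percent of the native-resolution
    reference magnitude) and absolute azimuth error (degrees) are recorded.
    """
    labels = layout.peripheral_labels
    for lab in labels:
        if lab not in profiles:
            raise ConfigError(f"missing profile for peripheral spot {lab}")
    native_us = profiles[labels[0]].dt_ms * 1000.0
    for lab in labels[1:]:
        if not np.isclose(profiles[lab].dt_ms * 1000.0, native_us):
            raise ConfigError("profiles must share a common native grid")

    ref_values = _da1_map(profiles, labels, **extract_kwargs)
    reference = AsymmetryVector.from_values(ref_values, layout, source_param)
    ref_zero = reference.is_zero

    n_off = max(1, int(np.ceil(target_dt_us / native_us - 1e-9)))
    offsets = native_us * np.arange(n_off)

    mag_err = np.full(n_off, np.nan)
    azi_err = np.zeros(n_off)
    for j, off in enumerate(offsets):
        coarse = {lab: downsample(profiles[lab], target_dt_us, off)
                  for lab in labels}
        values = _da1_map(coarse, labels, **extract_kwargs)
        vec = AsymmetryVector.from_values(values, layout, source_param)
        if not ref_zero:
            mag_err[j] = (abs(vec.magnitude - reference.magnitude)
                          / reference.magnitude * 100.0)
        azi_err[j] = angular_distance(vec.azimuth_deg, reference.azimuth_deg)
    return DownsamplingReport(
        target_dt_us=target_dt_us, offsets_us=offsets,
        magnitude_error_pct=mag_err, azimuth_error_deg=azi_err,
        reference=reference, ref_zero=ref_zero,
    )


# ---------------------------------------------------------------------------
# Repeatability
# ---------------------------------------------------------------------------


@dataclass
class RepeatabilityReport:
    """Spread of repeated asymmetry-vector measurements of one eye."""

    n: int
    mean_x: float
    mean_y: float
    mean_magnitude: float
    mean_azimuth_deg: float
    angle_sd_deg: float
    magnitude_sd_um: float
    normalized_magnitude_sd: float
    magnitude_sd_px: float | None = None
    source_param: str = "DA1"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_vector": [self.mean_x, self.mean_y],
            "mean_magnitude": self.mean_magnitude,
            "mean_azimuth_deg": self.mean_azimuth_deg,
            "angle_sd_deg": self.angle_sd_deg,
            "magnitude_sd_um": self.magnitude_sd_um,
            "magnitude_sd_px": self.magnitude_sd_px,
            "normalized_magnitude_sd": self.normalized_magnitude_sd,
            "source_param": self.source_param,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def repeatability(vectors: Sequence[AsymmetryVector],
                  pixel_pitch_um: float | None = None) -> RepeatabilityReport:
    """Mean vector and dispersion of >= 2 repeated asymmetry vectors.

    The angle spread is the circular standard deviation of the azimuths
    (azimuths are periodic, so a linear SD would be wrong near the 0/360
    seam); the magnitude spread is the sample standard deviation of the
    magnitudes, also reported normalized by the mean magnitude and — when a
    pixel pitch is given — in axial pixels.
    """
    if len(vectors) < 2:
        raise ConfigError("repeatability needs at least 2 repeated vectors")
    params = {v.source_param for v in vectors}
    if len(params) != 1:
        raise ConfigError(
            f"repeats mix source parameters: {sorted(params)}"
        )
    xs = np.array([v.x for v in vectors])
    ys = np.array([v.y for v in vectors])
    mags = np.array([v.magnitude for v in vectors])
    azis = np.array([v.azimuth_deg for v in vectors])

    mean_x, mean_y = float(xs.mean()), float(ys.mean())
    mean_mag = float(mags.mean())
    mean_azi = float(circmean(azis, high=360.0, low=0.0))
    angle_sd = float(circstd(azis, high=360.0, low=0.0))
    mag_sd = float(np.std(mags, ddof=1))
    norm_sd = mag_sd / mean_mag if mean_mag > 0 else float("nan")
    mag_sd_px = mag_sd / pixel_pitch_um if pixel_pitch_um else None
    return RepeatabilityReport(
        n=len(vectors), mean_x=mean_x, mean_y=mean_y,
        mean_magnitude=mean_mag, mean_azimuth_deg=mean_azi,
        angle_sd_deg=angle_sd, magnitude_sd_um=mag_sd,
        normalized_magnitude_sd=norm_sd, magnitude_sd_px=mag_sd_px,
        source_param=vectors[0].source_param,
    )
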