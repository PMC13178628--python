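"""Deformation parameters and the meridional asymmetry-vector statistic.

From each spot's displacement profile, nine descriptors of the transient
deformation are extracted: the displacement amplitudes DA1 (first
indentation peak), DA2 (intervening relaxation minimum) and DA3 (second
indentation peak), their latencies t_DA1–t_DA3 from deformation onset, the
symmetric mean (DA1+DA3)/2, the DA1/DA3 ratio, and the area enclosed by the
displacement curve.  Single-peak profiles carry DA1 only, with DA2/DA3
flagged absent.

The asymmetry statistic then works on the eight peripheral spots: each
opposite-spot pair yields a meridional vector whose length is the absolute
value difference and whose direction points toward the higher-valued spot;
the planar sum of the four meridional vectors is the overall asymmetry
vector, whose magnitude quantifies and azimuth localizes the biomechanical
imbalance (e.g. a keratoconus cone).  By construction the statistic is
linear in the per-spot values, invariant to a common offset, and equivariant
under rotation of the spot labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .core import (
    ConfigError,
    DisplacementProfile,
    OnsetError,
    ParameterError,
    SpotLayout,
)

__all__ = [
    "DeformationParams",
    "MeridionalVector",
    "AsymmetryVector",
    "detect_onset",
    "extract_params",
    "extract_all",
    "pair_vectors",
    "main_vector",
    "difference_vector",
    "angular_distance",
    "signed_angle",
]


def angular_distance(a_deg: float, b_deg: float) -> float:
    """Minimal absolute circular difference of two angles, in [0, 180]."""
    if not (math.isfinite(a_deg) and math.isfinite(b_deg)):
        raise ConfigError("angles must be finite")
    d = abs(a_deg - b_deg) % 360.0
    return min(d, 360.0 - d)


def signed_angle(azimuth_deg: float) -> float:
    """Map an azimuth to signed degrees in (−180, 180]."""
    return -((-azimuth_deg + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# Onset detection and parameter extraction
# ---------------------------------------------------------------------------


def _sustain_samples(dt_ms: float, m_sustain: int | None,
                     sustain_ms: float) -> int:
    if m_sustain is not None:
        if m_sustain < 1:
            raise ConfigError("m_sustain must be >= 1")
        return int(m_sustain)
    return max(1, int(round(sustain_ms / dt_ms)))


def detect_onset(
    profile: DisplacementProfile,
    k_sigma: float = 5.0,
    m_sustain: int | None = None,
    sustain_ms: float = 0.1,
) -> float:
    """Time (ms) when the deformation starts.

    Onset is the first sample where displacement exceeds
    ``k_sigma × baseline_sigma`` and stays above it for a sustained run.
    The sustain requirement is expressed as a physical duration
    (``sustain_ms``, default 0.1 ms = 10 samples at the native 10 µs grid)
    so that it adapts to down-sampled profiles; passing ``m_sustain``
    overrides it with an explicit sample count.
    """
    # tiny relative floor guards float rounding of an otherwise zero baseline
    floor = 1e-9 * float(np.max(np.abs(profile.displacement_um), initial=0.0))
    thr = max(k_sigma * profile.baseline_sigma_um, floor)
    m = _sustain_samples(profile.dt_ms, m_sustain, sustain_ms)
    above = profile.displacement_um > thr
    if m == 1:
        idx = np.flatnonzero(above)
    else:
        runs = np.convolve(above.astype(int), np.ones(m, dtype=int), "valid")
        idx = np.flatnonzero(runs == m)
    if idx.size == 0:
        raise OnsetError(
            f"no onset: displacement never exceeds {thr:.3g} um for "
            f"{m} consecutive samples"
        )
    return float(profile.time_ms[idx[0]])


@dataclass(frozen=True)
class DeformationParams:
    """The nine per-spot deformation descriptors (+ onset and flags)."""

    label: str
    onset_ms: float
    da1_um: float
    t_da1_ms: float
    da2_um: float | None
    t_da2_ms: float | None
    da3_um: float | None
    t_da3_ms: float | None
    mean_da_um: float | None      # (DA1 + DA3) / 2
    ratio: float | None           # DA1 / DA3
    area_um_ms: float

    @property
    def has_da2(self) -> bool:
        return self.da2_um is not None

    @property
    def has_da3(self) -> bool:
        return self.da3_um is not None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "onset_ms": self.onset_ms,
            "da1_um": self.da1_um,
            "t_da1_ms": self.t_da1_ms,
            "da2_um": self.da2_um,
            "t_da2_ms": self.t_da2_ms,
            "da3_um": self.da3_um,
            "t_da3_ms": self.t_da3_ms,
            "mean_da_um": self.mean_da_um,
            "ratio": self.ratio,
            "area_um_ms": self.area_um_ms,
            "has_da2": self.has_da2,
            "has_da3": self.has_da3,
        }


def extract_params(
    profile: DisplacementProfile,
    k_sigma: float = 5.0,
    m_sustain: int | None = None,
    sustain_ms: float = 0.1,
    smooth_window: int = 5,
    prominence_sigma: float = 3.0,
) -> DeformationParams:
    """Extract the deformation descriptors from one displacement profile.

    Extremum search runs on a moving-average smoothed copy (window
    ``smooth_window`` samples, prominence threshold
    ``prominence_sigma × baseline_sigma``); the reported amplitudes are the
    *raw* values at the located indices.  DA1 is the first prominent local
    maximum after onset, DA2 the minimum between DA1 and DA3, DA3 the second
    prominent maximum.  The area is the trapezoidal integral of displacement
    from onset until it first falls back below the onset threshold after the
    first peak (or until the record ends).
    """
    onset = detect_onset(profile, k_sigma, m_sustain, sustain_ms)
    t = profile.time_ms
    d = profile.displacement_um
    i0 = int(np.searchsorted(t, onset))
    seg = d[i0:]
    t_seg = t[i0:] - onset

    # search one sample before onset too, so a maximum (or plateau) that
    # starts right at the onset sample still has a lower left neighbour
    extra = 1 if i0 > 0 else 0
    search = uniform_filter1d(d[i0 - extra:], size=max(1, smooth_window),
                              mode="nearest")
    prom = max(prominence_sigma * profile.baseline_sigma_um,
               1e-9 * float(np.max(np.abs(seg))))
    peaks, _ = find_peaks(search, prominence=prom)
    peaks = peaks[peaks >= extra] - extra

    if peaks.size == 0:
        # monotone (or boundary-peaked) profile: DA1 = global maximum
        p1 = int(np.argmax(seg))
        if p1 == 0:
            raise ParameterError(
                f"channel {profile.label or '?'}: no prominent maximum after onset"
            )
        da1, t_da1 = float(seg[p1]), float(t_seg[p1])
        da2 = t_da2 = da3 = t_da3 = mean_da = ratio = None
    else:
        p1 = int(peaks[0])
        da1, t_da1 = float(seg[p1]), float(t_seg[p1])
        if peaks.size >= 2:
            p2 = int(peaks[1])
            da3, t_da3 = float(seg[p2]), float(t_seg[p2])
            v = p1 + int(np.argmin(seg[p1:p2 + 1]))
            da2, t_da2 = float(seg[v]), float(t_seg[v])
            mean_da = 0.5 * (da1 + da3)
            ratio = da1 / da3 if da3 != 0 else None
        else:
            da2 = t_da2 = da3 = t_da3 = mean_da = ratio = None

    thr = k_sigma * profile.baseline_sigma_um
    below = np.flatnonzero(seg[p1:] < thr)
    end = p1 + int(below[0]) if below.size else seg.size - 1
    area = float(np.trapezoid(seg[:end + 1], t_seg[:end + 1]))

    return DeformationParams(
        label=profile.label, onset_ms=onset,
        da1_um=da1, t_da1_ms=t_da1,
        da2_um=da2, t_da2_ms=t_da2,
        da3_um=da3, t_da3_ms=t_da3,
        mean_da_um=mean_da, ratio=ratio,
        area_um_ms=max(area, 0.0),
    )


def extract_all(profiles: Mapping[str, DisplacementProfile],
                **kwargs) -> dict[str, DeformationParams]:
    """Deformation parameters for a set of spot profiles."""
    return {lab: extract_params(p, **kwargs) for lab, p in profiles.items()}


# ---------------------------------------------------------------------------
# Asymmetry vectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeridionalVector:
    """Asymmetry of one opposite-spot pair.

    Magnitude is the absolute inter-pair value difference; the azimuth points
    toward the higher-valued spot.  Ties produce a zero-magnitude vector with
    the azimuth of the first label of the pair (direction immaterial).
    """

    pair: tuple[str, str]
    magnitude: float
    azimuth_deg: float

    @property
    def components(self) -> tuple[float, float]:
        a = math.radians(self.azimuth_deg)
        return (self.magnitude * math.cos(a), self.magnitude * math.sin(a))


@dataclass(frozen=True)
class AsymmetryVector:
    """Planar sum of the four meridional vectors.

    ``azimuth_deg`` is in [0, 360); ``signed_azimuth_deg`` maps the same
    direction into (−180, 180] for comparison with clinical map conventions.
    A zero-magnitude vector reports azimuth 0 with ``is_zero`` set.
    """

    x: float
    y: float
    source_param: str = "DA1"
    meridionals: tuple[MeridionalVector, ...] = ()

    @property
    def magnitude(self) -> float:
        return math.hypot(self.x, self.y)

    @property
    def is_zero(self) -> bool:
        return self.magnitude < 1e-12

    @property
    def azimuth_deg(self) -> float:
        if self.is_zero:
            return 0.0
        return math.degrees(math.atan2(self.y, self.x)) % 360.0

    @property
    def signed_azimuth_deg(self) -> float:
        return signed_angle(self.azimuth_deg)

    def to_dict(self) -> dict:
        return {
            "source_param": self.source_param,
            "components": [self.x, self.y],
            "magnitude": self.magnitude,
            "azimuth_deg": self.azimuth_deg,
            "signed_azimuth_deg": self.signed_azimuth_deg,
            "is_zero": self.is_zero,
            "meridionals": [
                {
                    "pair": list(m.pair),
                    "magnitude": m.magnitude,
                    "azimuth_deg": m.azimuth_deg,
                }
                for m in self.meridionals
            ],
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_values(cls, values: Mapping[str, float], layout: SpotLayout,
                    source_param: str = "DA1") -> "AsymmetryVector":
        return main_vector(pair_vectors(values, layout), source_param)


def pair_vectors(values: Mapping[str, float],
                 layout: SpotLayout) -> list[MeridionalVector]:
    """One meridional vector per opposite-spot pair of the layout."""
    for lab in layout.peripheral_labels:
        if lab not in values:
            raise ConfigError(f"missing value for peripheral spot {lab}")
        if not math.isfinite(values[lab]):
            raise ConfigError(f"non-finite value for peripheral spot {lab}")
    out = []
    for a, b in layout.pairs:
        va, vb = float(values[a]), float(values[b])
        mag = abs(va - vb)
        azi = layout.azimuth(a) if va >= vb else layout.azimuth(b)
        out.append(MeridionalVector(pair=(a, b), magnitude=mag, azimuth_deg=azi))
    return out


def main_vector(meridionals: Sequence[MeridionalVector],
                source_param: str = "DA1") -> AsymmetryVector:
    """Planar sum of meridional vectors on distinct meridians."""
    meridians = {round(m.azimuth_deg % 180.0, 6) for m in meridionals}
    if len(meridians) != len(meridionals):
        raise ConfigError("meridional vectors must lie on distinct meridians")
    x = sum(m.components[0] for m in meridionals)
    y = sum(m.components[1] for m in meridionals)
    return AsymmetryVector(x=x, y=y, source_param=source_param,
                           meridionals=tuple(meridionals))


def difference_vector(
    post: Mapping[str, float],
    pre: Mapping[str, float],
    layout: SpotLayout,
    source_param: str = "DA1",
) -> AsymmetryVector:
    """Asymmetry vector of the post-minus-pre per-spot values.

    By linearity this equals the componentwise difference of the two
    asymmetry vectors; both paths are computed and cross-checked.
    """
    if set(post) != set(pre):
        only = set(post).symmetric_difference(pre)
        raise ConfigError(f"spot labels differ between pre and post: {sorted(only)}")
    diff = {lab: post[lab] - pre[lab] for lab in post}
    via_values = AsymmetryVector.from_values(diff, layout, source_param)
    v_post = AsymmetryVector.from_values(post, layout, source_param)
    v_pre = AsymmetryVector.from_values(pre, layout, source_param)
    if not np.allclose([via_values.x, via_values.y],
                       [v_post.x - v_pre.x, v_post.y - v_pre.y],
                       atol=1e-9 * (1 + abs(via_values.magnitude))):
        raise ParameterError(
            "internal inconsistency: vector-of-differences != difference-of-vectors"
        )
    return via_values
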