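"""Synthetic multi-spot acquisitions with known ground truth.

No public air-puff OCT datasets exist, so every downstream stage is tested
against this generator: a phenomenological air-puff stimulus (Gaussian
pressure pulse, ~8 ms FWHM), a per-spot compliance law with an optional
keratoconus-like "cone" of excess compliance at a configurable azimuth, a
single- or dual-indentation displacement response, and a renderer that draws
each spot's anterior-surface ridge into its depth-encoded M-scan window.

The response law is deliberately simple — displacement(t) = compliance(spot)
× pressure peak × a one- or two-lobe unit-peak pulse — because parameter
recovery testing only requires that the truth be *known*, not mechanistic.
Displacement lobes are clipped Gaussians (compact support) so that the true
deformation onset is a well-defined first nonzero sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import (
    CENTRAL_LABEL,
    AcquisitionConfig,
    ConfigError,
    MScan,
    SpotLayout,
    WindowOverlapError,
)

__all__ = [
    "StimulusProfile",
    "CornealComplianceModel",
    "TruthParams",
    "GroundTruth",
    "make_stimulus",
    "simulate_displacement",
    "render_mscan",
    "synthetic_cohort",
]

_LN2x4 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class StimulusProfile:
    """Air-puff pressure pulse.

    ``onset_time_ms`` is the time of the pulse *maximum* (the half-maximum
    points sit half a FWHM on either side of it).  ``secondary_peak_fraction``
    models the occasional weak, delayed secondary pressure peak; it is kept
    below 0.25 because such peaks are typically more than 4× weaker than the
    primary and do not drive the corneal response.  ``spatial_fwhm_mm`` is
    recorded as metadata: the spatial broadening of the stimulus is what
    elicits the dual-indentation response, but no quantitative link from
    spatial width to lobe weight is established, so the response model keeps
    the lobe weight as its own free parameter.
    """

    peak_pressure: float = 1.0
    temporal_fwhm_ms: float = 8.0
    spatial_fwhm_mm: float = 4.0
    onset_time_ms: float = 15.0
    secondary_peak_fraction: float = 0.0
    secondary_delay_ms: float = 25.0

    def __post_init__(self) -> None:
        if self.temporal_fwhm_ms <= 0:
            raise ConfigError("temporal_fwhm_ms must be positive")
        if self.peak_pressure < 0:
            raise ConfigError("peak_pressure must be >= 0")
        if not 0 <= self.secondary_peak_fraction < 0.25:
            raise ConfigError("secondary_peak_fraction must be in [0, 0.25)")
        if self.spatial_fwhm_mm <= 0:
            raise ConfigError("spatial_fwhm_mm must be positive")
        if self.secondary_delay_ms <= 0:
            raise ConfigError("secondary_delay_ms must be positive")


@dataclass(frozen=True)
class CornealComplianceModel:
    """Phenomenological per-spot compliance of the cornea.

    compliance(spot) = base_compliance × (1 + cone_excess · g(Δθ)) where
    g is a wrapped-Gaussian angular weight of FWHM ``cone_width_deg`` centred
    on ``cone_azimuth_deg`` — a keratoconus-like focal softening.  The
    central spot uses a configurable constant weight ``central_cone_weight``
    instead of g (it has no azimuth and does not enter the asymmetry
    statistic).

    The temporal response is a mixture of two unit-peak lobes separated by
    ``lobe_separation_ms`` with weight ``dual_indentation_weight`` on the
    second lobe; weight 0 gives the classic single-indentation profile and
    weights near 0.3–0.5 the dual-indentation profile seen with a spatially
    broadened stimulus.  ``spot_scatter`` adds a fractional per-spot
    compliance jitter and ``timing_scatter_ms`` a per-spot shift of the
    whole response in time (both seeded from the acquisition config),
    emulating the small natural amplitude asymmetry of healthy corneas and
    the spot-to-spot timing differences of a propagating deformation.
    """

    base_compliance: float = 450.0      # µm per pressure unit
    cone_azimuth_deg: float = 0.0
    cone_width_deg: float = 60.0        # angular FWHM
    cone_excess: float = 0.0
    dual_indentation_weight: float = 0.35
    lobe_separation_ms: float = 10.0
    lobe_fwhm_ms: float = 6.0
    central_cone_weight: float = 0.0
    spot_scatter: float = 0.0
    timing_scatter_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.base_compliance <= 0:
            raise ConfigError("base_compliance must be positive")
        if self.cone_excess < 0:
            raise ConfigError("cone_excess must be >= 0")
        if not 0 <= self.dual_indentation_weight <= 1:
            raise ConfigError("dual_indentation_weight must be in [0, 1]")
        if self.dual_indentation_weight > 0 and self.lobe_separation_ms <= 0:
            raise ConfigError(
                "lobe_separation_ms must be positive when dual_indentation_weight > 0"
            )
        if self.cone_width_deg <= 0:
            raise ConfigError("cone_width_deg must be positive")
        if self.lobe_fwhm_ms <= 0:
            raise ConfigError("lobe_fwhm_ms must be positive")
        if not 0 <= self.central_cone_weight <= 1:
            raise ConfigError("central_cone_weight must be in [0, 1]")
        if self.spot_scatter < 0:
            raise ConfigError("spot_scatter must be >= 0")
        if self.timing_scatter_ms < 0:
            raise ConfigError("timing_scatter_ms must be >= 0")

    def angular_weight(self, azimuth_deg: float) -> float:
        """Wrapped-Gaussian cone weight g(Δθ), unit peak at the cone azimuth."""
        d = (azimuth_deg - self.cone_azimuth_deg + 180.0) % 360.0 - 180.0
        return float(np.exp(-_LN2x4 * (d / self.cone_width_deg) ** 2))


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth deformation descriptors of one spot's noiseless series."""

    onset_ms: float
    da1_um: float
    t_da1_ms: float
    da2_um: float | None
    t_da2_ms: float | None
    da3_um: float | None
    t_da3_ms: float | None
    area_um_ms: float

    def to_dict(self) -> dict:
        return {
            "onset_ms": self.onset_ms,
            "da1_um": self.da1_um,
            "t_da1_ms": self.t_da1_ms,
            "da2_um": self.da2_um,
            "t_da2_ms": self.t_da2_ms,
            "da3_um": self.da3_um,
            "t_da3_ms": self.t_da3_ms,
            "area_um_ms": self.area_um_ms,
        }


@dataclass
class GroundTruth:
    """Per-spot noiseless displacement series plus the generating parameters."""

    time_ms: np.ndarray
    series_um: dict[str, np.ndarray]
    params: dict[str, TruthParams]
    stimulus: StimulusProfile
    model: CornealComplianceModel
    layout: SpotLayout
    config: AcquisitionConfig

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame({"time_ms": self.time_ms})
        for lab, s in self.series_um.items():
            df[f"disp_um_{lab}"] = s
        df.to_csv(path, index=False, float_format="%.6f")
        return path

    def params_to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "truth_params": {lab: p.to_dict() for lab, p in self.params.items()},
            "stimulus": self.stimulus.__dict__,
            "model": self.model.__dict__,
            "layout": self.layout.to_dict(),
            "acquisition": self.config.to_dict(),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


# ---------------------------------------------------------------------------
# Stimulus
# ---------------------------------------------------------------------------


def make_stimulus(profile: StimulusProfile, time_ms: np.ndarray) -> np.ndarray:
    """Pressure series of the air-puff pulse on a uniform time grid.

    Gaussian main lobe of the stated FWHM and peak, centred at
    ``onset_time_ms``, plus an optional delayed secondary lobe scaled by
    ``secondary_peak_fraction``.  The grid must be uniform and extend at
    least 2.5 FWHM past the pulse centre so the pulse is fully contained.
    """
    t = np.asarray(time_ms, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ConfigError("time grid must be a 1-D array of >= 2 samples")
    steps = np.diff(t)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
        raise ConfigError("time grid must be uniform and increasing")
    if t[-1] < profile.onset_time_ms + 2.5 * profile.temporal_fwhm_ms:
        raise ConfigError(
            "time grid must extend >= 2.5 FWHM beyond the pulse centre"
        )
    u = (t - profile.onset_time_ms) / profile.temporal_fwhm_ms
    p = profile.peak_pressure * np.exp(-_LN2x4 * u * u)
    if profile.secondary_peak_fraction > 0:
        u2 = (t - profile.onset_time_ms - profile.secondary_delay_ms)
        u2 /= profile.temporal_fwhm_ms
        p = p + (profile.secondary_peak_fraction * profile.peak_pressure
                 * np.exp(-_LN2x4 * u2 * u2))
    return p


# ---------------------------------------------------------------------------
# Displacement simulation
# ---------------------------------------------------------------------------

_LOBE_CUT = 1.5  # clipped-Gaussian support half-width, in FWHM units


def _lobe(t: np.ndarray, center_ms: float, fwhm_ms: float) -> np.ndarray:
    """Unit-peak clipped Gaussian with compact support center ± 1.5 FWHM."""
    c = np.exp(-_LN2x4 * _LOBE_CUT**2)
    raw = np.exp(-_LN2x4 * ((t - center_ms) / fwhm_ms) ** 2)
    return np.clip((raw - c) / (1.0 - c), 0.0, None)


def _truth_params(t: np.ndarray, s: np.ndarray) -> TruthParams:
    """Descriptors straight off a noiseless series (independent of the
    measurement-path extractor in :mod:`puffoct.metrics`)."""
    nz = np.flatnonzero(s > 0)
    if nz.size == 0:
        return TruthParams(np.nan, 0.0, np.nan, None, None, None, None, 0.0)
    onset_idx = int(nz[0])
    onset = float(t[onset_idx])
    peaks, _ = find_peaks(s)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(s))])
    p1 = int(peaks[0])
    da1 = float(s[p1])
    t_da1 = float(t[p1] - onset)
    da2 = t_da2 = da3 = t_da3 = None
    if peaks.size >= 2:
        p2 = int(peaks[1])
        da3 = float(s[p2])
        t_da3 = float(t[p2] - onset)
        v = p1 + int(np.argmin(s[p1:p2 + 1]))
        da2 = float(s[v])
        t_da2 = float(t[v] - onset)
    # area from onset until the series returns to zero (or record end)
    zeros = np.flatnonzero(s[p1:] <= 0)
    end = p1 + int(zeros[0]) if zeros.size else s.size - 1
    area = float(np.trapezoid(s[onset_idx:end + 1], t[onset_idx:end + 1]))
    return TruthParams(onset, da1, t_da1, da2, t_da2, da3, t_da3, area)


def simulate_displacement(
    model: CornealComplianceModel,
    stimulus: StimulusProfile,
    layout: SpotLayout | None = None,
    config: AcquisitionConfig | None = None,
) -> GroundTruth:
    """Generate per-spot ground-truth displacement series.

    displacement(t) = compliance(spot) × peak_pressure ×
    [(1−w)·L1(t) + w·L2(t)], where L1 and L2 are unit-peak lobes of FWHM
    ``model.lobe_fwhm_ms``: L1 centred at the stimulus pulse maximum and L2
    delayed by ``model.lobe_separation_ms``, with w the dual-indentation
    weight.  The recorded truth parameters are read off the generated series
    directly, so they are consistent with it by construction.
    """
    layout = layout or SpotLayout()
    config = config or AcquisitionConfig()
    if config.n_channels != len(layout.labels):
        raise ConfigError(
            f"{config.n_channels} depth offsets for {len(layout.labels)} spots"
        )
    t = config.time_grid()
    t1 = stimulus.onset_time_ms
    w = model.dual_indentation_weight
    t2 = t1 + model.lobe_separation_ms
    if t1 - _LOBE_CUT * model.lobe_fwhm_ms < 0:
        raise ConfigError(
            "displacement would start before the record: move onset_time_ms later"
        )
    margin = 4.0 * model.timing_scatter_ms
    last = (t2 if w > 0 else t1) + _LOBE_CUT * model.lobe_fwhm_ms
    if last + margin > config.duration_ms:
        raise ConfigError(
            "displacement response does not fit the record: extend duration_ms"
        )
    if t1 - _LOBE_CUT * model.lobe_fwhm_ms - margin < 0:
        raise ConfigError(
            "displacement would start before the record: move onset_time_ms later"
        )

    rng = np.random.default_rng(config.seed)
    jitter: dict[str, float] = {}
    shifts: dict[str, float] = {}
    for lab in layout.labels:
        jitter[lab] = (1.0 + model.spot_scatter * rng.standard_normal()
                       if model.spot_scatter > 0 else 1.0)
        shifts[lab] = (model.timing_scatter_ms * rng.standard_normal()
                       if model.timing_scatter_ms > 0 else 0.0)

    series: dict[str, np.ndarray] = {}
    params: dict[str, TruthParams] = {}
    for lab in layout.labels:
        shift = float(np.clip(shifts[lab], -margin, margin))
        shape = (1.0 - w) * _lobe(t, t1 + shift, model.lobe_fwhm_ms)
        if w > 0:
            shape = shape + w * _lobe(t, t2 + shift, model.lobe_fwhm_ms)
        if lab == CENTRAL_LABEL:
            g = model.central_cone_weight
        else:
            g = model.angular_weight(layout.azimuth(lab))
        compliance = model.base_compliance * (1.0 + model.cone_excess * g)
        compliance *= jitter[lab]
        s = compliance * stimulus.peak_pressure * shape
        series[lab] = s
        params[lab] = _truth_params(t, s)
    return GroundTruth(
        time_ms=t, series_um=series, params=params,
        stimulus=stimulus, model=model, layout=layout, config=config,
    )


# ---------------------------------------------------------------------------
# M-scan rendering
# ---------------------------------------------------------------------------


def render_mscan(
    truth: GroundTruth,
    config: AcquisitionConfig | None = None,
    seed: int | None = None,
) -> MScan:
    """Render a depth-encoded M-scan image from ground-truth series.

    Each channel draws a Gaussian bright ridge (FWHM ``ridge_width_px``)
    centred at ``depth_offset + displacement / pixel_pitch`` inside its depth
    window, then additive Gaussian noise of ``noise_sigma`` is applied to the
    whole image.  Before deformation onset the ridge is constant — the beams
    are stationary, so pre-puff signals are speckle-free.  A fixed seed gives
    a bit-identical image.
    """
    config = config or truth.config
    seed = config.seed if seed is None else seed
    labels = list(truth.series_um)
    windows = config.channel_windows(labels)
    height = max(hi for _, hi in windows.values())
    n_t = len(truth.time_ms)
    if not np.allclose(truth.time_ms, config.time_grid()):
        raise ConfigError("truth series are not on the acquisition time grid")

    spans = sorted((lo, hi, lab) for lab, (lo, hi) in windows.items())
    for (lo1, hi1, a), (lo2, hi2, b) in zip(spans, spans[1:]):
        if lo2 < hi1:
            raise WindowOverlapError(
                f"depth windows of channels {a} and {b} overlap"
            )

    image = np.zeros((height, n_t), dtype=float)
    margin = config.ridge_width_px
    for i, lab in enumerate(labels):
        lo, hi = windows[lab]
        center = (config.rest_row(i)
                  + truth.series_um[lab] / config.axial_pixel_pitch_um)
        if center.max() > hi - margin or center.min() < lo + margin:
            raise ConfigError(
                f"rendered surface of channel {lab} exits its depth window; "
                "increase the depth-offset spacing or reduce the displacement"
            )
        rows = np.arange(lo, hi, dtype=float)
        block = config.ridge_amplitude * np.exp(
            -_LN2x4 * ((rows[:, None] - center[None, :])
                       / config.ridge_width_px) ** 2
        )
        image[lo:hi, :] += block

    if config.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, config.noise_sigma, image.shape)
    image = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    return MScan(image=image, config=config, layout=truth.layout,
                 windows=windows, seed=seed)


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------


def synthetic_cohort(
    n_healthy: int = 10,
    n_cone: int = 3,
    seed: int = 0,
    layout: SpotLayout | None = None,
    config: AcquisitionConfig | None = None,
    stimulus: StimulusProfile | None = None,
) -> list[GroundTruth]:
    """A small cohort of simulated eyes for sampling-rate studies.

    Healthy eyes have no cone but a 3% per-spot compliance scatter (real
    corneas are never perfectly centro-symmetric, so their asymmetry vector
    is small but nonzero); cone eyes add a 50% focal compliance excess at a
    per-eye azimuth.  Each eye gets its own sub-seed derived from ``seed``,
    so the cohort is reproducible as a whole.
    """
    layout = layout or SpotLayout()
    config = config or AcquisitionConfig()
    stimulus = stimulus or StimulusProfile()
    rng = np.random.default_rng(seed)
    eyes: list[GroundTruth] = []
    for i in range(n_healthy + n_cone):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = config.replace(seed=sub_seed)
        if i < n_healthy:
            model = CornealComplianceModel(spot_scatter=0.03,
                                           timing_scatter_ms=0.3)
        else:
            azimuth = float(rng.uniform(0.0, 360.0))
            model = CornealComplianceModel(
                cone_excess=0.5, cone_azimuth_deg=azimuth,
                spot_scatter=0.03, timing_scatter_ms=0.3,
            )
        eyes.append(simulate_displacement(model, stimulus, layout, cfg))
    return eyes
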