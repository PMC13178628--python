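"""Core containers for multi-spot air-puff OCT data.

The instrument probes the cornea at nine fixed spots — one central (``SC``)
and eight peripheral (``S1``..``S8``) on a 1.1 mm radius ring at 45° spacing —
with a single swept-source OCT A-scan stream.  Each spot is depth-encoded:
a per-channel path-length offset places its interference signal in a private
depth window of the common A-scan, so one M-scan image (axial pixels × time
samples) carries all nine channels stacked vertically.

This module holds the shared value types (:class:`SpotLayout`,
:class:`AcquisitionConfig`, :class:`MScan`, :class:`DisplacementProfile`),
their file formats (16-bit TIFF/PNG image + JSON sidecar for M-scans,
CSV + JSON sidecar for displacement profiles) and the package exception
hierarchy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "PuffOctError",
    "ConfigError",
    "WindowOverlapError",
    "MaskError",
    "TrackingError",
    "OnsetError",
    "ParameterError",
    "PipelineError",
    "SpotLayout",
    "AcquisitionConfig",
    "MScan",
    "DisplacementProfile",
    "write_profiles",
    "read_profiles",
]


class PuffOctError(Exception):
    """Base class for all puffoct errors."""


class ConfigError(PuffOctError, ValueError):
    """Invalid parameter or configuration value."""


class WindowOverlapError(ConfigError):
    """Two depth-encoded channels were assigned overlapping depth windows."""


class MaskError(PuffOctError, ValueError):
    """A segmentation mask is unusable (wrong shape, empty channel, ...)."""


class TrackingError(PuffOctError, RuntimeError):
    """Automatic surface tracking failed for a channel."""


class OnsetError(PuffOctError, RuntimeError):
    """No deformation onset could be detected in a displacement profile."""


class ParameterError(PuffOctError, RuntimeError):
    """Deformation-parameter extraction failed (no prominent maximum)."""


class PipelineError(PuffOctError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Spot layout
# ---------------------------------------------------------------------------

CENTRAL_LABEL = "SC"


@dataclass(frozen=True)
class SpotLayout:
    """Geometry of the nine illumination spots on the cornea.

    Peripheral spot ``Sk`` sits at azimuth ``anchor + (k-1)*360/n`` degrees on
    a ring of radius :attr:`peripheral_radius_mm` around the apex; opposite
    spots (180° apart) form the meridional pairs used by the asymmetry-vector
    statistic.  Azimuths are measured counter-clockwise from the +x axis of
    the instrument view; the anchor of ``S1`` is configurable because the eye
    reference (nasal/temporal/superior) is an acquisition convention.
    """

    peripheral_radius_mm: float = 1.1
    n_peripheral: int = 8
    anchor_azimuth_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.peripheral_radius_mm <= 0:
            raise ConfigError("peripheral_radius_mm must be positive")
        if self.n_peripheral < 2 or self.n_peripheral % 2:
            raise ConfigError("n_peripheral must be an even count >= 2")

    @property
    def peripheral_labels(self) -> tuple[str, ...]:
        return tuple(f"S{k}" for k in range(1, self.n_peripheral + 1))

    @property
    def labels(self) -> tuple[str, ...]:
        """Central label first, then peripheral labels in azimuth order."""
        return (CENTRAL_LABEL, *self.peripheral_labels)

    def azimuth(self, label: str) -> float:
        """Azimuth of a peripheral spot in degrees, in [0, 360)."""
        if label == CENTRAL_LABEL:
            raise ConfigError("the central spot has no azimuth")
        try:
            k = int(label[1:])
        except (ValueError, IndexError):
            raise ConfigError(f"unknown spot label {label!r}") from None
        if label[0] != "S" or not 1 <= k <= self.n_peripheral:
            raise ConfigError(f"unknown spot label {label!r}")
        step = 360.0 / self.n_peripheral
        return (self.anchor_azimuth_deg + (k - 1) * step) % 360.0

    @property
    def azimuths(self) -> dict[str, float]:
        return {s: self.azimuth(s) for s in self.peripheral_labels}

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        """Opposite-spot pairs: (S1,S5), (S2,S6), (S3,S7), (S4,S8) by default."""
        half = self.n_peripheral // 2
        return tuple(
            (f"S{k}", f"S{k + half}") for k in range(1, half + 1)
        )

    def to_dict(self) -> dict:
        return {
            "peripheral_radius_mm": self.peripheral_radius_mm,
            "n_peripheral": self.n_peripheral,
            "anchor_azimuth_deg": self.anchor_azimuth_deg,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpotLayout":
        return cls(**dict(d))


# ---------------------------------------------------------------------------
# Acquisition configuration
# ---------------------------------------------------------------------------


def _default_offsets() -> tuple[float, ...]:
    # 9 channels on a 2 mm grid: 18 mm span inside the 22 mm dual-edge range.
    return tuple(1.0 + 2.0 * i for i in range(9))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling and depth-encoding parameters of a multi-spot M-scan.

    Parameters
    ----------
    ascan_period_us:
        Time between consecutive A-scans; 10 µs at the native 100 kHz sweep
        rate.
    axial_pixel_pitch_um:
        Physical depth per axial pixel (8.6 µm/px default).
    depth_offsets_mm:
        Per-channel path-length offset ΔL_i placing each spot in its own
        depth window; must be strictly increasing and separated by more than
        the rendered signal extent.
    duration_ms:
        Record length.
    noise_sigma:
        Additive Gaussian intensity noise (16-bit counts); 0 = clean render.
    ridge_width_px / ridge_amplitude:
        FWHM and peak intensity of the rendered anterior-surface ridge.
    seed:
        RNG seed; a fixed seed yields bit-identical rendered images.
    """

    ascan_period_us: float = 10.0
    axial_pixel_pitch_um: float = 8.6
    depth_offsets_mm: tuple[float, ...] = field(default_factory=_default_offsets)
    duration_ms: float = 45.0
    noise_sigma: float = 0.0
    ridge_width_px: float = 6.0
    ridge_amplitude: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ascan_period_us <= 0:
            raise ConfigError("ascan_period_us must be positive")
        if self.axial_pixel_pitch_um <= 0:
            raise ConfigError("axial_pixel_pitch_um must be positive")
        if self.duration_ms <= 0:
            raise ConfigError("duration_ms must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.ridge_width_px <= 0:
            raise ConfigError("ridge_width_px must be positive")
        offs = np.asarray(self.depth_offsets_mm, dtype=float)
        object.__setattr__(self, "depth_offsets_mm", tuple(offs.tolist()))
        if offs.ndim != 1 or len(offs) < 1:
            raise ConfigError("depth_offsets_mm must be a non-empty sequence")
        if np.any(np.diff(offs) <= 0):
            raise ConfigError("depth_offsets_mm must be strictly increasing")
        if offs[0] < 0:
            raise ConfigError("depth_offsets_mm must be non-negative")

    @property
    def n_channels(self) -> int:
        return len(self.depth_offsets_mm)

    @property
    def dt_ms(self) -> float:
        return self.ascan_period_us / 1000.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms / self.dt_ms))

    def time_grid(self) -> np.ndarray:
        """Uniform sample times in milliseconds."""
        return np.arange(self.n_samples) * self.dt_ms

    def rest_row(self, channel: int) -> float:
        """Resting (pre-puff) surface row of a channel, in axial pixels."""
        return self.depth_offsets_mm[channel] * 1000.0 / self.axial_pixel_pitch_um

    def channel_windows(self, labels: Sequence[str]) -> dict[str, tuple[int, int]]:
        """Per-channel depth windows ``[lo, hi)`` in axial pixels.

        Windows are cut at 15% of the inter-channel gap above each resting
        row (guard band for noise) and 85% below (room for indentation,
        which moves the surface away from the probe, i.e. down the image).
        """
        if len(labels) != self.n_channels:
            raise ConfigError(
                f"{len(labels)} labels for {self.n_channels} depth offsets"
            )
        offs = np.asarray(self.depth_offsets_mm)
        gaps = np.diff(offs) * 1000.0 / self.axial_pixel_pitch_um
        gap = float(gaps.min()) if len(gaps) else 200.0
        los = [max(0, int(np.floor(self.rest_row(i) - 0.15 * gap)))
               for i in range(self.n_channels)]
        his = los[1:] + [int(np.ceil(self.rest_row(self.n_channels - 1)
                                     + 0.85 * gap))]
        return {lab: (lo, hi) for lab, lo, hi in zip(labels, los, his)}

    def to_dict(self) -> dict:
        return {
            "ascan_period_us": self.ascan_period_us,
            "axial_pixel_pitch_um": self.axial_pixel_pitch_um,
            "depth_offsets_mm": list(self.depth_offsets_mm),
            "duration_ms": self.duration_ms,
            "noise_sigma": self.noise_sigma,
            "ridge_width_px": self.ridge_width_px,
            "ridge_amplitude": self.ridge_amplitude,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionConfig":
        d = dict(d)
        if "depth_offsets_mm" in d:
            d["depth_offsets_mm"] = tuple(d["depth_offsets_mm"])
        return cls(**d)

    def replace(self, **kw) -> "AcquisitionConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# M-scan
# ---------------------------------------------------------------------------


@dataclass
class MScan:
    """A depth-encoded multi-channel M-scan image plus acquisition metadata.

    ``image`` is an (axial pixels × time samples) intensity grid; depth
    increases downward.  ``windows`` maps each spot label to its half-open
    depth window ``[lo, hi)`` in axial pixels.
    """

    image: np.ndarray
    config: AcquisitionConfig
    layout: SpotLayout
    windows: dict[str, tuple[int, int]]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ConfigError("M-scan image must be 2-D (axial px x time)")
        h = self.image.shape[0]
        for lab, (lo, hi) in self.windows.items():
            if not (0 <= lo < hi <= h):
                raise ConfigError(
                    f"depth window {lo, hi} of channel {lab} exceeds image height {h}"
                )
        spans = sorted((lo, hi, lab) for lab, (lo, hi) in self.windows.items())
        for (lo1, hi1, a), (lo2, hi2, b) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise WindowOverlapError(
                    f"depth windows of channels {a} and {b} overlap"
                )

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.image.shape[1]) * self.config.dt_ms

    def channel_image(self, label: str) -> np.ndarray:
        lo, hi = self.windows[label]
        return self.image[lo:hi, :]

    # -- I/O ----------------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write the image (16-bit TIFF or PNG by suffix) + JSON sidecar."""
        path = Path(path)
        img = np.clip(np.rint(self.image), 0, 65535).astype(np.uint16)
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, img)
        elif path.suffix.lower() == ".png":
            Image.fromarray(img).save(path)
        else:
            raise ConfigError(f"unsupported M-scan image format {path.suffix!r}")
        sidecar = {
            "acquisition": self.config.to_dict(),
            "layout": self.layout.to_dict(),
            "channels": [
                {
                    "label": lab,
                    "depth_window_px": [int(lo), int(hi)],
                    "depth_offset_mm": self.config.depth_offsets_mm[i],
                }
                for i, (lab, (lo, hi)) in enumerate(self.windows.items())
            ],
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MScan":
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            img = tifffile.imread(path)
        elif path.suffix.lower() == ".png":
            img = np.asarray(Image.open(path))
        else:
            raise ConfigError(f"unsupported M-scan image format {path.suffix!r}")
        meta = json.loads(path.with_suffix(".json").read_text())
        config = AcquisitionConfig.from_dict(meta["acquisition"])
        layout = SpotLayout.from_dict(meta["layout"])
        windows = {
            ch["label"]: tuple(ch["depth_window_px"]) for ch in meta["channels"]
        }
        return cls(image=img, config=config, layout=layout,
                   windows=windows, seed=meta.get("seed"))


# ---------------------------------------------------------------------------
# Displacement profile
# ---------------------------------------------------------------------------


@dataclass
class DisplacementProfile:
    """Displacement-versus-time of one spot's anterior surface.

    Positive displacement is indentation: the surface moving away from the
    probe along the instrument axis.  ``baseline_sigma_um`` is the standard
    deviation of the pre-onset baseline, used for onset detection and peak
    prominence thresholds.
    """

    time_ms: np.ndarray
    displacement_um: np.ndarray
    label: str = ""
    baseline_sigma_um: float = 0.0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.displacement_um = np.asarray(self.displacement_um, dtype=float)
        if self.time_ms.shape != self.displacement_um.shape:
            raise ConfigError("time and displacement arrays differ in length")
        if self.time_ms.size < 2:
            raise ConfigError("a displacement profile needs >= 2 samples")
        steps = np.diff(self.time_ms)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ConfigError("time grid must be uniform and increasing")
        if self.baseline_sigma_um < 0:
            raise ConfigError("baseline_sigma_um must be >= 0")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def n_samples(self) -> int:
        return int(self.time_ms.size)


def write_profiles(profiles: Mapping[str, DisplacementProfile],
                   path: str | Path) -> Path:
    """Write profiles as CSV (time_ms, disp_um_<label>...) + JSON sidecar."""
    path = Path(path)
    labels = list(profiles)
    t = profiles[labels[0]].time_ms
    for lab in labels[1:]:
        if not np.allclose(profiles[lab].time_ms, t):
            raise ConfigError("profiles must share a common time grid")
    df = pd.DataFrame({"time_ms": t})
    for lab in labels:
        df[f"disp_um_{lab}"] = profiles[lab].displacement_um
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {lab: {"baseline_sigma_um": profiles[lab].baseline_sigma_um}
               for lab in labels}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_profiles(path: str | Path) -> dict[str, DisplacementProfile]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(".json")
    sigmas = (json.loads(sidecar_path.read_text())
              if sidecar_path.exists() else {})
    t = df["time_ms"].to_numpy()
    out: dict[str, DisplacementProfile] = {}
    for col in df.columns:
        if not col.startswith("disp_um_"):
            continue
        lab = col[len("disp_um_"):]
        sigma = sigmas.get(lab, {}).get("baseline_sigma_um", 0.0)
        out[lab] = DisplacementProfile(
            time_ms=t, displacement_um=df[col].to_numpy(),
            label=lab, baseline_sigma_um=sigma,
        )
    return out
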