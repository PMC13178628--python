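"""Shared fixtures: small synthetic acquisitions reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from puffoct import (
    AcquisitionConfig,
    CornealComplianceModel,
    SpotLayout,
    StimulusProfile,
    render_mscan,
    simulate_displacement,
)


@pytest.fixture(scope="session")
def layout() -> SpotLayout:
    return SpotLayout()


@pytest.fixture(scope="session")
def config() -> AcquisitionConfig:
    return AcquisitionConfig(seed=7)


@pytest.fixture(scope="session")
def stimulus() -> StimulusProfile:
    return StimulusProfile()


@pytest.fixture(scope="session")
def cone_model() -> CornealComplianceModel:
    """Keratoconus-like eye: 50% excess compliance centred on S7 (270 deg)."""
    return CornealComplianceModel(cone_excess=0.5, cone_azimuth_deg=270.0)


@pytest.fixture(scope="session")
def cone_truth(cone_model, stimulus, layout, config):
    return simulate_displacement(cone_model, stimulus, layout, config)


@pytest.fixture(scope="session")
def clean_mscan(cone_truth):
    """Noise-free render of the cone eye."""
    return render_mscan(cone_truth)


@pytest.fixture(scope="session")
def truth_profiles(cone_truth):
    """Ground-truth series wrapped as displacement profiles (no rendering)."""
    from puffoct import DisplacementProfile

    return {
        lab: DisplacementProfile(
            time_ms=cone_truth.time_ms,
            displacement_um=cone_truth.series_um[lab],
            label=lab,
            baseline_sigma_um=0.0,
        )
        for lab in cone_truth.layout.peripheral_labels
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
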