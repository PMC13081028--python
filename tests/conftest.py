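"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pytest

from aortaflow.synthetic import (
    TubeSpec,
    WaveformSpec,
    generate_inlet_waveform,
    generate_tube_mesh,
)


@pytest.fixture(scope="session")
def cylinder():
    """Straight cylinder, radius 0.5 mm, with its centerline."""
    mesh, cl = generate_tube_mesh(
        TubeSpec(length_mm=10.0, base_radius_mm=0.5, n_axial=80, n_circ=48)
    )
    return mesh, cl


@pytest.fixture(scope="session")
def fusiform():
    """Fusiform tube: base radius 0.6 mm, bulge amplitude 0.2 mm at midlength."""
    spec = TubeSpec(
        length_mm=20.0,
        base_radius_mm=0.6,
        bulge_amplitude_mm=0.2,
        bulge_width_mm=1.5,
        n_axial=160,
        n_circ=64,
    )
    mesh, cl = generate_tube_mesh(spec)
    return spec, mesh, cl


@pytest.fixture(scope="session")
def mouse_waveform():
    """Pulsatile mouse aortic inflow: 0.12 s period, 100 uL/s mean, 15 samples."""
    return generate_inlet_waveform(
        WaveformSpec(period_s=0.12, mean_flow=100.0, pulsatility=3.0, n_samples=15, seed=1)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
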