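"""Shared fixtures: small synthetic scenes sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from aneupulse import PhantomConfig, sac_radius


@pytest.fixture
def small_phantom_config():
    """A compact noiseless scene: ~50 mm³ sac, thin vessel, no skull."""
    return PhantomConfig(
        baseline_volume=50.0,
        pulsation_amplitude=5.0,
        pulse_frequency=1.5,
        vessel_radius=0.8,
        vessel_gap=1.0,
        vessel_curvature_amplitude=0.5,
        noise_sd=0.0,
        scan_duration=2.0,
        reconstruction_interval=200.0,
        rotation_time=300.0,
        voxel_spacing=(0.25, 0.25, 0.5),
        grid_shape=(64, 64, 32),
        include_skull=False,
        seed=0,
    )


def bench_config(
    dv: float,
    noise: float | None = None,
    interval: float = 150.0,
    seed: int = 0,
):
    """Bench-emulating run configuration used by the acceptance suite.

    Grid spacing 0.25 mm in-plane (sphere rasterization error < 0.5 % at the
    sac radius) with a vessel offset such that the tracked elliptic mask
    never touches the pulsating sac surface.
    """
    from aneupulse import RunConfig

    phantom = dict(
        baseline_volume=310.0,
        pulsation_amplitude=dv,
        pulse_frequency=1.5,
        vessel_gap=1.5,
        noise_sd=30.0 if noise is None else noise,
        scan_duration=5.0,
        reconstruction_interval=interval,
        rotation_time=300.0,
        voxel_spacing=[0.25, 0.25, 0.5],
        grid_shape=[96, 96, 56],
        include_skull=False,
    )
    cx = 96 * 0.25 / 2 + sac_radius(310.0) + 1.5 + 1.5
    return RunConfig(
        phantom=phantom,
        threshold="suggest",
        mask_scheme="vitro",
        ellipse=dict(cx=cx, cy=12.0, a=1.8, b=1.8, init_slice=55),
        expected_period={"fixed_hz": 1.5},
        seed=seed,
    )
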