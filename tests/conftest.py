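"""Shared fixtures.

Desk-scale geometry used throughout: a 64-element, 0.1 mm pitch aperture
imaging a 5.12 mm field of which the central 2.56 mm patch (64 x 64 px at
40 um, below the acoustic half-wavelength) is reconstructed.  The
session-scoped ``benchmark_run`` fixture performs the one expensive
end-to-end study (dataset + U-Net training + DAS baseline) that several
tests share.
"""

import numpy as np
import pytest

from pavision.beamform import ReconGrid
from pavision.forward import ProbeConfig
from pavision.phantoms import PhantomConfig


@pytest.fixture(scope="session")
def desk_probe():
    return ProbeConfig(n_elements=64, n_samples=384)


@pytest.fixture(scope="session")
def desk_phantom_cfg():
    return PhantomConfig(field_size_mm=5.12, patch_size_mm=2.56,
                         pixel_pitch_um=40.0, n_primary_branches=3,
                         branch_depth=4, vein_width_px_range=(0.8, 1.8))


@pytest.fixture(scope="session")
def tiny_probe():
    return ProbeConfig(n_elements=48, n_samples=320)


@pytest.fixture(scope="session")
def tiny_phantom_cfg():
    return PhantomConfig(field_size_mm=2.56, patch_size_mm=1.28,
                         pixel_pitch_um=40.0, n_primary_branches=2,
                         branch_depth=3, vein_width_px_range=(0.8, 1.5))


@pytest.fixture(scope="session")
def pa_system():
    """Materialized 64x64-grid propagation matrix (shared: it is the one
    expensive dense-linear-algebra object in the suite)."""
    from pavision.forward import ProbeConfig, build_system_matrix

    probe = ProbeConfig(n_elements=64, n_samples=320)
    grid = ReconGrid.for_patch((0.0, 4.0), 2.56, 40.0)
    return probe, grid, build_system_matrix(probe, grid)


@pytest.fixture(scope="session")
def benchmark_run(desk_phantom_cfg, desk_probe):
    """One seeded end-to-end simulation study shared by the slow tests."""
    from pavision.experiments import run_simulation_benchmark

    return run_simulation_benchmark(desk_phantom_cfg, desk_probe, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
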