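"""Shared fixtures: small scan geometries and cached full-size synthetic scans."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from s21density import GeneratorConfig, S21Scan, ScanGeometry, generate_scan

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_geometry() -> ScanGeometry:
    """A 3x8x16 geometry small enough for exhaustive/text-format tests."""
    return ScanGeometry(
        n_tx=3, n_rx=8, rx_step_deg=45.0, tx_angles_deg=(0.0, 120.0, 240.0),
        f_start_hz=1.0e9, f_step_hz=5.0e6, n_freq=16,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_random_scan(geometry: ScanGeometry, rng: np.random.Generator, **labels) -> S21Scan:
    shape = (geometry.n_pairs, geometry.n_freq)
    matrix = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    return S21Scan(matrix=matrix, geometry=geometry, sample_id="random", **labels)


@pytest.fixture
def small_scan(small_geometry, rng) -> S21Scan:
    return make_random_scan(small_geometry, rng)


@pytest.fixture(scope="session")
def full_scan() -> S21Scan:
    """One full-size (800 x 1601) synthetic scan, shared across tests."""
    return generate_scan("HD", "healthy", seed=417, config=GeneratorConfig())
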