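"""Shared fixtures: simulated manoeuvres and hand-built waveform records."""

import numpy as np
import pytest

from pulmorecruit import (
    VentilatorSettings,
    WaveformRecord,
    sample_unit_population,
    simulate_rm,
)
from pulmorecruit.scenarios import (
    default_settings,
    make_population,
    simulate_scenario,
)

#: scenario seed used throughout the suite (the shipped seeded condition)
SCENARIO_SEED = 42


@pytest.fixture(scope="session")
def settings():
    return default_settings()


@pytest.fixture(scope="session")
def healthy_record_clean():
    """Noise-free healthy-scenario manoeuvre."""
    return simulate_scenario("healthy", seed=SCENARIO_SEED, noise_sd_frac=0.0)


@pytest.fixture(scope="session")
def healthy_record_noisy():
    """Healthy-scenario manoeuvre with the default 2 % measurement noise."""
    return simulate_scenario("healthy", seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def ards_record_noisy():
    return simulate_scenario("ards", seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def binary_population():
    """Small pure all-or-none population (no elasticity, no memory)."""
    return sample_unit_population(
        n_units=24_000, mu_top=42.4, sd_top=23.0, mu_tcp=18.0, sd_tcp=8.0,
        unit_volume=0.05, seed=SCENARIO_SEED,
    )


@pytest.fixture(scope="session")
def binary_record_clean(binary_population, settings):
    return simulate_rm(binary_population, settings, noise_sd_frac=0.0, seed=1)


def make_triangle_record(n_breaths=2, peep=5.0, vt=300.0, fs=50.0):
    """Hand-built record of identical square-flow breaths.

    Each breath: constant inspiratory flow for 1 s, constant expiratory
    flow for 1 s (complete emptying), 0.5 s pause; pressure ramps linearly
    up then down.  Used where an analytically known record is needed.
    """
    dt = 1.0 / fs
    n = int(fs)
    q = vt / (n * dt)
    rest = np.zeros(int(0.5 * fs))
    flow_b = np.concatenate([np.full(n, q), np.full(n, -q), rest])
    paw_b = np.concatenate([
        np.linspace(peep, peep + 20, n),
        np.linspace(peep + 20, peep, n),
        np.full(rest.size, peep),
    ])
    flow = np.concatenate([np.zeros(2)] + [flow_b] * n_breaths)
    paw = np.concatenate([np.full(2, peep)] + [paw_b] * n_breaths)
    left = np.concatenate(([0.0], flow[:-1]))
    volume = np.cumsum(0.5 * (left + flow) * dt)
    time = dt * np.arange(flow.size)
    return WaveformRecord(
        time=time, paw=paw, flow=flow, volume=volume,
        peep=np.full(flow.size, peep),
    )


@pytest.fixture()
def triangle_record():
    return make_triangle_record()
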