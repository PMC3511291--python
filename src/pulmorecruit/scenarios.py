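"""Reference simulation scenarios for healthy and ARDS-like lungs.

The healthy scenario uses a TOP distribution matching baseline fits in the
bundled reference tables (mean 42.4 cmH2O, SD 23 cmH2O) for a 24 kg
subject ventilated at 12 ml/kg over the PEEP 5 -> 20 cmH2O schedule.  The
generating TCP distribution (mean 18 cmH2O, SD 8 cmH2O) is wider than any
single per-PEEP deflation fit: in an all-or-none unit model the tidal
volume is stored and released purely by cyclic recruitment, so closure
mass must exist across the whole PEEP range for ventilation to remain
feasible — per-PEEP fitted TCP means are local features of that broad
distribution, not its global parameters.

The ARDS-like scenario shifts the TOP distribution up by 15 cmH2O and
widens it by 5 cmH2O (more collapse, more heterogeneity) and leaves the
TCP distribution unchanged, matching the observation that deflation
behaviour changes little with injury.
"""

from __future__ import annotations

from .lung_simulator import (
    LungUnitPopulation,
    VentilatorSettings,
    WaveformRecord,
    sample_unit_population,
    simulate_rm,
)

__all__ = [
    "HEALTHY_POPULATION",
    "ARDS_POPULATION",
    "default_settings",
    "make_population",
    "simulate_scenario",
]

HEALTHY_POPULATION = {
    "n_units": 18_000,
    "mu_top": 42.4,
    "sd_top": 23.0,
    "mu_tcp": 18.0,
    "sd_tcp": 8.0,
    "unit_volume": 0.05,  # ml -> 900 ml recruitable capacity
    "unit_compliance": 0.002,  # ml/cmH2O: ~15-25 ml/cmH2O lung compliance
    "elastic_knee": 15.0,
}

ARDS_POPULATION = {
    **HEALTHY_POPULATION,
    "mu_top": HEALTHY_POPULATION["mu_top"] + 15.0,
    "sd_top": HEALTHY_POPULATION["sd_top"] + 5.0,
}

_SCENARIOS = {"healthy": HEALTHY_POPULATION, "ards": ARDS_POPULATION}


def default_settings(**overrides) -> VentilatorSettings:
    """Ventilator settings of the reference protocol (24 kg, 12 ml/kg)."""
    kwargs = {"weight_kg": 24.0}
    kwargs.update(overrides)
    return VentilatorSettings(**kwargs)


def make_population(scenario: str, seed: int, **overrides) -> LungUnitPopulation:
    """Sample the unit population of a named scenario."""
    params = dict(_SCENARIOS[scenario])
    params.update(overrides)
    return sample_unit_population(seed=seed, **params)


def simulate_scenario(
    scenario: str,
    seed: int,
    noise_sd_frac: float = 0.02,
    auto_peep: float = 0.0,
    settings: VentilatorSettings | None = None,
) -> WaveformRecord:
    """Sample a scenario population and simulate the full manoeuvre.

    The population and noise seeds are derived from ``seed`` so a single
    integer reproduces the whole record.
    """
    population = make_population(scenario, seed=seed)
    if settings is None:
        settings = default_settings()
    return simulate_rm(
        population,
        settings,
        noise_sd_frac=noise_sd_frac,
        auto_peep=auto_peep,
        seed=seed + 1,
    )
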