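"""Multi-unit lung simulator for step-wise PEEP recruitment manoeuvres.

Generates synthetic ventilator waveforms (pressure, flow, volume) from a
ground-truth population of recruitable lung units, so that every
downstream processing and fitting stage can be tested against known truth.

Model
-----
Each lung unit is all-or-none: it opens when alveolar pressure reaches its
threshold opening pressure (TOP), contributes a fixed ``unit_volume`` while
open, and collapses again when pressure falls to its threshold closing
pressure (TCP < TOP).  Per-unit TOP and TCP are drawn from independent
normal distributions (with per-unit rejection to enforce TCP < TOP), so a
slow monotone inflation from the fully collapsed state traces the
error-function recruitment curve of :mod:`pulmorecruit.recruitment_model`.

Ventilation is volume-controlled: each inspiration delivers the set tidal
volume at constant flow; alveolar pressure at each sample is the smallest
pressure at which the hysteretic population holds the delivered volume.
Expiration is a passive exponential flow decay toward the volume the
population retains at the current PEEP (units with TCP below PEEP stay
open), truncated when flow falls under 1 % of its peak.  Incomplete
expiration after each PEEP increment produces the "trapped" end-expiratory
volume rise that the processing stage estimates; the simulator records the
true per-step trapped volumes alongside the waveforms.

Airway pressure adds a resistive drop ``resistance * flow`` to alveolar
pressure.  Optional multiplicative Gaussian noise is applied to the
pressure and flow channels; the volume channel is always the trapezoidal
integral of the (possibly noisy) flow channel, so the record is internally
consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    InfeasibleVentilationError,
    ParameterError,
)

__all__ = [
    "LungUnitPopulation",
    "VentilatorSettings",
    "WaveformRecord",
    "SimulationTruth",
    "sample_unit_population",
    "simulate_rm",
    "quasi_static_inflation",
]

CSV_HEADER = ["time_s", "paw_cmH2O", "flow_ml_s", "volume_ml", "peep_cmH2O"]

_MAX_REJECTION_ROUNDS = 1000


@dataclass
class LungUnitPopulation:
    """Ground-truth population of all-or-none lung units.

    ``top``/``tcp`` are per-unit threshold opening/closing pressures in
    cmH2O (``tcp < top`` for every unit); each open unit holds
    ``unit_volume`` ml, so total capacity is ``n_units * unit_volume``.
    """

    top: np.ndarray
    tcp: np.ndarray
    unit_volume: float
    is_open: np.ndarray
    mu_top: float
    sd_top: float
    mu_tcp: float
    sd_tcp: float
    unit_compliance: float = 0.0
    elastic_knee: float = 15.0  # cmH2O; pressure scale of elastic saturation
    reopen_fraction: float = 1.0  # opening-pressure memory (1 = none)

    def __post_init__(self) -> None:
        self.top = np.asarray(self.top, dtype=float)
        self.tcp = np.asarray(self.tcp, dtype=float)
        self.is_open = np.asarray(self.is_open, dtype=bool)
        if self.top.size < 1:
            raise ParameterError("population must contain at least one unit")
        if not (self.top.shape == self.tcp.shape == self.is_open.shape):
            raise ParameterError("top, tcp and is_open must have equal shapes")
        if self.unit_volume <= 0:
            raise ParameterError("unit_volume must be positive")
        if self.unit_compliance < 0:
            raise ParameterError("unit_compliance must be non-negative")
        if self.elastic_knee <= 0:
            raise ParameterError("elastic_knee must be positive")
        if not 0.0 < self.reopen_fraction <= 1.0:
            raise ParameterError("reopen_fraction must lie in (0, 1]")
        if np.any(self.tcp >= self.top):
            raise ParameterError("every unit must satisfy tcp < top")

    @property
    def n_units(self) -> int:
        return int(self.top.size)

    @property
    def capacity(self) -> float:
        """Total capacity in ml (the model's TotalLungCapacity)."""
        return self.n_units * self.unit_volume


@dataclass(frozen=True)
class VentilatorSettings:
    """Volume-control ventilator settings for a recruitment manoeuvre.

    Defaults follow a step-wise PEEP protocol: tidal volume 12 ml/kg,
    PEEP 5 -> 20 cmH2O in 5 cmH2O steps, 12 breaths per level.  The
    inspiratory flow profile is constant (square wave) and the I:E split
    is a convention (``insp_frac`` of the breath period), since neither is
    dictated by the protocol.  ``fio2`` is carried as metadata only.
    """

    weight_kg: float
    vt_ml_per_kg: float = 12.0
    peep_schedule: tuple = (5.0, 10.0, 15.0, 20.0)
    breaths_per_level: int = 12
    resp_rate: float = 15.0
    sample_rate: float = 50.0
    resistance: float = 0.005  # cmH2O.s/ml
    insp_frac: float = 1.0 / 3.0
    fio2: float = 0.5

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.vt_ml_per_kg <= 0:
            raise ParameterError("weight and tidal volume scale must be positive")
        schedule = tuple(float(p) for p in self.peep_schedule)
        if len(schedule) == 0:
            raise ParameterError("peep_schedule must not be empty")
        if any(b <= a for a, b in zip(schedule, schedule[1:])):
            raise ParameterError("peep_schedule must be strictly increasing")
        if self.breaths_per_level < 1:
            raise ParameterError("breaths_per_level must be >= 1")
        if self.sample_rate < 25.0:
            raise ParameterError("sample_rate must be at least 25 Hz")
        if not 0.0 < self.insp_frac < 1.0:
            raise ParameterError("insp_frac must lie in (0, 1)")
        object.__setattr__(self, "peep_schedule", schedule)

    @property
    def tidal_volume(self) -> float:
        """Delivered tidal volume per breath, ml."""
        return self.weight_kg * self.vt_ml_per_kg


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated manoeuvre."""

    capacity: float
    tidal_volume: float
    eev_ml: dict = field(default_factory=dict)  # PEEP level -> end-exp volume
    trapped_ml: dict = field(default_factory=dict)  # (low, high) step -> ml
    peak_pressure: dict = field(default_factory=dict)  # PEEP level -> cmH2O
    mu_top: float = float("nan")
    sd_top: float = float("nan")
    mu_tcp: float = float("nan")
    sd_tcp: float = float("nan")


@dataclass
class WaveformRecord:
    """Uniformly sampled airway pressure / flow / volume time series.

    ``volume`` is ml above the pre-manoeuvre relaxed state and equals the
    cumulative trapezoidal integral of ``flow``; ``peep`` annotates the
    PEEP level governing each sample.  ``truth`` is present on simulated
    records only.
    """

    time: np.ndarray
    paw: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    peep: np.ndarray
    truth: SimulationTruth | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.paw) == len(self.flow) == len(self.volume) == len(self.peep) == n):
            raise ParameterError("all waveform channels must have equal length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ParameterError("time must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_csv(self, path) -> None:
        """Write the record in the package CSV dialect (UTF-8, '.' decimal)."""
        frame = pd.DataFrame(
            dict(zip(CSV_HEADER, [self.time, self.paw, self.flow, self.volume, self.peep]))
        )
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WaveformRecord":
        frame = pd.read_csv(path)
        missing = [c for c in CSV_HEADER if c not in frame.columns]
        if missing:
            raise ParameterError(f"waveform CSV missing columns: {missing}")
        return cls(
            time=frame["time_s"].to_numpy(float),
            paw=frame["paw_cmH2O"].to_numpy(float),
            flow=frame["flow_ml_s"].to_numpy(float),
            volume=frame["volume_ml"].to_numpy(float),
            peep=frame["peep_cmH2O"].to_numpy(float),
        )


def sample_unit_population(
    n_units: int,
    mu_top: float,
    sd_top: float,
    mu_tcp: float,
    sd_tcp: float,
    unit_volume: float,
    seed: int,
    unit_compliance: float = 0.0,
    elastic_knee: float = 15.0,
    reopen_fraction: float = 1.0,
) -> LungUnitPopulation:
    """Draw a lung-unit population with normal TOP and TCP distributions.

    Per-unit TOPs are drawn from Normal(mu_top, sd_top); TCPs from
    Normal(mu_tcp, sd_tcp) conditioned on the hysteresis constraint
    ``tcp < top`` (a unit violating it has its closing pressure redrawn,
    which is realised exactly by inverse-CDF sampling of the truncated
    normal).  The TOP marginal is therefore exactly normal — the
    quasi-static inflation of a large population converges to the
    error-function curve even when the two distributions overlap — while
    the TCP marginal is truncated where the constraint binds.  All units
    start closed.  Identical seeds give bit-identical populations.

    ``unit_compliance`` (ml/cmH2O per open unit at zero pressure, default
    0) adds a saturating elastic volume
    ``unit_compliance * elastic_knee * (1 - exp(-p / elastic_knee))`` on
    top of the fixed ``unit_volume`` of each open unit, emulating tissue
    elasticity.  At 0 the lung is purely all-or-none and its quasi-static
    inflation is exactly the error-function recruitment curve.

    ``reopen_fraction`` models opening-pressure memory: after a unit has
    been recruited once, its effective re-opening pressure becomes
    ``tcp + reopen_fraction * (top - tcp)``.  At the default 1 thresholds
    are static; below 1 a previously opened unit re-opens more easily, as
    observed for airway reopening within a manoeuvre.  The first
    inflation from full collapse always follows the pristine TOP
    distribution.
    """
    if n_units < 1:
        raise ParameterError("n_units must be >= 1")
    if sd_top <= 0 or sd_tcp <= 0:
        raise ParameterError("sd_top and sd_tcp must be positive")
    if unit_volume <= 0:
        raise ParameterError("unit_volume must be positive")
    joint_sd = math.hypot(sd_top, sd_tcp)
    if mu_tcp - mu_top > 2.0 * joint_sd:
        raise ConfigurationError(
            "mu_tcp exceeds mu_top by more than 2 joint SDs; the tcp < top "
            "rejection loop would not terminate quickly"
        )
    rng = np.random.default_rng(seed)
    top = rng.normal(mu_top, sd_top, n_units)
    tcp = rng.normal(mu_tcp, sd_tcp, n_units)
    bad = tcp >= top
    if np.any(bad):
        # Redraw the closing pressures of violating units from the normal
        # truncated below the unit's TOP (exact, via the inverse CDF).
        u = rng.random(int(bad.sum()))
        cdf_at_top = stats.norm.cdf(top[bad], loc=mu_tcp, scale=sd_tcp)
        redrawn = stats.norm.ppf(u * cdf_at_top, loc=mu_tcp, scale=sd_tcp)
        # Guard against underflow for units with extremely low TOP.
        lo = np.minimum(top[bad] - 1e-9 * max(sd_tcp, 1.0), top[bad] - 1e-12)
        tcp[bad] = np.where(np.isfinite(redrawn), np.minimum(redrawn, lo), lo)
    return LungUnitPopulation(
        top=top,
        tcp=tcp,
        unit_volume=float(unit_volume),
        is_open=np.zeros(n_units, dtype=bool),
        mu_top=float(mu_top),
        sd_top=float(sd_top),
        mu_tcp=float(mu_tcp),
        sd_tcp=float(sd_tcp),
        unit_compliance=float(unit_compliance),
        elastic_knee=float(elastic_knee),
        reopen_fraction=float(reopen_fraction),
    )


def quasi_static_inflation(population: LungUnitPopulation, pressures) -> np.ndarray:
    """Open fraction during a slow monotone inflation from full collapse.

    At pressure ``p`` every unit with ``top <= p`` is open, so the curve is
    the empirical CDF of the TOP sample; for large populations it converges
    to the error-function recruitment curve of the generating distribution.
    """
    p = np.atleast_1d(np.asarray(pressures, dtype=float))
    if np.any(np.diff(p) < 0):
        raise ParameterError("pressures must be monotone non-decreasing")
    top_sorted = np.sort(population.top)
    return np.searchsorted(top_sorted, p, side="right") / population.n_units


class _UnitVolume:
    """Pressure-volume behaviour of a single open unit.

    ``v(p) = uv + c * p_el * (1 - exp(-p / p_el))``: the fixed recruited
    volume plus a saturating elastic expansion with zero-pressure
    compliance ``c`` and an exponential knee at ``p_el`` (the standard
    empirical shape of the deflating tissue PV relation).  ``c = 0``
    recovers the pure all-or-none unit.
    """

    def __init__(self, uv: float, c: float, p_el: float):
        self.uv = uv
        self.c = c
        self.p_el = p_el
        self.elastic_max = c * p_el

    def __call__(self, p):
        if self.c == 0.0:
            return np.broadcast_to(self.uv, np.shape(p)).astype(float) if np.ndim(p) else self.uv
        return self.uv + self.elastic_max * (1.0 - np.exp(-np.asarray(p, float) / self.p_el))

    def inverse(self, v):
        """Pressure at which one open unit holds volume ``v`` (vectorised);
        +inf above the elastic ceiling, -inf at or below ``uv``."""
        frac = 1.0 - (np.asarray(v, float) - self.uv) / self.elastic_max
        out = np.full(np.shape(frac), np.inf)
        with np.errstate(divide="ignore", invalid="ignore"):
            np.copyto(out, -self.p_el * np.log(frac), where=frac > 0)
        return out


def _inspiration_pressures(
    v_targets: np.ndarray,
    closed_tops: np.ndarray,
    n_open0: int,
    unit: _UnitVolume,
    peep_eff: float,
    level: float,
) -> np.ndarray:
    """Smallest alveolar pressure holding each target volume while inflating.

    ``closed_tops`` must be sorted ascending.  Pressure is monotone because
    the targets are; with elastic units pressure can also rise between
    openings while the already-open units expand.
    """
    infeasible = InfeasibleVentilationError(
        "population has too few recruitable units to accept the "
        f"tidal volume at PEEP {level:g} cmH2O"
    )
    if unit.c == 0.0:
        m_needed = np.ceil(v_targets / unit.uv).astype(np.int64)
        extra = np.clip(m_needed - n_open0, 0, None)
        if extra[-1] > closed_tops.size:
            raise infeasible
        p = np.where(
            extra > 0, closed_tops[np.maximum(extra, 1) - 1], peep_eff
        )
        return np.maximum(p, peep_eff)

    # Effective opening pressures: units with TOP below the end-expiratory
    # pressure open as soon as inflation starts.
    t_eff = np.maximum(closed_tops, peep_eff)
    counts = n_open0 + 1 + np.arange(t_eff.size, dtype=np.int64)
    v_at_open = counts * unit(t_eff)  # volume right after each opening
    j = np.searchsorted(v_at_open, v_targets, side="left")
    n_open = n_open0 + j
    p_cont = unit.inverse(v_targets / np.maximum(n_open, 1))
    t_next = np.append(t_eff, np.inf)[j]
    p = np.minimum(np.maximum(p_cont, peep_eff), t_next)
    p = np.where(n_open == 0, t_next, p)
    if not np.all(np.isfinite(p)):
        raise infeasible
    return p


def _expiration_pressures(
    v_targets: np.ndarray,
    open_tcps: np.ndarray,
    unit: _UnitVolume,
    peep_eff: float,
) -> np.ndarray:
    """Quasi-static pressure holding each target volume while deflating.

    ``open_tcps`` must be sorted ascending (the open set at end
    inspiration); as pressure falls the highest-TCP units close first, so
    the open set is always the lowest-TCP prefix.
    """
    m_total = open_tcps.size
    if unit.c == 0.0:
        m = np.clip(np.ceil(v_targets / unit.uv).astype(np.int64), 1, m_total)
        return np.maximum(open_tcps[m - 1], peep_eff)

    p_floor_n = np.maximum(open_tcps, peep_eff)  # min pressure with n open
    n_units_open = 1 + np.arange(m_total, dtype=np.int64)
    v_min_n = n_units_open * unit(p_floor_n)  # volume at that pressure
    n = np.clip(np.searchsorted(v_min_n, v_targets, side="right"), 1, m_total)
    p_cont = unit.inverse(v_targets / n)
    return np.maximum(p_cont, p_floor_n[n - 1])


def simulate_rm(
    population: LungUnitPopulation,
    settings: VentilatorSettings,
    noise_sd_frac: float = 0.02,
    auto_peep: float = 0.0,
    seed: int = 0,
) -> WaveformRecord:
    """Simulate a full step-wise PEEP recruitment manoeuvre.

    Parameters
    ----------
    population
        Ground-truth lung units; the stored ``is_open`` state is not
        mutated (the simulator works on a copy).
    settings
        Ventilator configuration (tidal volume, PEEP schedule, timing).
    noise_sd_frac
        Relative SD of multiplicative Gaussian noise applied to the
        pressure and flow channels (0 disables noise).
    auto_peep
        Additive intrinsic end-expiratory pressure, cmH2O.  Raises the
        effective end-expiratory pressure above the set PEEP, emulating
        incomplete lung emptying at low baseline PEEP.
    seed
        Seed for the noise generator.

    Returns
    -------
    WaveformRecord
        Waveforms with per-sample PEEP annotation and a ``truth`` block
        holding end-expiratory volumes and per-step trapped volumes.
    """
    if noise_sd_frac < 0:
        raise ParameterError("noise_sd_frac must be >= 0")
    vt = settings.tidal_volume
    if population.unit_compliance == 0.0 and vt >= population.capacity:
        raise InfeasibleVentilationError(
            f"tidal volume {vt:.0f} ml is not below total capacity "
            f"{population.capacity:.0f} ml"
        )

    dt = 1.0 / settings.sample_rate
    period = 60.0 / settings.resp_rate
    n_total = max(4, int(round(period * settings.sample_rate)))
    n_insp = max(2, int(round(settings.insp_frac * n_total)))
    n_exp = max(2, n_total - n_insp)
    uv = population.unit_volume
    unit = _UnitVolume(uv, population.unit_compliance, population.elastic_knee)
    top = population.top
    tcp = population.tcp
    # Effective opening pressures; relaxed toward TCP once a unit has been
    # recruited when the population carries opening-pressure memory.
    top_eff = top.copy()
    top_relaxed = tcp + population.reopen_fraction * (top - tcp)
    ever_open = population.is_open.copy()
    resistance = settings.resistance
    # Plateau flow chosen so that the clipped trapezoidal integral of the
    # inspiratory samples equals the set tidal volume exactly.
    q_insp = vt / (n_insp * dt)

    open_mask = population.is_open.copy()
    flow_parts: list[np.ndarray] = []
    palv_parts: list[np.ndarray] = []
    peep_parts: list[np.ndarray] = []
    truth = SimulationTruth(
        capacity=population.capacity,
        tidal_volume=vt,
        mu_top=population.mu_top,
        sd_top=population.sd_top,
        mu_tcp=population.mu_tcp,
        sd_tcp=population.sd_tcp,
    )

    # Short lead-in at rest so breath onset detection sees a quiet baseline.
    n_rest = max(2, int(round(0.5 * settings.sample_rate)))
    first_peep = settings.peep_schedule[0] + auto_peep
    flow_parts.append(np.zeros(n_rest))
    palv_parts.append(np.full(n_rest, first_peep))
    peep_parts.append(np.full(n_rest, settings.peep_schedule[0]))

    volume = 0.0  # running volume channel value (above relaxed state)
    last_flow = 0.0

    def _trapz_extend(flow_seg: np.ndarray) -> np.ndarray:
        """Volume values for a new flow segment, continuing the integral."""
        nonlocal volume, last_flow
        left = np.concatenate(([last_flow], flow_seg[:-1]))
        v = volume + np.cumsum(0.5 * (left + flow_seg) * dt)
        volume = float(v[-1])
        last_flow = float(flow_seg[-1])
        return v

    for level in settings.peep_schedule:
        peep_eff = level + auto_peep
        for breath in range(settings.breaths_per_level):
            # --- inspiration: constant flow, hysteretic pressure response
            flow_i = np.full(n_insp, q_insp)
            v_i = _trapz_extend(flow_i)
            n_open0 = int(open_mask.sum())
            closed_tops = np.sort(top_eff[~open_mask])
            p_i = _inspiration_pressures(
                v_i, closed_tops, n_open0, unit, peep_eff, level
            )
            p_i = np.maximum.accumulate(np.maximum(p_i, peep_eff))
            p_peak = float(p_i[-1])
            open_mask |= top_eff <= p_peak
            if population.reopen_fraction < 1.0:
                newly = open_mask & ~ever_open
                top_eff[newly] = top_relaxed[newly]
                ever_open |= open_mask
            palv_parts.append(p_i)
            flow_parts.append(flow_i)
            peep_parts.append(np.full(n_insp, level))

            # --- expiration: passive exponential flow decay toward the
            # volume retained by units whose TCP lies below the PEEP
            retained = open_mask & (tcp < peep_eff)
            v_retained = float(retained.sum()) * float(unit(peep_eff))
            v_end_insp = float(v_i[-1])
            dv = max(v_end_insp - v_retained, 0.0)
            if dv <= 0.0 and v_end_insp > 0.0:
                raise InfeasibleVentilationError(
                    "no unit closes above the current PEEP: the population "
                    "cannot release the delivered tidal volume"
                )
            t_exp = n_exp * dt
            compliance_proxy = dv / max(p_peak - peep_eff, 0.5)
            # Expiratory time constant: resistive emptying with a 0.3 s
            # viscoelastic floor, kept short enough to finish in the window.
            tau = max(resistance * compliance_proxy, 0.3)
            tau = float(max(min(tau, t_exp / 6.0), 2 * dt))
            t_grid = dt * np.arange(1, n_exp + 1)
            flow_e = -(dv / tau) * np.exp(-t_grid / tau)
            peak_exp_flow = abs(flow_e[0])
            if peak_exp_flow > 0:
                flow_e[np.abs(flow_e) < 0.01 * peak_exp_flow] = 0.0
                # Rescale so the trapezoidal integral of the segment —
                # including the boundary interval with the last inspiratory
                # sample — releases exactly dv; at ordinary sample rates the
                # raw trapezoid of a fast exponential under-integrates.
                left_e = np.concatenate(([0.0], flow_e[:-1]))
                scalable = float(np.sum(0.5 * (left_e + flow_e) * dt))
                boundary = 0.5 * last_flow * dt
                if scalable < 0 and dv + boundary > 0:
                    flow_e *= -(dv + boundary) / scalable
            v_e = _trapz_extend(flow_e)
            open_tcps = np.sort(tcp[open_mask])
            p_e = _expiration_pressures(v_e, open_tcps, unit, peep_eff)
            p_e = np.minimum.accumulate(np.minimum(p_e, p_peak))
            p_e = np.maximum(p_e, peep_eff)
            p_floor = float(p_e[-1])
            open_mask &= ~(tcp >= p_floor)
            palv_parts.append(p_e)
            flow_parts.append(flow_e)
            peep_parts.append(np.full(n_exp, level))

        truth.eev_ml[float(level)] = volume
        truth.peak_pressure[float(level)] = p_peak

    levels = [float(p) for p in settings.peep_schedule]
    for low, high in zip(levels, levels[1:]):
        truth.trapped_ml[(low, high)] = truth.eev_ml[high] - truth.eev_ml[low]

    flow = np.concatenate(flow_parts)
    palv = np.concatenate(palv_parts)
    peep_ann = np.concatenate(peep_parts)
    paw = palv + resistance * flow

    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        paw = paw * (1.0 + noise_sd_frac * rng.standard_normal(paw.size))
        flow = flow * (1.0 + noise_sd_frac * rng.standard_normal(flow.size))

    # Volume channel: trapezoidal integral of the (noisy) flow channel so
    # that the record invariant holds exactly.
    left = np.concatenate(([0.0], flow[:-1]))
    vol = np.cumsum(0.5 * (left + flow) * dt)
    time = dt * np.arange(flow.size)

    return WaveformRecord(
        time=time, paw=paw, flow=flow, volume=vol, peep=peep_ann, truth=truth
    )
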