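"""From raw manoeuvre waveforms to per-PEEP pressure-volume curves.

The processing chain mirrors how step-wise PEEP recordings are analysed at
the bedside:

1. segment the record into breaths from inspiratory flow onsets;
2. estimate the "trapped" volume of each PEEP increment — the
   end-expiratory lung-volume gain from incomplete expiration, summed as
   (inspired - expired) over the transition breaths at the new level;
3. pick a representative breath per PEEP level (pointwise mean of the last
   two breaths, after viscoelastic stabilisation);
4. assemble inflation and deflation PV curves per level, offsetting each
   curve's volume axis by the running sum of preceding trapped volumes so
   the curves stack into one absolute volume scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, MissingLevelError, NoBreathsError, ParameterError
from .lung_simulator import WaveformRecord

__all__ = [
    "Breath",
    "RepresentativeBreath",
    "PVCurve",
    "segment_breaths",
    "select_representative_breath",
    "estimate_trapped_volume",
    "transition_window",
    "build_pv_curves",
]

#: number of phase points used when resampling breaths for averaging
N_PHASE = 200


@dataclass
class Breath:
    """One breath located in a waveform record (sample indices)."""

    insp_start: int
    insp_end: int
    exp_end: int
    peep_level: float
    inspired_volume: float
    expired_volume: float

    def __post_init__(self) -> None:
        if not (self.insp_start < self.insp_end < self.exp_end):
            raise InputError("breath indices must satisfy insp_start < insp_end < exp_end")
        if self.inspired_volume <= 0:
            raise InputError("inspired_volume must be positive")
        if self.expired_volume < 0:
            raise InputError("expired_volume must be non-negative")


@dataclass
class RepresentativeBreath:
    """Phase-resampled representative breath for one PEEP level.

    Pressure/flow/volume traces are resampled onto ``N_PHASE`` points per
    limb; for the default "mean" rule they are the pointwise mean of the
    last two breaths at the level.
    """

    peep_level: float
    paw_insp: np.ndarray
    volume_insp: np.ndarray
    flow_insp: np.ndarray
    paw_exp: np.ndarray
    volume_exp: np.ndarray
    flow_exp: np.ndarray
    inspired_volume: float
    expired_volume: float
    single_breath: bool = False


@dataclass
class PVCurve:
    """Ordered pressure-volume points for one limb at one PEEP level.

    ``volume`` is absolute: the per-breath relative volume plus ``offset``,
    the running sum of trapped volumes of all preceding PEEP increments.
    Pressure is strictly monotone (increasing on inflation, decreasing on
    deflation).
    """

    limb: str
    peep: float
    pressure: np.ndarray
    volume: np.ndarray
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.limb not in ("inflation", "deflation"):
            raise ParameterError(f"limb must be inflation or deflation, got {self.limb!r}")
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.pressure.size != self.volume.size:
            raise InputError("pressure and volume must have equal length")
        if self.pressure.size < 3:
            raise InputError("a PV curve needs at least 3 points")
        dp = np.diff(self.pressure)
        if self.limb == "inflation" and np.any(dp <= 0):
            raise InputError("inflation pressures must be strictly increasing")
        if self.limb == "deflation" and np.any(dp >= 0):
            raise InputError("deflation pressures must be strictly decreasing")
        if np.any(self.volume < -1e-9):
            raise InputError("volumes must be non-negative")

    @property
    def n_points(self) -> int:
        return int(self.pressure.size)


def segment_breaths(record: WaveformRecord, flow_threshold_frac: float = 0.05) -> list[Breath]:
    """Delimit breaths by inspiratory flow onsets.

    An onset is a rising crossing of ``+flow_threshold_frac * max|flow|``;
    re-triggers are suppressed until flow has fallen back below a 1 %
    hysteresis band.  Inspired/expired volumes are trapezoidal integrals
    of the positive/negative flow within each breath.
    """
    flow = np.asarray(record.flow, dtype=float)
    if flow.size == 0:
        raise InputError("empty waveform record")
    peak = float(np.max(np.abs(flow)))
    if peak <= 0:
        raise NoBreathsError("no breaths detected: flow is identically zero")
    thr_on = flow_threshold_frac * peak
    thr_off = 0.01 * peak
    dt = record.dt

    onsets: list[int] = []
    armed = True
    for i in range(1, flow.size):
        if armed and flow[i] >= thr_on and flow[i - 1] < thr_on:
            onsets.append(i)
            armed = False
        elif not armed and flow[i] < thr_off:
            armed = True
    if not onsets:
        raise NoBreathsError("no breaths detected: no flow onsets found")

    bounds = onsets + [flow.size - 1]
    breaths: list[Breath] = []
    for start, nxt in zip(bounds[:-1], bounds[1:]):
        seg = flow[start:nxt + 1]
        neg = np.nonzero(seg < 0)[0]
        if neg.size == 0 or neg[0] < 2:
            continue  # truncated breath without an expiratory phase
        insp_end = start + int(neg[0]) - 1
        inspired = float(np.trapezoid(np.clip(seg, 0.0, None), dx=dt))
        expired = float(-np.trapezoid(np.clip(seg, None, 0.0), dx=dt))
        if inspired <= 0:
            continue
        breaths.append(
            Breath(
                insp_start=start,
                insp_end=insp_end,
                exp_end=nxt,
                peep_level=float(record.peep[start]),
                inspired_volume=inspired,
                expired_volume=expired,
            )
        )
    if not breaths:
        raise NoBreathsError("no complete breaths detected")
    return breaths


def _resample_limb(record: WaveformRecord, i0: int, i1: int):
    """Resample paw/volume/flow over samples [i0, i1] onto the phase grid."""
    phase = np.linspace(i0, i1, N_PHASE)
    idx = np.arange(i0, i1 + 1)
    return tuple(
        np.interp(phase, idx, np.asarray(ch)[i0:i1 + 1])
        for ch in (record.paw, record.volume, record.flow)
    )


def select_representative_breath(
    breaths: list[Breath],
    record: WaveformRecord,
    peep_level: float | None = None,
    rule: str = "mean",
) -> RepresentativeBreath:
    """Representative breath for one PEEP level.

    With ``rule="mean"`` (default) the traces are the pointwise mean of the
    last two breaths at the level, resampled to a common phase grid — the
    breaths after viscoelastic stabilisation.  ``rule="last"`` returns the
    final breath unchanged.  A single available breath is returned as-is
    with ``single_breath=True`` and a warning.
    """
    if peep_level is not None:
        breaths = [b for b in breaths if b.peep_level == peep_level]
    if not breaths:
        raise MissingLevelError(f"no breaths at PEEP level {peep_level!r}")
    if rule not in ("mean", "last"):
        raise ParameterError(f"unknown representative rule {rule!r}")

    chosen = breaths[-2:] if rule == "mean" else breaths[-1:]
    single = len(breaths) < 2
    if single:
        warnings.warn(
            f"only one breath available at PEEP {breaths[-1].peep_level:g}; "
            "representative breath is that single breath",
            stacklevel=2,
        )

    insp = [_resample_limb(record, b.insp_start, b.insp_end) for b in chosen]
    exp = [_resample_limb(record, b.insp_end, b.exp_end) for b in chosen]
    paw_i, vol_i, flow_i = (np.mean([t[k] for t in insp], axis=0) for k in range(3))
    paw_e, vol_e, flow_e = (np.mean([t[k] for t in exp], axis=0) for k in range(3))
    return RepresentativeBreath(
        peep_level=chosen[-1].peep_level,
        paw_insp=paw_i,
        volume_insp=vol_i,
        flow_insp=flow_i,
        paw_exp=paw_e,
        volume_exp=vol_e,
        flow_exp=flow_e,
        inspired_volume=float(np.mean([b.inspired_volume for b in chosen])),
        expired_volume=float(np.mean([b.expired_volume for b in chosen])),
        single_breath=single,
    )


def estimate_trapped_volume(record: WaveformRecord, transition_breaths: list[Breath]) -> float:
    """Trapped (recruitment) volume of one PEEP increment, in ml.

    The sum of (inspired - expired) over the transition breaths: the
    estimated end-expiratory lung-volume gain for the PEEP step.  A small
    negative estimate (measurement noise) is clamped to zero with a
    warning, since lung volume cannot fall when PEEP is raised.
    """
    if not transition_breaths:
        raise InputError("transition breath set is empty")
    total = float(sum(b.inspired_volume - b.expired_volume for b in transition_breaths))
    if total < 0:
        warnings.warn(
            f"negative trapped-volume estimate ({total:.1f} ml) clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return total


def transition_window(breaths: list[Breath], stabilize_frac: float = 0.01) -> list[Breath]:
    """Breaths of a PEEP level that span the volume transient.

    Walks the level's breaths in order and stops once the per-breath
    end-expiratory volume gain (inspired - expired) has settled within
    ``stabilize_frac`` of the inspired volume; the settled breath is
    included so the window always covers the tail of the transient.
    """
    if not breaths:
        raise InputError("breath list is empty")
    window: list[Breath] = []
    for b in breaths:
        window.append(b)
        if abs(b.inspired_volume - b.expired_volume) < stabilize_frac * b.inspired_volume:
            break
    return window


def _monotone_envelope(pressure, volume, increasing: bool):
    """Strictly monotone subsequence of the pressure trace.

    Within a run of (nearly) equal pressures — e.g. recruitment at constant
    airway pressure — the last sample is kept, so each retained pressure
    carries the equilibrated volume attained at that pressure.
    """
    sign = 1.0 if increasing else -1.0
    p_arr = np.asarray(pressure, dtype=float)
    v_arr = np.asarray(volume, dtype=float)
    keep: list[int] = []
    best = -np.inf
    for i, p in enumerate(p_arr):
        if sign * p > best + 1e-12:
            keep.append(i)
            best = sign * p
        elif keep and sign * p > best - 1e-12:
            keep[-1] = i  # same pressure: take the latest (equilibrated) volume
    idx = np.asarray(keep, dtype=int)
    return p_arr[idx], v_arr[idx]


def build_pv_curves(
    record: WaveformRecord,
    breaths: list[Breath],
    resistance: float | None = None,
    representative: str = "mean",
    stabilize_frac: float = 0.01,
) -> list[PVCurve]:
    """Per-PEEP inflation and deflation PV curves with cumulative offsets.

    For each PEEP level the representative breath yields two curves.  Each
    curve's volume axis is re-zeroed at inspiration onset and offset by the
    running sum of the trapped volumes of all preceding PEEP increments,
    so the curves stack on one absolute recruited-volume scale.  When a
    ``resistance`` estimate (cmH2O.s/ml) is given, the resistive pressure
    component ``resistance * flow`` is removed before curve construction;
    by default the raw airway pressure is used.
    """
    if not breaths:
        raise InputError("breath list is empty")
    levels = sorted({b.peep_level for b in breaths})
    by_level = {lvl: [b for b in breaths if b.peep_level == lvl] for lvl in levels}

    offsets: dict[float, float] = {}
    trapped_running = 0.0
    for i, lvl in enumerate(levels):
        if i > 0:
            window = transition_window(by_level[lvl], stabilize_frac)
            trapped_running += estimate_trapped_volume(record, window)
        offsets[lvl] = trapped_running

    curves: list[PVCurve] = []
    for lvl in levels:
        rep = select_representative_breath(by_level[lvl], record, rule=representative)
        v0 = rep.volume_insp[0]
        for limb, paw, vol, flw, increasing in (
            ("inflation", rep.paw_insp, rep.volume_insp, rep.flow_insp, True),
            ("deflation", rep.paw_exp, rep.volume_exp, rep.flow_exp, False),
        ):
            pressure = paw - resistance * flw if resistance is not None else paw
            volume = np.clip(vol - v0, 0.0, None) + offsets[lvl]
            p_env, v_env = _monotone_envelope(pressure, volume, increasing)
            if p_env.size < 3:
                raise MissingLevelError(
                    f"{limb} limb at PEEP {lvl:g} has fewer than 3 distinct pressures"
                )
            curves.append(
                PVCurve(limb=limb, peep=lvl, pressure=p_env, volume=v_env, offset=offsets[lvl])
            )
    return curves


def curves_to_frame(curves: list[PVCurve]) -> pd.DataFrame:
    """Tidy frame of PV curves (``limb,peep_cmH2O,pressure_cmH2O,volume_ml``)."""
    rows = [
        pd.DataFrame(
            {
                "limb": c.limb,
                "peep_cmH2O": c.peep,
                "pressure_cmH2O": c.pressure,
                "volume_ml": c.volume,
            }
        )
        for c in curves
    ]
    return pd.concat(rows, ignore_index=True)
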