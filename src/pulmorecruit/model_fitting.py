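"""Nonlinear least-squares estimation of recruitment-curve parameters.

Each PV limb is fitted independently for ``(mean, sd, tlc)`` by bounded
trust-region least squares on the residuals ``model_volume(p) - v``.
Inflation fits estimate the TOP distribution, deflation fits the TCP
distribution.  Fit quality is reported as the mean absolute percentage
error (MAPE) between fitted and measured volumes.

The recruitable capacity ``tlc`` is a free parameter of every fit
(bounded below by the largest measured volume): the manoeuvre itself gives
no independent capacity measurement, so fitting it keeps the procedure
self-contained.  No stochastic restarts are used by default, so results
are bit-reproducible; a seeded multi-start option exists for pathological
curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InputError, UnidentifiableCurveError
from .recruitment_model import RecruitmentParams, model_volume
from .waveform_processing import PVCurve

__all__ = [
    "RecruitmentFit",
    "ManoeuvreFits",
    "fit_limb",
    "compute_mape",
    "fit_manoeuvre",
    "fits_to_frame",
]

#: fraction of the maximum volume under which points are excluded from MAPE
MAPE_GUARD_FRAC = 0.01

_LIMB_ORDER = {"inflation": 0, "deflation": 1}


@dataclass
class RecruitmentFit:
    """Fitted recruitment parameters for one limb at one PEEP level."""

    params: RecruitmentParams
    limb: str
    peep: float
    mape: float
    n_points: int
    converged: bool
    poorly_identified: bool = False

    @property
    def distribution(self) -> str:
        """Which threshold distribution the fit estimates (TOP or TCP)."""
        return "TOP" if self.limb == "inflation" else "TCP"


@dataclass
class ManoeuvreFits:
    """Fits for a whole manoeuvre plus any per-curve failures."""

    fits: list = field(default_factory=list)
    failures: list = field(default_factory=list)  # (curve, exception) pairs


def _initial_params(curve: PVCurve) -> RecruitmentParams:
    """Default initialisation: mean at the steepest finite-difference slope,
    sd from the pressure span, tlc just above the largest volume."""
    p, v = curve.pressure, curve.volume
    slopes = np.diff(v) / np.diff(p)
    mids = 0.5 * (p[:-1] + p[1:])
    mean0 = float(mids[int(np.argmax(np.abs(slopes)))])
    span = float(p.max() - p.min())
    sd0 = max(span / 4.0, 1e-2)
    tlc0 = 1.05 * float(v.max())
    return RecruitmentParams(mean=mean0, sd=sd0, tlc=tlc0)


def fit_limb(
    curve: PVCurve,
    init: RecruitmentParams | None = None,
    bounds: tuple | None = None,
    multistart: int = 0,
    seed: int = 0,
) -> RecruitmentFit:
    """Fit ``(mean, sd, tlc)`` to one PV limb.

    Parameters
    ----------
    curve
        Valid PV curve (>= 3 points, strictly monotone pressure).
    init
        Optional starting parameters; otherwise derived from the curve.
    bounds
        Optional ``(lower, upper)`` triples for ``(mean, sd, tlc)``;
        defaults keep ``sd > 0`` and ``tlc >= max(volume)``.
    multistart
        Number of additional seeded random restarts (0 = deterministic).
    """
    if curve.n_points < 3:
        raise InputError("fit requires at least 3 PV points")
    p = np.asarray(curve.pressure, dtype=float)
    v = np.asarray(curve.volume, dtype=float)
    if np.ptp(v) <= 0:
        raise UnidentifiableCurveError(
            "all volumes equal: sd is unbounded and the curve is unidentifiable"
        )
    vmax = float(v.max())
    span = float(p.max() - p.min())
    if init is None:
        init = _initial_params(curve)
    if bounds is None:
        # Identifiable ranges for a span-limited curve: a mean far outside
        # the observed pressure window, an sd much wider than the window,
        # or an asymptote far above the data are all indistinguishable
        # from a straight line and lead the optimizer into flat valleys.
        lower = [p.min() - span, 1e-2, vmax]
        upper = [p.max() + span, 2.0 * span, 4.0 * vmax]
    else:
        lower, upper = (list(map(float, b)) for b in bounds)
    x0 = np.clip(
        [init.mean, init.sd, init.tlc],
        np.asarray(lower) * (1 + 1e-12) + 1e-12,
        upper,
    )

    def residuals(x):
        return model_volume(p, RecruitmentParams(*x)) - v

    starts = [x0]
    if multistart > 0:
        rng = np.random.default_rng(seed)
        lo, hi = np.asarray(lower), np.asarray(upper)
        for _ in range(multistart):
            starts.append(lo + rng.random(3) * (np.minimum(hi, lo + 4 * (x0 - lo) + 1) - lo))

    best = None
    for x_start in starts:
        res = least_squares(
            residuals,
            x_start,
            bounds=(lower, upper),
            method="trf",
            ftol=1e-10,
            xtol=1e-8,
            gtol=1e-10,
            x_scale=[max(span, 1.0), max(span, 1.0), vmax],
        )
        if best is None or res.cost < best.cost:
            best = res

    params = RecruitmentParams(*best.x)
    fit = RecruitmentFit(
        params=params,
        limb=curve.limb,
        peep=curve.peep,
        mape=np.nan,
        n_points=curve.n_points,
        converged=bool(best.success),
        poorly_identified=span < init.sd,
    )
    fit.mape = compute_mape(fit, curve)
    return fit


def compute_mape(fit: RecruitmentFit, curve: PVCurve) -> float:
    """Mean absolute percentage error of a fit against its curve.

    ``(100 / n) * sum(|model(p_i) - v_i| / v_i)`` over points whose volume
    exceeds ``MAPE_GUARD_FRAC`` of the maximum volume — near-zero volumes
    are excluded so the percentage cannot blow up.
    """
    p = np.asarray(curve.pressure, dtype=float)
    v = np.asarray(curve.volume, dtype=float)
    mask = v > MAPE_GUARD_FRAC * float(v.max())
    if not np.any(mask):
        raise InputError("MAPE undefined: every point excluded by the volume guard")
    pred = model_volume(p[mask], fit.params)
    return float(100.0 * np.mean(np.abs(pred - v[mask]) / v[mask]))


def fit_manoeuvre(curves: list[PVCurve], **fit_kwargs) -> ManoeuvreFits:
    """Fit every (PEEP, limb) curve of a manoeuvre.

    Inflation fits estimate TOP distributions, deflation fits TCP
    distributions.  Per-curve failures are collected and do not abort the
    remaining fits.  Output is ordered by PEEP, then inflation before
    deflation.
    """
    if not curves:
        raise InputError("no curves to fit")
    ordered = sorted(curves, key=lambda c: (c.peep, _LIMB_ORDER[c.limb]))
    result = ManoeuvreFits()
    for curve in ordered:
        try:
            result.fits.append(fit_limb(curve, **fit_kwargs))
        except (InputError, UnidentifiableCurveError) as exc:
            result.failures.append((curve, exc))
    return result


def fits_to_frame(
    fits: list[RecruitmentFit],
    subject: str | int = "",
    state: str = "",
) -> pd.DataFrame:
    """Tidy frame of fits (columns match the fits CSV layout)."""
    return pd.DataFrame(
        {
            "subject": subject,
            "state": state,
            "peep_cmH2O": [f.peep for f in fits],
            "limb": [f.limb for f in fits],
            "mean_cmH2O": [f.params.mean for f in fits],
            "sd_cmH2O": [f.params.sd for f in fits],
            "tlc_ml": [f.params.tlc for f in fits],
            "mape_pct": [f.mape for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
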