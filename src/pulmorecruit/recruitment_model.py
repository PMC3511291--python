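"""The minimal recruitment model: an error-function pressure-volume curve.

The lung is treated as a large collection of units that are either open or
collapsed.  Each unit opens when airway pressure exceeds its threshold
opening pressure (TOP) and, once open, contributes a fixed unit volume.
With TOPs normally distributed across units, the volume recruited at
pressure :math:`P` is

.. math::

    V(P) = \\tfrac{1}{2}\\left(1 + \\mathrm{erf}\\!\\left(
        \\frac{P - \\mu}{\\sqrt{2}\\,\\sigma}\\right)\\right) \\cdot V_{tlc}

i.e. the normal CDF of the TOP distribution scaled by the recruitable
capacity ``tlc``.  The mean :math:`\\mu` is the pressure of maximum
recruitment rate; the standard deviation :math:`\\sigma` measures lung
heterogeneity.  The deflation limb uses the identical functional form with
its own ``(mean, sd)`` interpreted as the threshold *closing* pressure
(TCP) distribution.

This module is a pure-function library surface: forward curve, inverse,
and the TOP/TCP density, all vectorised over pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import ParameterError

__all__ = [
    "RecruitmentParams",
    "fraction_recruited",
    "model_volume",
    "invert_model",
    "threshold_density",
]

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class RecruitmentParams:
    """Parameters of one recruitment curve (one limb at one PEEP).

    Parameters
    ----------
    mean : float
        Mean threshold pressure, cmH2O.  Mean TOP for an inflation limb,
        mean TCP for a deflation limb.
    sd : float
        Spread of the threshold distribution, cmH2O; must be positive.
    tlc : float
        Recruitable capacity of the fitted curve, ml; must be positive.
    """

    mean: float
    sd: float
    tlc: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sd) or self.sd <= 0:
            raise ParameterError(f"sd must be positive, got {self.sd}")
        if not np.isfinite(self.tlc) or self.tlc <= 0:
            raise ParameterError(f"tlc must be positive, got {self.tlc}")


def fraction_recruited(pressure, params: RecruitmentParams):
    """Fraction of recruitable units open at ``pressure``.

    Returns ``0.5 * (1 + erf((p - mean) / (sqrt(2) * sd)))``, the normal
    CDF of the threshold distribution.  Continuous and strictly increasing
    in pressure; vectorised.
    """
    p = np.asarray(pressure, dtype=float)
    z = (p - params.mean) / (_SQRT2 * params.sd)
    out = 0.5 * (1.0 + special.erf(z))
    return out if out.ndim else float(out)


def model_volume(pressure, params: RecruitmentParams):
    """Recruited volume (ml) at ``pressure``: ``tlc * fraction_recruited``."""
    return params.tlc * fraction_recruited(pressure, params)


def invert_model(volume, params: RecruitmentParams):
    """Pressure at which the model holds ``volume``.

    Exact inverse through the inverse error function.  ``volume`` must lie
    strictly inside ``(0, tlc)``.
    """
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0.0) or np.any(v >= params.tlc):
        raise ParameterError(
            "volume must lie strictly between 0 and tlc for inversion"
        )
    p = params.mean + _SQRT2 * params.sd * special.erfinv(2.0 * v / params.tlc - 1.0)
    return p if p.ndim else float(p)


def threshold_density(pressure, params: RecruitmentParams):
    """Normal density of the threshold (TOP or TCP) distribution.

    This is the derivative of :func:`fraction_recruited`; its maximum sits
    at ``mean``, the pressure of maximum recruitment (or derecruitment)
    rate.  Units: 1/cmH2O.
    """
    p = np.asarray(pressure, dtype=float)
    z = (p - params.mean) / params.sd
    out = np.exp(-0.5 * z * z) / (params.sd * _SQRT2PI)
    return out if out.ndim else float(out)
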