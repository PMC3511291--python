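"""Optional plots: PV curves with fitted models, threshold densities, DSG plane."""

from __future__ import annotations

import numpy as np

from .model_fitting import RecruitmentFit
from .recruitment_model import model_volume, threshold_density
from .reporting_dsg import DSGPoint
from .waveform_processing import PVCurve


def plot_pv_fits(curves: list[PVCurve], fits: list[RecruitmentFit], ax=None):
    """Measured PV curves overlaid with their fitted recruitment models."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    by_key = {(f.peep, f.limb): f for f in fits}
    for curve in curves:
        line, = ax.plot(curve.pressure, curve.volume, ".", ms=3,
                        label=f"PEEP {curve.peep:g} {curve.limb}")
        fit = by_key.get((curve.peep, curve.limb))
        if fit is not None:
            grid = np.linspace(curve.pressure.min(), curve.pressure.max(), 200)
            ax.plot(grid, model_volume(grid, fit.params), "-", lw=1,
                    color=line.get_color())
    ax.set_xlabel("airway pressure (cmH2O)")
    ax.set_ylabel("volume (ml)")
    ax.legend(fontsize=6)
    return ax


def plot_threshold_densities(fits: list[RecruitmentFit], ax=None):
    """TOP (inflation) and TCP (deflation) distribution densities per PEEP."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for fit in fits:
        grid = np.linspace(fit.params.mean - 4 * fit.params.sd,
                           fit.params.mean + 4 * fit.params.sd, 300)
        style = "-" if fit.limb == "inflation" else "--"
        ax.plot(grid, threshold_density(grid, fit.params), style,
                label=f"{fit.distribution} PEEP {fit.peep:g}")
    ax.set_xlabel("pressure (cmH2O)")
    ax.set_ylabel("density (1/cmH2O)")
    ax.legend(fontsize=6)
    return ax


def plot_dsg_plane(points: list[DSGPoint], top_threshold: float,
                   sd_threshold: float, ax=None):
    """Disease-state-grouping plane with panel boundaries and trajectory."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = sorted(points, key=lambda p: p.order)
    sd = [p.sd_top for p in pts]
    top = [p.mean_top for p in pts]
    ax.plot(sd, top, "o-")
    for p in pts:
        ax.annotate(f"{p.state_tag} ({p.panel})", (p.sd_top, p.mean_top),
                    fontsize=7, xytext=(4, 4), textcoords="offset points")
    ax.axvline(sd_threshold, color="grey", ls=":")
    ax.axhline(top_threshold, color="grey", ls=":")
    ax.set_xlabel("SD of TOP distribution (cmH2O)")
    ax.set_ylabel("mean TOP (cmH2O)")
    return ax
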