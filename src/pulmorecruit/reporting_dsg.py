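"""Summary statistics, rank-sum testing, compliance and disease-state grouping.

Per-group medians and interquartile ranges use nearest-rank order
statistics (for nine subjects: the 3rd and 7th order statistics), the
convention that reproduces the bundled reference tables.  The Wilcoxon
rank-sum test uses mid-ranks for ties and an exact enumeration of rank
assignments for small samples.

Disease-state grouping (DSG) places a subject on the (SD, mean TOP) plane:
Panel B (low SD, low TOP) is the healthiest corner; A is heterogeneous
(high SD, low TOP), D collapsed (low SD, high TOP), C both.  Thresholds
are mandatory configuration — no clinically validated boundaries exist —
and trajectories across the plane track disease progression or recovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

from .errors import ConfigurationError, InputError, ParameterError

__all__ = [
    "DSGPoint",
    "TrajectoryStep",
    "WilcoxonResult",
    "summarize_fits",
    "render_summary",
    "wilcoxon_rank_sum",
    "compute_static_compliance",
    "assign_dsg_panel",
    "track_dsg",
]

#: pooled sample size up to which the rank-sum p-value is exact
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class DSGPoint:
    """One subject's position on the disease-state-grouping plane."""

    mean_top: float
    sd_top: float
    panel: str
    state_tag: str = ""
    order: int = 0


@dataclass(frozen=True)
class TrajectoryStep:
    """Change between two consecutive DSG points."""

    d_mean_top: float
    d_sd_top: float
    label: str  # improving | worsening | mixed | unchanged


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank sum of the first sample (mid-ranks)
    pvalue: float
    method: str  # "exact" or "normal"


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    k = max(1, math.ceil(q * sorted_vals.size))
    return float(sorted_vals[k - 1])


def _median(sorted_vals: np.ndarray) -> float:
    n = sorted_vals.size
    if n % 2:
        return float(sorted_vals[n // 2])
    return float(0.5 * (sorted_vals[n // 2 - 1] + sorted_vals[n // 2]))


def summarize_fits(
    fits: pd.DataFrame,
    value: str = "mean_cmH2O",
    by: list[str] | tuple = ("state", "limb", "peep_cmH2O"),
) -> pd.DataFrame:
    """Median, nearest-rank IQR, mean and n per group of fitted values.

    Empty groups are simply absent; groups whose values contain NaN are
    summarised over the finite values with a warning.
    """
    if fits.empty:
        raise InputError("no fits to summarize")
    by = [k for k in by if k in fits.columns]
    rows = []
    for keys, grp in fits.groupby(by, sort=True, dropna=False):
        vals = grp[value].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            warnings.warn(f"group {keys!r} has no finite values; omitted", stacklevel=2)
            continue
        if finite.size < vals.size:
            warnings.warn(f"group {keys!r} contains non-finite values", stacklevel=2)
        s = np.sort(finite)
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(
            dict(zip(by, keys))
            | {
                "median": _median(s),
                "iqr_low": _nearest_rank(s, 0.25),
                "iqr_high": _nearest_rank(s, 0.75),
                "mean": float(np.mean(s)),
                "n": int(s.size),
            }
        )
    return pd.DataFrame(rows)


def render_summary(summary: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Report rendering: 'median [iqr_low-iqr_high]' and mean at fixed decimals.

    Rounding happens only here; the numeric summary keeps full precision.
    """
    out = summary.copy()
    fmt = f"{{:.{decimals}f}}"
    out["median_iqr"] = [
        f"{fmt.format(m)} [{fmt.format(lo)}-{fmt.format(hi)}]"
        for m, lo, hi in zip(summary["median"], summary["iqr_low"], summary["iqr_high"])
    ]
    out["mean_rendered"] = [fmt.format(m) for m in summary["mean"]]
    return out


def wilcoxon_rank_sum(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test with mid-ranks for ties.

    For pooled sample sizes up to :data:`EXACT_ENUMERATION_LIMIT` the
    p-value is exact: all ``C(n, n_x)`` assignments of the pooled mid-ranks
    are enumerated and ``p = min(1, 2 * min(P(W <= w), P(W >= w)))``.
    Larger samples use the normal approximation with tie correction and a
    0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks
    nx, ny = x.size, y.size
    n = nx + ny
    w_obs = float(ranks[:nx].sum())

    if n <= EXACT_ENUMERATION_LIMIT:
        # mid-ranks are multiples of 0.5; double to work in exact integers
        r2 = np.rint(2.0 * ranks).astype(np.int64)
        w2 = np.rint(2.0 * w_obs).astype(np.int64)
        sums = np.fromiter(
            (sum(c) for c in combinations(r2, nx)), dtype=np.int64
        )
        total = sums.size
        p_le = np.count_nonzero(sums <= w2) / total
        p_ge = np.count_nonzero(sums >= w2) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(statistic=w_obs, pvalue=p, method="exact")

    mean_w = nx * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return WilcoxonResult(statistic=w_obs, pvalue=1.0, method="normal")
    z = (w_obs - mean_w - math.copysign(0.5, w_obs - mean_w)) / math.sqrt(var_w)
    if abs(w_obs - mean_w) <= 0.5:
        z = 0.0
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return WilcoxonResult(statistic=w_obs, pvalue=p, method="normal")


def compute_static_compliance(vt: float, plateau_pressure: float, peep: float) -> float:
    """Static respiratory compliance ``vt / (plateau - PEEP)``, ml/cmH2O."""
    if plateau_pressure <= peep:
        raise ParameterError("plateau pressure must exceed PEEP")
    return vt / (plateau_pressure - peep)


def assign_dsg_panel(
    mean_top: float,
    sd_top: float,
    top_threshold: float | None,
    sd_threshold: float | None,
    state_tag: str = "",
    order: int = 0,
) -> DSGPoint:
    """Place a (mean TOP, SD) pair in one of the four DSG panels.

    Thresholds are mandatory: no defaults are claimed because validated
    boundaries do not exist.  Equality is assigned to the lower category
    (a note is emitted), so a value exactly on a threshold counts as low.
    """
    if top_threshold is None or sd_threshold is None:
        raise ConfigurationError("DSG thresholds must be configured explicitly")
    if mean_top == top_threshold or sd_top == sd_threshold:
        warnings.warn(
            "value equal to a DSG threshold assigned to the lower category",
            stacklevel=2,
        )
    top_high = mean_top > top_threshold
    sd_high = sd_top > sd_threshold
    panel = {
        (False, False): "B",
        (False, True): "A",
        (True, False): "D",
        (True, True): "C",
    }[(top_high, sd_high)]
    return DSGPoint(
        mean_top=float(mean_top),
        sd_top=float(sd_top),
        panel=panel,
        state_tag=state_tag,
        order=order,
    )


def track_dsg(points: list[DSGPoint]) -> list[TrajectoryStep]:
    """Qualitative trajectory across consecutive DSG points.

    Both deltas non-positive with at least one negative -> "improving"
    (recruitment pressures falling and/or the lung homogenising); both
    non-negative with at least one positive -> "worsening"; both exactly
    zero -> "unchanged"; opposite signs -> "mixed".
    """
    if len(points) < 2:
        raise InputError("a trajectory needs at least 2 points")
    ordered = sorted(points, key=lambda p: p.order)
    steps = []
    for a, b in zip(ordered, ordered[1:]):
        d_top = b.mean_top - a.mean_top
        d_sd = b.sd_top - a.sd_top
        if d_top == 0 and d_sd == 0:
            label = "unchanged"
        elif d_top <= 0 and d_sd <= 0:
            label = "improving"
        elif d_top >= 0 and d_sd >= 0:
            label = "worsening"
        else:
            label = "mixed"
        steps.append(TrajectoryStep(d_mean_top=d_top, d_sd_top=d_sd, label=label))
    return steps
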