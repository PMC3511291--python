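# Methods

## The minimal recruitment model

The analysis rests on an all-or-none picture of the injured (or
anaesthetised) lung: a large collection of units that are either open or
collapsed.  A collapsed unit opens when airway pressure reaches its
threshold opening pressure (TOP) and then holds a fixed unit volume; an
open unit collapses again when pressure falls to its threshold closing
pressure (TCP < TOP).  With thresholds normally distributed across units,
the recruited volume at pressure *P* is

    V(P) = 1/2 * (1 + erf((P - mean) / (sqrt(2) * sd))) * TLC

the normal CDF of the threshold distribution scaled by the recruitable
capacity `TLC`.  `mean` is the pressure of maximum (de)recruitment rate;
`sd` measures lung heterogeneity; the inflation limb of a
pressure-volume (PV) curve estimates the TOP distribution and the
deflation limb the TCP distribution.  `pulmorecruit.recruitment_model`
implements the curve, its exact inverse (via `erfinv`) and the threshold
density; all three are pure functions.

## Analysis pipeline

`waveform_processing` turns a recorded manoeuvre (time, airway pressure,
flow; volume integrated from flow) into per-PEEP, per-limb PV curves:

- **Breath segmentation.**  Inspiratory onsets are rising crossings of
  5 % of the record's peak absolute flow with a 1 % release band to
  suppress noise re-triggers.  Inspired/expired volumes are trapezoidal
  integrals of the positive/negative flow within each breath.
- **Representative breath.**  The pointwise mean of the last two breaths
  of each PEEP level (after viscoelastic stabilisation), resampled to 200
  phase points per limb.  Taking the final breath instead is available via
  `rule="last"`; the two coincide at steady state.
- **Trapped volume.**  When PEEP is raised, expiration is incomplete and
  the end-expiratory lung volume rises.  The gain for one PEEP increment
  is the sum of (inspired − expired) over the transition breaths of the
  new level; the summation window runs until a breath's volume imbalance
  settles below 1 % of its inspired volume (a configurable choice — the
  transient is geometric, so the truncated tail is below ~2 % of the
  step).  Small negative estimates are clamped to zero with a warning.
- **Curve stacking.**  Each level's curves are re-zeroed at inspiration
  onset and offset by the running sum of all preceding trapped volumes, so
  the per-PEEP curves stack on one absolute recruited-volume axis.
  Offset additivity is exact by construction.  Pressure is raw airway
  pressure by default; a known resistance can optionally be removed
  (`paw − R·flow`).  Within runs of equal pressure (recruitment at
  constant airway pressure) the last sample — the equilibrated volume —
  is kept when reducing to a strictly monotone curve.

`model_fitting` estimates `(mean, sd, tlc)` per limb per PEEP with
bounded trust-region least squares on the volume residuals
(`ftol=1e-10`, `xtol=1e-8`, no random restarts, hence bit-reproducible;
an optional seeded multi-start exists).  Initialisation: `mean` at the
steepest finite-difference slope, `sd` = span/4, `tlc` = 1.05 × max
volume.  Default bounds confine the parameters to their identifiable
ranges — `mean` within one pressure-span of the observed window,
`sd ≤ 2×` span, `max(v) ≤ tlc ≤ 4× max(v)` — because a span-limited,
nearly linear curve segment is equally well fitted by a family of far
larger, far-off-centre curves, and an unbounded optimizer wanders into
those flat valleys.  Fit quality is the mean absolute percentage error
(MAPE) over points with volume above 1 % of the curve maximum (the guard
keeps near-zero denominators out).  `tlc` is free per fit: the manoeuvre
itself provides no independent capacity measurement.

`reporting_dsg` summarises fits as median, nearest-rank interquartile
range (for nine subjects: the 3rd and 7th order statistics — the
convention that reproduces the bundled reference tables exactly) and
mean, rendered at one decimal only at report time.  The Wilcoxon
rank-sum test uses mid-ranks and, for pooled sizes ≤ 12, an exact
enumeration of all rank assignments with
`p = min(1, 2·min(P(W≤w), P(W≥w)))`; larger samples use the normal
approximation with tie correction and continuity correction.  Static
compliance is `Vt / (plateau − PEEP)`.  Disease-state grouping (DSG)
places a subject on the (SD, mean TOP) plane: Panel B (both low) is the
healthiest corner, A is heterogeneous, D collapsed, C both.  Panel
thresholds are mandatory configuration — no validated boundaries exist —
and equality is assigned to the lower category.  DSG points are taken
from the baseline (PEEP 5) inflation fit.  Trajectories label consecutive
changes improving / worsening / mixed / unchanged by the signs of
(Δmean TOP, ΔSD).

## The lung simulator

`lung_simulator` generates ventilator waveforms from an explicit unit
population so every processing stage can be tested against known truth.

- **Thresholds.**  Per-unit TOP ~ Normal(`mu_top`, `sd_top`); TCP ~
  Normal(`mu_tcp`, `sd_tcp`) conditioned on `tcp < top`, sampled exactly
  by inverse-CDF truncation.  The TOP marginal is therefore exactly
  normal, and the quasi-static inflation of a large population converges
  to the error-function curve (max deviation ~0.004 at 10⁵ units).
- **Ventilation.**  Volume control: each breath delivers
  `weight_kg × vt_ml_per_kg` at constant flow over the first third of the
  breath period (square flow and a 1:2 I:E split are conventions; the
  protocol does not dictate them).  Alveolar pressure at each sample is
  the smallest pressure at which the hysteretic population holds the
  delivered volume; airway pressure adds `resistance × flow`
  (default 0.005 cmH2O·s/ml).
- **Expiration.**  Passive exponential flow decay toward the volume the
  population retains at the current PEEP (open units with TCP below PEEP),
  with time constant `resistance × (ΔV/ΔP)` floored at 0.3 s (a lumped
  viscoelastic emptying constant) and truncated when flow falls below 1 %
  of its peak.  The discretised exponential is rescaled so its
  trapezoidal integral releases exactly the intended volume; without the
  rescaling, sampling at 50 Hz under-releases several percent per breath
  and end-expiratory volume ratchets unphysically.
- **Noise.**  Multiplicative Gaussian noise (default 2 % relative SD) on
  the pressure and flow channels; the volume channel is always the
  trapezoidal integral of the (noisy) flow, so records are internally
  consistent.  All randomness is seeded.
- **Elasticity (optional).**  Each open unit may add a saturating elastic
  volume `c · p_el · (1 − exp(−p/p_el))` on top of its fixed volume
  (zero-pressure compliance `c`, knee `p_el`).  The default `c = 0` keeps
  the lung purely all-or-none, so every error-function oracle holds
  exactly; the shipped scenarios use `c = 0.002` ml/cmH2O per unit
  (≈ 15–25 ml/cmH2O lung compliance at piglet scale, knee 15 cmH2O),
  because real tidal ventilation at PEEP 20 is impossible in a purely
  all-or-none lung whose closing pressures sit mostly below 20 cmH2O.
- **Opening-pressure memory (optional).**  `reopen_fraction < 1` lets a
  once-recruited unit re-open at `tcp + f·(top − tcp)`, emulating the
  easier re-opening of recently recruited airways.  The default (1)
  disables it; the first inflation from full collapse always follows the
  pristine TOP distribution.

The simulator records ground truth alongside the waveforms: generating
parameters, end-expiratory volume per PEEP level and true trapped volume
per PEEP step.

### Reference scenarios

The `healthy` scenario uses TOP ~ N(42.4, 23) cmH2O — the baseline-fit
scale of the bundled reference tables — for a 24 kg subject at
12 ml/kg over PEEP 5→20 cmH2O in 5 cmH2O steps, 12 breaths per level,
15 breaths/min, 50 Hz sampling.  The generating TCP distribution,
N(18, 8) cmH2O, is deliberately broader than any single per-PEEP
deflation fit: in a recruitment lung the tidal volume is stored and
released by cyclic opening and closing, so closure mass must exist across
the whole PEEP range for ventilation to remain feasible; per-PEEP fitted
TCP means are local features of that broad distribution.  18 000 units of
0.05 ml give 900 ml recruitable capacity.  The `ards` scenario shifts the
TOP distribution by +15 cmH2O and widens it by +5 cmH2O (more collapse,
more heterogeneity) and leaves TCP unchanged, matching the observation
that deflation behaviour changes little with this kind of injury.

## What the synthetic data does and does not show

Passing tests on simulated manoeuvres demonstrate that the pipeline
(segmentation → trapped volume → stacked curves → fits → summaries →
DSG) is internally correct: trapped-volume estimates match simulator
truth to ~1 %, noise-free synthetic curves are refitted to well under
0.5 % parameter error, fitted TCP rises with PEEP, the injured scenario
fits higher TOP at every PEEP and moves off Panel B, and median inflation
fitting error on the noisy healthy scenario is a few percent.  They do
not show that the simulator reproduces every behaviour of real lungs: the
simulator has no gravitational pressure gradient, no gas exchange, no
spontaneous effort, and static thresholds.

One documented divergence deserves emphasis.  In animal data the fitted
mean TOP *falls* monotonically as PEEP rises.  A quasi-static threshold
lung cannot reproduce this: units retained at PEEP are exactly those with
closing (and, through `tcp < top`, opening) thresholds below PEEP, so the
still-closed population at a level is conditioned on threshold ≥ PEEP and
every per-PEEP inflation window samples an upward-shifted conditional
distribution.  The stacked-volume offset counteracts this only at the
highest level, where trapped volume is large.  Across a wide sweep of
populations and mechanisms (elasticity, near-capacity ventilation,
re-opening memory), the fitted TOP series is at best flat at the
intermediate levels.  The corresponding trend check is therefore expected
to fail for the simulator and is retained as stated; the falling TOP seen
in vivo evidently reflects physiology outside this model class (e.g.
time- and history-dependent effective opening pressures).

## Numerical choices and problem sizes

Degenerate inputs raise typed errors: empty records, fewer than three
curve points, flat curves (unidentifiable `sd`), volumes outside
`(0, tlc)` for inversion, plateau ≤ PEEP for compliance, missing DSG
thresholds, tidal volumes the population cannot accept or release.
Optimizer convergence is reported per fit, and curves whose pressure span
is below one initial `sd` are flagged poorly identified rather than
rejected.

Test and acceptance problem sizes: populations of 10⁴–10⁵ units,
10⁶-draw Monte-Carlo checks, 20-seed recovery sweeps, and full
four-level manoeuvres at 50 Hz (~10⁴ samples); the whole suite runs in a
few seconds.
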