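# Methods

This note documents the models behind `optoloop`, the defaults and why they
were chosen, the numerical machinery, and what the simulations can and
cannot say about real experiments.

## The migrating-cell plant

State: position (µm), unit polarity vector, plus per-cell parameters.
Dynamics per control interval `dt`:

* **Unlit:** persistent random walk at `speed_base`; the polarity angle
  diffuses with rotational diffusion coefficient `D_r = 1/persistence_time`,
  which makes `persistence_time` the velocity decorrelation time of the
  undirected walk (the usual definition).
* **Lit (non-empty illumination sector):** the polarity angle relaxes toward
  the direction from the cell to the illuminated-region centroid with
  timescale `response_time`, and speed follows the saturating dose–response
  `speed_base + v_max·I/(I + K_I)`. Rotational noise still applies.

Two distinct timescales are deliberate. A single timescale serving both as
the undirected persistence (tens of minutes) and the light-response lag
would give a directed heading variance of `D_r·τ ≈ 1 rad²` — a plant no
controller could hold to a micrometre-scale track, contradicting the
observed steerability of optogenetically driven cells, which re-orient
within a couple of minutes when strongly and locally activated. Defaults:

| parameter | default | unit | rationale |
|---|---|---|---|
| `speed_base` | 0.3 (CV 30%) | µm/min | unstimulated fibrosarcoma-like crawl |
| `v_max` | 0.9 | µm/min | lit cells ~3× faster than baseline, saturating |
| `K_I` | 0.1 | µW/cm² | low half-saturation: small doses already steer |
| `persistence_time` | 25 | min | undirected persistence |
| `response_time` | 1.5 | min | light-driven lamellipod redirection |
| `shape_radius` | 10 | µm | rendered footprint |
| `expression` | 30000 (CV 30%) | counts | sets SNR ≈ 10 over background — a sensible exposure |

`expression` is in integrated camera counts (gain 1); the value is an
imaging-regime choice, not biology: cells must sit well above shot noise
for any thresholding segmenter to work, as they would in a reasonably
exposed experiment.

## The light-gated transport plant

Three states — activated exporter fraction `A ∈ [0,1]`, nuclear and
cytosolic concentrations `N`, `C` — with

    dA/dt = k_on_per_I·I·(1−A) − k_off·A
    dN/dt = k_imp·C/ρ − k_exp(E)·A·N
    dC/dt = ρ·k_exp(E)·A·N − k_imp·C,   k_exp(E) = k_exp0/(1 + E/K_E)

This is the minimal structure reproducing, simultaneously: a saturating
light dose–response; single-exponential export and import phases (the rise
of `C` under constant light fits a one-phase decay whose rate matches the
dominant eigenvalue `k_exp(E)·A* + k_imp` of the linearised 2×2 transport
system, verified in the tests); export rates that fall with expression
while import rates do not; and exact conservation of the volume-weighted
total `ρN + C` in production-free mode. The saturating-inverse form of
`k_exp(E)` keeps rates positive for any expression level, unlike a linear
decrement. Optional production and bleaching terms (default off) exist for
long-duration induction drift; the conservation invariant applies only with
them off.

Defaults: `ρ = 0.4`, `k_on_per_I = 0.01 /(s·µW/cm²)`, `k_off = 0.0115 /s`
(dark reversion half-time ≈ 1 min), `k_exp0 = 0.04 /s`, `K_E = 1`,
`k_imp = 0.01 /s`, expression log-normal (mean 1, CV 30%). These give
export/import half-times of ~1–2 min at saturating light (10.4 µW/cm², the
LED setting used for kinetic measurements) — a fast, controllable reporter.
Exporter saturation (finite exportin pool) is not modelled.

**Integration.** Explicit midpoint (RK2) with automatic substepping so that
`dt_sub × (fastest rate) ≤ 0.05`. Because the nucleus↔cytosol fluxes enter
the two equations with exactly cancelling volume weights, any Runge–Kutta
scheme conserves `ρN + C` to rounding error; the long-run drift over 10⁴
steps is < 10⁻⁶ relative. Negative concentrations beyond a 10⁻¹² tolerance
abort the step (none occur with the default substepping).

## Virtual microscope

Cells render as PSF-blurred discs (migration: integrated intensity equals
`expression`; transport: nucleus disc ∝ `E·N` inside a cell disc whose ring
is ∝ `E·C`). Camera model: Poisson shot noise on signal + background,
additive Gaussian read noise (σ = 2 counts), gain 1 count/photon,
background 100 counts, pixel size 1 µm, PSF σ 1.5 px. The transport scenes
carry a second, state-independent "marker" channel (bright nucleus, dim
cell body) used for segmentation only — the analogue of a nuclear marker
line — so that segmentation never depends on the controlled reporter
distribution.

Illumination commands are per-region binary masks with irradiance and PWM
duty cycle. PWM is modelled in the fast-PWM limit (effective dose =
duty × irradiance within a frame interval), justified when the PWM period
is much shorter than `1/k_off`; an explicit on/off segment generator exists
for slow-PWM studies and the tests verify the two agree within 2% at a 1 s
period. A plant receives a region's dose when its sensitive footprint
overlaps the mask; an optional scatter halo grants a configurable fraction
of the dose to near neighbours (the magnitude is a placeholder tunable —
the real scatter geometry is instrument-specific).

## Vision

Default segmentation backend: Gaussian smoothing → global Otsu → hole
filling → connected components → minimum-area filter, behind a one-call
contract so a learned segmenter could be plugged in unchanged. The
nucleus+cytosol mode uses a 3-class multi-Otsu for the cell outline (a
single global Otsu on a bright-nucleus/dim-body scene returns only the
nuclei) and a per-cell brighter-class threshold for the nucleus. Multi-cell
migration runs segment each field-of-view tile independently — one cell per
stage position — because one global threshold across a population with 30%
brightness CV drops the dimmest cells.

Compartment means are measured on masks eroded by 2 px so PSF blur at the
nucleus/cytosol boundary does not contaminate them; the render→segment→
measure round trip recovers N/C within 2%. Background is the median of
pixels outside all dilated masks. Per-cell dynamic ranges come from a
pre-run calibration (frames in the dark steady state and after a saturating
light hold); all controller measurements are normalised to [0,1] against
them. Low-contrast frames (|nucleus − cytosol| < 5% of the range) are
resolved by a temporal filter; the default holds the last valid value
(a PID fed a stale-but-plausible value degrades gracefully, whereas a
window median can lag setpoint transitions), with a median mode available.

Tracking is greedy nearest-centroid with a hard step gate and a
max-gap track lifetime — adequate for the ≤ 10, well-separated cells these
experiments control, and documented as not globally optimal.

## Controllers

**Trajectory controller:** project the measured centroid onto the guide
path; take the setpoint `lookahead` µm further along (wrapping on closed
paths); illuminate the top `front_fraction` quantile of cell-mask pixels by
scalar projection onto the centroid→setpoint direction, at constant
irradiance (default 0.23 µW/cm²). Lookahead default is 6 µm: pure pursuit
on a circle of radius R settles on a track offset inward by
`R(1 − cos(L/R))` (2.8 µm at L = 15 on R = 40, 0.45 µm at L = 6), and the
lateral correction rate is `v/L`, so a short lookahead both removes bias
and tightens regulation; below ~5 µm the aim direction becomes sensitive to
centroid measurement noise. A cell whose track is lost gets light off and
an event log entry.

**Collision avoidance:** constant-velocity extrapolation over a horizon
(default 5 frames); a pair predicted to come within `collision_distance`
(default 30 µm) is flagged and one cell — by default the lower track id —
has its illumination flipped to the rear sector, pulling it back against
its motion. The pullback is held (hysteresis, with the retreat direction
captured at flag time) until the pair separates beyond 1.5× the collision
distance; without the hold, the yielder's reversal immediately clears the
predicted collision, it resumes forward, and the pair ratchets together.

**PID:** derivative acts on the measurement, not the error, so setpoint
steps do not kick the output; the output clamps to `[0, I_max]`
(I_max = 10.4 µW/cm²); the integral freezes whenever integrating would push
a saturated output further into saturation. Nucleus-mode control folds the
plant sign (light lowers nuclear intensity) so the PID always sees positive
plant gain. Under PWM operation the command is delivered as duty cycle
`u/I_max` at full irradiance.

**Gain scheduling:** a value–gain matrix over operating points of the
measured intensity (default {0.1, 0.3, 0.5, 0.7, 0.9}), linearly
interpolated, constant beyond the ends. The scheduling variable is the
temporally filtered measurement additionally smoothed by a 3-frame moving
average to avoid gain chatter; when the controlled variable is the nucleus,
the conserved total makes normalised nucleus the mirror of normalised
cytosol, so the matrix is indexed at `1 − m`. Gain changes rescale the
integral accumulator so the integral's output contribution is continuous.

## The tuner

The plant's static gain `dC*/dI` varies by more than an order of magnitude
across the operating range (steep near dark, collapsing as `A` saturates),
which is exactly why one gain set cannot serve the whole range. Classical
step-response rules assume a fixed plant gain, so the tuner instead does an
overshoot-constrained grid search on the simulated plant:

1. **Per-point pass.** For each operating point, candidate (kp, ki) pairs
   are scored on step responses toward the point from below and above,
   across an expression ensemble (0.6/1.0/1.6× — expression being the
   dominant heterogeneity axis) with seeded measurement noise
   (σ = 0.005 normalised units, the level measured in the imaging loop).
   Responses start bumplessly (integral pre-loaded with the irradiance that
   holds the starting level), as a staircase epoch would. A candidate is
   feasible if every response settles with overshoot ≤ 0.05 *of the dynamic
   range* — range units rather than step-relative, because a downward step
   under 15 s sampling always undershoots by a fixed absolute amount set by
   the free dark-reversion decay, making a step-relative bound meaningless
   for small steps. Among feasible candidates, the smallest worst-case mean
   absolute tracking error wins (this penalises both slow transitions and
   the residual creep of a too-weak integral).
2. **Deployment fine-tuning pass.** Coordinate descent over the matrix,
   top point first: each point's gains are re-selected by simulating the
   *scheduled* controller — interpolation, scheduling-variable smoothing and
   all — through the mini-staircases passing that point. This prices in the
   cross-talk between neighbouring points that per-point tuning cannot see
   (aggressive top-end gains would otherwise leak into mid-range holds via
   interpolation and destabilise them).

The packaged default matrix (`optoloop/data/default_gain_schedule.yaml`)
was produced by this tuner against the default plant and can be
regenerated with `optoloop tune`. The fixed-PID baseline used in
comparisons is the same matrix evaluated at the 0.5 operating point.

## Post-run metrics

*Path deviation* is the distance to the nearest point on the path
(polyline projection; ties broken toward the smaller arc position).
*Projected speed* divides consecutive projected-position arc distances by
the frame interval. Per-loop summaries split the trajectory at wraps of the
cumulative arc progress. *Steady-state error*: the settling point of an
epoch is the first frame where the smoothed derivative (centred 5-point
moving average of the finite difference) changes sign or falls below 10⁻³
of the dynamic range; the mean |error| from there defines the epoch's
steady-state error, cleaning it of the transition. Rates are estimated by
least-squares one-phase-decay fits `y = plateau + (y0−plateau)e^{−kt}` with
`k > 0` enforced and flat series flagged as unidentifiable rather than
fitted.

## Problem sizes and determinism

Default study conditions: migration at 60 s frames on 40 µm circular paths
(single-cell runs of ~580 frames ≈ 2 loops; population runs of 24 cells ×
400 frames); titration at 15 s frames with 10 cells and 40-frame
(10-minute) setpoint epochs; tuner simulations of 80 × 15 s steps. These
sizes keep a full acceptance run at a couple of minutes on one core while
leaving each epoch several multiples of the slowest plant timescale. Every
run is reproducible bit-exactly from config + seed; per-frame wall-clock
times are logged (and scale about linearly in the number of controlled
cells, as each cell adds its own tile of imaging and analysis work).

## What passing tests do and do not show

The synthetic generator emulates the *structure* of the real problem —
heterogeneous dose–responses, expression-dependent export, shot-noise-limited
measurement, segmentation and tracking in the loop, PWM dose delivery — with
parameters chosen once to qualitatively match the observed system (speeds
~1 µm/min, transport half-times ~1–2 min, 30% CV heterogeneity). Passing
benchmarks therefore demonstrate that the *controllers and analysis
pipeline* achieve the target performance on plants with realistic dynamics,
noise and variability. They do not validate the biology: real cells deform,
divide, touch and occlude each other; segmentation of real images fails in
richer ways than threshold noise; the true scatter geometry, PWM hardware
limits and phototoxicity constraints are not modelled; and the plant
parameters are representative, not fitted to any dataset. The collision
model treats cells as non-interacting discs — avoidance prevents encounters
rather than resolving contacts.
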