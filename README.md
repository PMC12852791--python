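# optoloop

Closed-loop optogenetic feedback control on simulated cell "plants" — a
desk-scale, hardware-free implementation of outcome-driven microscopy. The
package is aimed at people designing feedback microscopy experiments
(cybergeneticists, smart-microscopy developers, control-minded cell
biologists) who want to develop and stress-test the *software* side of the
loop — segmentation, tracking, measurement, controllers, illumination
patterning — before ever touching a microscope.

Every frame executes the loop a real platform runs on hardware:

    acquire → segment / track → measure → control → illuminate → cell responds

with the microscope and the cells replaced by seeded simulations behind the
same interfaces a hardware backend would implement.

## What is simulated and controlled

**Directed cell migration.** A migrating cell performs a persistent random
walk; localised blue light (recruiting a RAC1 effector such as TIAM1 to the
plasma membrane) re-orients its polarity toward the illuminated sector and
adds speed along a saturating dose–response,

    v = v_base + v_max · I / (I + K_I).

The trajectory controller projects the tracked centroid **x** onto a guide
path, picks the setpoint a lookahead arc `L` further along, and illuminates
the front sector of the segmented cell mask facing it. The performance
metric is the *path deviation*: the distance from the centroid to the
nearest point on the path. Multi-cell runs add constant-velocity collision
lookahead: on an imminent encounter one cell of the pair is pulled back by
flipping its illumination to the rear sector.

**Nucleocytoplasmic transport titration (LEXY).** Blue light uncages a
nuclear export sequence; a three-state model captures the activated exporter
fraction `A` and the nuclear/cytosolic concentrations `N`, `C`:

    dA/dt = k_on·I·(1 − A) − k_off·A
    dN/dt = k_imp·C/ρ − k_exp(E)·A·N          ρ = V_nuc / V_cyto
    dC/dt = ρ·k_exp(E)·A·N − k_imp·C          k_exp(E) = k_exp0 / (1 + E/K_E)

so ρN + C is conserved, export slows with expression level `E`, and import
is expression-independent — the observed axes of cell-to-cell variation.
A PID controller (derivative-on-measurement, output clamped to [0, I_max],
conditional-integration anti-windup) drives the measured normalised nucleus
or cytosol intensity to a setpoint; a **gain-scheduled** variant interpolates
a value–gain matrix over operating points of the measured intensity, tuned
by the included model-based tuner (overshoot-constrained grid search plus a
deployment fine-tuning pass). Multi-cell runs drive each nucleus at the
hardware irradiance with a per-cell PWM duty cycle.

The virtual microscope renders fluorescence frames (PSF-blurred compartments,
Poisson shot noise, Gaussian read noise), and the vision stack —
Otsu/multi-Otsu segmentation behind a pluggable backend contract, greedy
gated nearest-neighbour tracking, per-cell dynamic-range calibration, a
temporal filter for low-contrast frames — closes the loop on *measured*
quantities only.

## Worked example

```python
from optoloop import (ExperimentConfig, run_closed_loop,
                      summarise_migration, summarise_lexy)

# guide one cell around a 40 µm circle at 0.23 µW/cm², 60 s frames
cfg = ExperimentConfig(mode="migration", n_cells=1, n_frames=300, seed=1)
rec = run_closed_loop(cfg)
print(summarise_migration(rec).round(3).to_string(index=False))
```

```
 cell  mean_deviation_um  max_deviation_um  n_loops  mean_projected_speed_um_min
    0              1.187             4.069        1                        0.902
```

The cell completed one full loop at 0.90 µm/min and its centroid stayed on
average 1.19 µm (at worst 4.07 µm) from the prescribed circle — the
controller is holding a noisy, stochastic walker on a track.

```python
# titrate cytosolic intensity in 3 cells through a 2-step staircase
cfg = ExperimentConfig(mode="lexy", n_cells=3, n_frames=80, seed=1,
                       setpoints=[(0, 0.3), (40, 0.7)])
print(summarise_lexy(run_closed_loop(cfg)).round(2).to_string(index=False))
```

```
 cell  epoch  setpoint  settled  steady_state_error_pct
    0      0       0.3     True                    1.47
    0      1       0.7     True                    1.20
    1      0       0.3     True                    1.45
    1      1       0.7     True                    1.21
    2      0       0.3     True                    1.60
    2      1       0.7     True                    1.15
```

Every cell reaches both setpoints; after the settling point (detected by the
smoothed-derivative criterion) the mean error is 1.2–1.6% of each cell's
calibrated dynamic range, despite the cells' different expression levels and
hence different export kinetics.

A CLI wraps the same machinery: `optoloop simulate` (open-loop plant
rollouts), `optoloop run <config.yaml>` (closed loop), `optoloop analyse
<rundir>`, and `optoloop tune` (regenerate the value–gain matrix).

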