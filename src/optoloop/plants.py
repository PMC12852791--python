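"""Virtual optogenetic plants.

Two simulated "plants" (control-theory sense) stand in for live cells:

* :class:`MigratingCell` — a persistent-random-walk cell whose polarity can be
  steered by localised blue light (membrane recruitment of a RAC1 effector
  drives protrusion toward the illuminated sector) and whose speed follows a
  saturating irradiance dose–response.
* :class:`LexyPlant` — nucleocytoplasmic transport of a LEXY-tagged reporter:
  blue light uncages a nuclear export sequence, a light-activated exporter
  fraction drives nucleus→cytosol flux, import restores the dark state.

These double as the synthetic-data generators: population sampling with
log-normal cell-to-cell heterogeneity emulates the expression and baseline
speed variability of real cell populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MigratingCell",
    "LexyPlant",
    "PopulationSpec",
    "migrate_step",
    "lexy_step",
    "lexy_steady_state",
    "sample_population",
]


# ---------------------------------------------------------------------------
# migrating cell
# ---------------------------------------------------------------------------

@dataclass
class MigratingCell:
    """State and parameters of one light-steerable migrating cell.

    Parameters
    ----------
    position : (2,) array, µm
    polarity : (2,) unit vector — current direction of motion.
    speed_base : µm/min
        Baseline (unstimulated) crawl speed; heterogeneous across cells.
    v_max : µm/min
        Maximal light-induced speed increment (dose–response saturates).
    K_I : µW/cm²
        Half-saturation irradiance of the speed dose–response.
    expression : a.u.
        Optogenetic construct expression level (sets fluorescence).
    shape_radius : µm
        Radius of the rendered cell footprint.
    persistence_time : min
        Undirected persistence time; rotational diffusion D_r = 1/persistence_time.
    response_time : min
        Timescale of polarity re-orientation toward an illuminated sector.
    """

    position: np.ndarray
    polarity: np.ndarray
    speed_base: float = 0.3
    v_max: float = 0.9
    K_I: float = 0.1
    expression: float = 30000.0
    shape_radius: float = 10.0
    persistence_time: float = 25.0
    response_time: float = 1.5

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        pol = np.asarray(self.polarity, dtype=float)
        n = np.hypot(*pol)
        if n == 0:
            raise ValueError("polarity must be a non-zero vector")
        self.polarity = pol / n
        for name in ("speed_base", "v_max", "K_I", "shape_radius",
                     "persistence_time", "response_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def migrate_step(cell: MigratingCell, irradiance: float, aoi_direction,
                 dt_s: float, rng: np.random.Generator | None = None) -> MigratingCell:
    """Advance a migrating cell by one interval.

    With light on a non-empty sector (``aoi_direction`` not None), the polarity
    angle relaxes toward the centroid→AOI-centroid direction with timescale
    ``response_time`` and the speed is ``speed_base + v_max·I/(I+K_I)``.
    Without light the cell performs a persistent random walk at ``speed_base``.
    Rotational diffusion noise (D_r = 1/persistence_time) applies throughout;
    pass ``rng=None`` for the noise-free plant.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    if irradiance < 0:
        raise ValueError("irradiance must be >= 0")
    dt_min = dt_s / 60.0
    theta = math.atan2(cell.polarity[1], cell.polarity[0])

    lit = aoi_direction is not None and irradiance > 0
    if lit:
        tgt = np.asarray(aoi_direction, dtype=float)
        tn = np.hypot(*tgt)
        if tn > 0:
            target_theta = math.atan2(tgt[1], tgt[0])
            err = (target_theta - theta + math.pi) % (2 * math.pi) - math.pi
            theta += err * (1.0 - math.exp(-dt_min / cell.response_time))
        speed = cell.speed_base + cell.v_max * irradiance / (irradiance + cell.K_I)
    else:
        speed = cell.speed_base

    if rng is not None:
        theta += math.sqrt(2.0 * dt_min / cell.persistence_time) * rng.normal()

    pol = np.array([math.cos(theta), math.sin(theta)])
    return replace(cell, position=cell.position + speed * dt_min * pol, polarity=pol)


# ---------------------------------------------------------------------------
# LEXY nucleocytoplasmic transport plant
# ---------------------------------------------------------------------------

@dataclass
class LexyPlant:
    """Three-state light-gated nucleocytoplasmic transport model.

    States: activated-exporter fraction ``A`` ∈ [0,1], nuclear concentration
    ``N`` and cytosolic concentration ``C`` (normalised units).  Dynamics::

        dA/dt = k_on_per_I · I · (1 − A) − k_off · A
        dN/dt = k_imp · C / ρ − k_exp(E) · A · N
        dC/dt = ρ · k_exp(E) · A · N − k_imp · C

    with ρ = V_nuc/V_cyto, so the total amount ρ·N + C is conserved when the
    optional production/bleaching terms are off.  Export saturates inversely
    with expression, ``k_exp(E) = k_exp0 / (1 + E/K_E)``: higher-expressing
    cells export more slowly, while the import rate is expression-independent
    — the two signatures of the measured cell-to-cell variation.

    Rates are per second; irradiance in µW/cm².
    """

    N: float = 2.5
    C: float = 0.0
    A: float = 0.0
    expression: float = 1.0
    vol_ratio: float = 0.4
    k_on_per_I: float = 0.01
    k_off: float = 0.0115
    k_exp0: float = 0.04
    K_E: float = 1.0
    k_imp: float = 0.01
    k_production: float = 0.0   # optional source into the nucleus (a.u./s)
    k_bleach: float = 0.0       # optional first-order loss from both pools (1/s)

    def __post_init__(self):
        if self.N < 0 or self.C < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 <= self.A <= 1.0:
            raise ValueError("A must lie in [0, 1]")
        for name in ("vol_ratio", "k_on_per_I", "k_off", "k_exp0", "K_E", "k_imp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k_exp(self) -> float:
        """Expression-dependent export rate k_exp0/(1+E/K_E), 1/s."""
        return self.k_exp0 / (1.0 + self.expression / self.K_E)

    @property
    def total(self) -> float:
        """Volume-weighted total reporter, ρ·N + C (conserved, production-free)."""
        return self.vol_ratio * self.N + self.C


def _lexy_rhs(y: np.ndarray, I: float, p: LexyPlant) -> np.ndarray:
    A, N, C = y
    ke = p.k_exp
    dA = p.k_on_per_I * I * (1.0 - A) - p.k_off * A
    export = ke * A * N
    imprt = p.k_imp * C
    dN = imprt / p.vol_ratio - export + p.k_production - p.k_bleach * N
    dC = p.vol_ratio * export - imprt - p.k_bleach * C
    return np.array([dA, dN, dC])


def lexy_step(plant: LexyPlant, irradiance: float, dt_s: float,
              max_rel_change: float = 0.05) -> LexyPlant:
    """Advance the transport model by ``dt_s`` seconds at constant irradiance.

    Explicit midpoint (RK2) integration with automatic substepping chosen so
    the fastest rate resolves to ``max_rel_change`` per substep.  The
    nucleus↔cytosol fluxes cancel exactly in the volume-weighted sum for any
    Runge–Kutta scheme, so ρ·N + C is conserved to rounding error.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    if irradiance < 0:
        raise ValueError("irradiance must be >= 0")
    fastest = max(plant.k_on_per_I * irradiance + plant.k_off,
                  plant.k_exp + plant.k_imp / plant.vol_ratio,
                  plant.k_bleach)
    n_sub = max(1, int(math.ceil(dt_s * fastest / max_rel_change)))
    h = dt_s / n_sub
    y = np.array([plant.A, plant.N, plant.C])
    for _ in range(n_sub):
        k1 = _lexy_rhs(y, irradiance, plant)
        k2 = _lexy_rhs(y + 0.5 * h * k1, irradiance, plant)
        y = y + h * k2
        y[0] = min(max(y[0], 0.0), 1.0)
    if y[1] < 0 or y[2] < 0:
        if y[1] > -1e-12 and y[2] > -1e-12:
            y[1:] = np.maximum(y[1:], 0.0)
        else:
            raise ArithmeticError("lexy_step produced negative concentrations")
    return replace(plant, A=float(y[0]), N=float(y[1]), C=float(y[2]))


def lexy_steady_state(plant: LexyPlant, irradiance: float) -> tuple[float, float, float]:
    """Closed-form production-free steady state (A*, N*, C*) at constant I."""
    A = plant.k_on_per_I * irradiance / (plant.k_on_per_I * irradiance + plant.k_off)
    T = plant.total
    keA = plant.k_exp * A
    C = T * keA / (keA + plant.k_imp) if keA + plant.k_imp > 0 else 0.0
    N = (T - C) / plant.vol_ratio
    return A, N, C


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Log-normal cell-to-cell heterogeneity for synthetic populations.

    ``heterogeneity`` maps parameter names to ``(mean, cv)``; each listed
    parameter is drawn log-normally with that arithmetic mean and coefficient
    of variation (cv = 0 collapses to the mean).  Unlisted parameters take the
    template's value.
    """

    n_cells: int
    kind: str = "migration"          # "migration" | "lexy"
    heterogeneity: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.kind not in ("migration", "lexy"):
            raise ValueError(f"unknown population kind {self.kind!r}")
        for name, (mean, cv) in self.heterogeneity.items():
            if mean <= 0 or cv < 0:
                raise ValueError(f"invalid distribution for {name!r}: mean>0, cv>=0")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def sample_population(spec: PopulationSpec, template=None) -> list:
    """Draw ``spec.n_cells`` plant parameter sets, deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    if template is None:
        template = (MigratingCell(position=np.zeros(2), polarity=(1.0, 0.0))
                    if spec.kind == "migration" else LexyPlant())
    draws = {name: _lognormal(rng, mean, cv, spec.n_cells)
             for name, (mean, cv) in spec.heterogeneity.items()}
    cells = []
    for i in range(spec.n_cells):
        cells.append(replace(template, **{k: float(v[i]) for k, v in draws.items()}))
    return cells
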