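"""Growth-vs-arrest discrimination, phase colours, and volume-conserving division.

A cell is *growing* while its nuclear YAP/TAZ exceeds the threshold
``X_th`` (strictly; equality arrests, a measure-zero tie-break fixed for
determinism) and *arrested* otherwise.  Arrest freezes both the age and the
size; it is re-entrant — a cell resumes growing the moment X2 recovers.
The cycle has two phases by age: mitosis M (age < T_M) and growth G1.
The four phase/arrest combinations are labelled with the colour code
cyan(0)/orange(1)/blue(2)/red(3); colours are purely diagnostic.

Growth adds ``d_sigma = gamma*dt*sigma0/T_CC`` per step so an uninterrupted
cycle takes exactly ``T_CC``.  When a cell reaches the doubling size
``2^(1/3)*sigma0`` it divides: the two daughters are placed at
``-/+ gamma*sigma0' * e_r`` around the mother (inside her footprint, since
two spheres of radius sigma0' at that spacing exactly fill her volume),
receive separation velocities ``-/+ (1-gamma)*sigma0' * e_r / T_M`` so they
clear each other within one mitosis phase, restart at size sigma0 and age 0
with colour orange, and inherit the mother's concentrations unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    COLOR_BLUE,
    COLOR_CYAN,
    COLOR_ORANGE,
    COLOR_RED,
    DIV_SIZE_FACTOR,
    DIV_SIZE_RTOL,
    GAMMA,
    CellState,
    CycleParams,
    MechanicsParams,
    Population,
    ReactionParams,
    draw_direction,
    growth_increment,
)


@dataclass(frozen=True)
class CycleDecision:
    """Outcome of the per-step growth/arrest and phase discrimination."""

    growing: bool  # X2 > X_th
    phase: str  # "M" (age < T_M) or "G1"
    color: int  # cyan 0 / orange 1 / blue 2 / red 3


def classify(cell: CellState, p: ReactionParams, c: CycleParams) -> CycleDecision:
    """Discriminate growth vs arrest and M vs G1 for one cell."""
    growing = cell.X2 > p.X_th
    m_phase = cell.age < c.T_M
    if growing:
        color = COLOR_ORANGE if m_phase else COLOR_RED
    else:
        color = COLOR_CYAN if m_phase else COLOR_BLUE
    return CycleDecision(growing=growing, phase="M" if m_phase else "G1", color=color)


def classify_population(pop: Population, p: ReactionParams, c: CycleParams):
    """Vectorised discrimination; returns (growing mask, M-phase mask, colours)."""
    growing = pop.X[:, 1] > p.X_th
    m_phase = pop.age < c.T_M
    colors = np.where(
        growing,
        np.where(m_phase, COLOR_ORANGE, COLOR_RED),
        np.where(m_phase, COLOR_CYAN, COLOR_BLUE),
    ).astype(np.int64)
    return growing, m_phase, colors


def division_size(mech: MechanicsParams) -> float:
    """Size parameter at which a cell divides, ``2^(1/3) * sigma0``."""
    return DIV_SIZE_FACTOR * mech.sigma0


def ready_to_divide(sigma, mech: MechanicsParams):
    """Division predicate ``sigma >= 2^(1/3)*sigma0`` with a 1e-9 relative
    slack absorbing float accumulation over a cycle's worth of increments."""
    return np.asarray(sigma) >= division_size(mech) * (1.0 - DIV_SIZE_RTOL)


def grow_step(cell: CellState, mech: MechanicsParams, c: CycleParams,
              decision: CycleDecision) -> CellState:
    """Advance one cell's age and size by one step.

    Growing cells (from birth size sigma0 up to, not beyond, the doubling
    size) age by dt and grow by d_sigma, clipped at ``2^(1/3)*sigma0``;
    arrested cells keep age and size bit-identical.
    """
    if not decision.growing:
        return cell
    cap = division_size(mech)
    sigma, age = cell.sigma, cell.age
    if cell.sigma < cap * (1.0 - DIV_SIZE_RTOL):
        age = cell.age + mech.dt
        sigma = min(cell.sigma + growth_increment(mech, c), cap)
    return CellState(
        id=cell.id, r=cell.r, v=cell.v, sigma=sigma, radius=mech.zeta * sigma,
        age=age, color=decision.color, X1=cell.X1, X2=cell.X2, X3=cell.X3,
        rho=cell.rho,
    )


def grow_population(pop: Population, mech: MechanicsParams, c: CycleParams,
                    p: ReactionParams) -> np.ndarray:
    """Vectorised classify-and-grow stage; mutates ``pop``, returns growing mask."""
    growing, _, colors = classify_population(pop, p, c)
    pop.color = colors
    cap = division_size(mech)
    can_grow = growing & (pop.sigma < cap * (1.0 - DIV_SIZE_RTOL))
    pop.age[can_grow] += mech.dt
    pop.sigma[can_grow] = np.minimum(pop.sigma[can_grow] + growth_increment(mech, c), cap)
    return growing


def divide_if_ready(
    pop: Population,
    i: int,
    rng: np.random.Generator,
    mech: MechanicsParams,
    c: CycleParams,
    sphere_uniform: bool = False,
) -> Population:
    """Divide cell ``i`` in place if it has reached the doubling size.

    The mother becomes one daughter (position shifted to
    ``r - gamma*sigma0'*e_r``, velocity set to ``-(1-gamma)*sigma0'*e_r/T_M``)
    and a fresh cell is appended for the other; both restart at sigma0 and
    age 0 with colour orange and copies of the mother's concentrations.
    Returns ``pop`` unchanged when the cell is below the division size.
    """
    if not bool(ready_to_divide(pop.sigma[i], mech)):
        return pop
    e_r = draw_direction(rng, sphere_uniform=sphere_uniform)
    offset = GAMMA * mech.sigma0_prime * e_r
    v_sep = (1.0 - GAMMA) * mech.sigma0_prime * e_r / c.T_M
    mother_r = pop.r[i].copy()
    mother_X = pop.X[i].copy()
    mother_rho = pop.rho[i]
    pop.r[i] = mother_r - offset
    pop.v[i] = -v_sep
    pop.sigma[i] = mech.sigma0
    pop.age[i] = 0.0
    pop.color[i] = COLOR_ORANGE
    pop.add_cells(
        r=mother_r + offset,
        v=v_sep,
        sigma=mech.sigma0,
        age=0.0,
        color=COLOR_ORANGE,
        X=mother_X,
        rho=mother_rho,
    )
    return pop
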