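"""Cell-cell mechanics: soft-core Lennard-Jones forces, friction, Verlet.

Cells are spheres interacting through a 12-6 Lennard-Jones potential with a
soft core,

    U(r) = 4*eps * (S^-2 - S^-1),    S(r) = c + (r / sigma_ij)^6,
    c = alpha_LJ * (1 - lambda_sc)^2,  sigma_ij = sigma_i + sigma_j,

which is finite at r = 0 (each cell keeps an exclusive domain without a
numerical blow-up on overlap) and has its minimum, of depth -eps, at
``r = zeta * sigma_ij`` with ``zeta = (2 - c)^(1/6)`` — i.e. exactly at the
sum of the two cell radii.  The potential is truncated at
``r_cut_factor * zeta * sigma_ij`` and shifted to continuity.

Each cell additionally feels Stokes drag ``-mu * v``.  Motion follows
``m0 * dv/dt = F_pair - mu*v``, integrated with velocity Verlet whose
friction term is treated semi-implicitly at the half-step velocity (exactly
time-reversible for mu = 0, second-order accurate damping otherwise).

Neighbour search: an exact O(N^2) vectorised path for small populations
(kept as the oracle in tests) and cell-linked lists with bin size at least
the largest pair cutoff for larger ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model_core import MechanicsParams, Population

logger = logging.getLogger(__name__)

#: Population size above which the cell-linked-list neighbour search is used.
BRUTE_FORCE_MAX_N = 200


class StabilityError(RuntimeError):
    """A Verlet substep displaced a cell by more than half the smallest radius."""


@dataclass(frozen=True)
class ForceField:
    """Interaction constants of the soft-core Lennard-Jones force field."""

    epsilon: float  # well depth (ng*um^2/s^2)
    alpha_LJ: float  # soft-core parameter
    lambda_sc: float  # coupling parameter in [0, 1]
    r_cut_factor: float  # cutoff in units of the pair equilibrium distance
    mu_fric: float  # friction coefficient (ng/s)

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 0.0 <= self.lambda_sc <= 1.0:
            raise ValueError("lambda_sc must lie in [0, 1]")
        if self.r_cut_factor <= 0:
            raise ValueError("r_cut_factor must be > 0")

    @classmethod
    def from_mechanics(cls, m: MechanicsParams) -> "ForceField":
        return cls(
            epsilon=m.epsilon,
            alpha_LJ=m.alpha_LJ,
            lambda_sc=m.lambda_sc,
            r_cut_factor=m.r_cut_factor,
            mu_fric=m.mu_fric,
        )

    @property
    def softcore_const(self) -> float:
        return self.alpha_LJ * (1.0 - self.lambda_sc) ** 2

    @property
    def zeta(self) -> float:
        """Pair equilibrium distance in units of sigma_ij (= radius/sigma ratio)."""
        return (2.0 - self.softcore_const) ** (1.0 / 6.0)


def _u_raw(r, sigma_ij, ff: ForceField):
    s = ff.softcore_const + (np.asarray(r, dtype=np.float64) / sigma_ij) ** 6
    return 4.0 * ff.epsilon * (s**-2 - s**-1)


def softcore_lj_energy(r, sigma_ij: float, ff: ForceField):
    """Truncated-and-shifted pair energy U(r); zero at and beyond the cutoff.

    Finite at r = 0 (value ``4*eps*(c^-2 - c^-1)`` before the shift) and
    minimal at ``r = zeta * sigma_ij``.
    """
    if sigma_ij <= 0:
        raise ValueError("sigma_ij must be > 0")
    r = np.asarray(r, dtype=np.float64)
    r_cut = ff.r_cut_factor * ff.zeta * sigma_ij
    shift = _u_raw(r_cut, sigma_ij, ff)
    u = np.where(r < r_cut, _u_raw(r, sigma_ij, ff) - shift, 0.0)
    return u if u.ndim else float(u)


def _force_over_r(dist, sigma_ij, ff: ForceField):
    """Scalar ``F(r)/r`` such that the force vector is ``(F/r) * r_vec``.

    F = -dU/dr with dU/dr = 4*eps*(S^-2 - 2*S^-3) * 6 r^5 / sigma_ij^6.
    """
    s = ff.softcore_const + (dist / sigma_ij) ** 6
    dudr_over_r = 4.0 * ff.epsilon * (s**-2 - 2.0 * s**-3) * 6.0 * dist**4 / sigma_ij**6
    return -dudr_over_r


def pair_force(r_vec, sigma_ij: float, ff: ForceField) -> np.ndarray:
    """Force on the cell at ``+r_vec/2`` exerted by the one at ``-r_vec/2``.

    Repulsive (along +r_vec) below the equilibrium separation
    ``zeta*sigma_ij``, attractive between it and the cutoff, zero beyond.
    At exactly zero separation the direction is undefined: the force is
    returned as zero (the soft core keeps the energy finite) with a warning.
    """
    if sigma_ij <= 0:
        raise ValueError("sigma_ij must be > 0")
    r_vec = np.asarray(r_vec, dtype=np.float64)
    dist = float(np.linalg.norm(r_vec))
    if dist == 0.0:
        logger.warning("pair_force: coincident centers, returning zero force")
        return np.zeros(3)
    if dist >= ff.r_cut_factor * ff.zeta * sigma_ij:
        return np.zeros(3)
    return _force_over_r(dist, sigma_ij, ff) * r_vec


def _pair_forces_brute(r: np.ndarray, sigma: np.ndarray, ff: ForceField) -> np.ndarray:
    """Exact O(N^2) pair-force sum (the oracle path)."""
    n = r.shape[0]
    if n < 2:
        return np.zeros((n, 3))
    d = r[:, None, :] - r[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    sij = sigma[:, None] + sigma[None, :]
    cut = ff.r_cut_factor * ff.zeta * sij
    np.fill_diagonal(dist, np.inf)
    active = dist < cut
    if np.any(dist[active] == 0.0):
        logger.warning("coincident cell centers: zero force assigned to those pairs")
        active &= dist > 0.0
    coeff = np.zeros((n, n))
    coeff[active] = _force_over_r(dist[active], sij[active], ff)
    return np.einsum("ij,ijk->ik", coeff, d)


def _pair_forces_linked(r: np.ndarray, sigma: np.ndarray, ff: ForceField) -> np.ndarray:
    """Cell-linked-list pair forces; bin size >= the largest pair cutoff."""
    n = r.shape[0]
    bin_size = ff.r_cut_factor * ff.zeta * 2.0 * float(sigma.max())
    bins = np.floor(r / bin_size).astype(np.int64)
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for i, key in enumerate(map(tuple, bins)):
        buckets.setdefault(key, []).append(i)
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    forces = np.zeros((n, 3))
    for key in sorted(buckets):
        members = np.array(buckets[key])
        cand: list[int] = []
        for off in offsets:
            nb = (key[0] + off[0], key[1] + off[1], key[2] + off[2])
            if nb in buckets:
                cand.extend(buckets[nb])
        cand_arr = np.array(sorted(cand))
        d = r[members][:, None, :] - r[cand_arr][None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        sij = sigma[members][:, None] + sigma[cand_arr][None, :]
        cut = ff.r_cut_factor * ff.zeta * sij
        active = (dist < cut) & (members[:, None] != cand_arr[None, :])
        if np.any(dist[active] == 0.0):
            logger.warning("coincident cell centers: zero force assigned to those pairs")
            active &= dist > 0.0
        coeff = np.zeros_like(dist)
        coeff[active] = _force_over_r(dist[active], sij[active], ff)
        forces[members] = np.einsum("ij,ijk->ik", coeff, d)
    return forces


def pair_forces(r: np.ndarray, sigma: np.ndarray, ff: ForceField,
                method: str = "auto") -> np.ndarray:
    """Per-cell sum of pair forces (no friction).

    ``method`` is ``"auto"`` (linked cells above ``BRUTE_FORCE_MAX_N``),
    ``"brute"`` or ``"linked"``.
    """
    if method == "auto":
        method = "brute" if r.shape[0] <= BRUTE_FORCE_MAX_N else "linked"
    if method == "brute":
        return _pair_forces_brute(r, sigma, ff)
    if method == "linked":
        return _pair_forces_linked(r, sigma, ff)
    raise ValueError(f"unknown neighbour-search method {method!r}")


def total_forces(pop: Population, ff: ForceField, method: str = "auto") -> np.ndarray:
    """Pair forces plus Stokes friction ``-mu * v`` for every cell."""
    return pair_forces(pop.r, pop.sigma, ff, method=method) - ff.mu_fric * pop.v


def total_pair_energy(r: np.ndarray, sigma: np.ndarray, ff: ForceField) -> float:
    """Total truncated-shifted pair potential energy (brute force)."""
    n = r.shape[0]
    e = 0.0
    for i in range(n - 1):
        d = np.linalg.norm(r[i + 1:] - r[i], axis=1)
        sij = sigma[i] + sigma[i + 1:]
        for dist, s in zip(d, sij):
            e += softcore_lj_energy(dist, float(s), ff)
    return e


def kinetic_energy(v: np.ndarray, m0: float) -> float:
    return 0.5 * m0 * float(np.einsum("ij,ij->", v, v))


def verlet_step(pop: Population, ff: ForceField, m0: float, dt: float,
                n_sub: int = 1, method: str = "auto") -> Population:
    """Advance positions and velocities by ``dt`` in ``n_sub`` Verlet substeps.

    Velocity-Verlet under ``m0 * dv/dt = F_pair - mu*v`` with the friction
    force evaluated semi-implicitly at the half-step velocity:

        v_half = (v + h*F(r)) / (1 + h*mu),     h = dt_sub / (2*m0)
        r'     = r + dt_sub * v_half
        v'     = v_half * (1 - h*mu) + h * F(r')

    Mutates ``pop`` in place and returns it.  If any substep displacement
    exceeds half the smallest cell diameter the step is aborted (state
    untouched) with a :class:`StabilityError` suggesting a larger ``n_sub``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    r = pop.r.copy()
    v = pop.v.copy()
    h_sub = dt / n_sub
    h = h_sub / (2.0 * m0)
    limit = float(pop.radius.min()) if pop.N else np.inf  # half the diameter
    f = pair_forces(r, pop.sigma, ff, method=method)
    for _ in range(n_sub):
        v_half = (v + h * f) / (1.0 + h * ff.mu_fric)
        dr = h_sub * v_half
        if pop.N and float(np.abs(dr).max()) > limit:
            raise StabilityError(
                f"substep displacement {float(np.abs(dr).max()):.3g} um exceeds "
                f"half the smallest cell diameter ({limit:.3g} um); "
                f"increase n_sub (currently {n_sub}) or reduce dt"
            )
        r = r + dr
        f = pair_forces(r, pop.sigma, ff, method=method)
        v = v_half * (1.0 - h * ff.mu_fric) + h * f
    pop.r = r
    pop.v = v
    return pop


def two_cell_settle_time(
    epsilon: float,
    mech: MechanicsParams,
    start_factor: float = 0.9,
    tol: float = 0.01,
    horizon: float = 4.0 * 3600.0,
) -> float:
    """Time for a two-cell system released at ``start_factor`` x equilibrium
    separation to settle permanently within ``tol`` of equilibrium.

    Returns ``inf`` if the pair has not settled within ``horizon`` seconds.
    Used by the epsilon calibration.
    """
    ff = ForceField(epsilon=epsilon, alpha_LJ=mech.alpha_LJ,
                    lambda_sc=mech.lambda_sc, r_cut_factor=mech.r_cut_factor,
                    mu_fric=mech.mu_fric)
    sigma0 = mech.sigma0
    d_eq = ff.zeta * 2.0 * sigma0
    pop = Population(zeta=ff.zeta)
    pop.add_cells(
        r=np.array([[-0.5 * start_factor * d_eq, 0.0, 0.0],
                    [+0.5 * start_factor * d_eq, 0.0, 0.0]]),
        v=np.zeros((2, 3)), sigma=sigma0, age=0.0, color=1,
        X=np.zeros((2, 3)), rho=0.0,
    )
    n_steps = int(math.ceil(horizon / mech.dt))
    last_outside = 0.0
    for k in range(1, n_steps + 1):
        verlet_step(pop, ff, mech.m0, mech.dt, mech.n_sub, method="brute")
        sep = float(np.linalg.norm(pop.r[1] - pop.r[0]))
        if abs(sep - d_eq) > tol * d_eq:
            last_outside = k * mech.dt
    if last_outside >= n_steps * mech.dt - mech.dt:
        return math.inf
    return last_outside


def calibrate_epsilon(
    mech: MechanicsParams | None = None,
    target_time: float | None = None,
    lo: float = 1e-8,
    hi: float = 1e-2,
    iters: int = 40,
) -> float:
    """Smallest well depth for which the two-cell settle time is <= ``target_time``.

    Settle time decreases with epsilon (stiffer bond relaxes faster in the
    overdamped regime), so the boundary is found by bisection.  The default
    target is one mitosis phase, tying the mechanical relaxation scale to the
    time daughters have to separate.
    """
    mech = mech or MechanicsParams(epsilon=1.0)
    if target_time is None:
        target_time = 3600.0
    if not two_cell_settle_time(hi, mech) <= target_time:
        raise RuntimeError("calibration bracket too small: hi does not settle in time")
    for _ in range(iters):
        mid = math.sqrt(lo * hi)
        if two_cell_settle_time(mid, mech, horizon=2.0 * target_time) <= target_time:
            hi = mid
        else:
            lo = mid
    return hi
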