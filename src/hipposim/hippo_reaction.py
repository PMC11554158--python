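"""Per-cell Hippo-YAP/TAZ reaction network and the packing-fraction input.

Each cell carries three concentrations: X1 cytoplasmic YAP/TAZ, X2 nuclear
YAP/TAZ and X3 phosphorylated YAP/TAZ (tethered in the cytoplasm).  The
network is linear in X for a fixed local packing fraction rho:

    dX1/dt = -a1*X1 + a2*X2 + a3*X3 - b1*rho*X0*X1
    dX2/dt = +a1*X1 - a2*X2
    dX3/dt = -a3*X3 + b1*rho*X0*X1

The density-dependent phosphorylation term ``b1*rho*X0`` lumps the
MST1/2 -> LATS1/2 kinase cascade of the Hippo pathway: crowding shifts
YAP/TAZ from the nucleus to the phosphorylated cytoplasmic pool.  Columns of
the rate matrix sum to zero, so total YAP/TAZ per cell is conserved.

Because rho is held fixed within one global step (it is refreshed after the
mechanics stage), the step-wise propagation is exactly ``X <- exp(A*dt) X``,
computed through an eigendecomposition of the 3x3 rate matrix with a
scaling-and-squaring fallback for ill-conditioned eigenvector bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model_core import Population, ReactionParams

#: Eigenvector-basis condition number beyond which the propagator falls back
#: to scaling-and-squaring.
_EIG_COND_LIMIT = 1e8


@dataclass(frozen=True)
class RateMatrix:
    """3x3 reaction rate matrix built for a given packing fraction."""

    A: np.ndarray  # (3, 3), 1/s
    rho: float


@dataclass(frozen=True)
class SteadyState:
    """Equilibrium concentrations at fixed density and conserved total."""

    X1: float
    X2: float
    X3: float
    rho: float
    total: float


def reaction_rhs(X, rho: float, p: ReactionParams) -> np.ndarray:
    """Time derivatives (dX1, dX2, dX3)/dt in uM/s; components sum to zero."""
    if rho < 0:
        raise ValueError("packing fraction rho cannot be negative")
    X = np.asarray(X, dtype=np.float64)
    x1, x2, x3 = X
    phos = p.b1 * rho * p.X0
    return np.array([
        -p.a1 * x1 + p.a2 * x2 + p.a3 * x3 - phos * x1,
        +p.a1 * x1 - p.a2 * x2,
        -p.a3 * x3 + phos * x1,
    ])


def rate_matrix(rho: float, p: ReactionParams) -> RateMatrix:
    """Matrix form A of the network, so that ``reaction_rhs(X) == A @ X``."""
    if rho < 0:
        raise ValueError("packing fraction rho cannot be negative")
    phos = p.b1 * rho * p.X0
    A = np.array([
        [-p.a1 - phos, p.a2, p.a3],
        [p.a1, -p.a2, 0.0],
        [phos, 0.0, -p.a3],
    ])
    return RateMatrix(A=A, rho=float(rho))


def propagator(rho: float, dt: float, p: ReactionParams) -> np.ndarray:
    """Exact one-step propagator ``exp(A(rho) * dt)``.

    Uses the eigendecomposition of A (three eigenvalues, one of which is 0
    by mass conservation); falls back to ``scipy.linalg.expm`` when the
    eigenvector basis is numerically defective.
    """
    A = rate_matrix(rho, p).A * dt
    w, V = np.linalg.eig(A)
    try:
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:  # pragma: no cover - singular basis
        cond = np.inf
    if not np.isfinite(cond) or cond > _EIG_COND_LIMIT:
        P = scipy.linalg.expm(A)
    else:
        P = (V * np.exp(w)) @ np.linalg.inv(V)
        P = P.real
    return P


def propagate(X, rho: float, dt: float, p: ReactionParams) -> np.ndarray:
    """Advance one cell's concentrations by ``dt`` at frozen density.

    The conserved total X1+X2+X3 is preserved to machine precision and the
    result is clipped at zero (the network is a Metzler system: exact
    propagation of a non-negative state is non-negative; tiny negative
    round-off is removed).
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite concentrations")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0.0:
        return X.copy()
    out = propagator(rho, dt, p) @ X
    return np.maximum(out, 0.0)


def steady_state(rho: float, total: float, p: ReactionParams) -> SteadyState:
    """Analytic equilibrium of the network at fixed density.

    Solving ``A @ X = 0`` with ``X1+X2+X3 = total`` gives
    ``X1* = total / (1 + a1/a2 + b1*rho*X0/a3)``, ``X2* = (a1/a2) X1*`` and
    ``X3* = (b1*rho*X0/a3) X1*``.  Nuclear YAP/TAZ X2* decreases
    monotonically with density — the contact-inhibition mechanism.
    """
    if total <= 0:
        raise ValueError("total concentration must be > 0")
    if rho < 0:
        raise ValueError("packing fraction rho cannot be negative")
    g = p.a1 / p.a2
    h = p.b1 * rho * p.X0 / p.a3
    x1 = total / (1.0 + g + h)
    return SteadyState(X1=x1, X2=g * x1, X3=h * x1, rho=float(rho), total=float(total))


def critical_density(total: float, p: ReactionParams) -> float:
    """Density at which steady-state nuclear YAP/TAZ equals the arrest threshold.

    Inverts the closed form above at ``X2* = X_th``; X2* is strictly
    decreasing in rho, so the crossing is unique.  Tissue held denser than
    this value eventually arrests; a twofold-YAP/TAZ tissue roughly doubles
    its critical density.
    """
    g = p.a1 / p.a2
    if total <= p.X_th * (1.0 + 1.0 / g):
        raise ValueError(
            "total YAP/TAZ too low: steady-state X2 never exceeds X_th even at rho=0"
        )
    h = total * g / p.X_th - 1.0 - g
    return h * p.a3 / (p.b1 * p.X0)


def packing_fraction(
    pop: Population,
    i: int,
    delta_rho: float = 0.25,
    r_cut_factor: float = 2.5,
) -> float:
    """Local packing fraction of cell ``i``.

    Size-normalised exponential kernel over neighbours,

        rho_i = (1/12) * sum_{j != i} exp(-(s_ij - 1) / delta_rho),
        s_ij  = |r_i - r_j| / (radius_i + radius_j),

    truncated at the mechanical pair cutoff (``s < r_cut_factor``).  The
    1/12 normalisation calibrates rho = 1 for twelve neighbours exactly at
    contact (the close-packing coordination number); overlapping neighbours
    contribute more, distant ones exponentially less.  Coincident centers
    (s = 0) contribute the finite value exp(1/delta_rho)/12.
    """
    if pop.N < 1:
        raise ValueError("population is empty")
    return float(packing_fractions(pop, delta_rho=delta_rho, r_cut_factor=r_cut_factor)[i])


def packing_fractions(
    pop: Population,
    delta_rho: float = 0.25,
    r_cut_factor: float = 2.5,
) -> np.ndarray:
    """Vectorised packing fraction for every cell (see :func:`packing_fraction`)."""
    n = pop.N
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.zeros(1)
    d = pop.r[:, None, :] - pop.r[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    radius = pop.radius
    rsum = radius[:, None] + radius[None, :]
    s = dist / rsum
    kern = np.exp(-(s - 1.0) / delta_rho)
    np.fill_diagonal(kern, 0.0)
    kern[s >= r_cut_factor] = 0.0
    return kern.sum(axis=1) / 12.0


class PropagatorCache:
    """Per-step reaction propagation with density-quantised propagator reuse.

    The rate matrix depends only on rho, so ``exp(A(rho)*dt)`` is cached on
    a rho grid (default spacing 1e-3) and reused across cells and steps;
    propagation of N cells then costs one small gather plus a batched 3x3
    matrix-vector product instead of N eigendecompositions.
    """

    def __init__(self, p: ReactionParams, dt: float, quantum: float = 1e-3,
                 quantise: bool = True) -> None:
        self.p = p
        self.dt = float(dt)
        self.quantum = float(quantum)
        self.quantise = quantise
        self._index: dict[int, int] = {}
        self._mats = np.empty((0, 3, 3))

    def _key_rho(self, key: int) -> float:
        return key * self.quantum

    def propagate_population(self, X: np.ndarray, rho: np.ndarray) -> np.ndarray:
        """Advance an (N, 3) concentration block one step at frozen densities."""
        if not self.quantise:
            out = np.empty_like(X)
            for i in range(X.shape[0]):
                out[i] = propagator(float(rho[i]), self.dt, self.p) @ X[i]
            return np.maximum(out, 0.0)
        keys = np.rint(rho / self.quantum).astype(np.int64)
        missing = [k for k in dict.fromkeys(keys.tolist()) if k not in self._index]
        if missing:
            new = np.stack([propagator(self._key_rho(k), self.dt, self.p) for k in missing])
            base = self._mats.shape[0]
            self._mats = np.concatenate([self._mats, new])
            for off, k in enumerate(missing):
                self._index[k] = base + off
        idx = np.fromiter((self._index[k] for k in keys.tolist()), dtype=np.int64,
                          count=keys.shape[0])
        out = np.einsum("nij,nj->ni", self._mats[idx], X)
        return np.maximum(out, 0.0)
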