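"""Core domain types, presets, configuration and seeded randomness.

The simulator advances two coupled layers: (i) center-based mechanics of
spherical cells interacting through a soft-core Lennard-Jones (12-6)
potential with linear friction, and (ii) a per-cell three-species
Hippo-YAP/TAZ reaction network whose input is the local packing fraction.
This module holds the parameter containers, the ``normal``/``cancer``
presets, the cell and population state containers, and the seeded random
stream that every other module shares.

Internal unit system (fixed): micrometres, seconds, nanograms, micromolar.
Configuration files may give cell-cycle durations in hours (``T_CC_h``,
``T_M_h``); they are converted exactly once at load time.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

#: Geometric division factor: two daughters born at size ``sigma0`` exactly
#: fill the volume of a mother of size ``2^(1/3) * sigma0``.
GAMMA: float = 2.0 ** (1.0 / 3.0) - 1.0

#: A cell divides when its size parameter reaches ``DIV_SIZE_FACTOR * sigma0``.
DIV_SIZE_FACTOR: float = 2.0 ** (1.0 / 3.0)

#: Relative slack used in the division-size comparison so that a cell grown by
#: ``T_CC/dt`` identical float increments reliably reaches the doubling size.
DIV_SIZE_RTOL: float = 1e-9

# Phase/arrest colour code: 0 cyan (arrest, M), 1 orange (growing, M),
# 2 blue (arrest, G1), 3 red (growing, G1).
COLOR_CYAN, COLOR_ORANGE, COLOR_BLUE, COLOR_RED = 0, 1, 2, 3
COLOR_NAMES: tuple[str, str, str, str] = ("cyan", "orange", "blue", "red")

#: Initial (X1, X2, X3) concentrations in uM for the two tissue presets.
#: The cancer tissue carries twofold YAP/TAZ relative to normal tissue.
PRESET_CONCENTRATIONS: dict[str, tuple[float, float, float]] = {
    "normal": (0.05, 0.2, 0.0),
    "cancer": (0.1, 0.4, 0.0),
}


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass
class ReactionParams:
    """Rate constants of the Hippo-YAP/TAZ reaction network.

    Species: X1 cytoplasmic YAP/TAZ, X2 nuclear YAP/TAZ, X3 phosphorylated
    (cytoplasm-tethered) YAP/TAZ.

    Parameters
    ----------
    a1 : float
        Nuclear import rate X1 -> X2 (1/s).
    a2 : float
        Nuclear export rate X2 -> X1 (1/s).
    a3 : float
        Dephosphorylation rate X3 -> X1 (1/s).
    b1 : float
        Phosphorylation rate constant X1 -> X3 (1/(uM*s)); the effective
        rate is ``b1 * rho * X0``, the density-controlled Hippo input.
    X0 : float
        Input signal concentration transmitted at packing fraction 1 (uM).
    X_th : float
        Nuclear YAP/TAZ threshold below which a cell arrests (uM).
    """

    a1: float = 5e-2
    a2: float = 5e-4
    a3: float = 1e-4
    b1: float = 1.0
    X0: float = 0.15
    X_th: float = 0.012

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "b1"):
            if getattr(self, name) < 0:
                raise ConfigError(f"rate {name} must be >= 0")
        if self.X0 <= 0:
            raise ConfigError("X0 must be > 0")
        if self.X_th <= 0:
            raise ConfigError("X_th must be > 0")


# Soft-core coupling chosen so that zeta = (2 - alpha_LJ*(1-lambda)^2)^(1/6)
# equals 5/4.53, the ratio of the birth radius (5 um) to the birth size
# parameter (4.53 um).
LAMBDA_DEFAULT: float = 0.38054029643567144

#: Calibrated adhesion strength (ng*um^2/s^2): smallest well depth for which
#: a two-cell system released at 0.9x the equilibrium separation settles to
#: within 1% of equilibrium in at most one mitosis phase (T_M = 1 h) under the
#: default friction.  Regenerate with ``hipposim calibrate-epsilon``.
EPSILON_DEFAULT: float = 1.266175794865112e-05


@dataclass
class MechanicsParams:
    """Mechanical constants of the center-based cell model.

    ``sigma0`` (birth size parameter) and ``zeta`` (radius-to-sigma ratio)
    are derived: ``zeta = (2 - alpha_LJ*(1-lambda_sc)^2)^(1/6)`` locates the
    soft-core potential minimum at the sum of the two cell radii, and
    ``sigma0 = sigma0_prime / zeta`` so a cell's physical radius at birth is
    ``sigma0_prime``.
    """

    sigma0_prime: float = 5.0  #: birth cell radius (um)
    m0: float = 2.0  #: cell mass (ng), constant over the cycle
    epsilon: float = EPSILON_DEFAULT  #: LJ well depth (ng*um^2/s^2)
    alpha_LJ: float = 0.5  #: soft-core parameter (dimensionless)
    lambda_sc: float = LAMBDA_DEFAULT  #: soft-core coupling in [0, 1]
    mu_fric: float = 1.0 / 30.0  #: friction coefficient (ng/s), m0/mu = 60 s
    r_cut_factor: float = 2.5  #: pair cutoff in units of the pair minimum
    dt: float = 3.75  #: global time step (s)
    n_sub: int = 1  #: mechanical substeps per global step

    def __post_init__(self) -> None:
        if self.sigma0_prime <= 0 or self.m0 <= 0:
            raise ConfigError("sigma0_prime and m0 must be > 0")
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if not 0.0 <= self.lambda_sc <= 1.0:
            raise ConfigError("lambda_sc must lie in [0, 1]")
        if self.mu_fric < 0:
            raise ConfigError("mu_fric must be >= 0")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.n_sub < 1:
            raise ConfigError("n_sub must be >= 1")
        if self.softcore_const >= 2.0:
            raise ConfigError("alpha_LJ*(1-lambda_sc)^2 must be < 2")
        if self.zeta < 1.0:
            raise ConfigError("derived zeta must be >= 1 (radius >= sigma)")

    @property
    def softcore_const(self) -> float:
        """Soft-core offset ``alpha_LJ * (1 - lambda_sc)^2`` added to (r/sigma)^6."""
        return self.alpha_LJ * (1.0 - self.lambda_sc) ** 2

    @property
    def zeta(self) -> float:
        """Ratio of cell radius to size parameter sigma."""
        return (2.0 - self.softcore_const) ** (1.0 / 6.0)

    @property
    def sigma0(self) -> float:
        """Birth size parameter (um); ``sigma0 * zeta == sigma0_prime``."""
        return self.sigma0_prime / self.zeta

    @property
    def gamma(self) -> float:
        return GAMMA


@dataclass
class CycleParams:
    """Cell-cycle durations (stored in seconds).

    The cycle is collapsed into a mitosis phase M (age < ``T_M``, daughters
    separating) and a growth phase G1 (age >= ``T_M``); the full cycle
    ``T_CC`` spans both.
    """

    T_CC: float = 20.0 * 3600.0
    T_M: float = 1.0 * 3600.0

    def __post_init__(self) -> None:
        if not 0 < self.T_M < self.T_CC:
            raise ConfigError("require 0 < T_M < T_CC")


def growth_increment(mech: MechanicsParams, cycle: CycleParams) -> float:
    """Per-step size increment ``d_sigma = gamma * dt * sigma0 / T_CC`` (um).

    A permanently growing cell therefore traverses ``sigma0 ->
    2^(1/3)*sigma0`` in exactly ``T_CC / dt`` steps.
    """
    return GAMMA * mech.dt * mech.sigma0 / cycle.T_CC


@dataclass(frozen=True)
class CellState:
    """Read-only snapshot of one agent."""

    id: int
    r: np.ndarray  # center position (um), shape (3,)
    v: np.ndarray  # velocity (um/s), shape (3,)
    sigma: float  # size parameter (um), in [sigma0, 2^(1/3) sigma0]
    radius: float  # physical radius (um) = zeta * sigma
    age: float  # time since last division (s); frozen while arrested
    color: int  # phase/arrest code, see COLOR_NAMES
    X1: float  # cytoplasmic YAP/TAZ (uM)
    X2: float  # nuclear YAP/TAZ (uM)
    X3: float  # phospho-YAP/TAZ (uM)
    rho: float  # local packing fraction (dimensionless)


class Population:
    """Ordered collection of cells with global time and step counter.

    State is stored as parallel NumPy arrays (structure-of-arrays) for
    vectorised mechanics and reactions; :meth:`cell` exposes a per-cell
    :class:`CellState` view.  Cells are never removed: ``N`` is
    non-decreasing over a run and ids are unique and increasing.
    """

    __slots__ = ("zeta", "ids", "r", "v", "sigma", "age", "color", "X",
                 "rho", "t", "k", "_next_id")

    def __init__(self, zeta: float) -> None:
        self.zeta = float(zeta)
        self.ids = np.empty(0, dtype=np.int64)
        self.r = np.empty((0, 3), dtype=np.float64)
        self.v = np.empty((0, 3), dtype=np.float64)
        self.sigma = np.empty(0, dtype=np.float64)
        self.age = np.empty(0, dtype=np.float64)
        self.color = np.empty(0, dtype=np.int64)
        self.X = np.empty((0, 3), dtype=np.float64)
        self.rho = np.empty(0, dtype=np.float64)
        self.t = 0.0
        self.k = 0
        self._next_id = 0

    def __len__(self) -> int:
        return self.ids.shape[0]

    @property
    def N(self) -> int:
        return self.ids.shape[0]

    @property
    def radius(self) -> np.ndarray:
        """Physical radii ``zeta * sigma`` (um)."""
        return self.zeta * self.sigma

    def add_cells(self, r, v, sigma, age, color, X, rho) -> np.ndarray:
        """Append cells (arrays broadcast over the leading axis); returns new ids."""
        r = np.atleast_2d(np.asarray(r, dtype=np.float64))
        n = r.shape[0]
        new_ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.ids = np.concatenate([self.ids, new_ids])
        self.r = np.concatenate([self.r, r])
        self.v = np.concatenate([self.v, np.atleast_2d(np.asarray(v, dtype=np.float64))])
        self.sigma = np.concatenate([self.sigma, np.broadcast_to(np.asarray(sigma, dtype=np.float64), (n,))])
        self.age = np.concatenate([self.age, np.broadcast_to(np.asarray(age, dtype=np.float64), (n,))])
        self.color = np.concatenate([self.color, np.broadcast_to(np.asarray(color, dtype=np.int64), (n,))])
        self.X = np.concatenate([self.X, np.atleast_2d(np.asarray(X, dtype=np.float64))])
        self.rho = np.concatenate([self.rho, np.broadcast_to(np.asarray(rho, dtype=np.float64), (n,))])
        return new_ids

    def cell(self, i: int) -> CellState:
        return CellState(
            id=int(self.ids[i]),
            r=self.r[i].copy(),
            v=self.v[i].copy(),
            sigma=float(self.sigma[i]),
            radius=float(self.zeta * self.sigma[i]),
            age=float(self.age[i]),
            color=int(self.color[i]),
            X1=float(self.X[i, 0]),
            X2=float(self.X[i, 1]),
            X3=float(self.X[i, 2]),
            rho=float(self.rho[i]),
        )

    def cells(self) -> list[CellState]:
        return [self.cell(i) for i in range(self.N)]

    def copy(self) -> "Population":
        new = Population(self.zeta)
        for name in ("ids", "r", "v", "sigma", "age", "color", "X", "rho"):
            setattr(new, name, getattr(self, name).copy())
        new.t, new.k, new._next_id = self.t, self.k, self._next_id
        return new


@dataclass
class SimConfig:
    """Full simulation configuration.

    ``preset`` is ``"normal"``, ``"cancer"`` or ``"custom"``; for the named
    presets the initial concentrations are pinned to the tissue values
    (cancer = twofold normal YAP/TAZ).
    """

    reaction: ReactionParams = field(default_factory=ReactionParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    preset: str = "custom"
    initial_concentrations: tuple[float, float, float] = (0.05, 0.2, 0.0)
    L: int = 200_000  #: number of global steps
    seed: int = 0
    snapshot_every: int = 160  #: record cadence in steps (160 = 10 min)
    delta_rho: float = 0.25  #: packing-fraction kernel decay width
    rho_quantum: float = 1e-3  #: density quantisation for propagator caching
    cache_propagators: bool = True
    sphere_uniform: bool = False  #: area-uniform division directions if True
    max_cells: Optional[int] = None  #: optional safety cap; run aborts beyond

    def __post_init__(self) -> None:
        self.initial_concentrations = tuple(float(x) for x in self.initial_concentrations)
        if self.preset not in ("normal", "cancer", "custom"):
            raise ConfigError(
                f"unknown preset {self.preset!r}; expected 'normal', 'cancer' or 'custom'"
            )
        if self.preset in PRESET_CONCENTRATIONS:
            expected = PRESET_CONCENTRATIONS[self.preset]
            if self.initial_concentrations != expected:
                raise ConfigError(
                    f"preset {self.preset!r} pins initial concentrations to {expected}"
                )
        if any(x < 0 for x in self.initial_concentrations):
            raise ConfigError("initial concentrations must be >= 0")
        if self.L < 0:
            raise ConfigError("L must be >= 0")
        if self.snapshot_every < 1:
            raise ConfigError("snapshot_every must be >= 1")
        if self.delta_rho <= 0:
            raise ConfigError("delta_rho must be > 0")
        if self.rho_quantum <= 0:
            raise ConfigError("rho_quantum must be > 0")

    @property
    def d_sigma(self) -> float:
        """Per-step growth increment (um)."""
        return growth_increment(self.mechanics, self.cycle)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "preset": self.preset,
            "initial_concentrations": list(self.initial_concentrations),
            "reaction": dataclasses.asdict(self.reaction),
            "mechanics": dataclasses.asdict(self.mechanics),
            "cycle": {"T_CC_h": self.cycle.T_CC / 3600.0, "T_M_h": self.cycle.T_M / 3600.0},
            "simulation": {
                "L": self.L,
                "seed": self.seed,
                "snapshot_every": self.snapshot_every,
                "delta_rho": self.delta_rho,
                "rho_quantum": self.rho_quantum,
                "cache_propagators": self.cache_propagators,
                "sphere_uniform": self.sphere_uniform,
                "max_cells": self.max_cells,
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        cyc = d.get("cycle", {})
        if "T_CC_h" in cyc or "T_M_h" in cyc:
            cycle = CycleParams(
                T_CC=float(cyc.get("T_CC_h", 20.0)) * 3600.0,
                T_M=float(cyc.get("T_M_h", 1.0)) * 3600.0,
            )
        else:
            cycle = CycleParams(**cyc)
        sim = dict(d.get("simulation", {}))
        return cls(
            reaction=ReactionParams(**d.get("reaction", {})),
            mechanics=MechanicsParams(**d.get("mechanics", {})),
            cycle=cycle,
            preset=d.get("preset", "custom"),
            initial_concentrations=tuple(d.get("initial_concentrations", (0.05, 0.2, 0.0))),
            **sim,
        )


def save_config(config: SimConfig, path) -> None:
    """Write a configuration to a YAML file (round-trip exact)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path) -> SimConfig:
    """Read a configuration from a YAML file."""
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return SimConfig.from_dict(d)


def default_config(preset: str) -> SimConfig:
    """Load the shipped ``normal`` or ``cancer`` preset.

    The preset files pin the reaction-network rates, the twofold-YAP/TAZ
    initial concentrations, the 20 h / 1 h cell-cycle structure and the
    dt = 3.75 s, L = 200000 step schedule.
    """
    if preset not in PRESET_CONCENTRATIONS:
        raise ConfigError(
            f"unknown preset {preset!r}; expected one of {sorted(PRESET_CONCENTRATIONS)}"
        )
    ref = resources.files("hipposim").joinpath(f"presets/{preset}.yaml")
    return SimConfig.from_dict(yaml.safe_load(ref.read_text()))


def make_rng(seed: int) -> np.random.Generator:
    """Reproducible random stream; identical seeds give bit-identical runs."""
    return np.random.default_rng(seed)


def draw_direction(rng: np.random.Generator, sphere_uniform: bool = False) -> np.ndarray:
    """Random unit vector for division placement.

    The default draws the azimuth theta uniform on [0, 2*pi) and the polar
    angle phi uniform on [0, pi) — the model's stated sampling, which is not
    area-uniform on the sphere.  ``sphere_uniform=True`` switches to
    cos(phi) uniform for sensitivity checks.
    """
    theta = rng.uniform(0.0, 2.0 * np.pi)
    if sphere_uniform:
        cos_phi = rng.uniform(-1.0, 1.0)
        sin_phi = math.sqrt(max(0.0, 1.0 - cos_phi * cos_phi))
    else:
        phi = rng.uniform(0.0, np.pi)
        cos_phi, sin_phi = math.cos(phi), math.sin(phi)
    return np.array(
        [sin_phi * math.cos(theta), sin_phi * math.sin(theta), cos_phi]
    )
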