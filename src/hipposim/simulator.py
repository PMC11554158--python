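"""End-to-end simulation loop: two-cell initialisation and the five-stage step.

Every global step of length dt applies, in order:

1. time update ``t = k*dt``;
2. growth/arrest discrimination and growth (age and size advance only while
   nuclear YAP/TAZ exceeds the threshold);
3. division of every cell that has reached the doubling size (processed in
   ascending id order; daughters are appended and not re-checked until the
   next step);
4. mechanics — one velocity-Verlet step of the soft-core Lennard-Jones /
   friction dynamics;
5. reactions — the packing fraction of every cell is refreshed from the new
   positions, then each cell's concentrations are advanced by the exact
   linear propagator at its (frozen) density.

A run starts from two daughter cells placed symmetrically about the origin,
exactly as if a single mother had just divided.  Identical (config, seed)
pairs produce bit-identical trajectories.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import analysis_io, cell_cycle, mechanics
from .hippo_reaction import PropagatorCache, packing_fractions
from .model_core import (
    COLOR_ORANGE,
    GAMMA,
    Population,
    SimConfig,
    draw_direction,
    make_rng,
)

logger = logging.getLogger(__name__)

#: Hard ceiling on automatic substep refinement after a stability abort.
MAX_N_SUB = 1024


@dataclass
class RunResult:
    """Outcome of :func:`run`: summaries, final state, config echo and seed."""

    timeseries: list[analysis_io.TrajectoryRecord]
    final: Population
    config_echo: SimConfig
    seed: int


def initialize(config: SimConfig, rng: np.random.Generator) -> Population:
    """Two birth-size cells straddling the origin along a random direction.

    Positions ``-/+ gamma*sigma0'*e_r`` and separation velocities
    ``-/+ (1-gamma)*sigma0'*e_r/T_M`` reproduce the state immediately after
    a division; concentrations follow the preset.
    """
    mech = config.mechanics
    e_r = draw_direction(rng, sphere_uniform=config.sphere_uniform)
    offset = GAMMA * mech.sigma0_prime * e_r
    v_sep = (1.0 - GAMMA) * mech.sigma0_prime * e_r / config.cycle.T_M
    pop = Population(zeta=mech.zeta)
    pop.add_cells(
        r=np.stack([-offset, offset]),
        v=np.stack([-v_sep, v_sep]),
        sigma=mech.sigma0,
        age=0.0,
        color=COLOR_ORANGE,
        X=np.tile(np.asarray(config.initial_concentrations), (2, 1)),
        rho=0.0,
    )
    pop.rho = packing_fractions(pop, delta_rho=config.delta_rho,
                                r_cut_factor=mech.r_cut_factor)
    return pop


def step(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    cache: PropagatorCache | None = None,
) -> Population:
    """Advance the population by one global step (mutates and returns ``pop``)."""
    mech, cyc, rp = config.mechanics, config.cycle, config.reaction
    if cache is None:
        cache = PropagatorCache(rp, mech.dt, quantum=config.rho_quantum,
                                quantise=config.cache_propagators)

    # (2) growth or cell-cycle arrest
    cell_cycle.grow_population(pop, mech, cyc, rp)

    # (3) division, ascending id order over cells present at stage entry
    n_before = pop.N
    order = np.argsort(pop.ids[:n_before])
    for i in order:
        cell_cycle.divide_if_ready(pop, int(i), rng, mech, cyc,
                                   sphere_uniform=config.sphere_uniform)

    # (4) multicellular kinetics, refining substeps on a stability abort
    ff = mechanics.ForceField.from_mechanics(mech)
    n_sub = mech.n_sub
    while True:
        try:
            mechanics.verlet_step(pop, ff, mech.m0, mech.dt, n_sub)
            break
        except mechanics.StabilityError:
            if n_sub >= MAX_N_SUB:
                raise mechanics.StabilityError(
                    f"step {pop.k + 1}: unstable even at n_sub={n_sub}"
                ) from None
            n_sub *= 2
            logger.warning("step %d: stability abort, retrying with n_sub=%d",
                           pop.k + 1, n_sub)

    # (5) density refresh, then exact linear reaction propagation
    pop.rho = packing_fractions(pop, delta_rho=config.delta_rho,
                                r_cut_factor=mech.r_cut_factor)
    pop.X = cache.propagate_population(pop.X, pop.rho)

    pop.k += 1
    pop.t = pop.k * mech.dt
    return pop


def run(
    config: SimConfig,
    out_dir=None,
    log_every: int = 0,
) -> RunResult:
    """Execute ``config.L`` steps from the two-cell state.

    A :class:`~hipposim.analysis_io.TrajectoryRecord` is emitted at step 0,
    every ``config.snapshot_every`` steps, and at the final step.  When
    ``out_dir`` is given, the time series, the final snapshot and an
    extended-XYZ view are written there.  ``log_every`` > 0 logs progress
    (step, time, N, wall time) at that step cadence.
    """
    rng = make_rng(config.seed)
    pop = initialize(config, rng)
    cache = PropagatorCache(config.reaction, config.mechanics.dt,
                            quantum=config.rho_quantum,
                            quantise=config.cache_propagators)
    records = [analysis_io.make_record(pop)]
    t0 = time.perf_counter()
    for k in range(1, config.L + 1):
        step(pop, config, rng, cache)
        if config.max_cells is not None and pop.N > config.max_cells:
            raise RuntimeError(
                f"population exceeded max_cells={config.max_cells} at step {k}"
            )
        if k % config.snapshot_every == 0 or k == config.L:
            records.append(analysis_io.make_record(pop))
        if log_every and k % log_every == 0:
            logger.info("step %d/%d  t=%.1f h  N=%d  wall=%.1f s",
                        k, config.L, pop.t / 3600.0, pop.N,
                        time.perf_counter() - t0)
    result = RunResult(timeseries=records, final=pop, config_echo=config,
                       seed=config.seed)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        analysis_io.write_timeseries(result.timeseries, out_dir / "timeseries.csv")
        written.append("timeseries.csv")
        analysis_io.write_snapshot(result.final, out_dir / "final_snapshot.csv")
        written.append("final_snapshot.csv")
        analysis_io.write_extxyz(result.final, out_dir / "final_snapshot.xyz")
        written.append("final_snapshot.xyz")
        from .model_core import save_config

        save_config(result.config_echo, out_dir / "config.yaml")
        written.append("config.yaml")
    except OSError as exc:
        raise OSError(
            f"failed writing outputs to {out_dir} (completed: {written})"
        ) from exc
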