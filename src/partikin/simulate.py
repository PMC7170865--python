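"""Simulation loop: alternate diffusion substeps and reaction steps.

One reaction step consists of ``dt_rxn / dt_diff`` Brownian substeps
followed by one pass of the reaction kernels on the end-of-step
positions.  Species counts are sampled on the ``record_interval`` grid;
the grid is shared with the ODE twin so the two outputs align.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .brownian import diffuse
from .metrics import MSDEstimate, estimate_D_msd
from .model_io import (
    Geometry,
    Localisation,
    ModelSpec,
    ParticleState,
    SimConfig,
    initial_state,
)
from .reactions import ReactionEvent, apply_reaction_step
from .timeseries import CountsTimeSeries


@dataclass
class SimulationResult:
    timeseries: CountsTimeSeries
    state: ParticleState
    events: list[ReactionEvent] = field(default_factory=list)


def record_grid(config: SimConfig) -> np.ndarray:
    n_steps = int(round(config.duration / config.dt_rxn))
    every = max(1, int(round(config.record_interval / config.dt_rxn)))
    idx = np.arange(0, n_steps + 1, every)
    return idx * config.dt_rxn


def run_abm(
    model: ModelSpec,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
    counts: dict[str, int] | None = None,
    collect_events: bool = False,
    snapshot_writer=None,
) -> SimulationResult:
    """Run one particle-based replicate.

    All randomness (initial placement, Brownian steps, reaction draws)
    comes from a single generator, so a fixed seed reproduces the run
    bit for bit.  ``snapshot_writer(state, time)``, when given, is
    called at every recorded time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = initial_state(model, rng, counts=counts)
    n_steps = int(round(config.duration / config.dt_rxn))
    every = max(1, int(round(config.record_interval / config.dt_rxn)))
    times = record_grid(config)
    values = np.zeros((times.size, model.n_species), np.int64)
    values[0] = state.counts(model.n_species)
    if snapshot_writer is not None:
        snapshot_writer(state, 0.0)
    events: list[ReactionEvent] = []
    rec = 1
    has_reactions = bool(model.reactions)
    for step in range(1, n_steps + 1):
        diffuse(state, model, config.dt_diff, config.n_substeps, rng)
        if has_reactions:
            evs = apply_reaction_step(state, model, rng)
            if collect_events:
                events.extend(evs)
        if step % every == 0:
            values[rec] = state.counts(model.n_species)
            if snapshot_writer is not None:
                snapshot_writer(state, times[rec])
            rec += 1
    ts = CountsTimeSeries(times, values[:rec], list(model.names),
                          model.geometry.volume, "counts")
    return SimulationResult(ts, state, events)


def run_single_particle_diffusion(
    D_values,
    duration: float = 300.0,
    dt: float = 1e-4,
    seed: int | None = None,
    box: float = 3e-6,
) -> list[MSDEstimate]:
    """Diffuse one agent per D value and recover each D from its MSD.

    Uses the full engine (reflective 3 um box by default) but estimates
    D from the accumulated pre-reflection squared step displacements,
    which are confinement-free.
    """
    from .fixtures import make_single_particle_scenario

    model, _ = make_single_particle_scenario(list(D_values), box=box)
    rng = np.random.default_rng(seed)
    state = initial_state(model, rng, counts={s.name: 1 for s in model.species})
    n_steps = int(round(duration / dt))
    diffuse(state, model, dt, n_steps, rng)
    out = []
    for i, sp in enumerate(model.species):
        j = int(np.flatnonzero(state.species == i)[0])
        dim = 2 if sp.localisation == Localisation.MEMBRANE else 3
        out.append(estimate_D_msd(state.sq_disp[j], state.time, dim))
    return out


def write_xyz(path, state: ParticleState, model: ModelSpec, time: float,
              append: bool = True) -> None:
    """Append one XYZ-format frame (positions in um) for visualisers."""
    idx = np.flatnonzero(state.alive)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{idx.size}\n")
        fh.write(f"time_s={time}\n")
        for i in idx:
            x, y, z = state.positions[i] * 1e6
            fh.write(f"{model.names[state.species[i]]} {x:.6f} {y:.6f} {z:.6f}\n")
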