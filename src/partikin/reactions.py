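"""Reaction execution: probability and proximity kernels.

First-order reactions fire per agent per reaction step with probability
P = 1 - exp(-k dt).  Second-order reactions fire when the two reactants
end a reaction step closer than an interaction distance d_i, chosen so
that the volume (or membrane area) swept per step reproduces the
mass-action rate constant:

* soluble-soluble: V_i is a sphere, d_i = (3 k_f dt / (4 pi 1e3 N_A))^(1/3)
* membrane-soluble: V_i is a hemisphere above the membrane,
  d_i = (3 k_f dt / (2 pi 1e3 N_A))^(1/3)
* membrane-membrane: A_i is a disc; with k_f in M^-1 s^-1 the constant is
  first scaled by the surface-to-volume ratio, k_f' = k_f A_C / V_C,
  giving d_i = (k_f A_C dt / (pi 1e3 V_C N_A))^(1/2).  A density mode
  (k_f declared in m^2 s^-1) is also implemented as
  d_i = (k_f dt / (pi 1e3 N_A))^(1/2); note the 1e3 N_A factor makes its
  dimensions questionable, so molar mode is the supported default.

When several substrates (or several reactions) compete for an agent the
closest pair wins: candidate pairs across all second-order reactions are
accepted greedily in ascending distance, each agent reacting at most
once per step.  Dissociation products are separated by an unbinding
distance d_u = 4 d_i to suppress immediate re-association (geminate
recombination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import N_A
from .model_io import (
    Geometry,
    GeometryClass,
    Localisation,
    ModelError,
    ModelSpec,
    ParticleState,
    ReactionDef,
    RType,
)


@dataclass
class DerivedReactionParams:
    """Per-reaction kernel parameters for a given reaction time step."""

    P: float = 0.0  # forward first-order probability per step
    P_reverse: float = 0.0  # reverse probability (reversible only)
    d_i: float = 0.0  # interaction distance, m
    d_u: float = 0.0  # unbinding distance, m
    V_i: float = 0.0  # interaction volume, m^3 (sol_sol, mem_sol)
    A_i: float = 0.0  # interaction area, m^2 (mem_mem)
    k_f_prime: float = 0.0  # area-scaled constant (mem_mem molar mode)


@dataclass
class ReactionEvent:
    reaction_index: int
    consumed: tuple[int, ...]  # agent slot ids
    produced: tuple[str, ...]  # species names
    positions: tuple = ()
    time: float = 0.0


def first_order_probability(k: float, dt: float) -> float:
    """P = 1 - exp(-k dt), the chance one molecule reacts within a step."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return -math.expm1(-k * dt)


def interaction_distance(
    reaction: ReactionDef, geometry: Geometry, dt: float
) -> float:
    """End-of-step separation below which a second-order pair reacts."""
    if not reaction.is_second_order:
        raise ModelError("interaction distance applies to second-order reactions")
    k_f = reaction.k_f
    if k_f == 0:
        return 0.0
    gc = reaction.geometry_class
    if gc == GeometryClass.SOL_SOL:
        return (3.0 * k_f * dt / (4.0 * math.pi * 1e3 * N_A)) ** (1.0 / 3.0)
    if gc == GeometryClass.MEM_SOL:
        return (3.0 * k_f * dt / (2.0 * math.pi * 1e3 * N_A)) ** (1.0 / 3.0)
    if gc == GeometryClass.MEM_MEM:
        if reaction.density_mode:
            return math.sqrt(k_f * dt / (math.pi * 1e3 * N_A))
        if geometry is None:
            raise ModelError(
                "membrane-membrane reaction with molar k_f requires the box "
                "geometry (A_C and V_C)"
            )
        return math.sqrt(
            k_f * geometry.area * dt / (math.pi * 1e3 * geometry.volume * N_A)
        )
    raise ModelError(f"no geometry class for reaction {reaction.expression()}")


def unbinding_distance(d_i: float) -> float:
    """d_u = 4 d_i, the post-dissociation separation."""
    if d_i < 0:
        raise ValueError("d_i must be >= 0")
    return 4.0 * d_i


def derive_reaction_params(
    reaction: ReactionDef, geometry: Geometry, dt: float
) -> DerivedReactionParams:
    d = DerivedReactionParams()
    if reaction.rtype == RType.FIRST_ORDER:
        d.P = first_order_probability(reaction.k_f, dt)
        return d
    d.d_i = interaction_distance(reaction, geometry, dt)
    d.d_u = unbinding_distance(d.d_i)
    gc = reaction.geometry_class
    if gc == GeometryClass.SOL_SOL:
        d.V_i = 4.0 / 3.0 * math.pi * d.d_i**3
    elif gc == GeometryClass.MEM_SOL:
        d.V_i = 2.0 / 3.0 * math.pi * d.d_i**3
    elif gc == GeometryClass.MEM_MEM:
        d.A_i = math.pi * d.d_i**2
        if not reaction.density_mode:
            d.k_f_prime = reaction.k_f * geometry.area / geometry.volume
    if reaction.rtype == RType.REVERSIBLE:
        d.P_reverse = first_order_probability(reaction.k_r, dt)
    return d


# ---------------------------------------------------------------------------
# pair matching

def _candidates(state: ParticleState, model: ModelSpec):
    """Candidate (reaction, agentA, agentB, distance) arrays, unfiltered."""
    pos3 = state.positions
    out = []
    for ri, (r, d) in enumerate(zip(model.reactions, model.derived)):
        if not r.is_second_order or d.d_i <= 0.0:
            continue
        in_plane = r.geometry_class == GeometryClass.MEM_MEM
        pos = pos3[:, :2] if in_plane else pos3
        sa = model.index[r.reactants[0]]
        sb = model.index[r.reactants[1]]
        ia = np.flatnonzero(state.alive & (state.species == sa))
        if sa == sb:
            if ia.size < 2:
                continue
            tree = cKDTree(pos[ia])
            prs = tree.query_pairs(d.d_i, output_type="ndarray")
            if prs.size == 0:
                continue
            gi, gj = ia[prs[:, 0]], ia[prs[:, 1]]
        else:
            ib = np.flatnonzero(state.alive & (state.species == sb))
            if ia.size == 0 or ib.size == 0:
                continue
            if ia.size >= ib.size:
                big, small, small_is_a = ia, ib, False
            else:
                big, small, small_is_a = ib, ia, True
            tree = cKDTree(pos[big])
            hits = tree.query_ball_point(pos[small], d.d_i)
            qi, hi = [], []
            for q, lst in enumerate(hits):
                for h in lst:
                    qi.append(q)
                    hi.append(h)
            if not qi:
                continue
            gs, gb = small[np.asarray(qi)], big[np.asarray(hi)]
            gi, gj = (gs, gb) if small_is_a else (gb, gs)
        dist = np.sqrt(((pos[gi] - pos[gj]) ** 2).sum(axis=1))
        keep = dist < d.d_i  # strict: the tree query is inclusive
        if keep.any():
            out.append((ri, gi[keep], gj[keep], dist[keep]))
    return out


def match_pairs(state: ParticleState, model: ModelSpec):
    """Accepted second-order pairs for this reaction step.

    Global greedy matching over all second-order reactions in ascending
    pair distance; ties break on lower agent id, then reaction order.
    Each agent appears in at most one accepted pair.  Equivalent to an
    O(N^2) exhaustive search with the same ordering.
    """
    cands = _candidates(state, model)
    if not cands:
        return []
    ri = np.concatenate([np.full(g.size, r) for r, g, _, _ in cands])
    gi = np.concatenate([g for _, g, _, _ in cands])
    gj = np.concatenate([g for _, _, g, _ in cands])
    dist = np.concatenate([ds for _, _, _, ds in cands])
    lo = np.minimum(gi, gj)
    hi = np.maximum(gi, gj)
    order = np.lexsort((ri, hi, lo, dist))
    used = np.zeros(state.n_slots, bool)
    accepted = []
    for k in order:
        a, b = gi[k], gj[k]
        if used[a] or used[b]:
            continue
        used[a] = used[b] = True
        accepted.append((int(ri[k]), int(a), int(b), float(dist[k])))
    return accepted


# ---------------------------------------------------------------------------
# product placement and event execution

def _random_direction(kind: str, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    if kind == "circle":
        v[2] = 0.0
    norm = np.linalg.norm(v)
    while norm == 0.0:  # pragma: no cover - measure zero
        v = rng.standard_normal(3)
        if kind == "circle":
            v[2] = 0.0
        norm = np.linalg.norm(v)
    v /= norm
    if kind == "hemisphere":
        v[2] = abs(v[2])
    return v


def place_products(
    products: tuple[str, ...],
    origins: list[np.ndarray],
    model: ModelSpec,
    d_u: float,
    origin_membrane: bool,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Positions for each product of one reaction event.

    The first ``len(origins)`` products inherit the reactant positions in
    order; any further products are displaced from the first origin by
    the unbinding distance ``d_u`` in a uniformly random admissible
    direction (in-plane for membrane products, upper hemisphere when
    leaving a membrane species, full sphere otherwise), then reflected
    into the box.  Membrane products are pinned to z = 0 exactly.
    """
    from .brownian import reflect_coordinate

    geo = model.geometry
    placed: list[np.ndarray] = []
    for j, name in enumerate(products):
        mem = model.localisation_of(name) == Localisation.MEMBRANE
        if j < len(origins):
            p = origins[j].copy()
        else:
            kind = "circle" if mem else ("hemisphere" if origin_membrane else "sphere")
            p = origins[0] + d_u * _random_direction(kind, rng)
            for k in range(3):
                p[k] = reflect_coordinate(float(p[k]), float(geo.edges[k]))
        if mem:
            p[2] = 0.0
        placed.append(p)
    return placed


def _execute(
    state: ParticleState,
    model: ModelSpec,
    ri: int,
    reactant_slots: tuple[int, ...],
    products: tuple[str, ...],
    d_u: float,
    rng: np.random.Generator,
) -> tuple[ReactionEvent, list[int]]:
    origins = [state.positions[i].copy() for i in reactant_slots]
    origin_species = model.species[int(state.species[reactant_slots[0]])]
    origin_membrane = origin_species.localisation == Localisation.MEMBRANE
    placed = place_products(products, origins, model, d_u, origin_membrane, rng)
    touched = list(reactant_slots)
    # reuse reactant slots for leading products, kill/spawn the rest
    n_reuse = min(len(reactant_slots), len(products))
    for j in range(n_reuse):
        i = reactant_slots[j]
        state.species[i] = model.index[products[j]]
        state.positions[i] = placed[j]
    for i in reactant_slots[n_reuse:]:
        state.kill(i)
    for j in range(n_reuse, len(products)):
        touched.append(state.spawn(model.index[products[j]], placed[j]))
    ev = ReactionEvent(
        ri,
        tuple(int(i) for i in reactant_slots),
        products,
        tuple(tuple(p) for p in placed),
        state.time,
    )
    return ev, touched


def apply_reaction_step(
    state: ParticleState, model: ModelSpec, rng: np.random.Generator
) -> list[ReactionEvent]:
    """Execute one reaction step on end-of-step positions, in place.

    Second-order events (from :func:`match_pairs`, which depend on the
    step's final geometry) run first; first-order draws then apply to
    agents not yet consumed.  Agents created this step do not react
    until the next step.
    """
    events: list[ReactionEvent] = []
    used = np.zeros(state.n_slots, bool)

    def mark(touched: list[int]) -> None:
        nonlocal used
        if state.n_slots > used.size:
            grown = np.zeros(state.n_slots, bool)
            grown[: used.size] = used
            used = grown
        used[touched] = True

    for ri, a, b, _dist in match_pairs(state, model):
        r = model.reactions[ri]
        ev, touched = _execute(
            state, model, ri, (a, b), r.products, model.derived[ri].d_u, rng
        )
        mark(touched)
        events.append(ev)

    for ri, (r, d) in enumerate(zip(model.reactions, model.derived)):
        if r.rtype == RType.FIRST_ORDER:
            source, P, products = r.reactants[0], d.P, r.products
        elif r.rtype == RType.REVERSIBLE:
            source, P, products = r.products[0], d.P_reverse, r.reactants
        else:
            continue
        if P <= 0.0:
            continue
        si = model.index[source]
        mask = state.alive & (state.species == si)
        mask &= ~used[: state.n_slots]
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        hits = idx[rng.random(idx.size) < P]
        for i in hits:
            ev, touched = _execute(state, model, ri, (int(i),), products, d.d_u, rng)
            mark(touched)
            events.append(ev)
    return events
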