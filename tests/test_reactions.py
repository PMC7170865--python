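"""Reaction kernels: probabilities, interaction distances, pair matching
against a brute-force oracle, and the statistical rate-law properties."""

import math

import numpy as np
import pytest

from partikin.constants import N_A
from partikin.model_io import (
    Geometry,
    GeometryClass,
    Localisation,
    ModelError,
    ParticleState,
    ReactionDef,
    RType,
    SpeciesDef,
    build_model,
    initial_state,
)
from partikin.reactions import (
    apply_reaction_step,
    first_order_probability,
    interaction_distance,
    match_pairs,
    place_products,
    unbinding_distance,
)
from partikin.fixtures import make_bimolecular_scenario, make_first_order_scenario


@pytest.mark.parametrize(
    "k, dt, expected",
    [
        (0.0, 0.05, 0.0),
        (1e-1, 0.05, 1.0 - math.exp(-5e-3)),
        (1e-5, 0.05, 1.0 - math.exp(-5e-7)),
    ],
)
def test_first_order_probability(k, dt, expected):
    assert first_order_probability(k, dt) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        first_order_probability(-1.0, dt)


def _rxn(gclass, k_f=1e6, density=False):
    return ReactionDef(RType.SECOND_ORDER, ("A", "B"), ("AB",), k_f,
                       density_mode=density, geometry_class=gclass)


def test_interaction_distance_matches_closed_forms(box3um):
    dt = 0.05
    d_ss = interaction_distance(_rxn(GeometryClass.SOL_SOL), box3um, dt)
    assert d_ss == pytest.approx(
        (3 * 1e6 * dt / (4 * math.pi * 1e3 * N_A)) ** (1 / 3), rel=1e-12)
    d_ms = interaction_distance(_rxn(GeometryClass.MEM_SOL), box3um, dt)
    assert d_ms == pytest.approx(d_ss * 2 ** (1 / 3), rel=1e-12)
    d_mm = interaction_distance(_rxn(GeometryClass.MEM_MEM), box3um, dt)
    assert d_mm == pytest.approx(
        math.sqrt(1e6 * 9e-12 * dt / (math.pi * 1e3 * 2.7e-17 * N_A)), rel=1e-12)
    # density mode, k_f in m^2/s, implemented as printed
    d_dens = interaction_distance(
        _rxn(GeometryClass.MEM_MEM, k_f=1e-15, density=True), box3um, dt)
    assert d_dens == pytest.approx(
        math.sqrt(1e-15 * dt / (math.pi * 1e3 * N_A)), rel=1e-12)
    for gc in (GeometryClass.SOL_SOL, GeometryClass.MEM_SOL, GeometryClass.MEM_MEM):
        assert interaction_distance(_rxn(gc, k_f=0.0), box3um, dt) == 0.0


def test_interaction_distance_requires_geometry_for_molar_mem_mem():
    with pytest.raises(ModelError, match="geometry"):
        interaction_distance(_rxn(GeometryClass.MEM_MEM), None, 0.05)


def test_unbinding_distance_is_four_binding_radii():
    assert unbinding_distance(0.0) == 0.0
    d_i = 2.7063055668600394e-08
    assert unbinding_distance(d_i) / d_i == 4.0
    with pytest.raises(ValueError):
        unbinding_distance(-1.0)


# ---------------------------------------------------------------------------
# pair matching

def brute_force_pairs(state, model):
    """O(N^2) oracle with the same ordering contract as match_pairs."""
    cands = []
    for ri, (r, d) in enumerate(zip(model.reactions, model.derived)):
        if not r.is_second_order or d.d_i <= 0:
            continue
        in_plane = r.geometry_class == GeometryClass.MEM_MEM
        sa, sb = model.index[r.reactants[0]], model.index[r.reactants[1]]
        ia = np.flatnonzero(state.alive & (state.species == sa))
        ib = np.flatnonzero(state.alive & (state.species == sb))
        for a in ia:
            for b in ib:
                if a == b or (sa == sb and a > b):
                    continue
                delta = state.positions[a] - state.positions[b]
                if in_plane:
                    delta = delta[:2]
                dist = float(np.sqrt((delta**2).sum()))
                if dist < d.d_i:
                    cands.append((dist, min(a, b), max(a, b), ri, a, b))
    cands.sort(key=lambda c: c[:4])
    used, accepted = set(), []
    for dist, lo, hi, ri, a, b in cands:
        if a in used or b in used:
            continue
        used.update((a, b))
        accepted.append((ri, a, b))
    return accepted


def _uniform_state(model, rng, counts):
    return initial_state(model, rng, counts=counts)


def test_match_single_pair_within_distance(sol_sol_model):
    d_i = sol_sol_model.derived[0].d_i
    pos = np.array([[1e-6, 1e-6, 1e-6], [1e-6 + 0.9 * d_i, 1e-6, 1e-6]])
    state = ParticleState(np.array([0, 1], np.int32), pos, np.ones(2, bool))
    pairs = match_pairs(state, sol_sol_model)
    assert len(pairs) == 1
    assert pairs[0][1:3] == (0, 1)


def test_closest_substrate_wins(sol_sol_model):
    d_i = sol_sol_model.derived[0].d_i
    pos = np.array([
        [1e-6, 1e-6, 1e-6],                 # A
        [1e-6 + 0.8 * d_i, 1e-6, 1e-6],     # B, farther
        [1e-6 + 0.5 * d_i, 1e-6, 1e-6],     # B, closer
    ])
    state = ParticleState(np.array([0, 1, 1], np.int32), pos, np.ones(3, bool))
    pairs = match_pairs(state, sol_sol_model)
    assert len(pairs) == 1
    assert pairs[0][1:3] == (0, 2)


@pytest.mark.parametrize("gclass", ["sol_sol", "mem_sol", "mem_mem"])
@pytest.mark.parametrize("seed", range(25))
def test_match_pairs_equals_brute_force(gclass, seed):
    model, _ = make_bimolecular_scenario(gclass, k_f=1e7)
    rng = np.random.default_rng(seed)
    state = _uniform_state(model, rng, {"A": 100, "B": 100, "AB": 0})
    got = {(ri, a, b) for ri, a, b, _ in match_pairs(state, model)}
    assert got == set(brute_force_pairs(state, model))


def test_match_pairs_brute_force_with_competing_reactions(box3um):
    """Two second-order reactions sharing species still match greedily."""
    species = [
        SpeciesDef("A", Localisation.SOLUBLE, 3e-11, 0.0),
        SpeciesDef("B", Localisation.SOLUBLE, 3e-11, 0.0),
        SpeciesDef("C", Localisation.SOLUBLE, 3e-11, 0.0),
        SpeciesDef("AB", Localisation.SOLUBLE, 3e-11, 0.0),
        SpeciesDef("AC", Localisation.SOLUBLE, 3e-11, 0.0),
        SpeciesDef("AA", Localisation.SOLUBLE, 3e-11, 0.0),
    ]
    rxns = [
        ReactionDef(RType.SECOND_ORDER, ("A", "B"), ("AB",), 1e7,
                    geometry_class=GeometryClass.SOL_SOL),
        ReactionDef(RType.SECOND_ORDER, ("A", "C"), ("AC",), 3e7,
                    geometry_class=GeometryClass.SOL_SOL),
        ReactionDef(RType.SECOND_ORDER, ("A", "A"), ("AA",), 1e7,
                    geometry_class=GeometryClass.SOL_SOL),
    ]
    model = build_model(species, rxns, box3um, 0.05)
    for seed in range(25):
        rng = np.random.default_rng(seed)
        state = _uniform_state(model, rng, {"A": 150, "B": 120, "C": 120})
        got = {(ri, a, b) for ri, a, b, _ in match_pairs(state, model)}
        assert got == set(brute_force_pairs(state, model))


# ---------------------------------------------------------------------------
# statistical properties of the step kernels

def test_well_mixed_second_order_rate_law():
    """With re-randomised positions, mean pairs/step = N_A N_B V_i / V_C."""
    model, _ = make_bimolecular_scenario("sol_sol", k_f=1e7)
    d = model.derived[0]
    v_c = model.geometry.volume
    n_a, n_b = 60, 60
    expected = n_a * n_b * d.V_i / v_c
    rng = np.random.default_rng(77)
    events = [len(match_pairs(
        _uniform_state(model, rng, {"A": n_a, "B": n_b, "AB": 0}), model))
        for _ in range(1500)]
    mean = np.mean(events)
    se = np.std(events, ddof=1) / math.sqrt(len(events))
    assert abs(mean - expected) < 3 * se + 1e-9


def test_well_mixed_mem_sol_rate_law():
    """Hemispherical V_i over the accessible half-space sets the rate."""
    model, _ = make_bimolecular_scenario("mem_sol", k_f=1e7)
    d = model.derived[0]
    v_c = model.geometry.volume
    n_r, n_s = 60, 60
    expected = n_r * n_s * d.V_i / v_c
    rng = np.random.default_rng(78)
    events = [len(match_pairs(
        _uniform_state(model, rng, {"A": n_r, "B": n_s, "AB": 0}), model))
        for _ in range(1500)]
    mean = np.mean(events)
    se = np.std(events, ddof=1) / math.sqrt(len(events))
    assert abs(mean - expected) < 3 * se + 1e-9


def test_first_order_decay_matches_exponential():
    """Survivors after n steps are Binomial(N0, (1-P)^n)."""
    model, cfg = make_first_order_scenario(k=1e-2)
    rng = np.random.default_rng(5)
    state = initial_state(model, rng)
    n0 = state.n_alive
    assert n0 == 1626
    for _ in range(6000):  # 300 s at dt_rxn = 0.05 s without diffusion
        apply_reaction_step(state, model, rng)
    p_survive = (1.0 - model.derived[0].P) ** 6000
    expected = n0 * p_survive  # ~ 1626 e^-3 = 81
    sd = math.sqrt(n0 * p_survive * (1 - p_survive))
    assert abs(state.n_alive - expected) < 4 * sd


def test_first_order_certain_conversion_in_one_step(box3um):
    """P -> 1 (k dt >> 1) converts every eligible agent in a single step."""
    species = [SpeciesDef("A", Localisation.SOLUBLE, 3e-11, 1e-7)]
    rxns = [ReactionDef(RType.FIRST_ORDER, ("A",), (), 1e3)]
    model = build_model(species, rxns, box3um, 0.05)
    rng = np.random.default_rng(0)
    state = initial_state(model, rng)
    apply_reaction_step(state, model, rng)
    assert state.n_alive == 0


def test_zero_rates_leave_state_unchanged(box3um):
    species = [
        SpeciesDef("A", Localisation.SOLUBLE, 3e-11, 1e-7),
        SpeciesDef("B", Localisation.SOLUBLE, 3e-11, 1e-7),
        SpeciesDef("AB", Localisation.SOLUBLE, 3e-11, 0.0),
    ]
    rxns = [
        ReactionDef(RType.SECOND_ORDER, ("A", "B"), ("AB",), 0.0,
                    geometry_class=GeometryClass.SOL_SOL),
        ReactionDef(RType.FIRST_ORDER, ("A",), (), 0.0),
    ]
    model = build_model(species, rxns, box3um, 0.05)
    assert all(d.P == 0 and d.d_i == 0 for d in model.derived)
    rng = np.random.default_rng(0)
    state = initial_state(model, rng)
    counts0 = state.counts(3).copy()
    events = apply_reaction_step(state, model, rng)
    assert not events
    np.testing.assert_array_equal(state.counts(3), counts0)


# ---------------------------------------------------------------------------
# product placement

def test_association_product_inherits_membrane_position(reversible_model, rng):
    d_i = reversible_model.derived[0].d_i
    pos = np.array([[1e-6, 1e-6, 0.0], [1e-6, 1e-6, 0.5 * d_i]])
    state = ParticleState(np.array([0, 1], np.int32), pos, np.ones(2, bool))
    events = apply_reaction_step(state, reversible_model, rng)
    assoc = [e for e in events if e.produced == ("RS",)]
    assert len(assoc) == 1
    i = int(np.flatnonzero(state.alive)[0])
    assert state.species[i] == reversible_model.index["RS"]
    np.testing.assert_allclose(state.positions[i], [1e-6, 1e-6, 0.0])


def test_dissociation_separates_products_by_d_u(sol_sol_model, rng):
    d_u = sol_sol_model.derived[0].d_u
    origin = np.array([1.5e-6, 1.5e-6, 1.5e-6])
    placed = place_products(("A", "B"), [origin], sol_sol_model, d_u, False, rng)
    np.testing.assert_allclose(placed[0], origin)
    assert np.linalg.norm(placed[1] - placed[0]) == pytest.approx(d_u, rel=1e-9)


def test_unimolecular_conversion_preserves_position(box3um, rng):
    species = [
        SpeciesDef("ES", Localisation.SOLUBLE, 3e-11, 0.0),
        SpeciesDef("ESp", Localisation.SOLUBLE, 3e-11, 0.0),
    ]
    rxns = [ReactionDef(RType.FIRST_ORDER, ("ES",), ("ESp",), 1e3)]
    model = build_model(species, rxns, box3um, 0.05)
    p = np.array([[1e-6, 2e-6, 5e-7]])
    state = ParticleState(np.array([0], np.int32), p.copy(), np.ones(1, bool))
    apply_reaction_step(state, model, rng)
    assert state.species[0] == 1
    np.testing.assert_array_equal(state.positions[0], p[0])


def test_degradation_removes_agent_without_products(rng):
    model, _ = make_first_order_scenario(k=1e3)  # P ~ 1
    state = initial_state(model, rng, counts={"A": 10})
    events = apply_reaction_step(state, model, rng)
    assert state.n_alive == 0
    assert all(e.produced == () for e in events)


def test_no_immediate_reassociation_after_dissociation(box3um):
    """Fragments placed d_u = 4 d_i apart are not re-matched."""
    species = [
        SpeciesDef("R", Localisation.MEMBRANE, 3e-13, 0.0),
        SpeciesDef("S", Localisation.SOLUBLE, 3e-11, 0.0),
        SpeciesDef("RS", Localisation.MEMBRANE, 3e-13, 0.0),
    ]
    rxns = [ReactionDef(RType.REVERSIBLE, ("R", "S"), ("RS",), 1e6, 1e3,
                        geometry_class=GeometryClass.MEM_SOL)]
    model = build_model(species, rxns, box3um, 0.05)  # P_reverse ~ 1
    d = model.derived[0]
    rng = np.random.default_rng(3)
    pos = np.array([[1.5e-6, 1.5e-6, 0.0]])
    state = ParticleState(
        np.array([model.index["RS"]], np.int32), pos, np.ones(1, bool))
    events = apply_reaction_step(state, model, rng)
    assert events and set(events[0].produced) == {"R", "S"}
    idx = np.flatnonzero(state.alive)
    sep = np.linalg.norm(state.positions[idx[0]] - state.positions[idx[1]])
    assert sep == pytest.approx(d.d_u, rel=1e-9)
    # without diffusion the pair sits outside d_i and cannot re-bind
    assert not match_pairs(state, model)


def test_mass_balance_with_composition_maps(reversible_model):
    """Monomer totals are conserved by binding/unbinding steps."""
    rng = np.random.default_rng(21)
    state = initial_state(reversible_model, rng)

    def monomers(st):
        totals = {}
        counts = st.counts(reversible_model.n_species)
        for sp, n in zip(reversible_model.species, counts):
            for mono, m in (sp.composition or {}).items():
                totals[mono] = totals.get(mono, 0) + m * int(n)
        return totals

    before = monomers(state)
    from partikin.brownian import diffuse

    for _ in range(50):
        diffuse(state, reversible_model, 0.05, 1, rng)
        apply_reaction_step(state, reversible_model, rng)
    assert monomers(state) == before
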