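"""Programmatic builders for the benchmark scenarios and the packaged
apoptosis execution network.

Defaults mirror the validation conditions: a 3 um x 3 um x 3 um box
whose bottom face is a planar membrane, reflective boundaries, a
diffusion substep of 1e-4 s and a reaction step of 0.05 s, 5 simulated
minutes, soluble D = 30 um^2 s^-1 and membrane D = 0.3 um^2 s^-1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

from .model_io import (
    Geometry,
    GeometryClass,
    Localisation,
    ModelSpec,
    ReactionDef,
    RType,
    SimConfig,
    SpeciesDef,
    build_model,
    parse_agents_file,
    parse_reactions_file,
)

BOX_EDGE = 3e-6  # m
DT_DIFF = 1e-4  # s
DT_RXN = 0.05  # s
DURATION = 300.0  # s
D_SOLUBLE = 3.0e-11  # m^2 s^-1 (30 um^2/s)
D_MEMBRANE = 3.0e-13  # m^2 s^-1 (0.3 um^2/s)


def default_geometry(box: float = BOX_EDGE) -> Geometry:
    return Geometry(box, box, box)


def default_config(
    duration: float = DURATION,
    dt_diff: float = DT_DIFF,
    dt_rxn: float = DT_RXN,
    record_interval: float = DT_RXN,
    seed: int = 0,
    replicates: int = 1,
) -> SimConfig:
    return SimConfig(dt_diff, dt_rxn, duration, record_interval, seed, replicates)


class ScenarioKind(str, enum.Enum):
    SINGLE_PARTICLES = "single_particles"
    FIRST_ORDER = "first_order"
    BIMOLECULAR = "bimolecular"


@dataclass
class ScenarioSpec:
    """Declarative description of one benchmark scenario."""

    kind: ScenarioKind
    params: dict = field(default_factory=dict)
    box: float = BOX_EDGE
    config: SimConfig | None = None


def make_single_particle_scenario(
    D_values, box: float = BOX_EDGE, dt_diff: float = DT_DIFF,
    duration: float = DURATION,
) -> tuple[ModelSpec, SimConfig]:
    """Non-reacting tracer species, one agent each (c0 of one molecule)."""
    geo = default_geometry(box)
    c_one = 1.0 / (1e3 * 6.02214076e23 * geo.volume)  # rounds to 1 agent
    species = [
        SpeciesDef(f"P{i}", Localisation.SOLUBLE, float(D), c_one)
        for i, D in enumerate(D_values)
    ]
    model = build_model(species, [], geo, DT_RXN)
    cfg = SimConfig(dt_diff, max(dt_diff, DT_RXN), duration, duration, 0, 1)
    return model, cfg


def make_first_order_scenario(
    k: float, c0: float = 1e-7, box: float = BOX_EDGE,
    dt_rxn: float = DT_RXN, duration: float = DURATION,
    record_interval: float = 5.0,
) -> tuple[ModelSpec, SimConfig]:
    """A -> degraded at rate k, starting from c0 (100 nM default)."""
    species = [SpeciesDef("A", Localisation.SOLUBLE, D_SOLUBLE, c0, {"a": 1})]
    rxn = [ReactionDef(RType.FIRST_ORDER, ("A",), (), k)]
    model = build_model(species, rxn, default_geometry(box), dt_rxn)
    cfg = SimConfig(dt_rxn, dt_rxn, duration, record_interval, 0, 1)
    return model, cfg


def make_bimolecular_scenario(
    geometry_class: GeometryClass | str = GeometryClass.SOL_SOL,
    k_f: float = 1e6,
    cA: float = 1e-7,
    cB: float = 1e-7,
    box: float = BOX_EDGE,
    dt_diff: float = DT_DIFF,
    dt_rxn: float = DT_RXN,
    duration: float = DURATION,
    record_interval: float = DT_RXN,
) -> tuple[ModelSpec, SimConfig]:
    """A + B -> AB in one of the three geometry classes.

    For ``mem_sol`` the membrane reactant is A (the receptor); for
    ``mem_mem`` both reactants and the product sit on the membrane and
    k_f (M^-1 s^-1) is scaled by the surface-to-volume ratio internally.
    """
    gc = GeometryClass(geometry_class)
    loc_a = Localisation.MEMBRANE if gc in (
        GeometryClass.MEM_SOL, GeometryClass.MEM_MEM) else Localisation.SOLUBLE
    loc_b = Localisation.MEMBRANE if gc == GeometryClass.MEM_MEM else Localisation.SOLUBLE
    loc_ab = Localisation.MEMBRANE if gc != GeometryClass.SOL_SOL else Localisation.SOLUBLE
    d_of = {Localisation.SOLUBLE: D_SOLUBLE, Localisation.MEMBRANE: D_MEMBRANE}
    species = [
        SpeciesDef("A", loc_a, d_of[loc_a], cA, {"a": 1}),
        SpeciesDef("B", loc_b, d_of[loc_b], cB, {"b": 1}),
        SpeciesDef("AB", loc_ab, d_of[loc_ab], 0.0, {"a": 1, "b": 1}),
    ]
    rxn = [ReactionDef(RType.SECOND_ORDER, ("A", "B"), ("AB",), k_f,
                       geometry_class=gc)]
    model = build_model(species, rxn, default_geometry(box), dt_rxn)
    cfg = SimConfig(dt_diff, dt_rxn, duration, record_interval, 0, 1)
    return model, cfg


def make_benchmark_scenario(spec: ScenarioSpec) -> tuple[ModelSpec, SimConfig]:
    """Dispatch a :class:`ScenarioSpec` to the concrete builder."""
    kind = ScenarioKind(spec.kind)
    if kind == ScenarioKind.SINGLE_PARTICLES:
        model, cfg = make_single_particle_scenario(
            spec.params.get("D", (1e-12, 5e-12, 1e-11)), box=spec.box)
    elif kind == ScenarioKind.FIRST_ORDER:
        model, cfg = make_first_order_scenario(
            spec.params.get("k", 1e-2), c0=spec.params.get("c0", 1e-7),
            box=spec.box)
    elif kind == ScenarioKind.BIMOLECULAR:
        model, cfg = make_bimolecular_scenario(
            spec.params.get("geometry_class", GeometryClass.SOL_SOL),
            k_f=spec.params.get("k_f", 1e6),
            cA=spec.params.get("cA", 1e-7),
            cB=spec.params.get("cB", 1e-7),
            box=spec.box)
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario kind {spec.kind!r}")
    return model, (spec.config or cfg)


def _read_data(name: str) -> str:
    return (resources.files("partikin.data") / name).read_text()


def build_apoptosis_model(
    dt_rxn: float = DT_RXN, box: float = BOX_EDGE
) -> ModelSpec:
    """The packaged 14-species / 23-reaction apoptosis execution model.

    Starts post-MOMP: cytosolic SMAC and assembled apoptosome are present
    at t = 0 and the cascade culminates in cleavage of the caspase-3
    FRET-substrate proxy.  The species/reaction counts are structural
    invariants; the rate constants are representative editable values
    (see the packaged data files).
    """
    species = parse_agents_file(_read_data("apoptosis_agents.txt"))
    reactions = parse_reactions_file(_read_data("apoptosis_reactions.txt"), species)
    return build_model(species, reactions, default_geometry(box), dt_rxn)


FIXTURE_BUILDERS = {
    "apoptosis": build_apoptosis_model,
    "bimolecular_sol_sol": lambda: make_bimolecular_scenario(GeometryClass.SOL_SOL)[0],
    "bimolecular_mem_sol": lambda: make_bimolecular_scenario(GeometryClass.MEM_SOL)[0],
    "bimolecular_mem_mem": lambda: make_bimolecular_scenario(GeometryClass.MEM_MEM)[0],
    "first_order": lambda: make_first_order_scenario(1e-2)[0],
}
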