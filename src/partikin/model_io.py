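"""Model files, validation and initial particle states.

A model is defined by two plain-text files.  The *agents* file lists one
species per row::

    # columns: name localisation D[m2/s] c0[M] composition
    name localisation D c0 composition
    A    soluble   3.0e-11  1.0e-7  -
    R    membrane  3.0e-13  1.0e-7  -

and the *reactions* file lists one reaction per row, with ``->`` for
irreversible and ``<->`` for reversible reactions and ``0`` for an empty
product side::

    # columns: reaction type k_f k_r
    reaction type k_f k_r
    A + B -> AB   second_order  1.0e6
    AB -> A + B   first_order   1.0e-3
    R + S <-> RS  reversible    1.0e6  1.0e-3

Columns are whitespace separated, ``#`` starts a comment and the first
non-comment line of each file is a header naming the columns; it is
required but not interpreted beyond a sanity check.  Units are fixed by
the dialect: D in m^2 s^-1, concentrations in mol L^-1 (all species,
including membrane-bound ones, referred to the fixed box volume), k in
s^-1 for first-order and M^-1 s^-1 for second-order constants.  A
trailing ``density`` token on a membrane-membrane reaction declares its
k_f in m^2 s^-1 (density mode, see :mod:`partikin.reactions`).

The optional ``composition`` column is a comma-separated
``monomer:count`` map (or ``-``) used by mass-balance checks.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .constants import N_A


class ModelError(ValueError):
    """Invalid model definition."""


class ParseError(ModelError):
    """Malformed model file; message carries the offending line number."""


class ModelBuildWarning(UserWarning):
    """Non-fatal issue detected while deriving reaction parameters."""


class Localisation(str, enum.Enum):
    SOLUBLE = "soluble"
    MEMBRANE = "membrane"


class RType(str, enum.Enum):
    FIRST_ORDER = "first_order"
    SECOND_ORDER = "second_order"
    REVERSIBLE = "reversible"


class GeometryClass(str, enum.Enum):
    SOL_SOL = "sol_sol"
    MEM_SOL = "mem_sol"
    MEM_MEM = "mem_mem"
    NA = "n/a"


@dataclass
class SpeciesDef:
    """One molecular species: localisation, mobility and initial amount."""

    name: str
    localisation: Localisation
    D: float  # translational diffusion coefficient, m^2 s^-1
    c0: float  # initial concentration, mol L^-1 (box-volume referenced)
    composition: dict[str, int] | None = None

    def __post_init__(self):
        self.localisation = Localisation(self.localisation)
        if self.D < 0:
            raise ModelError(f"species {self.name!r}: D must be >= 0")
        if self.c0 < 0:
            raise ModelError(f"species {self.name!r}: c0 must be >= 0")
        if self.composition is not None:
            for mono, cnt in self.composition.items():
                if cnt < 1:
                    raise ModelError(
                        f"species {self.name!r}: composition count for "
                        f"{mono!r} must be >= 1"
                    )


@dataclass
class ReactionDef:
    """One reaction: reactants, products, type and rate constants.

    For ``mem_sol`` second-order reactions the reactants are stored
    membrane-first so that association products inherit the membrane
    reactant's position.
    """

    rtype: RType
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k_f: float
    k_r: float | None = None
    density_mode: bool = False
    geometry_class: GeometryClass = GeometryClass.NA

    def __post_init__(self):
        self.rtype = RType(self.rtype)
        self.reactants = tuple(self.reactants)
        self.products = tuple(self.products)
        if self.k_f < 0:
            raise ModelError("rate constant k_f must be >= 0")
        if self.rtype == RType.FIRST_ORDER:
            if len(self.reactants) != 1:
                raise ModelError("first_order reactions take exactly 1 reactant")
        else:
            if len(self.reactants) != 2:
                raise ModelError(
                    f"{self.rtype.value} reactions take exactly 2 reactants"
                )
        if self.rtype == RType.REVERSIBLE:
            if self.k_r is None:
                raise ModelError("reversible reaction missing k_r")
            if self.k_r < 0:
                raise ModelError("rate constant k_r must be >= 0")
            if len(self.products) != 1:
                raise ModelError(
                    "reversible reactions must form a single complex product"
                )

    @property
    def is_second_order(self) -> bool:
        return self.rtype in (RType.SECOND_ORDER, RType.REVERSIBLE)

    def expression(self) -> str:
        arrow = "<->" if self.rtype == RType.REVERSIBLE else "->"
        left = " + ".join(self.reactants)
        right = " + ".join(self.products) if self.products else "0"
        return f"{left} {arrow} {right}"


@dataclass
class Geometry:
    """Axis-aligned box; the z = 0 face is the planar membrane."""

    Lx: float
    Ly: float
    Lz: float

    def __post_init__(self):
        if min(self.Lx, self.Ly, self.Lz) <= 0:
            raise ModelError("box edge lengths must be > 0")

    @property
    def area(self) -> float:
        """Membrane face area A_C, m^2."""
        return self.Lx * self.Ly

    @property
    def volume(self) -> float:
        """Box volume V_C, m^3."""
        return self.Lx * self.Ly * self.Lz

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz])


@dataclass
class SimConfig:
    """Time stepping and replication parameters of one run."""

    dt_diff: float  # diffusion substep, s
    dt_rxn: float  # reaction step, s
    duration: float  # total simulated time, s
    record_interval: float  # sampling interval, s
    seed: int = 0
    replicates: int = 1

    def __post_init__(self):
        if self.dt_diff <= 0 or self.dt_rxn <= 0:
            raise ModelError("time steps must be > 0")
        if self.duration < 0:
            raise ModelError("duration must be >= 0")
        n = self.dt_rxn / self.dt_diff
        if abs(n - round(n)) > 1e-9 * n or round(n) < 1:
            raise ModelError("dt_rxn must be an integer multiple of dt_diff")
        if self.record_interval < self.dt_rxn:
            raise ModelError("record_interval must be >= dt_rxn")
        if self.replicates < 1:
            raise ModelError("replicates must be >= 1")

    @property
    def n_substeps(self) -> int:
        return int(round(self.dt_rxn / self.dt_diff))


@dataclass
class ModelSpec:
    """A validated reaction network plus geometry and derived parameters."""

    species: list[SpeciesDef]
    reactions: list[ReactionDef]
    geometry: Geometry
    dt_rxn: float | None = None
    derived: list = field(default_factory=list)  # DerivedReactionParams

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelError("duplicate species name")
        self.index = {n: i for i, n in enumerate(names)}
        for r in self.reactions:
            for n in r.reactants + r.products:
                if n not in self.index:
                    raise ModelError(f"reaction references unknown species {n!r}")
        self.names = names
        self.D_array = np.array([s.D for s in self.species])
        self.membrane_mask = np.array(
            [s.localisation == Localisation.MEMBRANE for s in self.species]
        )
        self._sigma_cache: dict[float, np.ndarray] = {}

    @property
    def n_species(self) -> int:
        return len(self.species)

    def localisation_of(self, name: str) -> Localisation:
        return self.species[self.index[name]].localisation


@dataclass
class ParticleState:
    """Positions, species identity and alive flags of all agents.

    Backing arrays may contain dead slots (freed by degradation or
    association); ``free`` tracks them for reuse so that product creation
    rarely reallocates.  ``sq_disp`` accumulates each agent's
    pre-reflection squared step displacements for MSD estimation.
    """

    species: np.ndarray  # (N,) int32
    positions: np.ndarray  # (N, 3) float64
    alive: np.ndarray  # (N,) bool
    time: float = 0.0
    sq_disp: np.ndarray | None = None
    free: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.sq_disp is None:
            self.sq_disp = np.zeros(len(self.species))

    @property
    def n_slots(self) -> int:
        return self.species.shape[0]

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def counts(self, n_species: int) -> np.ndarray:
        return np.bincount(self.species[self.alive], minlength=n_species)

    def kill(self, i: int) -> None:
        self.alive[i] = False
        self.free.append(i)

    def spawn(self, species_idx: int, position: np.ndarray) -> int:
        if self.free:
            i = self.free.pop()
        else:
            i = self._grow()
        self.species[i] = species_idx
        self.positions[i] = position
        self.alive[i] = True
        self.sq_disp[i] = 0.0
        return i

    def _grow(self) -> int:
        n = self.n_slots
        extra = max(64, n // 4)
        self.species = np.concatenate([self.species, np.zeros(extra, np.int32)])
        self.positions = np.concatenate([self.positions, np.zeros((extra, 3))])
        self.alive = np.concatenate([self.alive, np.zeros(extra, bool)])
        self.sq_disp = np.concatenate([self.sq_disp, np.zeros(extra)])
        self.free.extend(range(n + 1, n + extra))
        return n


# ---------------------------------------------------------------------------
# parsing

def _data_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line


def _parse_composition(tok: str, lineno: int) -> dict[str, int] | None:
    if tok == "-":
        return None
    comp: dict[str, int] = {}
    try:
        for part in tok.split(","):
            mono, cnt = part.split(":")
            comp[mono] = int(cnt)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed composition {tok!r}") from exc
    return comp


def parse_agents_file(text: str) -> list[SpeciesDef]:
    """Parse the agents file into species definitions, in file order."""
    species: list[SpeciesDef] = []
    seen: set[str] = set()
    header_done = False
    for lineno, line in _data_lines(text):
        if not header_done:
            if not line.lower().startswith("name"):
                raise ParseError(
                    f"line {lineno}: expected header line starting with 'name'"
                )
            header_done = True
            continue
        toks = line.split()
        if len(toks) not in (4, 5):
            raise ParseError(f"line {lineno}: expected 4 or 5 columns, got {len(toks)}")
        name, loc, d_tok, c_tok = toks[:4]
        if name in seen:
            raise ParseError(f"line {lineno}: duplicate species name {name!r}")
        seen.add(name)
        try:
            loc_enum = Localisation(loc)
        except ValueError:
            raise ParseError(f"line {lineno}: unknown localisation {loc!r}") from None
        try:
            D = float(d_tok)
            c0 = float(c_tok)
        except ValueError:
            raise ParseError(f"line {lineno}: malformed number") from None
        comp = _parse_composition(toks[4], lineno) if len(toks) == 5 else None
        try:
            species.append(SpeciesDef(name, loc_enum, D, c0, comp))
        except ModelError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    if not header_done:
        raise ParseError("agents file is empty")
    return species


def _geometry_class(
    reactants: tuple[str, ...], loc: dict[str, Localisation]
) -> GeometryClass:
    mem = sum(loc[r] == Localisation.MEMBRANE for r in reactants)
    return (
        GeometryClass.SOL_SOL,
        GeometryClass.MEM_SOL,
        GeometryClass.MEM_MEM,
    )[mem]


def parse_reactions_file(text: str, species: list[SpeciesDef]) -> list[ReactionDef]:
    """Parse the reactions file; geometry classes derive from localisation."""
    loc = {s.name: s.localisation for s in species}
    reactions: list[ReactionDef] = []
    header_done = False
    for lineno, line in _data_lines(text):
        if not header_done:
            if not line.lower().startswith("reaction"):
                raise ParseError(
                    f"line {lineno}: expected header line starting with 'reaction'"
                )
            header_done = True
            continue
        toks = line.split()
        density = False
        if toks and toks[-1] == "density":
            density = True
            toks = toks[:-1]
        # numeric constants from the right, then the type token
        consts: list[float] = []
        while toks:
            try:
                consts.append(float(toks[-1]))
            except ValueError:
                break
            toks.pop()
        consts.reverse()
        if not toks:
            raise ParseError(f"line {lineno}: missing reaction type")
        rtype_tok = toks.pop()
        try:
            rtype = RType(rtype_tok)
        except ValueError:
            raise ParseError(
                f"line {lineno}: unknown reaction type {rtype_tok!r}"
            ) from None
        if "<->" in toks:
            arrow = "<->"
        elif "->" in toks:
            arrow = "->"
        else:
            raise ParseError(f"line {lineno}: missing reaction arrow")
        if (arrow == "<->") != (rtype == RType.REVERSIBLE):
            raise ParseError(
                f"line {lineno}: arrow {arrow!r} inconsistent with type "
                f"{rtype.value!r}"
            )
        ai = toks.index(arrow)
        reactants = tuple(t for t in toks[:ai] if t != "+")
        prod_toks = tuple(t for t in toks[ai + 1 :] if t != "+")
        products = () if prod_toks == ("0",) else prod_toks
        for n in reactants + products:
            if n not in loc:
                raise ParseError(f"line {lineno}: unknown species {n!r}")
        if rtype == RType.REVERSIBLE:
            if len(consts) != 2:
                raise ParseError(f"line {lineno}: reversible needs k_f and k_r")
            k_f, k_r = consts
        else:
            if len(consts) != 1:
                raise ParseError(f"line {lineno}: expected one rate constant")
            k_f, k_r = consts[0], None
        gclass = (
            _geometry_class(reactants, loc)
            if rtype != RType.FIRST_ORDER
            else GeometryClass.NA
        )
        if density and gclass != GeometryClass.MEM_MEM:
            raise ParseError(
                f"line {lineno}: density mode only applies to membrane-membrane "
                "reactions"
            )
        if gclass == GeometryClass.MEM_SOL and loc[reactants[0]] != Localisation.MEMBRANE:
            reactants = (reactants[1], reactants[0])  # membrane reactant first
        try:
            reactions.append(
                ReactionDef(rtype, reactants, products, k_f, k_r, density, gclass)
            )
        except ModelError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    if not header_done:
        raise ParseError("reactions file is empty")
    return reactions


# ---------------------------------------------------------------------------
# serialisation (round-trips through the parsers)

def agents_text(species: list[SpeciesDef]) -> str:
    lines = ["name localisation D c0 composition"]
    for s in species:
        comp = (
            "-"
            if not s.composition
            else ",".join(f"{m}:{c}" for m, c in s.composition.items())
        )
        lines.append(f"{s.name} {s.localisation.value} {s.D!r} {s.c0!r} {comp}")
    return "\n".join(lines) + "\n"


def reactions_text(reactions: list[ReactionDef]) -> str:
    lines = ["reaction type k_f k_r"]
    for r in reactions:
        row = f"{r.expression()} {r.rtype.value} {r.k_f!r}"
        if r.k_r is not None:
            row += f" {r.k_r!r}"
        if r.density_mode:
            row += " density"
        lines.append(row)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# model building and initial states

def build_model(
    species: list[SpeciesDef],
    reactions: list[ReactionDef],
    geometry: Geometry,
    dt_rxn: float,
) -> ModelSpec:
    """Assemble a :class:`ModelSpec` with derived per-reaction parameters.

    Emits :class:`ModelBuildWarning` when an interaction distance exceeds
    10% of the smallest box edge or when the expected number of reaction
    partners per agent per step exceeds 1 (both signs that the reaction
    step is too coarse for the requested kinetics).
    """
    from .reactions import derive_reaction_params  # local import: avoids cycle

    model = ModelSpec(species, reactions, geometry, dt_rxn)
    c0 = {s.name: s.c0 for s in species}
    min_edge = min(geometry.Lx, geometry.Ly, geometry.Lz)
    for r in reactions:
        d = derive_reaction_params(r, geometry, dt_rxn)
        if r.is_second_order:
            if d.d_i > 0.1 * min_edge:
                warnings.warn(
                    f"{r.expression()}: d_i={d.d_i:.3e} m exceeds 10% of the "
                    "smallest box edge",
                    ModelBuildWarning,
                    stacklevel=2,
                )
            a, b = r.reactants
            if r.geometry_class == GeometryClass.MEM_MEM:
                # partner count over the membrane face, per unit area
                dens = {n: c0[n] * 1e3 * N_A * geometry.volume / geometry.area
                        for n in (a, b)}
                n_exp = max(dens[b] * d.A_i, dens[a] * d.A_i)
            else:
                n_exp = max(c0[b], c0[a]) * 1e3 * N_A * d.V_i
            if n_exp > 1:
                warnings.warn(
                    f"{r.expression()}: expected partners per agent per step "
                    f"= {n_exp:.2f} > 1; reduce the reaction time step",
                    ModelBuildWarning,
                    stacklevel=2,
                )
        model.derived.append(d)
    # unbinding distances for standalone dissociations whose reverse
    # association exists in the model
    for ri, r in enumerate(reactions):
        if r.rtype != RType.FIRST_ORDER or len(r.products) < 2:
            continue
        for rj, r2 in enumerate(reactions):
            if (
                r2.is_second_order
                and Counter(r2.reactants) == Counter(r.products)
                and r2.products == r.reactants
            ):
                model.derived[ri].d_u = model.derived[rj].d_u
                break
    return model


def initial_state(
    model: ModelSpec,
    seed: int | np.random.Generator | None = None,
    counts: dict[str, int] | None = None,
) -> ParticleState:
    """Draw the initial particle state.

    Counts follow ``round(c0 * 1e3 * V_C * N_A)`` unless overridden via
    ``counts``.  Soluble agents are uniform in the box, membrane agents
    uniform on the z = 0 face.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geo = model.geometry
    per_species = []
    for s in model.species:
        if counts is not None and s.name in counts:
            n = counts[s.name]
        else:
            n = int(round(s.c0 * 1e3 * geo.volume * N_A))
        per_species.append(n)
    total = int(sum(per_species))
    if total == 0:
        warnings.warn("model initialises with zero agents", ModelBuildWarning,
                      stacklevel=2)
    species = np.zeros(total, np.int32)
    positions = np.zeros((total, 3))
    ofs = 0
    for i, n in enumerate(per_species):
        if n == 0:
            continue
        species[ofs : ofs + n] = i
        pos = rng.uniform(0.0, 1.0, size=(n, 3)) * geo.edges
        if model.membrane_mask[i]:
            pos[:, 2] = 0.0
        positions[ofs : ofs + n] = pos
        ofs += n
    return ParticleState(species, positions, np.ones(total, bool))
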