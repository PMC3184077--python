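"""Domain types and file formats for reaction universes, environments and annotations.

The central object is the :class:`ReactionUniverse`: a global set of N
candidate reactions over m metabolites, encoded as a sparse stoichiometric
matrix.  A metabolic network *genotype* is a length-N bit vector selecting a
subset of those reactions; an *environment* is a minimal medium given as the
set of external metabolites whose uptake is open.

File dialect (all plain text, canonically sorted so that write/read
round-trips are byte-identical):

``reactions.tsv``
    columns ``reaction_id  equation  role  swappable``. The equation grammar is
    ``coef? met (" + " coef? met)* (" => " | " <=> ") [products]`` with an
    implicit coefficient of 1; ``<=>`` marks the reaction reversible. Either
    side may be empty (exchange and biomass reactions consume without internal
    products).
``metabolites.tsv``
    columns ``metabolite_id  external`` (0/1).
``environments.json``
    list of ``{"label": ..., "importable": [...]}`` objects.
``annotations.tsv``
    columns ``reaction_id  pathway``; repeated reaction rows accumulate labels.

Exchange reactions are oriented so that positive flux is secretion and
negative flux is uptake; each has a single stoichiometric entry of -1 on an
external metabolite.  Exactly one reaction carries the ``biomass`` role; its
consumed metabolites define the biomass precursor demands.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

ROLE_METABOLIC = "metabolic"
ROLE_EXCHANGE = "exchange"
ROLE_BIOMASS = "biomass"
_ROLES = (ROLE_METABOLIC, ROLE_EXCHANGE, ROLE_BIOMASS)


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------
class ModelError(Exception):
    """Base class for model construction and validation errors."""


class DuplicateIdentifierError(ModelError):
    """A metabolite or reaction identifier occurs more than once."""


class UnknownMetaboliteError(ModelError):
    """An equation or environment references a metabolite not in the table."""


class UnknownReactionError(ModelError):
    """An annotation references a reaction not in the universe."""


class MalformedEquationError(ModelError):
    """An equation string does not follow the grammar."""


class MissingBiomassError(ModelError):
    """The universe declares no biomass reaction."""


class MultipleBiomassError(ModelError):
    """The universe declares more than one biomass reaction."""


class InvalidExchangeError(ModelError):
    """An exchange reaction violates the single-external-entry convention."""


class InvalidEnvironmentError(ModelError):
    """An environment imports a metabolite that is not external."""


class EmptyTableError(ModelError):
    """A required input table contains no data rows."""


class ValidationError(ModelError):
    """A structural invariant of the universe is violated."""


# --------------------------------------------------------------------------
# equation grammar
# --------------------------------------------------------------------------
_COEF_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def parse_equation(equation: str):
    """Parse ``"2 A + B <=> C"`` into (substrates, products, reversible).

    Substrates/products are lists of ``(coefficient, metabolite_id)`` with
    positive coefficients; direction is encoded by side membership.
    """
    if " <=> " in equation:
        left, right = equation.split(" <=> ", 1)
        reversible = True
    elif equation.endswith(" <=>"):
        left, right, reversible = equation[: -len(" <=>")], "", True
    elif " => " in equation:
        left, right = equation.split(" => ", 1)
        reversible = False
    elif equation.endswith(" =>"):
        left, right, reversible = equation[: -len(" =>")], "", False
    else:
        raise MalformedEquationError(f"no arrow in equation: {equation!r}")

    def side(text: str):
        text = text.strip()
        if not text:
            return []
        terms = []
        for chunk in text.split(" + "):
            m = _COEF_RE.match(chunk.strip())
            if not m:
                raise MalformedEquationError(f"bad term {chunk!r} in {equation!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            if coef <= 0:
                raise MalformedEquationError(f"non-positive coefficient in {equation!r}")
            terms.append((coef, m.group(2)))
        return terms

    return side(left), side(right), reversible


def format_equation(substrates, products, reversible: bool) -> str:
    """Inverse of :func:`parse_equation`, with canonical term order."""

    def fmt(terms):
        parts = []
        for coef, met in sorted(terms, key=lambda t: t[1]):
            if coef == 1:
                parts.append(met)
            elif coef == int(coef):
                parts.append(f"{int(coef)} {met}")
            else:
                parts.append(f"{coef:.12g} {met}")
        return " + ".join(parts)

    arrow = "<=>" if reversible else "=>"
    left, right = fmt(substrates), fmt(products)
    if right:
        return f"{left} {arrow} {right}"
    return f"{left} {arrow}"


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class Environment:
    """One minimal medium: the set of external metabolites open for uptake."""

    label: str
    importable: frozenset

    def __post_init__(self):
        object.__setattr__(self, "importable", frozenset(self.importable))


@dataclass(frozen=True)
class Genotype:
    """A bit vector over the universe's reactions; ``n`` counts present reactions."""

    bits: np.ndarray

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=bool)
        bits.setflags(write=False)
        object.__setattr__(self, "bits", bits)

    @property
    def n(self) -> int:
        return int(self.bits.sum())

    def key(self) -> bytes:
        """Hashable chain-memoisation key."""
        return np.packbits(self.bits).tobytes()

    def present_indices(self) -> np.ndarray:
        return np.nonzero(self.bits)[0]

    def __eq__(self, other):
        return isinstance(other, Genotype) and np.array_equal(self.bits, other.bits)

    def __hash__(self):
        return hash(self.key())


class AnnotationMap:
    """reaction_id -> non-empty set of pathway labels."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map = {}
        for rid, labels in mapping.items():
            labels = frozenset(labels)
            if not labels:
                raise EmptyTableError(f"reaction {rid!r} has an empty label set")
            self._map[rid] = labels

    def __getitem__(self, rid: str) -> frozenset:
        return self._map[rid]

    def get(self, rid: str, default=frozenset()) -> frozenset:
        return self._map.get(rid, default)

    def __contains__(self, rid: str) -> bool:
        return rid in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def validate(self, universe: "ReactionUniverse") -> None:
        for rid in self._map:
            if rid not in universe.reaction_index:
                raise UnknownReactionError(f"annotated reaction {rid!r} not in universe")

    def __eq__(self, other):
        return isinstance(other, AnnotationMap) and self._map == other._map


@dataclass
class ReactionUniverse:
    """The global reaction set: stoichiometry, reversibility, roles, biomass demand."""

    metabolite_ids: tuple
    external: np.ndarray            # per-metabolite: may cross the boundary
    reaction_ids: tuple
    S: sp.csc_matrix                # m x N stoichiometric matrix
    reversible: np.ndarray
    role: tuple                     # per-reaction: metabolic / exchange / biomass
    swappable: np.ndarray

    metabolite_index: dict = field(init=False, repr=False)
    reaction_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.metabolite_ids = tuple(self.metabolite_ids)
        self.reaction_ids = tuple(self.reaction_ids)
        self.role = tuple(self.role)
        self.external = np.asarray(self.external, dtype=bool)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.swappable = np.asarray(self.swappable, dtype=bool)
        self.S = sp.csc_matrix(self.S)
        self.metabolite_index = {m: i for i, m in enumerate(self.metabolite_ids)}
        self.reaction_index = {r: j for j, r in enumerate(self.reaction_ids)}

    # -- basic shape ----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def biomass_indices(self) -> np.ndarray:
        return np.array([j for j, r in enumerate(self.role) if r == ROLE_BIOMASS], dtype=int)

    @property
    def biomass_index(self) -> int:
        idx = self.biomass_indices
        if len(idx) == 0:
            raise MissingBiomassError("universe has no biomass reaction")
        if len(idx) > 1:
            raise MultipleBiomassError("universe has more than one biomass reaction")
        return int(idx[0])

    @property
    def exchange_mask(self) -> np.ndarray:
        return np.array([r == ROLE_EXCHANGE for r in self.role])

    @property
    def metabolic_mask(self) -> np.ndarray:
        return np.array([r == ROLE_METABOLIC for r in self.role])

    @property
    def biomass_precursors(self) -> dict:
        """precursor metabolite -> positive stoichiometric demand of the biomass reaction."""
        j = self.biomass_index
        col = self.S.getcol(j).tocoo()
        return {
            self.metabolite_ids[i]: -float(v)
            for i, v in zip(col.row, col.data)
            if v < 0
        }

    def exchanged_metabolite(self, j: int) -> str:
        col = self.S.getcol(j).tocoo()
        if col.nnz != 1:
            raise InvalidExchangeError(
                f"exchange reaction {self.reaction_ids[j]!r} has {col.nnz} stoichiometric entries"
            )
        return self.metabolite_ids[int(col.row[0])]

    # -- genotypes ------------------------------------------------------
    def fixed_pattern(self) -> np.ndarray:
        """Presence bits forced on every genotype (all non-swappable reactions)."""
        return ~self.swappable

    def full_genotype(self) -> Genotype:
        return Genotype(np.ones(self.n_reactions, dtype=bool))

    def genotype_from_reactions(self, reaction_ids: Iterable[str]) -> Genotype:
        bits = self.fixed_pattern().copy()
        for rid in reaction_ids:
            bits[self.reaction_index[rid]] = True
        return Genotype(bits)

    def check_genotype(self, genotype: Genotype) -> None:
        if len(genotype.bits) != self.n_reactions:
            raise ValidationError("genotype length does not match universe")
        if np.any(~genotype.bits & ~self.swappable):
            raise ValidationError("genotype clears a non-swappable reaction")

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if len(set(self.metabolite_ids)) != self.n_metabolites:
            raise DuplicateIdentifierError("duplicate metabolite identifiers")
        if len(set(self.reaction_ids)) != self.n_reactions:
            raise DuplicateIdentifierError("duplicate reaction identifiers")
        if self.S.shape != (self.n_metabolites, self.n_reactions):
            raise ValidationError("stoichiometric matrix shape mismatch")
        for r in self.role:
            if r not in _ROLES:
                raise ValidationError(f"unknown reaction role {r!r}")
        # exactly one biomass reaction (raises otherwise)
        bj = self.biomass_index
        if not self.biomass_precursors:
            raise ValidationError("biomass reaction consumes no precursors")
        for j, r in enumerate(self.role):
            if r == ROLE_EXCHANGE:
                met = self.exchanged_metabolite(j)
                if not self.external[self.metabolite_index[met]]:
                    raise InvalidExchangeError(
                        f"exchange {self.reaction_ids[j]!r} acts on internal metabolite {met!r}"
                    )
            if self.swappable[j] and r != ROLE_METABOLIC:
                raise ValidationError(
                    f"non-metabolic reaction {self.reaction_ids[j]!r} marked swappable"
                )
        del bj


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------
def _read_tsv(path: Path, expected_header: Sequence[str]):
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise EmptyTableError(f"{path} is empty")
    header = lines[0].split("\t")
    if header != list(expected_header):
        raise ModelError(f"{path}: expected header {expected_header}, got {header}")
    rows = [line.split("\t") for line in lines[1:] if line.strip()]
    if not rows:
        raise EmptyTableError(f"{path} has no data rows")
    return rows


def read_universe(path, dialect: str = "tsv") -> ReactionUniverse:
    """Read a universe from a model directory (tsv dialect) or an SBML file."""
    if dialect == "sbml":
        return _read_sbml(path)
    if dialect != "tsv":
        raise ModelError(f"unknown dialect {dialect!r}")
    path = Path(path)

    met_rows = _read_tsv(path / "metabolites.tsv", ("metabolite_id", "external"))
    metabolite_ids, external = [], []
    seen = set()
    for row in met_rows:
        if len(row) != 2:
            raise ModelError(f"metabolites.tsv: malformed row {row}")
        mid, ext = row
        if mid in seen:
            raise DuplicateIdentifierError(f"duplicate metabolite {mid!r}")
        seen.add(mid)
        metabolite_ids.append(mid)
        external.append(ext == "1")

    rxn_rows = _read_tsv(path / "reactions.tsv", ("reaction_id", "equation", "role", "swappable"))
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    reaction_ids, role, swappable, reversible = [], [], [], []
    rows_, cols_, data_ = [], [], []
    seen = set()
    for j, row in enumerate(rxn_rows):
        if len(row) != 4:
            raise ModelError(f"reactions.tsv: malformed row {row}")
        rid, eq, rrole, sw = row
        if rid in seen:
            raise DuplicateIdentifierError(f"duplicate reaction {rid!r}")
        seen.add(rid)
        if rrole not in _ROLES:
            raise ValidationError(f"reaction {rid!r}: unknown role {rrole!r}")
        subs, prods, rev = parse_equation(eq)
        net = {}
        for coef, met in subs:
            if met not in met_index:
                raise UnknownMetaboliteError(f"reaction {rid!r}: unknown metabolite {met!r}")
            net[met] = net.get(met, 0.0) - coef
        for coef, met in prods:
            if met not in met_index:
                raise UnknownMetaboliteError(f"reaction {rid!r}: unknown metabolite {met!r}")
            net[met] = net.get(met, 0.0) + coef
        for met, coef in net.items():
            if coef != 0.0:
                rows_.append(met_index[met])
                cols_.append(j)
                data_.append(coef)
        reaction_ids.append(rid)
        role.append(rrole)
        swappable.append(sw == "1")
        reversible.append(rev)

    S = sp.coo_matrix(
        (data_, (rows_, cols_)), shape=(len(metabolite_ids), len(reaction_ids))
    ).tocsc()
    universe = ReactionUniverse(
        metabolite_ids=metabolite_ids,
        external=np.array(external, dtype=bool),
        reaction_ids=reaction_ids,
        S=S,
        reversible=np.array(reversible, dtype=bool),
        role=role,
        swappable=np.array(swappable, dtype=bool),
    )
    universe.validate()
    return universe


def _universe_equation(universe: ReactionUniverse, j: int) -> str:
    col = universe.S.getcol(j).tocoo()
    subs, prods = [], []
    for i, v in zip(col.row, col.data):
        met = universe.metabolite_ids[int(i)]
        if v < 0:
            subs.append((-float(v), met))
        else:
            prods.append((float(v), met))
    return format_equation(subs, prods, bool(universe.reversible[j]))


def write_universe(universe: ReactionUniverse, path) -> None:
    """Write the canonical TSV form (rows sorted by identifier)."""
    universe.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    met_lines = ["metabolite_id\texternal"]
    for mid in sorted(universe.metabolite_ids):
        ext = universe.external[universe.metabolite_index[mid]]
        met_lines.append(f"{mid}\t{1 if ext else 0}")
    (path / "metabolites.tsv").write_text("\n".join(met_lines) + "\n")

    rxn_lines = ["reaction_id\tequation\trole\tswappable"]
    for rid in sorted(universe.reaction_ids):
        j = universe.reaction_index[rid]
        rxn_lines.append(
            f"{rid}\t{_universe_equation(universe, j)}\t{universe.role[j]}"
            f"\t{1 if universe.swappable[j] else 0}"
        )
    (path / "reactions.tsv").write_text("\n".join(rxn_lines) + "\n")


def read_annotations(path, universe: ReactionUniverse | None = None) -> AnnotationMap:
    rows = _read_tsv(Path(path), ("reaction_id", "pathway"))
    mapping: dict[str, set] = {}
    for row in rows:
        if len(row) != 2:
            raise ModelError(f"annotations: malformed row {row}")
        rid, pathway = row
        mapping.setdefault(rid, set()).add(pathway)
    annotations = AnnotationMap(mapping)
    if universe is not None:
        annotations.validate(universe)
    return annotations


def write_annotations(annotations: AnnotationMap, path) -> None:
    lines = ["reaction_id\tpathway"]
    for rid in sorted(dict(annotations.items())):
        for pathway in sorted(annotations[rid]):
            lines.append(f"{rid}\t{pathway}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_environments(path, universe: ReactionUniverse | None = None) -> list:
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list) or not raw:
        raise EmptyTableError(f"{path}: expected a non-empty list of environments")
    environments = []
    for entry in raw:
        env = Environment(label=entry["label"], importable=frozenset(entry["importable"]))
        if universe is not None:
            for met in env.importable:
                i = universe.metabolite_index.get(met)
                if i is None:
                    raise UnknownMetaboliteError(
                        f"environment {env.label!r}: unknown metabolite {met!r}"
                    )
                if not universe.external[i]:
                    raise InvalidEnvironmentError(
                        f"environment {env.label!r}: metabolite {met!r} is not external"
                    )
        environments.append(env)
    return environments


def write_environments(environments: Iterable[Environment], path) -> None:
    payload = [
        {"label": env.label, "importable": sorted(env.importable)} for env in environments
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_sbml(path) -> ReactionUniverse:
    """SBML import via the cobra stack; species boundaryCondition maps to external."""
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ModelError("SBML import requires the cobra package") from exc
    model = cobra.io.read_sbml_model(str(path))
    metabolite_ids = [m.id for m in model.metabolites]
    external = np.array(
        [bool(getattr(m, "boundary_condition", False)) or m.compartment in ("e", "ext")
         for m in model.metabolites]
    )
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    reaction_ids, role, swappable, reversible = [], [], [], []
    rows_, cols_, data_ = [], [], []
    objective_ids = {r.id for r in model.reactions if r.objective_coefficient}
    for j, rxn in enumerate(model.reactions):
        reaction_ids.append(rxn.id)
        if rxn.id in objective_ids:
            role.append(ROLE_BIOMASS)
        elif rxn.boundary:
            role.append(ROLE_EXCHANGE)
        else:
            role.append(ROLE_METABOLIC)
        swappable.append(role[-1] == ROLE_METABOLIC)
        reversible.append(rxn.reversibility)
        for met, coef in rxn.metabolites.items():
            rows_.append(met_index[met.id])
            cols_.append(j)
            data_.append(float(coef))
    S = sp.coo_matrix(
        (data_, (rows_, cols_)), shape=(len(metabolite_ids), len(reaction_ids))
    ).tocsc()
    universe = ReactionUniverse(
        metabolite_ids=metabolite_ids,
        external=external,
        reaction_ids=reaction_ids,
        S=S,
        reversible=np.array(reversible, dtype=bool),
        role=role,
        swappable=np.array(swappable, dtype=bool),
    )
    universe.validate()
    return universe
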