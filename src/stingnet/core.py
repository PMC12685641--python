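"""Kinetic-model data structures and rate-law evaluation.

A :class:`ReactionModel` is a compartmental reaction network: species with
initial abundances (dimensionless molecule counts; compartment volumes are
fixed at 1 so amount equals concentration), irreversible reactions with one
of three rate-law families, and optional pathway-membership tags used by the
crosstalk analysis.

Rate-law families
-----------------
mass_action        v = k * prod_i [R_i]^s_i          (association,
                                                      dissociation,
                                                      translocation)
michaelis_menten   v = Vmax * [S] / (Km + [S])       (enzymatic conversion)
hill               v = Vmax * [S]^n / (K^n + [S]^n)  (gene expression)

For Michaelis-Menten the driving species [S] is the single substrate
(reactant); for Hill it is the modifier that drives expression (typically a
transcription factor), falling back to a single reactant when no dynamic
modifier exists.  Hill with n = 1 reduces exactly to Michaelis-Menten with
Km = K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "CompartmentKind",
    "Compartment",
    "Species",
    "RateLawKind",
    "RateLaw",
    "Reaction",
    "ReactionModel",
    "Finding",
    "ModelDefinitionError",
    "UnknownRateLawError",
    "evaluate_rate",
    "rate_state_gradient",
    "rate_parameter_gradient",
    "driving_species",
    "validate_model",
    "mass_action",
    "michaelis_menten",
    "hill",
    "INITIAL_AMOUNT_BAND",
]

#: Expected abundance band for dynamic signaling species (molecules).
INITIAL_AMOUNT_BAND = (1e3, 1e6)


class ModelDefinitionError(ValueError):
    """A reaction or model is structurally ill-defined."""


class UnknownRateLawError(ModelDefinitionError):
    """Rate-law kind not one of the supported families."""


class CompartmentKind(str, Enum):
    CYTOPLASM = "cytoplasm"
    PLASMA_MEMBRANE = "plasma_membrane"
    NUCLEUS = "nucleus"
    ENDOPLASMIC_RETICULUM = "endoplasmic_reticulum"
    GOLGI = "golgi"
    ERGIC = "ergic"
    OTHER = "other"


@dataclass
class Compartment:
    id: str
    name: str
    kind: CompartmentKind = CompartmentKind.OTHER


@dataclass
class Species:
    """A pool of molecules in one compartment.

    Boundary species (``is_boundary=True``) are held constant during
    integration; they model gene loci and external inputs whose abundance is
    not a state variable.
    """

    id: str
    name: str
    compartment: str
    initial_amount: float
    is_boundary: bool = False


class RateLawKind(str, Enum):
    MASS_ACTION = "mass_action"
    MICHAELIS_MENTEN = "michaelis_menten"
    HILL = "hill"


#: Required parameter names per rate-law family.
_REQUIRED_PARAMS = {
    RateLawKind.MASS_ACTION: ("k",),
    RateLawKind.MICHAELIS_MENTEN: ("Vmax", "Km"),
    RateLawKind.HILL: ("Vmax", "K", "n"),
}


@dataclass
class RateLaw:
    kind: RateLawKind
    parameters: Dict[str, float]

    def __post_init__(self) -> None:
        self.kind = RateLawKind(self.kind)

    def require(self, name: str) -> float:
        try:
            return self.parameters[name]
        except KeyError:
            raise ModelDefinitionError(
                f"rate law {self.kind.value} missing parameter {name!r}"
            ) from None


def mass_action(k: float) -> RateLaw:
    return RateLaw(RateLawKind.MASS_ACTION, {"k": k})


def michaelis_menten(Vmax: float, Km: float) -> RateLaw:
    return RateLaw(RateLawKind.MICHAELIS_MENTEN, {"Vmax": Vmax, "Km": Km})


def hill(Vmax: float, K: float, n: float = 1.0) -> RateLaw:
    return RateLaw(RateLawKind.HILL, {"Vmax": Vmax, "K": K, "n": n})


@dataclass
class Reaction:
    """An irreversible reaction with typed kinetics.

    ``reactants``/``products`` are ``(species_id, stoichiometry)`` pairs;
    ``modifiers`` are species that influence the reaction (catalysts,
    transcription factors, gene templates) without being consumed.
    """

    id: str
    name: str
    reactants: List[Tuple[str, int]]
    products: List[Tuple[str, int]]
    rate_law: RateLaw
    modifiers: List[str] = field(default_factory=list)
    reversible: bool = False

    def species_ids(self) -> Set[str]:
        out = {sid for sid, _ in self.reactants}
        out |= {sid for sid, _ in self.products}
        out |= set(self.modifiers)
        return out


@dataclass
class ReactionModel:
    name: str
    compartments: List[Compartment]
    species: List[Species]
    reactions: List[Reaction]
    pathway_tags: Dict[str, Set[str]] = field(default_factory=dict)
    metadata: Dict[str, str] = field(default_factory=dict)

    # -- indexing -----------------------------------------------------------
    def species_index(self) -> Dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    # -- census -------------------------------------------------------------
    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def n_species(self) -> int:
        """Number of dynamic (non-boundary) species — the model's state
        variables.  Boundary entities (gene loci, constant inputs) are
        counted separately via :attr:`n_boundary_species`."""
        return sum(1 for s in self.species if not s.is_boundary)

    @property
    def n_boundary_species(self) -> int:
        return sum(1 for s in self.species if s.is_boundary)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    # -- parameters ---------------------------------------------------------
    def parameter_ids(self) -> List[str]:
        """Global parameter ids, ``<reaction id>:<name>``, in model order."""
        out = []
        for r in self.reactions:
            for pname in _REQUIRED_PARAMS[r.rate_law.kind]:
                out.append(f"{r.id}:{pname}")
        return out

    def get_parameter(self, pid: str) -> float:
        rid, pname = pid.rsplit(":", 1)
        return self.get_reaction(rid).rate_law.require(pname)

    def set_parameter(self, pid: str, value: float) -> None:
        rid, pname = pid.rsplit(":", 1)
        self.get_reaction(rid).rate_law.parameters[pname] = value

    # -- linear algebra views ------------------------------------------------
    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometric matrix (species x reactions).  Boundary
        species rows are all zero: their amounts never change."""
        idx = self.species_index()
        boundary = {s.id for s in self.species if s.is_boundary}
        N = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sid, st in r.reactants:
                if sid not in boundary:
                    N[idx[sid], j] -= st
            for sid, st in r.products:
                if sid not in boundary:
                    N[idx[sid], j] += st
        return N

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def copy(self) -> "ReactionModel":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- tabular exports ----------------------------------------------------
    def species_table(self):
        """Species as a DataFrame (id, name, compartment, initial_amount,
        is_boundary)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "id": s.id,
                    "name": s.name,
                    "compartment": s.compartment,
                    "initial_amount": s.initial_amount,
                    "is_boundary": s.is_boundary,
                }
                for s in self.species
            ]
        )

    def reaction_table(self):
        """Reactions as a DataFrame (id, name, rate-law kind, parameters)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "name": r.name,
                    "rate_law": r.rate_law.kind.value,
                    "parameters": ";".join(
                        f"{k}={v:g}" for k, v in sorted(r.rate_law.parameters.items())
                    ),
                }
                for r in self.reactions
            ]
        )


# ---------------------------------------------------------------------------
# rate evaluation


def driving_species(reaction: Reaction, boundary: Optional[Set[str]] = None) -> str:
    """The single species whose abundance drives a saturable rate law.

    Michaelis-Menten reads its substrate from the reactant list;
    gene-expression (Hill) reactions are driven by their dynamic modifier
    (the transcription factor), with gene-locus templates excluded via the
    boundary flag.  Exactly one candidate must exist.
    """
    boundary = boundary or set()
    kind = reaction.rate_law.kind
    reactant_ids = [sid for sid, _ in reaction.reactants]
    dyn_modifiers = [m for m in reaction.modifiers if m not in boundary]
    if kind == RateLawKind.HILL:
        candidates = dyn_modifiers or reactant_ids
    else:
        candidates = reactant_ids or dyn_modifiers
    if len(candidates) != 1:
        raise ModelDefinitionError(
            f"reaction {reaction.id!r}: {kind.value} needs exactly one driving "
            f"species, found {candidates!r}"
        )
    return candidates[0]


def evaluate_rate(
    reaction: Reaction,
    state: Mapping[str, float],
    boundary: Optional[Set[str]] = None,
) -> float:
    """Instantaneous reaction rate (mol/s) at the given state."""
    law = reaction.rate_law
    if law.kind == RateLawKind.MASS_ACTION:
        v = law.require("k")
        for sid, st in reaction.reactants:
            v *= state[sid] ** st
        return v
    if law.kind == RateLawKind.MICHAELIS_MENTEN:
        s = state[driving_species(reaction, boundary)]
        return law.require("Vmax") * s / (law.require("Km") + s)
    if law.kind == RateLawKind.HILL:
        s = state[driving_species(reaction, boundary)]
        n = law.require("n")
        K = law.require("K")
        if s <= 0.0:
            return 0.0
        sn = s**n
        return law.require("Vmax") * sn / (K**n + sn)
    raise UnknownRateLawError(f"unknown rate-law kind {law.kind!r}")


def rate_state_gradient(
    reaction: Reaction,
    state: Mapping[str, float],
    boundary: Optional[Set[str]] = None,
) -> Dict[str, float]:
    """dv/d[species] for every species the rate depends on."""
    law = reaction.rate_law
    grad: Dict[str, float] = {}
    if law.kind == RateLawKind.MASS_ACTION:
        k = law.require("k")
        for sid, st in reaction.reactants:
            # d/dx_i of k * prod x^s : handle x=0 without dividing by zero
            d = k * st * state[sid] ** (st - 1)
            for other, so in reaction.reactants:
                if other != sid:
                    d *= state[other] ** so
            grad[sid] = d
        return grad
    drv = driving_species(reaction, boundary)
    s = state[drv]
    if law.kind == RateLawKind.MICHAELIS_MENTEN:
        Vmax, Km = law.require("Vmax"), law.require("Km")
        grad[drv] = Vmax * Km / (Km + s) ** 2
        return grad
    if law.kind == RateLawKind.HILL:
        Vmax, K, n = law.require("Vmax"), law.require("K"), law.require("n")
        if s <= 0.0:
            # derivative at 0: n>1 -> 0; n==1 -> Vmax/K
            grad[drv] = Vmax / K if n == 1.0 else 0.0
            return grad
        sn, Kn = s**n, K**n
        grad[drv] = Vmax * n * s ** (n - 1.0) * Kn / (Kn + sn) ** 2
        return grad
    raise UnknownRateLawError(f"unknown rate-law kind {law.kind!r}")


def rate_parameter_gradient(
    reaction: Reaction,
    state: Mapping[str, float],
    boundary: Optional[Set[str]] = None,
) -> Dict[str, float]:
    """dv/d(parameter) keyed by local parameter name."""
    law = reaction.rate_law
    if law.kind == RateLawKind.MASS_ACTION:
        prod = 1.0
        for sid, st in reaction.reactants:
            prod *= state[sid] ** st
        return {"k": prod}
    drv = driving_species(reaction, boundary)
    s = state[drv]
    if law.kind == RateLawKind.MICHAELIS_MENTEN:
        Vmax, Km = law.require("Vmax"), law.require("Km")
        return {
            "Vmax": s / (Km + s),
            "Km": -Vmax * s / (Km + s) ** 2,
        }
    if law.kind == RateLawKind.HILL:
        Vmax, K, n = law.require("Vmax"), law.require("K"), law.require("n")
        if s <= 0.0:
            return {"Vmax": 0.0, "K": 0.0, "n": 0.0}
        sn, Kn = s**n, K**n
        denom = (Kn + sn) ** 2
        return {
            "Vmax": sn / (Kn + sn),
            "K": -Vmax * sn * n * K ** (n - 1.0) / denom,
            "n": Vmax * Kn * sn * (math.log(s) - math.log(K)) / denom,
        }
    raise UnknownRateLawError(f"unknown rate-law kind {law.kind!r}")


# ---------------------------------------------------------------------------
# validation


@dataclass
class Finding:
    severity: str  # "error" | "warning"
    where: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.where}: {self.message}"


def validate_model(model: ReactionModel) -> List[Finding]:
    """Structural checks.  Errors make a model unusable; warnings flag
    departures from the curated model's conventions (e.g. initial amounts
    outside the 10^3-10^6 molecules band)."""
    findings: List[Finding] = []
    err = lambda where, msg: findings.append(Finding("error", where, msg))
    warn = lambda where, msg: findings.append(Finding("warning", where, msg))

    comp_ids = [c.id for c in model.compartments]
    if len(set(comp_ids)) != len(comp_ids):
        err("compartments", "duplicate compartment ids")
    sp_ids = [s.id for s in model.species]
    if len(set(sp_ids)) != len(sp_ids):
        err("species", "duplicate species ids")
    known = set(sp_ids)
    comp_known = set(comp_ids)
    boundary = {s.id for s in model.species if s.is_boundary}

    lo, hi = INITIAL_AMOUNT_BAND
    for s in model.species:
        if s.compartment not in comp_known:
            err(s.id, f"unknown compartment {s.compartment!r}")
        if s.initial_amount < 0:
            err(s.id, "negative initial amount")
        elif not s.is_boundary and not (lo <= s.initial_amount <= hi):
            warn(s.id, f"initial amount {s.initial_amount:g} outside 10^3-10^6 band")

    rx_ids = [r.id for r in model.reactions]
    if len(set(rx_ids)) != len(rx_ids):
        err("reactions", "duplicate reaction ids")
    for r in model.reactions:
        missing = sorted(r.species_ids() - known)
        if missing:
            err(r.id, f"unresolved species ids: {missing}")
        if not r.products:
            err(r.id, "reaction has no products")
        for st_list, label in ((r.reactants, "reactant"), (r.products, "product")):
            for sid, st in st_list:
                if st < 1:
                    err(r.id, f"non-positive {label} stoichiometry for {sid!r}")
        for pname, value in r.rate_law.parameters.items():
            if not (value > 0) or not math.isfinite(value):
                err(r.id, f"non-positive parameter {pname}={value!r}")
        for pname in _REQUIRED_PARAMS.get(r.rate_law.kind, ()):
            if pname not in r.rate_law.parameters:
                err(r.id, f"missing {r.rate_law.kind.value} parameter {pname!r}")
        if r.rate_law.kind in (RateLawKind.MICHAELIS_MENTEN, RateLawKind.HILL):
            if not missing:
                try:
                    driving_species(r, boundary)
                except ModelDefinitionError as e:
                    err(r.id, str(e))
    for sid in model.pathway_tags:
        if sid not in known:
            err("pathway_tags", f"tag for unknown species {sid!r}")
    return findings
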