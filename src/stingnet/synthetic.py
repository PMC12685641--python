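"""Seeded generators of random kinetic models and graphs.

The model generator emulates the structural statistics the analyses assume:
multiple compartments, a mix of mass-action / Michaelis-Menten / Hill rate
laws, initial abundances drawn log-uniformly from the 10^3-10^6 molecules
band, and a connected reaction graph guaranteed by a spanning construction
(every species is wired into the network in the order it first appears).
Determinism under the seed is the master invariant: the same spec always
yields an identical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import networkx as nx
import numpy as np

from .core import (
    Compartment,
    CompartmentKind,
    RateLawKind,
    Reaction,
    ReactionModel,
    Species,
    hill,
    mass_action,
    michaelis_menten,
)
from .network import InteractionNetwork

__all__ = ["GeneratorSpec", "random_model", "perturb_model", "random_graph"]


def _r12(x: float) -> float:
    """Round to 12 significant digits so values survive SBML serialization
    (libsbml prints doubles with 15 significant digits)."""
    return float(f"{x:.12g}")


@dataclass
class GeneratorSpec:
    n_compartments: int = 3
    n_species: int = 12
    n_reactions: int = 16
    rate_law_mix: Tuple[float, float, float] = (0.6, 0.25, 0.15)
    initial_amount_range: Tuple[float, float] = (1e3, 1e6)
    k_range: Tuple[float, float] = (1e-4, 1.0)
    vmax_range: Tuple[float, float] = (1e2, 1e4)
    km_range: Tuple[float, float] = (1e3, 1e5)
    hill_n_choices: Tuple[float, ...] = (1.0, 2.0)
    #: chance that a mass-action reaction is a two-reactant binding step
    #: (0 gives pure conversion networks, which conserve total copy number)
    binding_probability: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_reactions < 1:
            raise ValueError("need at least 1 reaction")
        if self.n_compartments < 1:
            raise ValueError("need at least 1 compartment")
        if abs(sum(self.rate_law_mix) - 1.0) > 1e-9:
            raise ValueError("rate_law_mix proportions must sum to 1")


_KIND_CYCLE = [
    CompartmentKind.CYTOPLASM,
    CompartmentKind.NUCLEUS,
    CompartmentKind.PLASMA_MEMBRANE,
    CompartmentKind.ENDOPLASMIC_RETICULUM,
    CompartmentKind.GOLGI,
    CompartmentKind.ERGIC,
]


def random_model(spec: GeneratorSpec) -> ReactionModel:
    """Generate a random, validated, connected reaction model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.initial_amount_range

    compartments = [
        Compartment(f"c{i}", f"compartment {i}", _KIND_CYCLE[i % len(_KIND_CYCLE)])
        for i in range(spec.n_compartments)
    ]
    species = [
        Species(
            id=f"s{i:02d}",
            name=f"species {i}",
            compartment=f"c{rng.integers(spec.n_compartments)}",
            initial_amount=_r12(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        )
        for i in range(spec.n_species)
    ]

    def draw_kind() -> RateLawKind:
        u = rng.random()
        a, b, _ = spec.rate_law_mix
        if u < a:
            return RateLawKind.MASS_ACTION
        if u < a + b:
            return RateLawKind.MICHAELIS_MENTEN
        return RateLawKind.HILL

    def draw_law(kind: RateLawKind, n_reactants: int):
        if kind == RateLawKind.MASS_ACTION:
            k = np.exp(rng.uniform(*np.log(spec.k_range)))
            # second-order constants scaled down so rates stay comparable
            return mass_action(_r12(k / (1e4 ** (n_reactants - 1))))
        vmax = _r12(np.exp(rng.uniform(*np.log(spec.vmax_range))))
        km = _r12(np.exp(rng.uniform(*np.log(spec.km_range))))
        if kind == RateLawKind.MICHAELIS_MENTEN:
            return michaelis_menten(vmax, km)
        return hill(vmax, km, float(rng.choice(spec.hill_n_choices)))

    sids = [s.id for s in species]
    # spanning construction: species join the reachable set one at a time
    order = list(rng.permutation(spec.n_species))
    reached = [sids[order[0]]]
    unreached = [sids[i] for i in order[1:]]
    reactions = []
    for j in range(spec.n_reactions):
        kind = draw_kind()
        if unreached:
            # connect a new species: reachable reactant -> new product
            new = unreached.pop(0)
            if (kind == RateLawKind.MASS_ACTION and rng.random() < spec.binding_probability and len(reached) > 1):
                reactants = [
                    (str(x), 1) for x in rng.choice(reached, size=2, replace=False)
                ]
            else:
                reactants = [(str(rng.choice(reached)), 1)]
            products = [(new, 1)]
            reached.append(new)
        else:
            if kind == RateLawKind.MASS_ACTION and rng.random() < spec.binding_probability:
                reactants = [
                    (str(x), 1) for x in rng.choice(sids, size=2, replace=False)
                ]
            else:
                reactants = [(str(rng.choice(sids)), 1)]
            in_use = {sid for sid, _ in reactants}
            pool = [s for s in sids if s not in in_use]
            products = [(str(rng.choice(pool)), 1)]
        reactions.append(
            Reaction(
                id=f"r{j:02d}",
                name=f"{'+'.join(s for s, _ in reactants)} -> "
                f"{'+'.join(s for s, _ in products)}",
                reactants=reactants,
                products=products,
                rate_law=draw_law(kind, len(reactants)),
            )
        )

    return ReactionModel(
        name=f"synthetic model (seed {spec.seed})",
        compartments=compartments,
        species=species,
        reactions=reactions,
        metadata={"generator_seed": str(spec.seed)},
    )


def perturb_model(
    model: ReactionModel, relative_scale: float, seed: int
) -> ReactionModel:
    """Multiply every rate parameter by exp(u), u ~ U(-scale, +scale).

    Structure, species and initial amounts are unchanged.
    """
    if not (0.0 < relative_scale < 1.0):
        raise ValueError("relative_scale must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = model.copy()
    out.name = f"{model.name} (perturbed)"
    for r in out.reactions:
        for pname in list(r.rate_law.parameters):
            u = rng.uniform(-relative_scale, relative_scale)
            r.rate_law.parameters[pname] = _r12(r.rate_law.parameters[pname] * np.exp(u))
    return out


def random_graph(n: int, p: float, seed: int) -> InteractionNetwork:
    """Erdos-Renyi undirected simple graph wrapped as a network."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    return InteractionNetwork.from_undirected(g, name=f"gnp(n={n}, p={p}, seed={seed})")
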