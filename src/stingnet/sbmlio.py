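"""SBML Level 3 Version 2 import/export for reaction models.

Kinetic laws are written as explicit MathML formulas with local parameters
(``k`` for mass action; ``Vmax``/``Km`` for Michaelis-Menten;
``Vmax``/``K``/``n`` for Hill).  The rate-law family, compartment kind and
pathway tags — which have no native SBML slot — ride along in notes
elements, so a write-then-read round trip reproduces the model exactly.
Reading a foreign SBML file classifies each kinetic law by its local
parameter names; anything outside the three supported families raises
:class:`UnsupportedConstructError` naming the reaction.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Set

import libsbml

from .core import (
    Compartment,
    CompartmentKind,
    RateLaw,
    RateLawKind,
    Reaction,
    ReactionModel,
    Species,
    driving_species,
    validate_model,
)

__all__ = ["read_model", "write_model", "SbmlParseError", "UnsupportedConstructError"]


class SbmlParseError(ValueError):
    """The file is not well-formed SBML."""


class UnsupportedConstructError(ValueError):
    """The SBML uses a construct outside the supported model family."""


_NOTE_BODY = '<body xmlns="http://www.w3.org/1999/xhtml"><p>{}</p></body>'


def _set_note(element, text: str) -> None:
    element.setNotes(_NOTE_BODY.format(text))


def _get_note(element) -> str:
    if not element.isSetNotes():
        return ""
    raw = element.getNotesString()
    # extract the first <p>...</p> payload
    start = raw.find("<p>")
    end = raw.find("</p>")
    return raw[start + 3 : end].strip() if 0 <= start < end else ""


def _formula(reaction: Reaction, boundary: Set[str]) -> str:
    law = reaction.rate_law
    if law.kind == RateLawKind.MASS_ACTION:
        terms = ["k"]
        for sid, st in reaction.reactants:
            terms.append(sid if st == 1 else f"{sid}^{st}")
        return " * ".join(terms)
    s = driving_species(reaction, boundary)
    if law.kind == RateLawKind.MICHAELIS_MENTEN:
        return f"Vmax * {s} / (Km + {s})"
    return f"Vmax * {s}^n / (K^n + {s}^n)"


def write_model(model: ReactionModel, path: str) -> None:
    """Serialize a validated model to an SBML L3V2 file."""
    errors = [f for f in validate_model(model) if f.severity == "error"]
    if errors:
        raise ValueError(f"model does not validate: {[str(e) for e in errors]}")
    doc = libsbml.SBMLDocument(3, 2)
    sm = doc.createModel()
    sm.setId("stingnet_model")
    sm.setName(model.name)
    if model.metadata:
        _set_note(sm, "metadata:" + "|".join(
            f"{k}={v}" for k, v in sorted(model.metadata.items())
        ))

    for comp in model.compartments:
        c = sm.createCompartment()
        c.setId(comp.id)
        c.setName(comp.name)
        c.setSize(1.0)
        c.setConstant(True)
        c.setSpatialDimensions(3)
        _set_note(c, f"kind:{comp.kind.value}")

    boundary = {s.id for s in model.species if s.is_boundary}
    for sp in model.species:
        s = sm.createSpecies()
        s.setId(sp.id)
        s.setName(sp.name)
        s.setCompartment(sp.compartment)
        s.setInitialAmount(float(sp.initial_amount))
        s.setBoundaryCondition(bool(sp.is_boundary))
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(True)
        tags = model.pathway_tags.get(sp.id)
        if tags:
            _set_note(s, "pathways:" + "|".join(sorted(tags)))

    for rx in model.reactions:
        r = sm.createReaction()
        r.setId(rx.id)
        r.setName(rx.name)
        r.setReversible(bool(rx.reversible))
        for sid, st in rx.reactants:
            ref = r.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(st))
            ref.setConstant(True)
        for sid, st in rx.products:
            ref = r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(st))
            ref.setConstant(True)
        for sid in rx.modifiers:
            ref = r.createModifier()
            ref.setSpecies(sid)
        kl = r.createKineticLaw()
        math = libsbml.parseL3Formula(_formula(rx, boundary))
        if math is None:
            raise UnsupportedConstructError(
                f"cannot encode rate law of reaction {rx.id!r}"
            )
        kl.setMath(math)
        for pname, value in rx.rate_law.parameters.items():
            lp = kl.createLocalParameter()
            lp.setId(pname)
            lp.setValue(float(value))
        _set_note(r, f"ratelaw:{rx.rate_law.kind.value}")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


_PARAM_SIGNATURES = {
    frozenset(["k"]): RateLawKind.MASS_ACTION,
    frozenset(["Vmax", "Km"]): RateLawKind.MICHAELIS_MENTEN,
    frozenset(["Vmax", "K", "n"]): RateLawKind.HILL,
}


def read_model(path: str) -> ReactionModel:
    """Parse an SBML file into a :class:`ReactionModel`."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        fatal = [
            doc.getError(i)
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        if fatal:
            msgs = "; ".join(
                f"line {e.getLine()}: {e.getMessage().strip()}" for e in fatal[:5]
            )
            raise SbmlParseError(f"malformed SBML in {path}: {msgs}")
    sm = doc.getModel()
    if sm is None:
        raise SbmlParseError(f"no model element in {path}")

    compartments = []
    for i in range(sm.getNumCompartments()):
        c = sm.getCompartment(i)
        note = _get_note(c)
        kind = CompartmentKind.OTHER
        if note.startswith("kind:"):
            try:
                kind = CompartmentKind(note[5:])
            except ValueError:
                pass
        compartments.append(Compartment(c.getId(), c.getName() or c.getId(), kind))

    species = []
    pathway_tags: Dict[str, Set[str]] = {}
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        species.append(
            Species(
                id=s.getId(),
                name=s.getName() or s.getId(),
                compartment=s.getCompartment(),
                initial_amount=float(s.getInitialAmount()),
                is_boundary=bool(s.getBoundaryCondition()),
            )
        )
        note = _get_note(s)
        if note.startswith("pathways:"):
            pathway_tags[s.getId()] = set(note[len("pathways:"):].split("|"))

    reactions = []
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        kl = r.getKineticLaw()
        if kl is None:
            raise UnsupportedConstructError(
                f"reaction {r.getId()!r} has no kinetic law"
            )
        params = {
            kl.getLocalParameter(j).getId(): kl.getLocalParameter(j).getValue()
            for j in range(kl.getNumLocalParameters())
        }
        note = _get_note(r)
        if note.startswith("ratelaw:"):
            try:
                kind = RateLawKind(note[len("ratelaw:"):])
            except ValueError:
                raise UnsupportedConstructError(
                    f"reaction {r.getId()!r}: unknown rate-law tag {note!r}"
                ) from None
        else:
            sig = _PARAM_SIGNATURES.get(frozenset(params))
            if sig is None:
                raise UnsupportedConstructError(
                    f"reaction {r.getId()!r}: cannot classify kinetic law with "
                    f"parameters {sorted(params)}"
                )
            kind = sig
        reactions.append(
            Reaction(
                id=r.getId(),
                name=r.getName() or r.getId(),
                reactants=[
                    (r.getReactant(j).getSpecies(), int(r.getReactant(j).getStoichiometry()))
                    for j in range(r.getNumReactants())
                ],
                products=[
                    (r.getProduct(j).getSpecies(), int(r.getProduct(j).getStoichiometry()))
                    for j in range(r.getNumProducts())
                ],
                modifiers=[
                    r.getModifier(j).getSpecies() for j in range(r.getNumModifiers())
                ],
                rate_law=RateLaw(kind, params),
                reversible=bool(r.getReversible()),
            )
        )

    metadata: Dict[str, str] = {}
    note = _get_note(sm)
    if note.startswith("metadata:"):
        for item in note[len("metadata:"):].split("|"):
            if "=" in item:
                k, v = item.split("=", 1)
                metadata[k] = v

    return ReactionModel(
        name=sm.getName() or sm.getId() or "model",
        compartments=compartments,
        species=species,
        reactions=reactions,
        pathway_tags=pathway_tags,
        metadata=metadata,
    )
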