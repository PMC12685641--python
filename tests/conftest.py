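"""Shared fixtures: the curated model and its (expensive) analysis artifacts
are computed once per session; tiny analytic models are built per test."""

from __future__ import annotations

import pytest

from stingnet import (
    Compartment,
    ReactionModel,
    Reaction,
    Species,
    build_nsclc_model,
    compute_fluxes,
    mass_action,
    model_to_network,
    simulate,
)
from stingnet.sensitivity import aggregate, local_sensitivities


@pytest.fixture(scope="session")
def nsclc_model():
    return build_nsclc_model()


@pytest.fixture(scope="session")
def nsclc_network(nsclc_model):
    return model_to_network(nsclc_model)


@pytest.fixture(scope="session")
def nsclc_trajectory(nsclc_model):
    return simulate(nsclc_model)


@pytest.fixture(scope="session")
def nsclc_score_matrix(nsclc_model):
    tensor = local_sensitivities(nsclc_model, inputs="parameters")
    return aggregate(tensor)


@pytest.fixture(scope="session")
def nsclc_flux(nsclc_model, nsclc_trajectory):
    return compute_fluxes(nsclc_model, nsclc_trajectory)


@pytest.fixture()
def decay_model():
    """Closed two-pool system A -> B with k = 0.5 and A(0) = 1000."""
    return ReactionModel(
        name="decay",
        compartments=[Compartment("c", "cell")],
        species=[
            Species("A", "A", "c", 1000.0),
            Species("B", "B", "c", 0.0),
        ],
        reactions=[
            Reaction("r1", "A -> B", [("A", 1)], [("B", 1)], mass_action(0.5)),
        ],
    )
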