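"""Quasi-potential landscape and model reduction."""

import numpy as np
import pytest

from stingnet import (
    Compartment,
    ReactionModel,
    Reaction,
    Species,
    mass_action,
    simulate,
)
from stingnet.flux import compute_fluxes
from stingnet.reduction import (
    ReductionCriteria,
    ReductionResult,
    combined_rank,
    quasi_potential_landscape,
    reduce_model,
    reduced_submodel,
)
from stingnet.sensitivity import aggregate, local_sensitivities

import pandas as pd


def make_result(n_keep, n_total):
    return ReductionResult(
        retained_reactions=[f"r{i}" for i in range(n_keep)],
        removed_reactions=[f"r{i}" for i in range(n_keep, n_total)],
        landscape=pd.DataFrame(),
    )


class TestReductionArithmetic:
    def test_twelve_of_eightythree_rounds_to_86_percent(self):
        assert make_result(12, 83).reduction_percent_rounded == 86

    def test_retain_all_is_zero(self):
        assert make_result(83, 83).reduction_percent_rounded == 0

    def test_retain_none_is_100(self):
        assert make_result(0, 83).reduction_percent_rounded == 100


@pytest.fixture(scope="module")
def curated_artifacts():
    from stingnet import build_nsclc_model

    model = build_nsclc_model()
    traj = simulate(model)
    score = aggregate(local_sensitivities(model, inputs="parameters"))
    flux = compute_fluxes(model, traj)
    return model, traj, score, flux


class TestLandscape:
    def test_single_reaction_model_has_one_point(self, decay_model):
        traj = simulate(decay_model, t_end=1.0)
        score = aggregate(
            local_sensitivities(decay_model, t_end=1.0, inputs="parameters")
        )
        flux = compute_fluxes(decay_model, traj)
        land = quasi_potential_landscape(decay_model, score, flux, traj)
        assert len(land) == 1

    def test_triple_argmax_reaction_is_apex(self, curated_artifacts):
        model, traj, score, flux = curated_artifacts
        land = quasi_potential_landscape(model, score, flux, traj)
        rank = combined_rank(land)
        best = rank.idxmin()
        # the apex has the best (smallest) mean rank by construction
        assert rank[best] == rank.min()

    def test_apex_region_contains_autophagosome_formation(self, curated_artifacts):
        model, traj, score, flux = curated_artifacts
        land = quasi_potential_landscape(model, score, flux, traj)
        rank = combined_rank(land).sort_values(kind="mergesort")
        top12 = set(rank.index[:12])
        lcatg_to_autoph = next(
            r.id for r in model.reactions
            if r.name == "LC3/ATG12/5/16L -> Autophagosome"
        )
        assert lcatg_to_autoph in top12


class TestReduceModel:
    def test_curated_default_criteria_retain_twelve(self, curated_artifacts):
        model, traj, score, flux = curated_artifacts
        res = reduce_model(model, trajectory=traj, score_matrix=score, flux_table=flux)
        assert len(res.retained_reactions) == 12
        assert res.reduction_percent_rounded == 86

    def test_reduction_monotone_in_max_retained(self, curated_artifacts):
        model, traj, score, flux = curated_artifacts
        pcts = []
        for k in (5, 12, 30, 83):
            res = reduce_model(
                model,
                ReductionCriteria(max_retained=k),
                trajectory=traj, score_matrix=score, flux_table=flux,
            )
            pcts.append(res.reduction_percent)
        assert pcts == sorted(pcts, reverse=True)

    def test_impossible_criteria_warn_not_raise(self, decay_model):
        res = reduce_model(
            decay_model,
            ReductionCriteria(flux_min=1e18, max_retained=None),
            t_end=1.0,
        )
        assert res.retained_reactions == []
        assert res.warnings

    def test_reduced_submodel_still_integrates(self, curated_artifacts):
        """Stability smoke test: the retained subsystem simulates cleanly
        (finite, non-negative) and its products' final amounts stay within a
        documented four-order-of-magnitude band of the full model — a loose
        no-blow-up/no-collapse bound, since pruning upstream sources
        necessarily shifts absolute levels."""
        model, traj, score, flux = curated_artifacts
        res = reduce_model(model, trajectory=traj, score_matrix=score, flux_table=flux)
        sub = reduced_submodel(model, res)
        sub_traj = simulate(sub)
        full_final = traj.states[-1]
        sub_final = sub_traj.states[-1]
        idx = model.species_index()
        products = {
            p
            for rid in res.retained_reactions
            for p, _ in model.get_reaction(rid).products
        }
        for sid in products:
            a, b = full_final[idx[sid]], sub_final[idx[sid]]
            assert np.isfinite(b) and b >= 0.0
            ratio = (a + 1.0) / (b + 1.0)
            assert 1e-4 <= ratio <= 1e4

    def test_bad_criteria_rejected(self):
        with pytest.raises(ValueError):
            ReductionCriteria(sensitivity_half_width=0.0)
        with pytest.raises(ValueError):
            ReductionCriteria(concentration_quantile=1.5)
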