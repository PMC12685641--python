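"""Quasi-potential landscape and model reduction.

Each reaction is placed in a three-axis landscape: its sensitivity score
(max rescaled aggregated sensitivity over its own rate parameters), its
kinetic flux, and the peak concentration of its first product.  The
dominant subsystem sits at the apex of this landscape — reactions that are
simultaneously high-flux, high-concentration and of near-unit (typical)
sensitivity.  Reduction retains reactions that pass all enabled per-axis
criteria or that rank in the top ``max_retained`` by combined rank (mean of
the three per-axis ranks), and reports the percentage of reactions removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .core import ReactionModel
from .flux import FluxTable, compute_fluxes
from .pca import run_pca
from .sensitivity import ScoreMatrix, aggregate, local_sensitivities
from .simulate import Trajectory, simulate

__all__ = [
    "ReductionCriteria",
    "ReductionResult",
    "quasi_potential_landscape",
    "reduce_model",
    "reduced_submodel",
]


@dataclass
class ReductionCriteria:
    """Per-axis retention thresholds.

    sensitivity_center/half_width: keep reactions whose rescaled sensitivity
    score lies within center +/- half_width (default: "close to one").
    flux_min: minimum flux in mol/s.
    concentration_quantile: the reaction's product peak must reach this
    quantile of all product peaks.
    max_retained: reactions in the top-k by combined rank are kept
    regardless of the per-axis tests.
    """

    sensitivity_center: float = 1.0
    sensitivity_half_width: float = 0.2
    flux_min: float = 500.0
    concentration_quantile: float = 0.85
    max_retained: Optional[int] = 12

    def __post_init__(self) -> None:
        if self.sensitivity_half_width <= 0:
            raise ValueError("sensitivity_half_width must be positive")
        if not (0.0 <= self.concentration_quantile <= 1.0):
            raise ValueError("concentration_quantile must lie in [0, 1]")


@dataclass
class ReductionResult:
    retained_reactions: List[str]
    removed_reactions: List[str]
    landscape: pd.DataFrame  # reaction_id, reaction, sensitivity, flux, concentration
    warnings: List[str] = field(default_factory=list)

    @property
    def reduction_percent(self) -> float:
        total = len(self.retained_reactions) + len(self.removed_reactions)
        return 100.0 * (1.0 - len(self.retained_reactions) / total) if total else 0.0

    @property
    def reduction_percent_rounded(self) -> int:
        return int(round(self.reduction_percent))


def _reaction_sensitivity_scores(
    model: ReactionModel, score_matrix: ScoreMatrix
) -> pd.Series:
    """Per-reaction sensitivity on the unit-median scale.

    A reaction's raw score is the maximum aggregated sensitivity over its
    own rate parameters (max over output species); scores are rescaled to
    unit median across reactions so "close to one" means "of typical
    leverage", mirroring the species-level PCA scale.
    """
    frame = score_matrix.to_frame()
    raw = {}
    for r in model.reactions:
        cols = [c for c in frame.columns if c.startswith(f"{r.id}:")]
        raw[r.id] = float(frame[cols].to_numpy().max()) if cols else 0.0
    s = pd.Series(raw)
    med = s.median()
    return s / med if med > 0 else s


def quasi_potential_landscape(
    model: ReactionModel,
    score_matrix: ScoreMatrix,
    flux_table: FluxTable,
    trajectory: Trajectory,
) -> pd.DataFrame:
    """One (sensitivity, flux, concentration) triple per reaction.

    Concentration is the time-maximum abundance of the reaction's first
    product.  All three inputs must derive from the same model.
    """
    flux = flux_table.fluxes()
    if set(flux.index) != {r.id for r in model.reactions}:
        raise ValueError("flux table does not match the model's reactions")
    if trajectory.species_ids != [s.id for s in model.species]:
        raise ValueError("trajectory does not match the model's species")
    sens = _reaction_sensitivity_scores(model, score_matrix)
    idx = model.species_index()
    peak = trajectory.states.max(axis=0)
    rows = []
    for r in model.reactions:
        first_product = r.products[0][0]
        rows.append(
            {
                "reaction_id": r.id,
                "reaction": r.name,
                "sensitivity": float(sens[r.id]),
                "flux": float(flux[r.id]),
                "concentration": float(peak[idx[first_product]]),
            }
        )
    return pd.DataFrame(rows)


def combined_rank(landscape: pd.DataFrame) -> pd.Series:
    """Mean of the three per-axis ranks (1 = best) per reaction."""
    ranks = pd.DataFrame(
        {
            axis: landscape[axis].rank(ascending=False, method="min").to_numpy()
            for axis in ("sensitivity", "flux", "concentration")
        },
        index=pd.Index(landscape["reaction_id"], name="reaction_id"),
    )
    return ranks.mean(axis=1)


def reduce_model(
    model: ReactionModel,
    criteria: Optional[ReductionCriteria] = None,
    *,
    trajectory: Optional[Trajectory] = None,
    score_matrix: Optional[ScoreMatrix] = None,
    flux_table: Optional[FluxTable] = None,
    t_end: float = 100.0,
) -> ReductionResult:
    """Select the dominant reaction subsystem.

    Any of the three analysis artifacts may be passed in; missing ones are
    recomputed (simulation, parameter sensitivities aggregated by L2 over
    time, final-time fluxes).
    """
    criteria = criteria or ReductionCriteria()
    if trajectory is None:
        trajectory = simulate(model, t_end=t_end)
    if score_matrix is None:
        tensor = local_sensitivities(model, t_end=t_end, inputs="parameters")
        score_matrix = aggregate(tensor)
    if flux_table is None:
        flux_table = compute_fluxes(model, trajectory)

    land = quasi_potential_landscape(model, score_matrix, flux_table, trajectory)
    lo = criteria.sensitivity_center - criteria.sensitivity_half_width
    hi = criteria.sensitivity_center + criteria.sensitivity_half_width
    conc_min = land["concentration"].quantile(criteria.concentration_quantile)
    passes = (
        land["sensitivity"].between(lo, hi)
        & (land["flux"] >= criteria.flux_min)
        & (land["concentration"] >= conc_min)
    )
    retained = set(land.loc[passes, "reaction_id"])
    if criteria.max_retained is not None:
        rank = combined_rank(land).sort_values(kind="mergesort")
        retained |= set(rank.index[: criteria.max_retained])

    all_ids = [r.id for r in model.reactions]
    kept = [rid for rid in all_ids if rid in retained]
    removed = [rid for rid in all_ids if rid not in retained]
    warnings = []
    if not kept:
        warnings.append("criteria retained zero reactions")
    return ReductionResult(
        retained_reactions=kept,
        removed_reactions=removed,
        landscape=land,
        warnings=warnings,
    )


def reduced_submodel(model: ReactionModel, result: ReductionResult) -> ReactionModel:
    """The model restricted to the retained reactions (species unchanged)."""
    keep = set(result.retained_reactions)
    sub = model.copy()
    sub.name = f"{model.name} (reduced)"
    sub.reactions = [r for r in sub.reactions if r.id in keep]
    return sub
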