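"""Deterministic stiff time-course integration of a reaction model.

The state equation is dx/dt = N v(x) with N the net stoichiometric matrix
and v the vector of reaction rates.  Boundary species (gene loci, constant
inputs) have zero rows in N and stay at their initial amounts.  Integration
uses an implicit multistep method (scipy's BDF), the standard choice for
stiff biochemical systems; tiny negative undershoots within the absolute
tolerance are clipped to zero after integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import (
    ReactionModel,
    evaluate_rate,
    rate_state_gradient,
    validate_model,
)

__all__ = ["Trajectory", "IntegrationError", "simulate", "final_state"]


class IntegrationError(RuntimeError):
    """The stiff solver failed to produce a valid trajectory."""


@dataclass
class Trajectory:
    model: ReactionModel
    time_grid: np.ndarray  # (T,)
    states: np.ndarray  # (T, n_species), model species order
    success: bool = True
    solver_message: str = ""
    n_steps: int = 0
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9

    @property
    def species_ids(self) -> List[str]:
        return [s.id for s in self.model.species]

    def series(self, species_id: str) -> np.ndarray:
        idx = self.model.species_index()[species_id]
        return self.states[:, idx]

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per time point, one column per species."""
        df = pd.DataFrame(self.states, columns=self.species_ids)
        df.insert(0, "time", self.time_grid)
        return df

    def to_tidy(self) -> pd.DataFrame:
        """Long table (time, species, amount)."""
        return self.to_frame().melt(
            id_vars="time", var_name="species", value_name="amount"
        )

    def net_change(self) -> pd.Series:
        """Final minus initial amount for every species."""
        delta = self.states[-1] - self.states[0]
        return pd.Series(delta, index=self.species_ids).sort_values(ascending=False)


def _state_map(model: ReactionModel, x: np.ndarray) -> Dict[str, float]:
    return dict(zip((s.id for s in model.species), x))


def make_rhs(model: ReactionModel):
    """Build vectorized rhs(t, x) and jac(t, x) closures for the model."""
    species = model.species
    idx = {s.id: i for i, s in enumerate(species)}
    boundary = {s.id for s in species if s.is_boundary}
    N = model.stoichiometry_matrix()
    reactions = model.reactions
    n = len(species)

    def rates(x: np.ndarray) -> np.ndarray:
        state = dict(zip((s.id for s in species), x))
        v = np.empty(len(reactions))
        for j, r in enumerate(reactions):
            v[j] = evaluate_rate(r, state, boundary)
        return v

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        xc = np.maximum(x, 0.0)  # guard against tiny undershoots mid-step
        v = rates(xc)
        if not np.all(np.isfinite(v)):
            bad = reactions[int(np.flatnonzero(~np.isfinite(v))[0])]
            raise IntegrationError(f"non-finite rate in reaction {bad.id!r} at t={t:g}")
        return N @ v

    def jac(t: float, x: np.ndarray) -> np.ndarray:
        xc = np.maximum(x, 0.0)
        state = dict(zip((s.id for s in species), xc))
        J = np.zeros((n, n))
        for j, r in enumerate(reactions):
            for sid, dv in rate_state_gradient(r, state, boundary).items():
                J[:, idx[sid]] += N[:, j] * dv
        return J

    return rhs, jac, rates


def simulate(
    model: ReactionModel,
    t_end: float = 100.0,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-9,
    n_out: int = 201,
) -> Trajectory:
    """Integrate the model over [0, t_end] seconds.

    Returns amounts on an evenly spaced output grid of ``n_out`` points.
    Raises :class:`IntegrationError` on solver failure or if any state
    undershoots below ``-abs_tol``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    errors = [f for f in validate_model(model) if f.severity == "error"]
    if errors:
        raise ValueError(f"model does not validate: {[str(e) for e in errors]}")
    rhs, jac, _ = make_rhs(model)
    t_eval = np.linspace(0.0, t_end, n_out)
    x0 = model.initial_state()
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        x0,
        method="BDF",
        jac=jac,
        rtol=rel_tol,
        atol=abs_tol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"stiff integration failed at t={sol.t[-1]:g}: {sol.message}")
    states = sol.y.T.copy()
    min_val = states.min()
    if min_val < -abs_tol * 100:
        t_bad, s_bad = np.unravel_index(np.argmin(states), states.shape)
        raise IntegrationError(
            f"state {model.species[s_bad].id!r} fell to {min_val:g} "
            f"at t={t_eval[t_bad]:g}"
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(
        model=model,
        time_grid=t_eval,
        states=states,
        success=True,
        solver_message=str(sol.message),
        n_steps=int(sol.t.size),
        rel_tol=rel_tol,
        abs_tol=abs_tol,
    )


def final_state(trajectory: Trajectory) -> Dict[str, float]:
    """Species amounts at the last time point."""
    if not trajectory.success:
        raise IntegrationError("trajectory did not complete successfully")
    return _state_map(trajectory.model, trajectory.states[-1])
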