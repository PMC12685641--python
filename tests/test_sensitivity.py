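"""Forward sensitivities against analytic solutions, finite differences and
the matrix exponential; aggregation oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

from stingnet import (
    Compartment,
    GeneratorSpec,
    ReactionModel,
    Reaction,
    Species,
    mass_action,
    perturb_model,
    random_model,
    simulate,
)
from stingnet.sensitivity import (
    SensitivityTensor,
    aggregate,
    local_sensitivities,
)


def two_pool(k=1.0, x0=1.0):
    return ReactionModel(
        name="decay",
        compartments=[Compartment("c", "c")],
        species=[Species("A", "A", "c", x0), Species("B", "B", "c", 0.0)],
        reactions=[Reaction("r1", "A->B", [("A", 1)], [("B", 1)], mass_action(k))],
    )


def fd_check(model, t_end=3.0, rel_step=1e-4, tol=1e-4):
    """Central finite differences vs forward sensitivities on every input.

    Agreement is demanded to ``tol`` relative, with a columnwise absolute
    floor of ``tol`` times the column maximum so that entries that are
    numerically zero on the problem scale (abundances of 10^3-10^6
    molecules) do not trip on finite-difference roundoff.  The step is
    ``rel_step`` times the input value; central differencing at 1e-4
    balances truncation against subtraction noise at these magnitudes.
    """
    sens = local_sensitivities(
        model, t_end=t_end, inputs="all", normalization="none", n_out=13
    )

    def finals(m):
        return simulate(m, t_end=t_end, rel_tol=1e-10, abs_tol=1e-12, n_out=13).states

    for j, pid in enumerate(sens.inputs):
        m = model.copy()
        if pid.startswith("x0:"):
            sid = pid[3:]
            v = m.get_species(sid).initial_amount
            h = rel_step * v if v else rel_step
            m.get_species(sid).initial_amount = v + h
            up = finals(m)
            m.get_species(sid).initial_amount = v - h
            down = finals(m)
        else:
            v = m.get_parameter(pid)
            h = rel_step * v
            m.set_parameter(pid, v + h)
            up = finals(m)
            m.set_parameter(pid, v - h)
            down = finals(m)
        fd = (up - down) / (2 * h)
        analytic = sens.values[:, :, j]
        colmax = max(float(np.abs(analytic).max()), 1e-12)
        excess = np.abs(fd - analytic) - (tol * np.abs(analytic) + tol * colmax)
        assert excess.max() <= 0.0, (
            f"finite-difference mismatch for {pid}: "
            f"{float(excess.max() / colmax):.2e} beyond tolerance"
        )


class TestAnalytic:
    def test_decay_parameter_sensitivity(self):
        # x' = -k x  =>  dx/dk(t) = -t x0 e^{-kt}
        tensor = local_sensitivities(
            two_pool(), t_end=1.0, inputs="parameters", normalization="none",
            n_out=11,
        )
        iA = tensor.outputs.index("A")
        ik = tensor.inputs.index("r1:k")
        assert tensor.values[-1, iA, ik] == pytest.approx(-np.exp(-1.0), abs=1e-5)

    def test_decoupled_species_have_zero_cross_sensitivity(self):
        model = ReactionModel(
            name="pair",
            compartments=[Compartment("c", "c")],
            species=[
                Species("A", "A", "c", 10.0),
                Species("A2", "A2", "c", 0.0),
                Species("B", "B", "c", 10.0),
                Species("B2", "B2", "c", 0.0),
            ],
            reactions=[
                Reaction("ra", "A->A2", [("A", 1)], [("A2", 1)], mass_action(0.7)),
                Reaction("rb", "B->B2", [("B", 1)], [("B2", 1)], mass_action(0.3)),
            ],
        )
        tensor = local_sensitivities(
            model, t_end=2.0, inputs="parameters", normalization="none", n_out=9
        )
        iA = tensor.outputs.index("A")
        jkb = tensor.inputs.index("rb:k")
        assert np.allclose(tensor.values[:, iA, jkb], 0.0, atol=1e-10)

    def test_linear_system_x0_sensitivities_equal_matrix_exponential(self):
        # A -> B (k1), B -> A (k2): S_x0(t) is exactly expm(M t)
        k1, k2 = 0.8, 0.3
        model = ReactionModel(
            name="reversible-pair",
            compartments=[Compartment("c", "c")],
            species=[Species("A", "A", "c", 5.0), Species("B", "B", "c", 2.0)],
            reactions=[
                Reaction("r1", "A->B", [("A", 1)], [("B", 1)], mass_action(k1)),
                Reaction("r2", "B->A", [("B", 1)], [("A", 1)], mass_action(k2)),
            ],
        )
        tensor = local_sensitivities(
            model, t_end=2.0, inputs="initial_amounts", normalization="none",
            n_out=5,
        )
        M = np.array([[-k1, k2], [k1, -k2]])
        for ti, t in enumerate(tensor.time_grid):
            assert np.allclose(tensor.values[ti], expm(M * t), atol=1e-7)


class TestFiniteDifferenceOracle:
    @pytest.mark.parametrize("seed", [0, 3, 8, 21])
    def test_random_models_match_finite_differences(self, seed):
        model = random_model(GeneratorSpec(n_species=7, n_reactions=9, seed=seed))
        fd_check(model)

    def test_perturbed_model_matches_finite_differences(self):
        base = random_model(GeneratorSpec(n_species=6, n_reactions=8, seed=4))
        fd_check(perturb_model(base, relative_scale=0.3, seed=11))


class TestAggregate:
    def make_tensor(self, values, t):
        T, m, n = values.shape
        return SensitivityTensor(
            time_grid=t,
            outputs=[f"o{i}" for i in range(m)],
            inputs=[f"p{j}" for j in range(n)],
            values=values,
        )

    def test_zero_tensor_aggregates_to_zero(self):
        t = np.linspace(0, 1, 11)
        tensor = self.make_tensor(np.zeros((11, 2, 3)), t)
        assert np.all(aggregate(tensor).A == 0.0)

    def test_constant_sensitivity_time_integral(self):
        t = np.linspace(0, 4.0, 41)
        tensor = self.make_tensor(np.full((41, 1, 1), 2.5), t)
        A = aggregate(tensor, "time_integral_abs").A
        assert A[0, 0] == pytest.approx(10.0)

    def test_l2_matches_quadrature_for_decay_sensitivity(self):
        # S(t) = t e^{-t}: L2 over [0,1] is sqrt(int (t e^{-t})^2 dt)
        t = np.linspace(0, 1, 2001)
        tensor = self.make_tensor((t * np.exp(-t)).reshape(-1, 1, 1), t)
        expected = np.sqrt(quad(lambda x: (x * np.exp(-x)) ** 2, 0, 1)[0])
        assert aggregate(tensor, "L2_over_time").A[0, 0] == pytest.approx(
            expected, rel=1e-6
        )

    def test_final_time_aggregation(self):
        t = np.linspace(0, 1, 5)
        vals = np.linspace(-4, 0, 5).reshape(-1, 1, 1)
        assert aggregate(self.make_tensor(vals, t), "final_time").A[0, 0] == 0.0

    def test_empty_tensor_rejected(self):
        tensor = self.make_tensor(np.zeros((0, 0, 0)), np.array([]))
        with pytest.raises(ValueError):
            aggregate(tensor)
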