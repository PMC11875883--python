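"""The auxiliary-function gate, decay, mask-aware gates, and the cell step."""

import math

import numpy as np
import pytest

from lmdpnet.autodiff import Tensor
from lmdpnet.irlstm import (
    IRLSTMCell,
    IRLSTMState,
    VanillaLSTMCell,
    auxiliary_psi,
    reformulated_gate,
)

GRID = np.linspace(0.0, 1.0, 100001)


class TestAuxiliaryPsi:
    def test_zero_at_half(self):
        assert auxiliary_psi(0.5, math.pi) == pytest.approx(0.0, abs=1e-15)

    def test_quarter_value(self):
        assert auxiliary_psi(0.25, math.pi) == pytest.approx(-0.5 / math.pi, abs=1e-12)

    def test_odd_symmetry_about_half(self):
        assert auxiliary_psi(0.75, math.pi) == pytest.approx(0.5 / math.pi, abs=1e-12)

    def test_sign_matches_side_of_half(self):
        f = np.linspace(0.01, 0.99, 99)
        psi = auxiliary_psi(f, math.pi)
        assert np.all(np.sign(psi[np.abs(f - 0.5) > 1e-9])
                      == np.sign(f[np.abs(f - 0.5) > 1e-9] - 0.5))

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            auxiliary_psi(0.5, 0.0)

    def test_max_magnitude_is_half_beta_amplitude(self):
        # |psi| peaks at 1/(2*beta); at beta=pi this is ~0.1592, inside [-0.5, 0.5]
        m = np.abs(auxiliary_psi(GRID, math.pi)).max()
        assert m == pytest.approx(1.0 / (2.0 * math.pi), abs=1e-9)
        assert m <= 0.5


class TestReformulatedGate:
    def test_endpoints_fixed(self):
        assert reformulated_gate(0.0) == pytest.approx(0.0, abs=1e-15)
        assert reformulated_gate(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_quarter_value(self):
        assert reformulated_gate(0.25) == pytest.approx(0.25 - 0.5 / math.pi, abs=1e-9)

    def test_symmetric_about_half(self):
        g = reformulated_gate(GRID)
        assert np.max(np.abs(g + reformulated_gate(1.0 - GRID) - 1.0)) < 1e-12

    def test_bounded_on_unit_interval_at_minimal_beta(self):
        g = reformulated_gate(GRID, math.pi)
        assert g.min() >= -1e-12 and g.max() <= 1.0 + 1e-12

    def test_bound_violated_below_minimal_beta(self):
        g = reformulated_gate(GRID, 0.9 * math.pi)
        assert g.min() < -1e-6 or g.max() > 1.0 + 1e-6

    def test_monotone_iff_beta_at_least_pi(self):
        # g'(f) = 1 - (pi/beta) cos(2 pi f); min over [0,1] is 0 exactly at beta=pi
        dgrid = 1.0 - (math.pi / math.pi) * np.cos(2 * math.pi * GRID)
        assert dgrid.min() == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(reformulated_gate(GRID, math.pi)) >= -1e-12)
        below = 1.0 - (math.pi / (0.9 * math.pi)) * np.cos(2 * math.pi * GRID)
        assert below.min() < 0

    def test_sharpening_toward_extremes(self):
        g = reformulated_gate(GRID)
        assert np.all(np.abs(g - 0.5) >= np.abs(GRID - 0.5) - 1e-12)
        interior = (GRID > 1e-3) & (GRID < 1 - 1e-3) & (np.abs(GRID - 0.5) > 1e-3)
        assert np.all(np.abs(g[interior] - 0.5) > np.abs(GRID[interior] - 0.5))


@pytest.fixture
def cell():
    return IRLSTMCell(input_dim=3, mask_dim=3, delta_dim=2, hidden_dim=4, seed=0)


class TestDecay:
    def test_zero_weights_mean_no_decay(self, cell):
        h = Tensor(np.ones((1, 4)))
        h_hat, gamma = cell.decay_hidden(h, np.array([[5.0, 9.0]]))
        assert np.allclose(gamma.data, 1.0)  # weights initialize at zero
        assert np.allclose(h_hat.data, 1.0)

    def test_scalar_exponential_decay(self):
        c = IRLSTMCell(input_dim=1, mask_dim=1, delta_dim=1, hidden_dim=1, seed=0)
        c.W_gamma.data[:] = 1.0
        _, gamma = c.decay_hidden(Tensor(np.ones((1, 1))), np.array([[2.0]]))
        assert gamma.data[0, 0] == pytest.approx(math.exp(-2.0), abs=1e-12)

    def test_rectifier_branch_clamps_to_no_decay(self):
        c = IRLSTMCell(input_dim=1, mask_dim=1, delta_dim=1, hidden_dim=1, seed=0)
        c.W_gamma.data[:] = 1.0
        c.b_gamma.data[:] = -5.0
        _, gamma = c.decay_hidden(Tensor(np.ones((1, 1))), np.array([[0.0]]))
        assert gamma.data[0, 0] == pytest.approx(1.0)

    def test_negative_interval_rejected(self, cell):
        with pytest.raises(ValueError):
            cell.decay_hidden(Tensor(np.zeros((1, 4))), np.array([[-1.0, 0.0]]))


class TestGates:
    def test_all_zero_weights_give_half(self):
        c = IRLSTMCell(input_dim=2, mask_dim=2, delta_dim=2, hidden_dim=3, seed=0)
        for p in c.params:
            p.data[:] = 0.0
        g = c.compute_gates(np.zeros((1, 2)), Tensor(np.zeros((1, 3))), np.zeros((1, 2)))
        for t in (g.candidate, g.output, g.forget):
            assert np.allclose(t.data, 0.5)

    def test_mask_bit_flip_shifts_preactivation_by_column(self, cell):
        u = np.zeros((1, 3))
        h = Tensor(np.zeros((1, 4)))
        m0, m1 = np.zeros((1, 3)), np.zeros((1, 3))
        m1[0, 1] = 1.0
        f0 = cell.compute_gates(u, h, m0).forget.data
        f1 = cell.compute_gates(u, h, m1).forget.data
        pre0 = np.log(f0 / (1 - f0))
        pre1 = np.log(f1 / (1 - f1))
        assert np.allclose(pre1 - pre0, cell.W["f"]["m"].data[1], atol=1e-9)

    def test_outputs_strictly_inside_unit_interval(self, cell, rng):
        g = cell.compute_gates(rng.normal(size=(5, 3)),
                               Tensor(rng.normal(size=(5, 4))),
                               rng.integers(0, 2, (5, 3)).astype(float))
        for t in (g.candidate, g.output, g.forget):
            assert np.all(t.data > 0) and np.all(t.data < 1)


class TestCellStep:
    def test_zero_weight_closed_form(self):
        # all gates 0.5, candidate 0.5, c0=0: c1 = 0.25, h1 = 0.5*tanh(0.25)
        c = IRLSTMCell(input_dim=2, mask_dim=2, delta_dim=2, hidden_dim=3, seed=0)
        for p in c.params:
            p.data[:] = 0.0
        state, bundle = c.step(np.zeros((1, 2)), np.zeros((1, 2)),
                               np.zeros((1, 2)), c.initial_state(1))
        assert np.allclose(state.c.data, 0.25)
        assert np.allclose(state.h.data, 0.5 * math.tanh(0.25))
        assert np.allclose(bundle.forget_reformulated.data, 0.5)

    def test_full_retention_and_replacement_limits(self):
        c = IRLSTMCell(input_dim=1, mask_dim=1, delta_dim=1, hidden_dim=2, seed=0)
        prev = IRLSTMState(h=Tensor(np.zeros((1, 2))), c=Tensor(np.array([[3.0, -2.0]])))
        c.W["f"]["b"].data[:] = 30.0  # forget ~ 1, g(1) = 1
        state, _ = c.step(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)), prev)
        assert np.allclose(state.c.data, prev.c.data, atol=1e-9)
        c.W["f"]["b"].data[:] = -30.0  # forget ~ 0, g(0) = 0: full replacement
        state, bundle = c.step(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)), prev)
        assert np.allclose(state.c.data, bundle.candidate.data, atol=1e-9)

    def test_shape_mismatch_rejected(self, cell):
        with pytest.raises(ValueError):
            cell.step(np.zeros((1, 5)), np.zeros((1, 3)), np.zeros((1, 2)),
                      cell.initial_state(1))

    def test_hidden_state_initialized_with_zeros(self, cell):
        s = cell.initial_state(3)
        assert np.all(s.h.data == 0) and np.all(s.c.data == 0)

    def test_gradient_check_through_one_step(self):
        """Finite-difference check over every parameter of a cell step."""
        cell = IRLSTMCell(input_dim=2, mask_dim=2, delta_dim=2, hidden_dim=2, seed=3)
        # move the decay parameters off the rectifier kink at exactly zero,
        # where the subgradient and the central difference disagree
        r = np.random.default_rng(9)
        cell.W_gamma.data[:] = r.uniform(0.02, 0.1, cell.W_gamma.shape)
        cell.b_gamma.data[:] = 0.05
        u = np.array([[0.4, -0.2]])
        m = np.array([[1.0, 0.0]])
        d = np.array([[2.0, 5.0]])
        prev = IRLSTMState(h=Tensor(np.array([[0.3, -0.1]])),
                           c=Tensor(np.array([[0.2, 0.4]])))

        def loss_value():
            state, _ = cell.step(u, m, d, prev)
            return (state.h ** 2.0).sum() + (state.c ** 2.0).sum()

        loss = loss_value()
        for p in cell.params:
            p.grad = None
        loss.backward()
        eps = 1e-6
        for p in cell.params:
            grad = np.zeros_like(p.data) if p.grad is None else p.grad
            flat = p.data.reshape(-1)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_value().item()
                flat[i] = orig - eps
                down = loss_value().item()
                flat[i] = orig
                num = (up - down) / (2 * eps)
                got = grad.reshape(-1)[i]
                assert got == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestBaselineCells:
    def test_vanilla_ignores_masks_and_intervals(self, rng):
        c = VanillaLSTMCell(input_dim=3, hidden_dim=4, seed=1)
        u = rng.normal(size=(2, 3))
        s0 = c.initial_state(2)
        a, _ = c.step(u, np.zeros((2, 3)), np.zeros((2, 3)), s0)
        b, _ = c.step(u, np.ones((2, 3)), np.full((2, 3), 9.0), s0)
        assert np.array_equal(a.h.data, b.h.data)

    def test_coupled_variant_uses_one_minus_forget(self):
        c = VanillaLSTMCell(input_dim=1, hidden_dim=1, coupled=True, seed=0)
        c.W["f"]["b"].data[:] = 30.0
        prev = IRLSTMState(h=Tensor(np.zeros((1, 1))), c=Tensor(np.array([[2.0]])))
        state, _ = c.step(np.zeros((1, 1)), None, None, prev)
        assert state.c.data[0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_lstm_mask_is_irlstm_without_aux(self):
        c = IRLSTMCell(input_dim=1, mask_dim=1, delta_dim=1, hidden_dim=1,
                       use_aux=False, seed=0)
        _, bundle = c.step(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                           c.initial_state(1))
        assert np.array_equal(bundle.forget_reformulated.data, bundle.forget.data)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            IRLSTMCell(1, 1, 1, 1, beta=-1.0)
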