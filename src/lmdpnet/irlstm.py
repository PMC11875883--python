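"""Recurrent cells for irregular, partially observed sequences.

:class:`IRLSTMCell` implements the mask- and decay-aware cell: the previous
hidden state is attenuated by a decay weight computed from the per-element
time intervals, the masking vector enters every gate, and the forget gate
is passed through an auxiliary-function reformulation

    g(f) = f - sin(f pi) cos(f pi) / beta

which pushes gate outputs toward 0 or 1 while remaining bounded on [0, 1],
monotone (iff beta >= pi), and symmetric about 0.5.  beta = pi is the
minimal admissible value and the default.  The cell state is coupled:
c_t = g * c_{t-1} + (1 - g) * c_hat (no separate input gate), and the
candidate uses a sigmoid.

Baselines for ablations: :class:`VanillaLSTMCell` (standard uncoupled LSTM,
no masks, no decay) and ``IRLSTMCell(use_aux=False)`` ("LSTM-Mask": masks
and decay but the raw forget gate).  A ``coupled_f`` variant of the vanilla
cell (forget-coupled input gate, sigmoid candidate) is available via
``VanillaLSTMCell(coupled=True)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "IRLSTMState",
    "GateBundle",
    "auxiliary_psi",
    "reformulated_gate",
    "IRLSTMCell",
    "VanillaLSTMCell",
]


@dataclass
class IRLSTMState:
    h: Tensor
    c: Tensor


@dataclass
class GateBundle:
    candidate: Tensor
    output: Tensor
    forget: Tensor
    forget_reformulated: Tensor | None
    decay: Tensor | None


def auxiliary_psi(f, beta):
    """psi(f) = -sin(f pi) cos(f pi) / beta.

    Positive for f > 0.5, negative for f < 0.5, zero at f in {0, 0.5, 1}.
    Works on floats, numpy arrays, and autodiff tensors.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    return -(ad.sin(f * math.pi) * ad.cos(f * math.pi)) / beta


def reformulated_gate(f, beta: float = math.pi):
    """g(f) = f + psi(f); maps [0, 1] to [0, 1], monotone iff beta >= pi."""
    return f + auxiliary_psi(f, beta)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class IRLSTMCell:
    """Mask/decay-aware cell with the auxiliary-function forget gate.

    Parameters
    ----------
    input_dim : size of u_t.
    mask_dim : size of the masking vector entering the gates.
    delta_dim : size of the interval vector driving hidden decay.
    hidden_dim : hidden/cell state size.
    beta : auxiliary-function divisor (default pi; never trained).
    use_aux : apply the gate reformulation (False gives "LSTM-Mask").
    candidate_act : "sigmoid" (as specified) or "tanh" (conventional).
    """

    uses_masks = True

    def __init__(self, input_dim: int, mask_dim: int, delta_dim: int,
                 hidden_dim: int, beta: float = math.pi, use_aux: bool = True,
                 candidate_act: str = "sigmoid", seed: int = 0):
        if beta <= 0:
            raise ValueError("beta must be positive")
        self.input_dim, self.mask_dim, self.delta_dim = input_dim, mask_dim, delta_dim
        self.hidden_dim = hidden_dim
        self.beta = float(beta)
        self.use_aux = use_aux
        if candidate_act not in ("sigmoid", "tanh"):
            raise ValueError("candidate_act must be 'sigmoid' or 'tanh'")
        self.candidate_act = candidate_act
        rng = np.random.default_rng(seed)
        H = hidden_dim
        self.params = []

        def mat(rows, cols):
            p = ad.glorot(rng, rows, cols)
            self.params.append(p)
            return p

        def vec(shape):
            p = Tensor(np.zeros(shape), requires_grad=True)
            self.params.append(p)
            return p

        # decay starts disabled (gamma = 1); the weights learn how strongly
        # elapsed time should attenuate the hidden state
        self.W_gamma, self.b_gamma = vec((delta_dim, H)), vec(H)
        self.W = {}
        for gate in ("c", "o", "f"):
            self.W[gate] = {
                "u": mat(input_dim, H), "h": mat(H, H), "m": mat(mask_dim, H),
                "b": vec(H),
            }
        # standard positive forget-bias init: retain state early in training
        self.W["f"]["b"].data += 1.0

    # ------------------------------------------------------------------
    def initial_state(self, batch: int) -> IRLSTMState:
        # hidden state initialized with zeros
        return IRLSTMState(h=Tensor(np.zeros((batch, self.hidden_dim))),
                           c=Tensor(np.zeros((batch, self.hidden_dim))))

    def decay_hidden(self, h_prev: Tensor, delta):
        """gamma = exp(-max(0, W delta + b)); h_hat = h_prev * gamma."""
        delta = _as_tensor(delta)
        if np.any(delta.data < 0):
            raise ValueError("intervals must be nonnegative")
        gamma = ad.exp(-ad.relu(delta @ self.W_gamma + self.b_gamma))
        return h_prev * gamma, gamma

    def compute_gates(self, u, h_hat, m) -> GateBundle:
        """Candidate, output and forget gates, each sigma(Wu u + Wh h + Wm m + b)."""
        u, h_hat, m = _as_tensor(u), _as_tensor(h_hat), _as_tensor(m)
        if u.shape[-1] != self.input_dim or m.shape[-1] != self.mask_dim:
            raise ValueError("input/mask dimension mismatch")

        def gate(name, act):
            W = self.W[name]
            pre = u @ W["u"] + h_hat @ W["h"] + m @ W["m"] + W["b"]
            return act(pre)

        cand_act = ad.sigmoid if self.candidate_act == "sigmoid" else ad.tanh
        return GateBundle(
            candidate=gate("c", cand_act),
            output=gate("o", ad.sigmoid),
            forget=gate("f", ad.sigmoid),
            forget_reformulated=None,
            decay=None,
        )

    def step(self, u, m, delta, state: IRLSTMState):
        """One recurrence step: returns (new state, gate bundle)."""
        u = _as_tensor(u)
        if u.shape[-1] != self.input_dim:
            raise ValueError(
                f"input dim {u.shape[-1]} != configured {self.input_dim}"
            )
        h_hat, gamma = self.decay_hidden(state.h, delta)
        gates = self.compute_gates(u, h_hat, m)
        f = gates.forget
        g = reformulated_gate(f, self.beta) if self.use_aux else f
        c = g * state.c + (1.0 - g) * gates.candidate
        h = gates.output * ad.tanh(c)
        bundle = GateBundle(candidate=gates.candidate, output=gates.output,
                            forget=f, forget_reformulated=g, decay=gamma)
        return IRLSTMState(h=h, c=c), bundle

    def run_sequence(self, inputs, masks, deltas, state: IRLSTMState | None = None):
        """Apply the cell along time; returns (hidden list, final state)."""
        if state is None:
            state = self.initial_state(inputs[0].shape[0])
        hs = []
        for u, m, d in zip(inputs, masks, deltas):
            state, _ = self.step(u, m, d, state)
            hs.append(state.h)
        return hs, state


class VanillaLSTMCell:
    """Standard LSTM over u_t only: no mask terms, no interval decay.

    ``coupled=True`` replaces the separate input gate with (1 - f) and uses
    a sigmoid candidate, matching the pre-reformulation coupled update.
    """

    uses_masks = False

    def __init__(self, input_dim: int, hidden_dim: int, coupled: bool = False,
                 seed: int = 0):
        self.input_dim, self.hidden_dim = input_dim, hidden_dim
        self.coupled = coupled
        rng = np.random.default_rng(seed)
        H = hidden_dim
        self.params = []
        gates = ("c", "o", "f") if coupled else ("c", "o", "f", "i")
        self.W = {}
        for gate in gates:
            Wu = ad.glorot(rng, input_dim, H)
            Wh = ad.glorot(rng, H, H)
            b = Tensor(np.zeros(H), requires_grad=True)
            self.W[gate] = {"u": Wu, "h": Wh, "b": b}
            self.params.extend([Wu, Wh, b])

    def initial_state(self, batch: int) -> IRLSTMState:
        return IRLSTMState(h=Tensor(np.zeros((batch, self.hidden_dim))),
                           c=Tensor(np.zeros((batch, self.hidden_dim))))

    def step(self, u, m, delta, state: IRLSTMState):
        u = _as_tensor(u)

        def pre(name):
            W = self.W[name]
            return u @ W["u"] + state.h @ W["h"] + W["b"]

        o = ad.sigmoid(pre("o"))
        f = ad.sigmoid(pre("f"))
        if self.coupled:
            cand = ad.sigmoid(pre("c"))
            c = f * state.c + (1.0 - f) * cand
        else:
            cand = ad.tanh(pre("c"))
            i = ad.sigmoid(pre("i"))
            c = f * state.c + i * cand
        h = o * ad.tanh(c)
        bundle = GateBundle(candidate=cand, output=o, forget=f,
                            forget_reformulated=None, decay=None)
        return IRLSTMState(h=h, c=c), bundle

    def run_sequence(self, inputs, masks, deltas, state: IRLSTMState | None = None):
        if state is None:
            state = self.initial_state(inputs[0].shape[0])
        hs = []
        for u, m, d in zip(inputs, masks, deltas):
            state, _ = self.step(u, m, d, state)
            hs.append(state.h)
        return hs, state
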