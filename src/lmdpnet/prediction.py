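"""Next-visit prediction heads and the multi-task training objective.

The feature forecast is residual: x_hat_{t+1} = W_g h_t + u_t (feature part
of u only), so with zero weights the model falls back to persistence.  The
class head is a 3-way softmax over {CN, MCI, AD}.  The total objective is
the unweighted sum L_total = L_p + L_i + L_f of the progression
cross-entropy, the biomarker L1 imputation loss, and the representation
loss; L_p and L_i are restricted to visits where the ground truth is
observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "VisitPrediction",
    "LossReport",
    "PredictionHeads",
    "progression_loss",
    "imputation_loss",
    "total_loss",
]


@dataclass
class VisitPrediction:
    x_hat_next: Tensor
    y_prob_next: Tensor

    def __post_init__(self):
        p = self.y_prob_next.data
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
            raise ValueError("class probabilities must be nonnegative and sum to 1")


@dataclass
class LossReport:
    Lp: float
    Li: float
    Lf: float

    @property
    def Ltotal(self) -> float:
        return self.Lp + self.Li + self.Lf


class PredictionHeads:
    def __init__(self, hidden_dim: int, feature_dim: int, n_classes: int = 3,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.feature_dim = feature_dim
        self.W_g = ad.glorot(rng, hidden_dim, feature_dim)
        self.W_y = ad.glorot(rng, hidden_dim, n_classes)
        self.b_y = Tensor(np.zeros(n_classes), requires_grad=True)
        self.params = [self.W_g, self.W_y, self.b_y]

    def forecast_next(self, h: Tensor, u_features: Tensor) -> Tensor:
        """Residual forecast of the next visit's feature vector."""
        if u_features.shape[-1] != self.feature_dim:
            raise ValueError("feature dimension mismatch")
        return h @ self.W_g + u_features

    def classify_next(self, h: Tensor) -> Tensor:
        """Softmax class probabilities for the next visit."""
        return ad.exp(ad.log_softmax(h @ self.W_y + self.b_y, axis=-1))

    def predict(self, h: Tensor, u_features: Tensor) -> VisitPrediction:
        return VisitPrediction(x_hat_next=self.forecast_next(h, u_features),
                               y_prob_next=self.classify_next(h))


def progression_loss(y_prob, y_true_onehot, label_mask) -> Tensor:
    """Cross-entropy over visits with an observed diagnosis.

    ``y_prob``: (..., 3) predicted probabilities; ``y_true_onehot``: matching
    one-hot labels; ``label_mask``: (...,) observation indicator.  Unobserved
    labels contribute 0.
    """
    y_prob = y_prob if isinstance(y_prob, Tensor) else Tensor(y_prob)
    y = np.asarray(y_true_onehot, dtype=float)
    m = np.asarray(label_mask, dtype=float)
    logp = ad.log(y_prob + 1e-12)
    return -((logp * Tensor(y)).sum(axis=-1) * Tensor(m)).sum()


def imputation_loss(x_hat_bio, x_bio, bio_mask) -> Tensor:
    """L1 forecast error on biomarker slots, restricted to observed entries."""
    x_hat_bio = x_hat_bio if isinstance(x_hat_bio, Tensor) else Tensor(x_hat_bio)
    diff = x_hat_bio - Tensor(np.asarray(x_bio, dtype=float))
    return (diff.abs() * Tensor(np.asarray(bio_mask, dtype=float))).sum()


def total_loss(Lp, Li, Lf) -> LossReport:
    """Equal-weight sum of the three task losses (components retained)."""
    to_f = lambda v: v.item() if isinstance(v, Tensor) else float(v)
    return LossReport(Lp=to_f(Lp), Li=to_f(Li), Lf=to_f(Lf))
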