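"""Per-visit input assembly and mask-gated imputation.

The model input at visit t is u_t = [fused imaging mean | tabular features
| diagnosis one-hot].  Observed entries pass through; unobserved entries
are filled from the previous step's forecasts (u_hat), or from training
global means at the first visit where no forecast exists yet.  Masks are
binary, so every imputed entry is exactly one of {observed value, forecast,
global mean} - never a blend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["AssembledVisitInput", "assemble_visit", "impute_visit"]


def _lift(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


@dataclass
class AssembledVisitInput:
    """Observed input u_tilde and its slot-level mask for one visit (or batch)."""

    u_tilde: Tensor
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=float)
        if self.u_tilde.shape != self.mask.shape:
            raise ValueError(
                f"u_tilde shape {self.u_tilde.shape} != mask shape {self.mask.shape}"
            )


def assemble_visit(mu_fused, tab_features, diag_onehot, tab_mask, diag_mask,
                   latent_dim: int | None = None) -> AssembledVisitInput:
    """Concatenate [mu_fused, tabular, diagnosis one-hot] with slot masks.

    ``mu_fused`` may be None (no imaging observed at the visit): the imaging
    slots are zero-filled and their mask bits are 0.  The imaging mask bits
    broadcast the visit-level availability (1 iff any modality observed).
    Diagnosis one-hot must be zero where the diagnosis mask is 0.
    """
    tab = _lift(tab_features)
    diag = _lift(diag_onehot)
    batch_shape = tab.shape[:-1]
    if mu_fused is None:
        if latent_dim is None:
            raise ValueError("latent_dim required when no imaging is observed")
        img = Tensor(np.zeros(batch_shape + (latent_dim,)))
        img_mask = np.zeros(batch_shape + (latent_dim,))
    else:
        img = _lift(mu_fused)
        img_mask = np.ones(batch_shape + (img.shape[-1],))
    tab_mask = np.broadcast_to(np.asarray(tab_mask, dtype=float), tab.shape)
    diag_mask = np.asarray(diag_mask, dtype=float)
    diag_mask = np.broadcast_to(
        diag_mask[..., None] if diag_mask.ndim < diag.ndim else diag_mask, diag.shape
    )
    u_tilde = concat([img, tab, diag], axis=-1)
    mask = np.concatenate([img_mask, tab_mask, diag_mask], axis=-1)
    return AssembledVisitInput(u_tilde=u_tilde, mask=mask)


def impute_visit(assembled: AssembledVisitInput, u_hat, global_mean, t: int):
    """u_t = m * u_tilde + (1 - m) * fill.

    At the first visit (t == 1) the fill is the training global mean; later
    visits fill from the previous step's forecast ``u_hat``.  Observed
    entries always pass through unchanged.
    """
    if t < 1:
        raise ValueError("visit index t is 1-based")
    m = Tensor(assembled.mask)
    if t == 1:
        if global_mean is None:
            raise ValueError("global stats required to impute the first visit")
        fill = _lift(np.broadcast_to(np.asarray(global_mean, dtype=float),
                                     assembled.mask.shape))
    else:
        if u_hat is None:
            raise ValueError("previous-step prediction required for t > 1")
        fill = _lift(u_hat)
    return m * assembled.u_tilde + (1.0 - m) * fill
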