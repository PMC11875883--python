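"""Multimodal neuroimaging representation fusion (M3VAE).

Each imaging modality gets its own variational encoder producing a diagonal
Gaussian (mu, sigma) over a shared latent space.  For every nonzero subset
of the observed modalities the expert Gaussians are fused by a product of
experts: precisions add, the fused mean is the precision-weighted mean.  A
reparameterized sample from each fused Gaussian is pushed through every
modality decoder (cross-modal generation), and the representation loss Lf
sums reconstruction error over observed target modalities plus the KL of
each fused posterior to a standard-normal prior.

No universal prior expert is included in the product: only the observed
modalities contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "M3VAEConfig",
    "ModalityLatent",
    "FusedLatent",
    "M3VAE",
    "enumerate_subset_codes",
    "poe_fuse",
    "sample_fused",
    "kl_standard_normal",
]

_SIGMA_FLOOR = 1e-6


@dataclass
class M3VAEConfig:
    volume_shape: tuple = (16, 20, 16)
    n_modalities: int = 2
    latent_dim: int = 16
    hidden_dim: int = 256
    kl_form: str = "standard"  # or "as_printed" for the published variant
    recon_noise_std: float = 0.02  # observation noise of the Gaussian likelihood
    seed: int = 0


@dataclass
class ModalityLatent:
    """Diagonal-Gaussian posterior of one modality at one visit."""

    mu: Tensor
    sigma: Tensor  # standard deviation, strictly positive

    def __post_init__(self):
        if np.any(self.sigma.data <= 0) or not np.all(np.isfinite(self.sigma.data)):
            raise ValueError("sigma must be strictly positive and finite")


@dataclass
class FusedLatent:
    mu: Tensor
    sigma: Tensor
    code: str


def enumerate_subset_codes(n_modalities: int) -> list:
    """All nonzero binary modality-subset codes, lexicographically ordered.

    The leftmost character is modality 1 (MRI); '1' marks a contributing
    modality.  For two modalities: ['01', '10', '11'].
    """
    if n_modalities < 1:
        raise ValueError("need at least one modality")
    return [format(n, f"0{n_modalities}b") for n in range(1, 2**n_modalities)]


def poe_fuse(latents, mask) -> FusedLatent:
    """Product-of-experts fusion of the observed modality Gaussians.

    Precision T_c = sigma_c^-2; sigma_fused = (sum_c T_c)^-1/2 over observed
    experts; mu_fused = (sum_c mu_c T_c) sigma_fused^2.  Raises if no
    modality is observed (caller must skip fusion and mark the visit's
    imaging features missing).
    """
    mask = [int(b) for b in mask]
    if len(mask) != len(latents):
        raise ValueError("mask length must match number of modalities")
    if sum(mask) == 0:
        raise ValueError("no imaging observed: nothing to fuse")
    precision_sum = None
    weighted_mu = None
    for latent, bit in zip(latents, mask):
        if not bit:
            continue
        T = latent.sigma ** -2.0
        precision_sum = T if precision_sum is None else precision_sum + T
        wm = latent.mu * T
        weighted_mu = wm if weighted_mu is None else weighted_mu + wm
    sigma_fused = precision_sum ** -0.5
    mu_fused = weighted_mu * sigma_fused**2.0
    code = "".join(str(b) for b in mask)
    return FusedLatent(mu=mu_fused, sigma=sigma_fused, code=code)


def sample_fused(fused: FusedLatent, rng: np.random.Generator) -> Tensor:
    """Reparameterized draw z = mu + sigma * eps, eps ~ N(0, I).

    The noise is a constant, so gradients flow to mu and sigma.
    """
    eps = rng.standard_normal(fused.mu.shape)
    return fused.mu + fused.sigma * Tensor(eps)


def kl_standard_normal(mu: Tensor, sigma: Tensor, form: str = "standard") -> Tensor:
    """KL( N(mu, diag sigma^2) || N(0, I) ), summed over latent dimensions.

    ``form='standard'`` uses 0.5 * sum(mu^2 + sigma^2 - 2 ln sigma - 1);
    ``form='as_printed'`` evaluates the published 0.5 * sum(mu^2 + sigma
    - ln sigma - 1) variant (both vanish at mu=0, sigma=1).
    """
    if form == "standard":
        body = mu**2.0 + sigma**2.0 - 2.0 * ad.log(sigma) - 1.0
    elif form == "as_printed":
        body = mu**2.0 + sigma - ad.log(sigma) - 1.0
    else:
        raise ValueError(f"unknown KL form {form!r}")
    return (body * 0.5).sum()


class M3VAE:
    """Per-modality MLP encoders/decoders over flattened volumes."""

    def __init__(self, config: M3VAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        V = int(np.prod(config.volume_shape))
        H, L = config.hidden_dim, config.latent_dim
        self.params = []
        self.enc, self.dec = [], []
        for _ in range(config.n_modalities):
            # sigma head biased low at init: large initial posterior noise
            # drowns the mu signal and lets the decoders learn to ignore z
            sig0 = float(np.log(np.expm1(0.01)))  # softplus(sig0) = 0.01
            # mu head gets a wide init: the voxel-level signal is faint, and a
            # macroscopic latent spread at step 0 is what lets the decoders
            # latch onto z instead of settling for the mean volume
            Wmu = ad.glorot(rng, H, L)
            Wmu.data *= 10.0
            enc = {
                "W1": ad.glorot(rng, V, H), "b1": Tensor(np.zeros(H), requires_grad=True),
                "Wmu": Wmu, "bmu": Tensor(np.zeros(L), requires_grad=True),
                "Wsig": ad.glorot(rng, H, L), "bsig": Tensor(np.full(L, sig0), requires_grad=True),
            }
            dec = {
                "W1": ad.glorot(rng, L, H), "b1": Tensor(np.zeros(H), requires_grad=True),
                "W2": ad.glorot(rng, H, V), "b2": Tensor(np.zeros(V), requires_grad=True),
            }
            self.enc.append(enc)
            self.dec.append(dec)
            self.params.extend(enc.values())
            self.params.extend(dec.values())
        # per-modality encoder input centering (set from training data);
        # without it the static background drives aligned gradient steps
        # that saturate the hidden layer within one epoch
        self.input_mean = [np.zeros(V) for _ in range(config.n_modalities)]

    # ------------------------------------------------------------------
    def encode_modality(self, volumes, modality: int) -> ModalityLatent:
        """Encode a batch of volumes of one modality into (mu, sigma).

        ``volumes``: array of shape ``(batch, *volume_shape)`` or a single
        volume; sigma positivity comes from a softplus head.
        """
        x = np.asarray(volumes, dtype=float)
        single = x.shape == self.config.volume_shape
        if single:
            x = x[None]
        if x.shape[1:] != self.config.volume_shape:
            raise ValueError(
                f"volume shape {x.shape[1:]} != configured {self.config.volume_shape}"
            )
        e = self.enc[modality]
        centered = x.reshape(x.shape[0], -1) - self.input_mean[modality]
        h = ad.tanh(Tensor(centered) @ e["W1"] + e["b1"])
        mu = h @ e["Wmu"] + e["bmu"]
        sigma = ad.softplus(h @ e["Wsig"] + e["bsig"]) + _SIGMA_FLOOR
        if single:
            mu, sigma = mu[0], sigma[0]
        return ModalityLatent(mu=mu, sigma=sigma)

    def init_from_data(self, mean_volumes: dict) -> None:
        """Anchor encoders and decoders at the training-mean volumes.

        The encoder input is centered at the mean (so hidden pre-activations
        track image variation, not the static background) and each decoder's
        output layer is biased at the mean (so only the latent-driven
        modulation remains to learn).
        """
        for c, vol in mean_volumes.items():
            flat = np.asarray(vol, dtype=float).reshape(-1)
            self.input_mean[c] = flat.copy()
            p = np.clip(flat, 1e-4, 1 - 1e-4)
            self.dec[c]["b2"].data = np.log(p / (1.0 - p))

    def decode(self, z: Tensor, modality: int) -> Tensor:
        """Decode latent(s) to a volume batch with values in (0, 1)."""
        d = self.dec[modality]
        h = ad.tanh(z @ d["W1"] + d["b1"])
        return ad.sigmoid(h @ d["W2"] + d["b2"])

    def decode_all(self, z: Tensor, code: str) -> dict:
        """Apply every modality decoder to a subset's latent sample."""
        return {c: self.decode(z, c) for c in range(self.config.n_modalities)}

    def select_downstream_fused(self, latents, mask):
        """Fused mean for the subset matching exactly the observed pattern.

        Returns ``(mu, code)``, or ``(None, code_of_zeros)`` when no imaging
        is observed so the imputation path fills the slots instead.
        """
        mask = [int(b) for b in mask]
        code = "".join(str(b) for b in mask)
        if sum(mask) == 0:
            return None, code
        fused = poe_fuse(latents, mask)
        return fused.mu, fused.code

    # ------------------------------------------------------------------
    def representation_loss(self, visits, rng: np.random.Generator,
                            return_parts: bool = False):
        """Lf over a batch of visits.

        ``visits`` is a sequence of ``(volumes_by_modality, imaging_mask)``
        pairs; a visit contributes one term per nonzero subset of its
        observed modalities: the Gaussian reconstruction negative
        log-likelihood sum(err^2) / (2 * recon_noise_std^2) for each
        observed target modality, plus KL of the fused posterior to the
        standard-normal prior.  Visits with no imaging contribute nothing;
        an all-missing batch returns 0 with a warning.
        """
        total = Tensor(0.0)
        recon_total, kl_total = 0.0, 0.0
        any_obs = False
        for volumes, mask in visits:
            mask = [int(b) for b in mask]
            if sum(mask) == 0:
                continue
            any_obs = True
            latents = [
                self.encode_modality(volumes[c], c) if mask[c] else None
                for c in range(self.config.n_modalities)
            ]
            observed = [c for c in range(self.config.n_modalities) if mask[c]]
            for code in enumerate_subset_codes(self.config.n_modalities):
                bits = [int(b) for b in code]
                if any(b and not mask[c] for c, b in enumerate(bits)):
                    continue  # subset needs an unobserved source
                fused = poe_fuse([latents[c] if bits[c] else None for c in range(len(bits))],
                                 bits)
                z = sample_fused(fused, rng)
                recons = self.decode_all(z, code)
                for c in observed:  # only observed targets have ground truth
                    target = np.asarray(volumes[c], dtype=float).reshape(-1)
                    err = recons[c] - Tensor(target)
                    term = (err**2.0).sum() * (0.5 / self.config.recon_noise_std**2)
                    total = total + term
                    recon_total += term.item()
                kl = kl_standard_normal(fused.mu, fused.sigma, self.config.kl_form)
                total = total + kl
                kl_total += kl.item()
        if not any_obs:
            warnings.warn("no imaging observed in batch; representation loss is 0")
        if return_parts:
            return total, {"recon": recon_total, "kl": kl_total}
        return total
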