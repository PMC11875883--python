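"""Training protocol, cross-validation, metrics, and ablation designs.

The full model chains the modules end to end: imaging volumes are encoded
and fused by the product-of-experts VAE, the fused mean joins the tabular
features and diagnosis one-hot as the per-visit input, missing entries are
imputed from the previous step's forecasts (global means at the first
visit), the recurrent cell consumes (input, mask, intervals), and linear
heads emit the next visit's feature forecast and class probabilities.  The
objective is the equal-weight sum of progression cross-entropy, biomarker
L1 loss, and the VAE representation loss; Adam with learning rate 0.002.

Evaluation withholds every input after the anchor visit and rolls the model
forward autoregressively for K followup visits; only observed followup
labels and biomarkers are scored.  Folds are assigned at the patient level;
patients already diagnosed AD at baseline are always moved into the
training split of each fold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import data_model as dm
from .autodiff import Adam, Tensor, concat
from .imputation import AssembledVisitInput, impute_visit
from .irlstm import IRLSTMCell, VanillaLSTMCell
from .m3vae import (M3VAE, M3VAEConfig, enumerate_subset_codes,
                    kl_standard_normal, poe_fuse, sample_fused)
from .prediction import PredictionHeads, imputation_loss, progression_loss, total_loss

__all__ = [
    "TrainConfig",
    "MetricReport",
    "LMDPNet",
    "train_model",
    "evaluate",
    "evaluate_reconstruction",
    "cross_validate",
    "assign_folds",
    "run_ablation",
    "accuracy",
    "macro_precision_recall",
    "macro_auc",
    "psnr",
]


@dataclass
class TrainConfig:
    """Trainer settings; defaults follow the reference protocol."""

    learning_rate: float = 0.002
    optimizer: str = "adam"
    epochs: int = 30
    batch_size: int = 32
    hidden_dim: int = 128
    latent_dim: int = 16
    m3vae_hidden: int = 256
    beta: float = math.pi
    seed: int = 0
    k_followup: int = 5
    n_history: int = 0  # T - 1 past visits available at evaluation
    train_anchor: str = "fixed"  # "fixed" (= n_history) or "random"
    diagnosis_mask_prob: float = 1.0  # hide the anchor visit's diagnosis input
    n_folds: int = 5
    cell: str = "irlstm"  # irlstm | lstm_mask | lstm | lstm_coupled
    candidate_act: str = "sigmoid"
    use_imaging: bool = True
    modalities: tuple = ("mri", "pet")
    kl_form: str = "standard"
    recon_noise_std: float = 0.02  # observation noise of the imaging likelihood
    kl_warmup_epochs: int = 30  # linear KL annealing against posterior collapse
    loss_weights: tuple = (1.0, 1.0, 1.0)  # (Lp, Li, Lf); equal by default
    volume_shape: tuple = (16, 20, 16)

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("fold count must be >= 2")
        for name in ("learning_rate", "epochs", "batch_size", "hidden_dim", "latent_dim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MetricReport:
    """Classification, imputation and reconstruction metrics."""

    acc: float | None = None
    precision: float | None = None
    recall: float | None = None
    mauc: float | None = None
    mae_ml: float | None = None
    mre_pct: float | None = None
    psnr_db: float | None = None
    mse: float | None = None
    n_scored: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("acc", "precision", "recall", "mauc", "mae_ml", "mre_pct",
                 "psnr_db", "mse", "n_scored")}


# ----------------------------------------------------------------------
# metrics


def accuracy(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    return float((y_true == y_pred).mean())


def macro_precision_recall(y_true, y_pred, n_classes: int = 3):
    """Macro precision/recall; classes absent from y_true are skipped."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    precisions, recalls = [], []
    for k in range(n_classes):
        support = (y_true == k).sum()
        if support == 0:
            warnings.warn(f"class {k} absent from evaluation labels; skipped")
            continue
        predicted = (y_pred == k).sum()
        tp = ((y_true == k) & (y_pred == k)).sum()
        precisions.append(tp / predicted if predicted else 0.0)
        recalls.append(tp / support)
    return float(np.mean(precisions)), float(np.mean(recalls))


def macro_auc(y_true, y_prob, n_classes: int = 3) -> float:
    """Mean one-vs-rest ROC AUC over classes present with both outcomes."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob)
    aucs = []
    for k in range(n_classes):
        pos = y_true == k
        if pos.all() or not pos.any():
            continue
        aucs.append(roc_auc_score(pos.astype(int), y_prob[:, k]))
    if not aucs:
        raise ValueError("no class with both positive and negative labels")
    return float(np.mean(aucs))


def psnr(mse: float, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB for unit-scaled volumes."""
    return float(10.0 * np.log10(peak**2 / mse))


# ----------------------------------------------------------------------
# batch preparation


class _Batch:
    __slots__ = ("B", "T", "tab", "tab_mask", "y_onehot", "y_mask", "deltas",
                 "img_mask", "volumes", "valid", "icv", "timestamps")

    def __init__(self, seqs, stats, modalities):
        self.B = len(seqs)
        self.T = max(s.n_visits for s in seqs)
        B, T = self.B, self.T
        self.timestamps = np.zeros((B, T))
        self.tab = np.zeros((B, T, dm.N_TAB_SLOTS))
        self.tab_mask = np.zeros((B, T, dm.N_TAB_SLOTS))
        self.y_onehot = np.zeros((B, T, 3))
        self.y_mask = np.zeros((B, T))
        self.deltas = np.zeros((B, T, dm.N_ELEMENTS))
        self.img_mask = np.zeros((B, T, len(modalities)))
        self.volumes = [[None] * T for _ in range(B)]
        self.valid = np.zeros((B, T))
        self.icv = np.array([s.icv for s in seqs])
        for b, s in enumerate(seqs):
            Tb = s.n_visits
            self.valid[b, :Tb] = 1
            ts = s.timestamps
            self.timestamps[b, :Tb] = ts
            if Tb < T:  # keep padded timestamps strictly increasing
                step = ts[-1] - ts[-2] if Tb > 1 else 1.0
                self.timestamps[b, Tb:] = ts[-1] + step * np.arange(1, T - Tb + 1)
            self.tab[b, :Tb] = dm.preprocess_tabular(s, stats)
            self.tab_mask[b, :Tb] = dm.tabular_masks(s)
            self.deltas[b, :Tb] = s.intervals
            for t, v in enumerate(s.visits):
                if v.diagnosis is not None:
                    self.y_onehot[b, t, dm.DIAGNOSIS_INDEX[v.diagnosis]] = 1.0
                    self.y_mask[b, t] = 1.0
                vols = {}
                for c, name in enumerate(modalities):
                    vol = v.volumes.get(name)
                    if vol is not None:
                        self.img_mask[b, t, c] = 1.0
                        vols[c] = np.asarray(vol, dtype=float).reshape(-1)
                self.volumes[b][t] = vols


def _effective_masks(batch: _Batch, withhold_after: int | None, diag_input_mask):
    """Element/tabular/label masks as the model sees them, plus rebuilt deltas."""
    tab_mask = batch.tab_mask.copy()
    y_in = batch.y_mask * diag_input_mask
    img = batch.img_mask.copy()
    if withhold_after is not None:
        tab_mask[:, withhold_after + 1:, :] = 0.0
        y_in = y_in.copy()
        y_in[:, withhold_after + 1:] = 0.0
        img[:, withhold_after + 1:, :] = 0.0
    if withhold_after is None:
        deltas = batch.deltas
    else:
        # rebuild element-level intervals from the effective (withheld) masks
        elem = np.zeros((batch.B, batch.T, dm.N_ELEMENTS))
        elem[:, :, :img.shape[2]] = img
        for j in range(dm.N_TAB_SLOTS):
            e = dm.TAB_SLOT_ELEMENT[j]
            elem[:, :, e] = np.maximum(elem[:, :, e], tab_mask[:, :, j])
        elem[:, :, dm.E_DIAG] = y_in
        deltas = np.stack([
            dm.build_intervals(batch.timestamps[b], elem[b])
            for b in range(batch.B)
        ])
    return tab_mask, y_in, img, deltas


class LMDPNet:
    """End-to-end longitudinal multimodal progression predictor."""

    def __init__(self, config: TrainConfig, stats: dm.GlobalStats,
                 label_freq=None):
        self.config = config
        self.stats = stats
        L = config.latent_dim if config.use_imaging else 0
        self.latent_dim = L
        self.feature_dim = L + dm.N_TAB_SLOTS
        self.input_dim = self.feature_dim + 3
        if config.use_imaging:
            self.m3vae = M3VAE(M3VAEConfig(
                volume_shape=config.volume_shape,
                n_modalities=len(config.modalities),
                latent_dim=config.latent_dim,
                hidden_dim=config.m3vae_hidden,
                kl_form=config.kl_form,
                recon_noise_std=config.recon_noise_std,
                seed=config.seed,
            ))
        else:
            self.m3vae = None
        if config.cell == "irlstm":
            self.cell = IRLSTMCell(self.input_dim, self.input_dim, dm.N_ELEMENTS,
                                   config.hidden_dim, beta=config.beta,
                                   candidate_act=config.candidate_act,
                                   seed=config.seed + 1)
        elif config.cell == "lstm_mask":
            self.cell = IRLSTMCell(self.input_dim, self.input_dim, dm.N_ELEMENTS,
                                   config.hidden_dim, use_aux=False,
                                   candidate_act=config.candidate_act,
                                   seed=config.seed + 1)
        elif config.cell == "lstm":
            self.cell = VanillaLSTMCell(self.input_dim, config.hidden_dim,
                                        seed=config.seed + 1)
        elif config.cell == "lstm_coupled":
            self.cell = VanillaLSTMCell(self.input_dim, config.hidden_dim,
                                        coupled=True, seed=config.seed + 1)
        else:
            raise ValueError(f"unknown cell {config.cell!r}")
        self.heads = PredictionHeads(config.hidden_dim, self.feature_dim,
                                     seed=config.seed + 2)
        self.params = list(self.cell.params) + list(self.heads.params)
        if self.m3vae is not None:
            self.params += list(self.m3vae.params)
        freq = np.full(3, 1.0 / 3.0) if label_freq is None else np.asarray(label_freq)
        self.global_fill = np.concatenate(
            [np.zeros(L), stats.slot_global_mean, freq])
        # running standardization of the fused imaging mean so it enters the
        # cell on the same scale as the z-scored tabular features
        self._fused_mean = np.zeros(L)
        self._fused_std = np.ones(L)
        self._fused_stats_ready = False

    # ------------------------------------------------------------------
    def _fused_rows(self, batch: _Batch, img_mask, rng, collect_lf: bool,
                    kl_weight: float = 1.0):
        """Fused downstream means per (patient, visit) and the Lf loss.

        Visits are grouped by observed-modality pattern so encoders run on
        batched matrices.  Returns (rows dict (b, t) -> Tensor[L], Lf Tensor).
        """
        C = len(self.config.modalities)
        groups = {}
        for b in range(batch.B):
            for t in range(batch.T):
                if not batch.valid[b, t]:
                    continue
                bits = tuple(int(x) for x in img_mask[b, t])
                if sum(bits) == 0:
                    continue
                groups.setdefault(bits, []).append((b, t))
        rows, lf = {}, Tensor(0.0)
        for bits, cells in groups.items():
            observed = [c for c in range(C) if bits[c]]
            stacks = {
                c: np.stack([batch.volumes[b][t][c] for b, t in cells])
                .reshape((len(cells),) + self.config.volume_shape)
                for c in observed
            }
            latents = {c: self.m3vae.encode_modality(stacks[c], c) for c in observed}
            # every nonzero sub-pattern of the observed modalities
            for code in enumerate_subset_codes(C):
                sub = [int(x) for x in code]
                if any(s and not bits[c] for c, s in enumerate(sub)):
                    continue
                fused = poe_fuse(
                    [latents.get(c) if sub[c] else None for c in range(C)], sub)
                if code == "".join(str(x) for x in bits):
                    for i, (b, t) in enumerate(cells):
                        rows[(b, t)] = fused.mu[i]
                if collect_lf:
                    z = sample_fused(fused, rng)
                    w = 0.5 / self.m3vae.config.recon_noise_std**2
                    for c in observed:
                        recon = self.m3vae.decode(z, c)
                        err = recon - Tensor(stacks[c].reshape(len(cells), -1))
                        lf = lf + (err**2.0).sum() * w
                    lf = lf + kl_standard_normal(fused.mu, fused.sigma,
                                                 self.config.kl_form) * kl_weight
        return rows, lf

    def _standardize_fused(self, rows: dict, train: bool) -> dict:
        """Scale fused means to unit variance using running training stats.

        The standardization is affine with detached statistics, so gradients
        still reach the encoders through the downstream losses.
        """
        if not rows:
            return rows
        if train and len(rows) >= 2:
            data = np.stack([r.data for r in rows.values()])
            m, s = data.mean(axis=0), data.std(axis=0) + 1e-6
            if self._fused_stats_ready:
                self._fused_mean = 0.9 * self._fused_mean + 0.1 * m
                self._fused_std = 0.9 * self._fused_std + 0.1 * s
            else:
                self._fused_mean, self._fused_std = m, s
                self._fused_stats_ready = True
        m, s = self._fused_mean, self._fused_std
        return {k: (r - Tensor(m)) * Tensor(1.0 / s) for k, r in rows.items()}

    def forward(self, seqs, rng: np.random.Generator, train: bool = True,
                withhold_after: int | None = None, anchor: int | None = None,
                kl_weight: float = 1.0):
        """Run the model over a batch of sequences.

        Returns a dict with per-visit predictions and the loss Tensors.
        ``withhold_after``: visit index after which every input is treated
        as unobserved (evaluation rollout).  ``anchor``: visit whose
        diagnosis input is hidden with probability ``diagnosis_mask_prob``.
        """
        cfg = self.config
        batch = _Batch(seqs, self.stats, cfg.modalities if cfg.use_imaging else ())
        B, T = batch.B, batch.T
        diag_input = np.ones((B, T))
        if anchor is not None and cfg.diagnosis_mask_prob > 0:
            if train:
                hide = rng.random(B) < cfg.diagnosis_mask_prob
            else:
                hide = np.ones(B, dtype=bool)
            diag_input[hide, anchor] = 0.0
        tab_mask, y_in, img_eff, deltas = _effective_masks(
            batch, withhold_after, diag_input)

        # Lf is self-supervised on all observed imaging; downstream fused
        # features are gated by the effective (possibly withheld) mask
        if cfg.use_imaging and batch.img_mask.any():
            fused_rows, lf = self._fused_rows(batch, batch.img_mask, rng,
                                              collect_lf=train,
                                              kl_weight=kl_weight)
            fused_rows = self._standardize_fused(fused_rows, train)
        else:
            fused_rows, lf = {}, Tensor(0.0)

        L = self.latent_dim
        state = self.cell.initial_state(B)
        y_prob_seq = [Tensor(np.full((B, 3), 1.0 / 3.0))]
        x_hat_seq = [Tensor(np.tile(self.global_fill[: self.feature_dim], (B, 1)))]
        lp, li = Tensor(0.0), Tensor(0.0)
        for t in range(T):
            if L > 0:
                mu_rows = []
                any_img = img_eff[:, t, :].max(axis=1)
                for b in range(B):
                    row = fused_rows.get((b, t)) if any_img[b] > 0 else None
                    mu_rows.append(row.reshape(1, L) if row is not None
                                   else Tensor(np.zeros((1, L))))
                img_feat = concat(mu_rows, axis=0)
                img_m = np.repeat(any_img[:, None], L, axis=1)
            else:
                img_feat = Tensor(np.zeros((B, 0)))
                img_m = np.zeros((B, 0))
            diag_feat = batch.y_onehot[:, t, :] * y_in[:, t, None]
            u_tilde = concat([img_feat, Tensor(batch.tab[:, t, :]),
                              Tensor(diag_feat)], axis=-1)
            m_t = np.concatenate([img_m, tab_mask[:, t, :],
                                  np.repeat(y_in[:, t, None], 3, axis=1)], axis=-1)
            assembled = AssembledVisitInput(u_tilde=u_tilde, mask=m_t)
            if t == 0:
                u = impute_visit(assembled, None, self.global_fill, t=1)
            else:
                u_hat = concat([x_hat_seq[-1], y_prob_seq[-1]], axis=-1)
                u = impute_visit(assembled, u_hat, None, t=t + 1)
            state, _ = self.cell.step(u, m_t, deltas[:, t, :], state)
            u_feat = u[:, : self.feature_dim]
            x_hat_seq.append(self.heads.forecast_next(state.h, u_feat))
            y_prob_seq.append(self.heads.classify_next(state.h))
            if t >= 1:
                w = batch.valid[:, t]
                lp = lp + progression_loss(y_prob_seq[t], batch.y_onehot[:, t, :],
                                           batch.y_mask[:, t] * w)
                bio_hat = x_hat_seq[t][:, L: L + 6]
                li = li + imputation_loss(bio_hat, batch.tab[:, t, dm.S_BIO],
                                          batch.tab_mask[:, t, dm.S_BIO] * w[:, None])
        return {
            "y_prob": y_prob_seq,  # y_prob[t] predicts visit t (index 0 = prior)
            "x_hat": x_hat_seq,
            "Lp": lp, "Li": li, "Lf": lf,
            "batch": batch,
        }

    def save(self, path) -> None:
        import json

        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.config.__dict__.items()}
        np.savez(path, _config=json.dumps(cfg), _mean=self.stats.mean,
                 _std=self.stats.std, _gmean=self.stats.slot_global_mean,
                 _fill=self.global_fill, _fmean=self._fused_mean,
                 _fstd=self._fused_std,
                 _fready=np.array(self._fused_stats_ready),
                 **({f"_imean{c}": im for c, im in enumerate(self.m3vae.input_mean)}
                    if self.m3vae is not None else {}),
                 **arrays)

    @classmethod
    def load(cls, path) -> "LMDPNet":
        import json

        with np.load(path, allow_pickle=False) as f:
            cfg = json.loads(str(f["_config"]))
            for key in ("modalities", "volume_shape"):
                cfg[key] = tuple(cfg[key])
            stats = dm.GlobalStats(mean=f["_mean"], std=f["_std"],
                                   slot_global_mean=f["_gmean"])
            model = cls(TrainConfig(**cfg), stats)
            model.global_fill = f["_fill"]
            model._fused_mean = f["_fmean"]
            model._fused_std = f["_fstd"]
            model._fused_stats_ready = bool(f["_fready"])
            if model.m3vae is not None:
                for c in range(len(model.m3vae.input_mean)):
                    model.m3vae.input_mean[c] = f[f"_imean{c}"]
            for i, p in enumerate(model.params):
                p.data = f[f"p{i}"]
        return model


# ----------------------------------------------------------------------


def _label_frequencies(seqs) -> np.ndarray:
    counts = np.zeros(3)
    for s in seqs:
        for v in s.visits:
            if v.diagnosis is not None:
                counts[dm.DIAGNOSIS_INDEX[v.diagnosis]] += 1
    return counts / counts.sum() if counts.sum() else np.full(3, 1 / 3)


def train_model(train_seqs, config: TrainConfig, stats: dm.GlobalStats | None = None,
                log_path=None):
    """Fit the model on a training split; returns (model, loss-trace frame)."""
    if stats is None:
        stats = dm.compute_global_stats(train_seqs)
    model = LMDPNet(config, stats, label_freq=_label_frequencies(train_seqs))
    if model.m3vae is not None:
        means = {}
        for c, name in enumerate(config.modalities):
            vols = [v.volumes[name] for s in train_seqs for v in s.visits
                    if v.volumes.get(name) is not None]
            if vols:
                means[c] = np.mean(np.stack(vols), axis=0)
        model.m3vae.init_from_data(means)
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    max_anchor = min(s.n_visits for s in train_seqs) - 2
    rows = []
    order = np.arange(len(train_seqs))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        ep = {"Lp": 0.0, "Li": 0.0, "Lf": 0.0}
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            seqs = [train_seqs[i] for i in idx]
            # the followup rollout is part of training: inputs after the
            # anchor visit are withheld, so post-anchor predictions are
            # autoregressive exactly as at evaluation time
            if config.train_anchor == "random":
                anchor = int(rng.integers(0, max(max_anchor, 0) + 1))
            else:
                anchor = config.n_history
            kl_w = (min(1.0, (epoch + 1) / config.kl_warmup_epochs)
                    if config.kl_warmup_epochs > 0 else 1.0)
            out = model.forward(seqs, rng, train=True, anchor=anchor,
                                withhold_after=anchor, kl_weight=kl_w)
            wp, wi, wf = config.loss_weights
            loss = (out["Lp"] * wp + out["Li"] * wi + out["Lf"] * wf) \
                * (1.0 / len(seqs))
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in ep:
                ep[k] += out[k].item() / len(train_seqs)
        report = total_loss(ep["Lp"], ep["Li"], ep["Lf"])
        rows.append({"epoch": epoch + 1, "Lp": report.Lp, "Li": report.Li,
                     "Lf": report.Lf, "Ltotal": report.Ltotal})
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return model, log


def evaluate(model: LMDPNet, test_seqs, k_followup: int | None = None,
             n_history: int | None = None) -> MetricReport:
    """Score followup predictions on a held-out split.

    Inputs after the anchor visit (index ``n_history``) are withheld; the
    model rolls forward autoregressively for the followup visits, which are
    scored against observed labels and biomarkers only.
    """
    cfg = model.config
    K = cfg.k_followup if k_followup is None else k_followup
    if K < 1:
        raise ValueError("need at least one followup visit")
    anchor = cfg.n_history if n_history is None else n_history
    rng = np.random.default_rng(cfg.seed + 999)
    out = model.forward(test_seqs, rng, train=False, withhold_after=anchor,
                        anchor=anchor)
    batch = out["batch"]
    y_true, y_pred, y_prob = [], [], []
    abs_err, rel_err = [], []
    L = model.latent_dim
    for t in range(anchor + 1, min(anchor + K + 1, batch.T)):
        prob = out["y_prob"][t].data
        bio_hat = out["x_hat"][t].data[:, L: L + 6]
        for b in range(batch.B):
            if not batch.valid[b, t]:
                continue
            if batch.y_mask[b, t]:
                y_true.append(int(batch.y_onehot[b, t].argmax()))
                y_pred.append(int(prob[b].argmax()))
                y_prob.append(prob[b])
            obs = batch.tab_mask[b, t, dm.S_BIO] > 0
            if obs.any():
                truth_ml = dm.inverse_biomarkers(batch.tab[b, t, dm.S_BIO],
                                                 batch.icv[b], model.stats)
                hat_ml = dm.inverse_biomarkers(bio_hat[b], batch.icv[b], model.stats)
                err = np.abs(hat_ml[obs] - truth_ml[obs])
                abs_err.extend(err.tolist())
                rel_err.extend((err / np.abs(truth_ml[obs])).tolist())
    report = MetricReport(n_scored=len(y_true))
    if y_true:
        y_true_a, y_pred_a = np.array(y_true), np.array(y_pred)
        report.acc = accuracy(y_true_a, y_pred_a)
        report.precision, report.recall = macro_precision_recall(y_true_a, y_pred_a)
        try:
            report.mauc = macro_auc(y_true_a, np.array(y_prob))
        except ValueError:
            report.mauc = None
    if abs_err:
        report.mae_ml = float(np.mean(abs_err))
        report.mre_pct = float(np.mean(rel_err) * 100.0)
    return report


def evaluate_reconstruction(model: LMDPNet, test_seqs, source: str = "mri",
                            target: str = "pet") -> MetricReport:
    """Cross-modal reconstruction quality on visits where both are observed.

    Encodes the source modality alone, fuses (single expert), decodes the
    target, and reports voxel-mean MSE and PSNR (peak 1).
    """
    if model.m3vae is None:
        raise ValueError("model was trained without imaging")
    mods = list(model.config.modalities)
    cs, ct = mods.index(source), mods.index(target)
    errors = []
    for s in test_seqs:
        for v in s.visits:
            sv, tv = v.volumes.get(source), v.volumes.get(target)
            if sv is None or tv is None:
                continue
            latent = model.m3vae.encode_modality(np.asarray(sv), cs)
            mask = [0] * len(mods)
            mask[cs] = 1
            fused = poe_fuse([latent if c == cs else None for c in range(len(mods))],
                             mask)
            recon = model.m3vae.decode(fused.mu.reshape(1, -1), ct).data.reshape(-1)
            errors.append(np.mean((recon - np.asarray(tv, dtype=float).reshape(-1))**2))
    if not errors:
        return MetricReport()
    mse = float(np.mean(errors))
    return MetricReport(mse=mse, psnr_db=psnr(mse), n_scored=len(errors))


# ----------------------------------------------------------------------
# cross-validation and ablations


def _is_ad_baseline(seq) -> bool:
    return seq.visits[0].diagnosis == "AD"


def assign_folds(n_patients: int, n_folds: int, seed: int):
    """Deterministic patient-level partition into test folds."""
    if n_patients < n_folds:
        raise ValueError("fewer patients than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_patients)
    return [np.sort(part) for part in np.array_split(order, n_folds)]


def cross_validate(cohort, config: TrainConfig):
    """Patient-level k-fold cross-validation.

    AD-at-baseline patients found in a test fold are moved into that fold's
    training split (the method targets patients at earlier stages).
    Normalization statistics and global means are recomputed inside each
    fold from its training split only.
    """
    folds = assign_folds(len(cohort), config.n_folds, config.seed)
    reports, fold_stats = [], []
    for fi, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_seqs = [s for i, s in enumerate(cohort)
                      if i not in test_set or _is_ad_baseline(s)]
        test_seqs = [cohort[i] for i in test_idx if not _is_ad_baseline(cohort[i])]
        if not test_seqs:
            warnings.warn(f"fold {fi} has no scorable test patients; skipped")
            continue
        stats = dm.compute_global_stats(train_seqs)
        fold_stats.append(stats)
        model, _ = train_model(train_seqs, replace(config, seed=config.seed + fi),
                               stats=stats)
        reports.append(evaluate(model, test_seqs))
    agg = {}
    for key in ("acc", "precision", "recall", "mauc", "mae_ml", "mre_pct"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if vals:
            agg[key] = (float(np.mean(vals)), float(np.std(vals)))
    return {"folds": reports, "aggregate": agg, "fold_stats": fold_stats}


ABLATION_DESIGNS = ("gate", "history", "diagnosis", "modality", "hidden")


def run_ablation(cohort, design: str, config: TrainConfig,
                 seeds=(0, 1, 2), variants=None) -> pd.DataFrame:
    """Run one of the ablation grids with shared seeds; returns a table.

    Designs: ``gate`` (LSTM / LSTM-Mask / IRLSTM beta=2pi / IRLSTM beta=pi),
    ``history`` (0..4 past visits), ``diagnosis`` (anchor diagnosis hidden
    vs given), ``modality`` (MRI-only / PET-only / both), ``hidden``
    (64 / 128 / 256).  Each variant trains on a fixed 80/20 patient split
    per seed and reports metric mean +- std across seeds.
    """
    if design not in ABLATION_DESIGNS:
        raise ValueError(f"unknown ablation design {design!r}")
    if variants is None:
        if design == "gate":
            variants = [
                ("LSTM", {"cell": "lstm"}),
                ("LSTM-Mask", {"cell": "lstm_mask"}),
                ("IRLSTM (beta=2pi)", {"cell": "irlstm", "beta": 2 * math.pi}),
                ("IRLSTM (beta=pi)", {"cell": "irlstm", "beta": math.pi}),
            ]
        elif design == "history":
            variants = [(f"T-1={h}", {"n_history": h}) for h in range(5)]
        elif design == "diagnosis":
            variants = [("Without", {"diagnosis_mask_prob": 1.0}),
                        ("With", {"diagnosis_mask_prob": 0.0})]
        elif design == "modality":
            variants = [("MRI", {"modalities": ("mri",)}),
                        ("PET", {"modalities": ("pet",)}),
                        ("MRI+PET", {"modalities": ("mri", "pet")})]
        else:
            variants = [(str(h), {"hidden_dim": h}) for h in (64, 128, 256)]
    rows = []
    for name, overrides in variants:
        per_seed = []
        for seed in seeds:
            cfg = replace(config, seed=seed, **overrides)
            n_test = max(1, len(cohort) // 5)
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(cohort))
            test_idx = set(order[:n_test].tolist())
            train_seqs = [s for i, s in enumerate(cohort)
                          if i not in test_idx or _is_ad_baseline(s)]
            test_seqs = [cohort[i] for i in sorted(test_idx)
                         if not _is_ad_baseline(cohort[i])]
            stats = dm.compute_global_stats(train_seqs)
            model, _ = train_model(train_seqs, cfg, stats=stats)
            K = cfg.k_followup
            h = cfg.n_history
            per_seed.append(evaluate(model, test_seqs, k_followup=min(K, 5 - h),
                                     n_history=h))
        row = {"variant": name}
        for key in ("acc", "precision", "recall", "mauc"):
            vals = [getattr(r, key) for r in per_seed if getattr(r, key) is not None]
            if vals:
                row[key] = float(np.mean(vals))
                row[f"{key}_std"] = float(np.std(vals))
        rows.append(row)
    return pd.DataFrame(rows)
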