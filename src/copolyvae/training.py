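"""Semi-supervised VAE training: reconstruction + KL + masked property loss,
cyclical KL annealing, Adam with gradient clipping, early stopping.

The total loss per batch is

    total = recon + beta * kl + alpha * prop

where ``recon`` is mean token-level cross entropy over non-PAD positions,
``kl`` the closed-form diagonal-Gaussian KL to the standard-normal prior and
``prop`` the masked mean squared error over the two property labels, computed
only on labelled rows so the property head receives gradients exclusively
from labelled data.  ``beta`` follows a cyclical ramp-then-plateau schedule
to avoid posterior collapse; properties are z-scored on the labelled training
rows before the MSE (predictions are de-standardized for reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .dataset import DatasetRecord
from .model_core import (
    CopolymerVAE, EncoderOutput, ModelConfig, PackedGraphs, decoder_forward,
    encoder_forward, pack_graphs, property_forward,
)
from .polymer_repr import build_graph, parse_polymer_string, tokenize


class DegenerateInputError(ValueError):
    pass


class DomainError(ValueError):
    pass


@dataclass
class LossBreakdown:
    recon: float
    kl: float
    prop: float
    beta: float
    alpha: float

    @property
    def total(self) -> float:
        return self.recon + self.beta * self.kl + self.alpha * self.prop


@dataclass
class TrainConfig:
    alpha: float = 0.2
    beta_max: float = 0.0004
    cycle: int = 200            # annealing cycle length in optimizer steps
    epochs: int = 50
    batch_size: int = 32
    patience: int = 10
    lr: float = 1e-3
    clip_norm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta_max <= 0:
            raise ValueError("beta_max must be > 0")


# --------------------------------------------------------------------------
# loss terms (operate on Tensors during training, plain arrays otherwise)

def reconstruction_loss(logits, targets: np.ndarray, pad_id: int,
                        class_weights: Optional[np.ndarray] = None):
    """Mean token cross entropy (nats) over non-PAD target positions.

    logits: (B, L, V); targets: (B, L) int ids.  Optional per-class weights
    (default uniform) weight each target token's contribution.
    """
    targets = np.asarray(targets)
    mask = (targets != pad_id).astype(np.float64)
    if mask.sum() == 0:
        raise DegenerateInputError("all-PAD target")
    w = mask if class_weights is None else mask * class_weights[targets]
    return ad.cross_entropy_logits(logits, targets, w)


def kl_from_mu_logvar(mu, logvar):
    """Closed-form KL(q || N(0, I)) summed over dims, averaged over batch."""
    s2 = ad.exp(logvar)
    per = 0.5 * ad.tsum(mu * mu + s2 - 1.0 - logvar, axis=-1)
    return ad.tmean(per)


def kl_loss(out: EncoderOutput) -> float:
    """KL divergence (nats) of an encoder posterior from the prior."""
    sigma2 = np.asarray(out.sigma2, dtype=np.float64)
    if np.any(sigma2 <= 0):
        raise DomainError("sigma2 must be positive")
    mu = np.asarray(out.mu, dtype=np.float64)
    per = 0.5 * np.sum(mu ** 2 + sigma2 - 1.0 - np.log(sigma2), axis=-1)
    return float(np.mean(per))


def masked_property_loss(pred, labels: np.ndarray, mask: np.ndarray):
    """MSE averaged over the M properties and the labelled samples; exactly 0
    (with zero gradients) when the mask is all-zero."""
    labels = np.nan_to_num(np.asarray(labels, dtype=np.float64))
    mask = np.asarray(mask, dtype=np.float64)
    n_lab = mask.sum()
    if n_lab == 0:
        return ad.tsum(pred * 0.0) if isinstance(pred, Tensor) else 0.0
    err = (pred - labels) * mask[:, None]
    m = np.shape(labels)[-1]
    return ad.tsum(err * err) / (n_lab * m)


def beta_schedule(step: int, config: TrainConfig) -> float:
    """Cyclical annealing: linear ramp 0 -> beta_max over the first half of
    each cycle, plateau at beta_max for the second half."""
    if step < 0:
        raise ValueError("step must be >= 0")
    pos = step % config.cycle
    half = config.cycle / 2.0
    frac = min(pos / half, 1.0)
    return config.beta_max * frac


# --------------------------------------------------------------------------
# optimizer

class Adam:
    def __init__(self, params: Dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, clip_norm: float = 1.0):
        self.params = params
        self.lr, self.betas, self.eps, self.clip = lr, betas, eps, clip_norm
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        gnorm = np.sqrt(sum(float((p.grad ** 2).sum())
                            for p in self.params.values() if p.grad is not None))
        scale = min(1.0, self.clip / (gnorm + 1e-12)) if self.clip else 1.0
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1 ** self.t)
            vh = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


# --------------------------------------------------------------------------
# data preparation

@dataclass
class PreparedBatch:
    packed: PackedGraphs
    tokens: np.ndarray          # (B, Lmax) padded full sequences (BOS..EOS PAD*)
    labels: np.ndarray          # (B, M) standardized, nan->0 on unlabelled
    mask: np.ndarray            # (B,)


def prepare_records(records: Sequence[DatasetRecord], model: CopolymerVAE):
    """Tokenize and graph-build all records once."""
    graphs, toks, labels, mask = [], [], [], []
    for r in records:
        spec = parse_polymer_string(r.polymer_string)
        graphs.append(build_graph(spec))
        toks.append(tokenize(r.polymer_string, model.vocab).ids)
        if r.properties is not None:
            labels.append(list(r.properties))
            mask.append(1.0)
        else:
            labels.append([np.nan] * model.cfg.n_props)
            mask.append(0.0)
    return graphs, toks, np.array(labels), np.array(mask)


def _pad(toks: List[List[int]], pad_id: int) -> np.ndarray:
    L = max(len(t) for t in toks)
    out = np.full((len(toks), L), pad_id, dtype=int)
    for i, t in enumerate(toks):
        out[i, :len(t)] = t
    return out


def batch_losses(model: CopolymerVAE, graphs, toks, labels, mask,
                 beta: float, alpha: float,
                 rng: np.random.Generator) -> Tuple[Tensor, LossBreakdown]:
    p = model.params
    packed = pack_graphs(graphs, dtype=ad.DTYPE)
    mu, logvar, _ = encoder_forward(p, packed, model.cfg)
    eps = rng.standard_normal(mu.shape)
    z = mu + ad.exp(logvar * 0.5) * eps

    tokens = _pad(toks, model.vocab.pad_id)
    inp, tgt = tokens[:, :-1], tokens[:, 1:]
    logits = decoder_forward(p, z, inp, model.cfg, model.vocab.pad_id)
    recon = reconstruction_loss(logits, tgt, model.vocab.pad_id)
    kl = kl_from_mu_logvar(mu, logvar)
    pred = property_forward(p, z, model.cfg)
    prop = masked_property_loss(pred, labels, mask)
    total = recon + beta * kl + alpha * prop
    bd = LossBreakdown(recon=float(recon.data), kl=float(kl.data),
                       prop=float(prop.data) if isinstance(prop, Tensor) else float(prop),
                       beta=beta, alpha=alpha)
    return total, bd


def train(model: CopolymerVAE, train_records: Sequence[DatasetRecord],
          val_records: Optional[Sequence[DatasetRecord]] = None,
          config: TrainConfig = TrainConfig(),
          verbose: bool = False) -> List[Dict[str, float]]:
    """Fit the VAE; returns per-epoch history of loss breakdowns.

    Early stopping monitors validation total loss (beta fixed at beta_max so
    epochs are comparable) with the configured patience; the best parameters
    are restored at the end.
    """
    if not train_records:
        raise ValueError("empty training partition")
    rng = np.random.default_rng(config.seed)

    graphs, toks, labels, mask = prepare_records(train_records, model)
    lab_rows = labels[mask == 1]
    if len(lab_rows):
        model.prop_mean = lab_rows.mean(axis=0)
        model.prop_std = np.maximum(lab_rows.std(axis=0), 1e-8)
    labels_std = (labels - model.prop_mean) / model.prop_std

    if val_records:
        vg, vt, vl, vm = prepare_records(val_records, model)
        vl_std = (vl - model.prop_mean) / model.prop_std

    opt = Adam(model.params, lr=config.lr, clip_norm=config.clip_norm)
    history: List[Dict[str, float]] = []
    best_val, best_state, since_best = np.inf, None, 0
    step = 0
    n = len(train_records)
    # Length-bucketed batches: group sequences of similar length so padded
    # length (and the quadratic attention cost) stays close to the true
    # lengths; the batch order is reshuffled every epoch.
    by_len = np.argsort([len(t) for t in toks], kind="stable")
    buckets = [by_len[lo:lo + config.batch_size]
               for lo in range(0, n, config.batch_size)]
    for epoch in range(config.epochs):
        ep = {"recon": 0.0, "kl": 0.0, "prop": 0.0, "total": 0.0, "beta": 0.0}
        nb = 0
        for bi in rng.permutation(len(buckets)):
            idx = buckets[bi]
            beta = beta_schedule(step, config)
            total, bd = batch_losses(
                model, [graphs[i] for i in idx], [toks[i] for i in idx],
                labels_std[idx], mask[idx], beta, config.alpha, rng)
            opt.zero_grad()
            total.backward()
            opt.step()
            step += 1
            nb += 1
            for k, v in (("recon", bd.recon), ("kl", bd.kl), ("prop", bd.prop),
                         ("total", bd.total), ("beta", bd.beta)):
                ep[k] += v
        for k in ep:
            ep[k] /= nb
        ep["epoch"] = epoch

        if val_records:
            vtotal, vbd = batch_losses(model, vg, vt, vl_std, vm,
                                       config.beta_max, config.alpha,
                                       np.random.default_rng(config.seed))
            ep["val_total"] = float(vtotal.data)
            monitored = ep["val_total"]
        else:
            monitored = ep["total"]
        history.append(ep)
        if verbose:
            print({k: round(v, 4) for k, v in ep.items()})

        if monitored < best_val - 1e-6:
            best_val = monitored
            best_state = {k: v.data.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    if best_state is not None:
        for k in model.params:
            model.params[k].data = best_state[k]
    return history
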