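"""Joint end-to-end training of the dual-branch model.

All components are optimized together from the first epoch under one
composite loss: in ``domain`` mode the graph ELBO, the local-global
contrastive loss, the adversarial alignment loss and the attention-
fusion reconstruction; in ``svg`` mode the fusion term is replaced by
the linear reconstruction from the concatenated latent that the
spatial-relevance score later decomposes.

Optimization is full-batch Adam with decoupled weight decay.  A single
seed drives parameter initialization, the per-epoch reparameterization
noise, and the negative-pair permutations through independently spawned
generator streams, so runs are bit-reproducible on CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import value_and_grad
from autograd.tracer import getval

from . import interactions as cx
from . import model as nn
from .config import ModelConfig
from .graph import SpatialGraph
from .io import STDataset
from .srs import srs_reconstruction_loss

logger = logging.getLogger(__name__)

COMPONENT_NAMES = {"domain": ("sab", "lgcm", "aam", "afm"),
                   "svg": ("sab", "lgcm", "aam", "srs")}


@dataclass
class TrainedModel:
    """A trained model: parameters, loss trace and noiseless embeddings."""

    params: Dict[str, np.ndarray]
    config: ModelConfig
    loss_trace: pd.DataFrame            # epochs x (total + components)
    Z_sa: np.ndarray
    Z_ns: np.ndarray
    Z_att: np.ndarray
    alphas: np.ndarray
    X_hat: Optional[np.ndarray]
    bn_stats: tuple
    graph: SpatialGraph = field(repr=False, default=None)


class Adam:
    """Adam with decoupled weight decay over a dict of arrays."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            out[k] = p - self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                    + self.wd * p)
        return out


def grl_schedule(epoch: int, config: ModelConfig) -> float:
    """Linear warm-up of the gradient-reversal scale over the first
    ``grl_warmup_frac`` of training, then constant at the maximum."""
    warm = max(1, int(round(config.grl_warmup_frac * config.epochs)))
    return config.grl_lambda_max * min(1.0, (epoch + 1) / warm)


def composite_loss(params, X1, X2, A, A_norm, AX, neigh_op, eps_noise, perm,
                   grl_lambda, config: ModelConfig, components: Optional[dict] = None):
    """The active composite loss at one parameter point.

    ``components``, if given, is filled with the unweighted component
    values (floats) as a side channel for the loss trace.
    """
    w1, w2, w3, w4 = config.loss_weights

    mu, logvar = nn.encode_spatial(X1, A_norm, params, AX=AX)
    Z_sa = nn.reparameterize(mu, logvar, eps_noise)
    Z_ns = nn.encode_nonspatial(X2, params, use_bn=config.use_bn)

    logits = anp.dot(Z_sa, Z_sa.T)
    L_sab = nn.sab_loss_from_logits(A, logits, mu, logvar)

    C = anp.dot(neigh_op, Z_sa)
    Z_neg = Z_ns[perm]
    L_lgcm = cx.lgcm_loss(Z_sa, Z_ns, C, Z_neg, params["disc_M"],
                          eps=config.eps_clip)
    L_aam = cx.aam_loss(Z_sa, Z_ns, params, grl_lambda, eps=config.eps_clip)

    if config.mode == "domain":
        _, Z_att = cx.attention_fuse(Z_sa, Z_ns, params["att_w"])
        L_task, _ = cx.afm_loss(Z_att, params, X1)
    else:
        Z_con = anp.concatenate([Z_sa, Z_ns], axis=1)
        L_task = srs_reconstruction_loss(Z_con, params["srs_W"], X1)

    if components is not None:
        names = COMPONENT_NAMES[config.mode]
        for name, val in zip(names, (L_sab, L_lgcm, L_aam, L_task)):
            components[name] = float(getval(val))

    return w1 * L_sab + w2 * L_lgcm + w3 * L_aam + w4 * L_task


def train(dataset: STDataset, graph: SpatialGraph,
          config: ModelConfig) -> TrainedModel:
    """Full-batch joint optimization of the configured composite loss.

    ``dataset`` must already be preprocessed (``X1`` is both the model
    input and the reconstruction target).  Returns the trained
    parameters, a per-epoch component loss trace, and noiseless
    embeddings (latent mean for the spatial branch, recorded
    normalization statistics for the non-spatial branch).
    """
    # float32 throughout the hot loop: halves memory traffic on the
    # dense N x N terms with no effect on the learned structure
    X1 = np.asarray(dataset.X1, dtype=np.float32)
    X2 = np.asarray(dataset.X2, dtype=np.float32)
    N = X1.shape[0]
    if graph.n_spots != N:
        raise ValueError("graph and dataset disagree on the number of spots")

    ss = np.random.SeedSequence(config.seed)
    init_rng, eps_rng, perm_rng = (np.random.default_rng(s)
                                   for s in ss.spawn(3))

    params = nn.init_params(X1.shape[1], X2.shape[1], config, init_rng)
    params = {k: v.astype(np.float32) for k, v in params.items()}
    A = graph.A.astype(np.float32)
    A_norm = graph.A_norm.astype(np.float32)
    AX = A_norm @ X1
    neigh_op = graph.neighbor_mean_operator().astype(np.float32)

    opt = Adam(params, config.learning_rate, config.weight_decay)
    trace_rows = []
    names = COMPONENT_NAMES[config.mode]

    for epoch in range(config.epochs):
        eps_noise = eps_rng.standard_normal((N, config.d4)).astype(np.float32)
        perm = perm_rng.permutation(N)
        lam = grl_schedule(epoch, config)
        components: dict = {}

        loss_fn = lambda p: composite_loss(
            p, X1, X2, A, A_norm, AX, neigh_op, eps_noise, perm, lam,
            config, components)
        total, grads = value_and_grad(loss_fn)(params)
        total = float(total)
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: components={components}")
        params = opt.step(params, grads)
        trace_rows.append({"epoch": epoch, "total": total, **components})
        if epoch % 100 == 0 or epoch == config.epochs - 1:
            comp_str = ", ".join(f"{k}={v:.4f}" for k, v in components.items())
            logger.info("epoch %d: total=%.4f (%s)", epoch, total, comp_str)

    loss_trace = pd.DataFrame(trace_rows).set_index("epoch")

    # noiseless inference pass
    mu, logvar = nn.encode_spatial(X1, A_norm, params, AX=AX)
    Z_sa = np.asarray(mu)
    Z_ns, bn_stats = nn.encode_nonspatial(X2, params, use_bn=config.use_bn,
                                          return_stats=True)
    Z_ns = np.asarray(Z_ns)
    alphas, Z_att = cx.attention_fuse(Z_sa, Z_ns, params["att_w"])
    X_hat = None
    if config.mode == "domain":
        X_hat = np.asarray(cx.decode_expression(Z_att, params))
    for name, Z in (("Z_sa", Z_sa), ("Z_ns", Z_ns), ("Z_att", Z_att)):
        if not np.all(np.isfinite(Z)):
            raise FloatingPointError(f"non-finite values in {name}")

    return TrainedModel(params=params, config=config, loss_trace=loss_trace,
                        Z_sa=Z_sa, Z_ns=Z_ns, Z_att=np.asarray(Z_att),
                        alphas=np.asarray(alphas), X_hat=X_hat,
                        bn_stats=bn_stats, graph=graph)


def get_embeddings(model: TrainedModel, which: str) -> np.ndarray:
    """Retrieve a noiseless embedding: ``Z_sa``, ``Z_ns``, ``Z_att`` or
    the concatenation ``Z_con`` (available in either mode)."""
    if which == "Z_sa":
        return model.Z_sa.copy()
    if which == "Z_ns":
        return model.Z_ns.copy()
    if which == "Z_att":
        return model.Z_att.copy()
    if which == "Z_con":
        return np.concatenate([model.Z_sa, model.Z_ns], axis=1)
    raise ValueError(f"unknown embedding {which!r}")
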