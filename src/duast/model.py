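"""The two encoders of the dual-branch model and their branch-local losses.

Spatial-aware branch: a variational graph auto-encoder.  A shared
single-layer GCN smooths expression over the spatial graph; two parallel
GCN heads produce the posterior mean and log-variance; the latent is
sampled by the reparameterization trick and decoded to an adjacency
reconstruction by an inner product.  The branch loss is the negative
ELBO: adjacency binary cross-entropy plus KL to the standard-normal
prior.

Non-spatial branch: a two-layer MLP (Linear -> BatchNorm -> ReLU twice)
applied to the second modality, producing a latent of the same width so
the two branches can be contrasted, aligned and fused downstream.

All forward math is written against ``autograd.numpy`` so the training
loop can differentiate end-to-end on CPU.
"""

from __future__ import annotations

from typing import Optional

import autograd.numpy as anp
import numpy as np

BN_EPS = 1e-5


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(d1: int, d2: int, config, rng: np.random.Generator) -> dict:
    """Initialize every parameter tensor of the full model.

    The same dictionary is used in both training modes; components that
    a mode does not exercise simply receive no task gradient.
    """
    d3, d4 = config.d3, config.d4
    h_ns, h_dm, h_dec = config.nsb_hidden, config.disc_hidden, config.dec_hidden
    p = {
        # spatial-aware branch (shared GCN + mu/log-variance heads);
        # the posterior heads start near the prior (small-scale init) so
        # the KL term does not crush the branch before the graph and
        # cross-branch signals can shape it
        "W_g": _glorot(rng, d1, d3),
        "W_mu": 0.1 * _glorot(rng, d3, d4),
        "W_sigma": 0.1 * _glorot(rng, d3, d4),
        # non-spatial branch: 2-layer MLP with batch norm
        "ns_W1": _glorot(rng, d2, h_ns),
        "ns_b1": np.zeros(h_ns),
        "ns_gamma1": np.ones(h_ns),
        "ns_beta1": np.zeros(h_ns),
        "ns_W2": _glorot(rng, h_ns, d4),
        "ns_b2": np.zeros(d4),
        "ns_gamma2": np.ones(d4),
        "ns_beta2": np.zeros(d4),
        # shared bilinear contrastive discriminator
        "disc_M": _glorot(rng, d4, d4),
        # modality discriminator (adversarial alignment)
        "dm_W1": _glorot(rng, d4, h_dm),
        "dm_b1": np.zeros(h_dm),
        "dm_W2": _glorot(rng, h_dm, 1),
        "dm_b2": np.zeros(1),
        # attention scorer (shared one-layer linear, one scalar per branch)
        "att_w": _glorot(rng, d4, 1)[:, 0],
        # expression decoder (attention-fusion reconstruction head)
        "dec_W1": _glorot(rng, d4, h_dec),
        "dec_b1": np.zeros(h_dec),
        "dec_W2": _glorot(rng, h_dec, d1),
        "dec_b2": np.zeros(d1),
        # linear decoder for spatial relevance scoring (svg mode)
        "srs_W": _glorot(rng, 2 * d4, d1),
    }
    return p


# ---------------------------------------------------------------------------
# spatial-aware branch
# ---------------------------------------------------------------------------

def gcn_propagate(X, A_norm, W, activation: str = "relu"):
    """One graph-convolution step: ``activation(A_norm @ X @ W)``."""
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: X has {X.shape[1]} features, "
                         f"W expects {W.shape[0]}")
    if A_norm.shape[1] != X.shape[0]:
        raise ValueError("propagation operator does not match X rows")
    H = anp.dot(anp.dot(A_norm, X), W)
    if activation == "relu":
        return anp.maximum(H, 0.0)
    if activation == "identity":
        return H
    raise ValueError(f"unknown activation {activation!r}")


def encode_spatial(X1, A_norm, params, AX=None):
    """Gaussian posterior parameters from the VGAE encoder.

    ``AX`` may carry the precomputed ``A_norm @ X1`` (it is constant
    across epochs, so the training loop caches it).
    """
    if AX is None:
        AX = anp.dot(A_norm, X1)
    H1 = anp.maximum(anp.dot(AX, params["W_g"]), 0.0)
    AH1 = anp.dot(A_norm, H1)
    mu = anp.dot(AH1, params["W_mu"])
    logvar = anp.dot(AH1, params["W_sigma"])
    return mu, logvar


def reparameterize(mu, logvar, epsilon):
    """``Z = mu + exp(logvar/2) * eps`` — the reparameterization trick."""
    return mu + anp.exp(0.5 * logvar) * epsilon


def reconstruct_adjacency(Z_sa):
    """Inner-product decoder: elementwise sigmoid of the Gram matrix."""
    logits = anp.dot(Z_sa, Z_sa.T)
    return 1.0 / (1.0 + anp.exp(-logits))


def sab_loss(A, A_hat, mu, logvar, eps: float = 1e-7):
    """Negative ELBO of the graph auto-encoder.

    Adjacency binary cross-entropy (diagonal excluded, positive class
    up-weighted by the zero/one ratio to counter sparsity, averaged over
    off-diagonal entries) plus the closed-form Gaussian KL to N(0, I)
    (summed over latent dimensions, averaged over spots).
    """
    A = anp.asarray(A, dtype=float) if isinstance(A, np.ndarray) else A
    N = A.shape[0]
    if N < 2:
        raise ValueError("adjacency loss needs at least two spots")
    mask = 1.0 - np.eye(N)
    n_off = N * (N - 1)
    n_pos = float(np.sum(np.asarray(A) * mask))
    pos_weight = (n_off - n_pos) / n_pos if n_pos > 0 else 1.0

    P = anp.clip(A_hat, eps, 1.0 - eps)
    ll = pos_weight * A * anp.log(P) + (1.0 - A) * anp.log(1.0 - P)
    bce = -anp.sum(ll * mask) / n_off

    kl_per_spot = 0.5 * anp.sum(mu ** 2 + anp.exp(logvar) - logvar - 1.0, axis=1)
    kl = anp.mean(kl_per_spot)
    return bce + kl


def sab_loss_from_logits(A, logits, mu, logvar):
    """Fused negative ELBO computed from the Gram-matrix logits.

    Mathematically identical to ``sab_loss(A, sigmoid(logits), ...)``
    up to the clipping guard, but uses the stable softplus form and
    avoids materializing the sigmoid — the training loop's hot path.
    """
    N = A.shape[0]
    n_off = N * (N - 1)
    n_pos = float(np.sum(A)) - float(np.trace(A))
    pos_weight = (n_off - n_pos) / n_pos if n_pos > 0 else 1.0

    # log sigmoid(s) = -softplus(-s); log(1 - sigmoid(s)) = -softplus(s)
    sp_pos = anp.maximum(-logits, 0.0) + anp.log1p(anp.exp(-anp.abs(logits)))
    sp_neg = logits + sp_pos            # softplus(s)
    ll = -(pos_weight * A) * sp_pos - (1.0 - A) * sp_neg
    bce = -(anp.sum(ll) - anp.trace(ll)) / n_off
    return bce + kl_term(mu, logvar)


def kl_term(mu, logvar):
    """Gaussian KL(q(z|mu, sigma^2) || N(0, I)), mean over spots."""
    return anp.mean(0.5 * anp.sum(mu ** 2 + anp.exp(logvar) - logvar - 1.0,
                                  axis=1))


# ---------------------------------------------------------------------------
# non-spatial branch
# ---------------------------------------------------------------------------

def _batchnorm(a, gamma, beta, stats: Optional[tuple] = None):
    if stats is None:
        m = anp.mean(a, axis=0)
        v = anp.var(a, axis=0)
    else:
        m, v = stats
    return (a - m) / anp.sqrt(v + BN_EPS) * gamma + beta


def encode_nonspatial(X2, params, use_bn: bool = True, bn_stats=None,
                      return_stats: bool = False):
    """Two-layer MLP encoder ``ReLU(BN(W2 ReLU(BN(W1 x + b1)) + b2))``.

    During training batch statistics are used (and differentiated
    through); at inference, pass the recorded ``bn_stats`` so the map is
    a fixed function of each spot.  With ``return_stats=True`` the
    batch statistics of this forward pass are returned for recording.
    """
    if X2.shape[1] != params["ns_W1"].shape[0]:
        raise ValueError(f"X2 has {X2.shape[1]} features but the encoder "
                         f"expects {params['ns_W1'].shape[0]}")
    a1 = anp.dot(X2, params["ns_W1"]) + params["ns_b1"]
    s1 = None if bn_stats is None else bn_stats[0]
    h = a1 if not use_bn else _batchnorm(a1, params["ns_gamma1"],
                                         params["ns_beta1"], s1)
    h = anp.maximum(h, 0.0)
    a2 = anp.dot(h, params["ns_W2"]) + params["ns_b2"]
    s2 = None if bn_stats is None else bn_stats[1]
    z = a2 if not use_bn else _batchnorm(a2, params["ns_gamma2"],
                                         params["ns_beta2"], s2)
    z = anp.maximum(z, 0.0)
    if return_stats:
        stats = (
            (np.mean(np.asarray(a1), axis=0), np.var(np.asarray(a1), axis=0)),
            (np.mean(np.asarray(a2), axis=0), np.var(np.asarray(a2), axis=0)),
        )
        return z, stats
    return z
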