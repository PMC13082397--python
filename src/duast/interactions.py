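"""Cross-branch interaction mechanisms.

Three couplings tie the spatial and non-spatial branches together:

- a local-global contrastive mechanism (Deep-Graph-Infomax style):
  a shared bilinear discriminator scores (embedding, neighborhood
  summary) and (spatial, non-spatial) pairs against permuted negatives;
- an adversarial alignment mechanism: an MLP discriminator tries to
  tell which branch an embedding came from, while a gradient reversal
  layer turns its loss into alignment pressure on both encoders;
- an attention fusion mechanism: a shared one-layer scorer produces a
  per-spot convex combination of the two branch embeddings, which a
  two-layer MLP decodes back to expression.
"""

from __future__ import annotations

from typing import Optional, Union

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive


# ---------------------------------------------------------------------------
# gradient reversal layer
# ---------------------------------------------------------------------------

@primitive
def grad_reverse(x, grl_lambda: float = 1.0):
    """Identity in the forward pass; gradient scaled by ``-grl_lambda``
    in the backward pass."""
    return x


defvjp(grad_reverse,
       lambda ans, x, grl_lambda=1.0: lambda g: -grl_lambda * g)


# ---------------------------------------------------------------------------
# local-global contrastive mechanism
# ---------------------------------------------------------------------------

def local_summaries(Z_sa, neighbor_sets):
    """Per-spot mean of neighbor embeddings (self excluded)."""
    for i, nbrs in enumerate(neighbor_sets):
        if len(nbrs) == 0:
            raise ValueError(f"spot {i} has an empty neighbor set")
    op = neighbor_mean_matrix(neighbor_sets, len(neighbor_sets))
    return anp.dot(op, Z_sa)


def neighbor_mean_matrix(neighbor_sets, N: int) -> np.ndarray:
    """Row-stochastic neighbor-averaging operator as a dense matrix."""
    op = np.zeros((N, N))
    for i, nbrs in enumerate(neighbor_sets):
        if len(nbrs):
            op[i, np.asarray(nbrs, dtype=int)] = 1.0 / len(nbrs)
    return op


def permute_negatives(Z_ns, rng: Union[int, np.random.Generator, None] = None,
                      permutation: Optional[np.ndarray] = None):
    """Row-permuted copy of ``Z_ns`` serving as the negative samples.

    The permutation is drawn uniformly from the seeded generator; the
    row multiset is preserved so positives and negatives share a
    marginal distribution.  A fixed ``permutation`` can be injected for
    testing.
    """
    N = Z_ns.shape[0]
    if permutation is None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        permutation = rng.permutation(N)
    permutation = np.asarray(permutation, dtype=int)
    return Z_ns[permutation]


def bilinear_score(a, b, M):
    """Shared bilinear discriminator ``D_c(a, b) = a^T M b`` per row."""
    return anp.sum(anp.dot(a, M) * b, axis=1)


def _sigmoid(x):
    # tanh form with clipped input: overflow-safe in both passes
    # (beyond +-60 the sigmoid is saturated and the gradient is ~0)
    return 0.5 * (anp.tanh(0.5 * anp.clip(x, -60.0, 60.0)) + 1.0)


def lgcm_loss(Z_sa, Z_ns, C, Z_neg, M, eps: float = 1e-7):
    """Sum of the local and global contrastive losses.

    Local: spot embeddings against their neighborhood summaries;
    global: spot embeddings against the paired non-spatial embeddings;
    both against the same row-aligned permuted negatives, scored by one
    shared bilinear discriminator.  With a zero discriminator every
    probability is 1/2 and the loss equals ``4 log 2``.
    """
    def _binary_terms(pos_scores, neg_scores):
        p_pos = anp.clip(_sigmoid(pos_scores), eps, 1.0 - eps)
        p_neg = anp.clip(_sigmoid(neg_scores), eps, 1.0 - eps)
        return -anp.mean(anp.log(p_pos) + anp.log(1.0 - p_neg))

    neg = bilinear_score(Z_sa, Z_neg, M)
    local = _binary_terms(bilinear_score(Z_sa, C, M), neg)
    global_ = _binary_terms(bilinear_score(Z_sa, Z_ns, M), neg)
    return local + global_


# ---------------------------------------------------------------------------
# adversarial alignment mechanism
# ---------------------------------------------------------------------------

def modality_probability(Z, params):
    """Discriminator probability that an embedding is spatial-branch."""
    h = anp.maximum(anp.dot(Z, params["dm_W1"]) + params["dm_b1"], 0.0)
    logit = anp.dot(h, params["dm_W2"])[:, 0] + params["dm_b2"][0]
    return _sigmoid(logit)


def aam_loss(Z_sa, Z_ns, params, grl_lambda: float = 1.0, eps: float = 1e-7):
    """Adversarial objective with gradient reversal on both branches.

    ``-E[log D(Z_sa)] - E[log(1 - D(Z_ns))]``: minimized directly it
    trains the discriminator; the reversal layer flips the gradient
    reaching the encoders, pushing the branches toward
    indistinguishability.  At chance (D = 1/2) the loss is ``2 log 2``.
    """
    p_sa = modality_probability(grad_reverse(Z_sa, grl_lambda), params)
    p_ns = modality_probability(grad_reverse(Z_ns, grl_lambda), params)
    p_sa = anp.clip(p_sa, eps, 1.0 - eps)
    p_ns = anp.clip(p_ns, eps, 1.0 - eps)
    return -anp.mean(anp.log(p_sa)) - anp.mean(anp.log(1.0 - p_ns))


# ---------------------------------------------------------------------------
# attention fusion mechanism
# ---------------------------------------------------------------------------

def attention_fuse(Z_sa, Z_ns, att_w):
    """Per-spot softmax weighting of the two branch embeddings.

    A single linear scorer maps either embedding to a scalar; the two
    logits are softmaxed into ``(alpha_1, alpha_2)`` with rows summing
    to one, and the fused embedding is the convex combination.
    """
    l1 = anp.dot(Z_sa, att_w)
    l2 = anp.dot(Z_ns, att_w)
    m = anp.maximum(l1, l2)
    e1 = anp.exp(l1 - m)
    e2 = anp.exp(l2 - m)
    denom = e1 + e2
    a1 = e1 / denom
    a2 = e2 / denom
    alphas = anp.stack([a1, a2], axis=1)
    Z_att = a1[:, None] * Z_sa + a2[:, None] * Z_ns
    return alphas, Z_att


def decode_expression(Z, params):
    """Two-layer MLP decoder from the fused embedding to expression."""
    h = anp.maximum(anp.dot(Z, params["dec_W1"]) + params["dec_b1"], 0.0)
    return anp.dot(h, params["dec_W2"]) + params["dec_b2"]


def afm_loss(Z_att, params, X):
    """Mean-squared reconstruction error of the fused-embedding decoder.

    Returns the loss and the reconstruction (the "enhanced" expression
    used downstream).
    """
    X_hat = decode_expression(Z_att, params)
    return anp.mean((X_hat - X) ** 2), X_hat
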