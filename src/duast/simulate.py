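"""Synthetic spatial-omics data with known domains and known SVGs.

The generator emulates the structure the model's tasks assume: spots on
a jittered square lattice partitioned into spatially contiguous domains
(Voronoi cells of random seed points); a planted subset of spatially
variable genes that behave like domain markers (equally spaced domain
levels, permuted per gene) and additionally carry a smooth
Gaussian-bump field; and null genes whose values are permuted across
spots, so they keep a realistic marginal distribution but are spatially
random (Moran's I ~ 0) by construction.  Log-scale values are
exponentiated and rounded to nonnegative integer counts.  An optional
second modality is a linear read-out of the domain identity plus noise,
with a coupling knob from uninformative (0) upward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import STDataset


@dataclass
class SyntheticTruth:
    domain_labels: np.ndarray          # length N
    svg_flags: np.ndarray              # boolean, length n_genes
    domain_means: np.ndarray           # n_domains x n_genes (log scale)
    spatial_fields: list = field(default_factory=list)  # per-SVG bump params

    def save_json(self, path) -> None:
        obj = {
            "domain_labels": self.domain_labels.tolist(),
            "svg_flags": self.svg_flags.astype(int).tolist(),
            "spatial_fields": self.spatial_fields,
        }
        Path(path).write_text(json.dumps(obj))


def generate_st(
    n_spots: int = 900,
    n_genes: int = 200,
    n_domains: int = 3,
    n_svg: int = 20,
    noise_sd: float = 1.0,
    seed: int = 0,
    domain_sd: float = 0.3,
    base_mean: float = 2.0,
    bump_amplitude: tuple = (1.2, 2.0),
    bump_bandwidth: tuple = (0.15, 0.3),
    svg_domain_boost: float = 4.0,
    jitter: float = 0.3,
    count_model: str = "lognormal",
) -> tuple[STDataset, SyntheticTruth]:
    """Simulate one spatial-transcriptomics slice with ground truth.

    Defaults: 900 spots on a 30x30 lattice, 200 genes, 3 contiguous
    domains, 20 planted SVGs.  Expression of gene g in domain k is
    ``Normal(base_mean + domain effect, noise_sd)`` on the log scale
    (domain effects drawn ``Normal(0, domain_sd)`` per gene and domain);
    planted SVGs add a Gaussian bump ``a * exp(-||x - c||^2 / (2 b^2))``
    with amplitude and bandwidth (as a fraction of the slice side) drawn
    from the given ranges and centers kept away from the border.  Counts
    are ``round(exp(value))`` (lognormal), or Poisson with that mean
    under ``count_model="nb"``-free alternative ``"poisson"``.
    """
    if n_svg > n_genes:
        raise ValueError("n_svg cannot exceed n_genes")
    if n_domains < 2:
        raise ValueError("need at least 2 domains")
    rng = np.random.default_rng(seed)

    # jittered lattice
    side = int(np.ceil(np.sqrt(n_spots)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    coords = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)[:n_spots]
    coords += rng.uniform(-jitter, jitter, size=coords.shape)
    L = float(side - 1)

    # contiguous domains: Voronoi cells of random seed points
    for _ in range(100):
        centers = rng.uniform(0, L, size=(n_domains, 2))
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        labels = d2.argmin(axis=1)
        if np.unique(labels).size == n_domains:
            break
    else:
        raise RuntimeError("could not place non-empty domains")

    domain_means = base_mean + rng.normal(0.0, domain_sd,
                                          size=(n_domains, n_genes))

    svg_flags = np.zeros(n_genes, dtype=bool)
    svg_idx = rng.choice(n_genes, size=n_svg, replace=False)
    svg_flags[svg_idx] = True
    # planted SVGs behave like domain markers: equally spaced domain
    # levels (permuted per gene) guarantee each a floor of between-
    # domain spread, so their spatial variability reflects tissue
    # structure, not only the added smooth field
    if n_svg and svg_domain_boost > 0:
        levels = np.linspace(-1.0, 1.0, n_domains) * svg_domain_boost * domain_sd
        for gidx in svg_idx:
            domain_means[:, gidx] = base_mean + rng.permutation(levels)

    log_expr = domain_means[labels] + rng.normal(0.0, noise_sd,
                                                 size=(n_spots, n_genes))
    fields = []
    for g in np.sort(svg_idx):
        c = rng.uniform(0.2 * L, 0.8 * L, size=2)
        bw = rng.uniform(*bump_bandwidth) * L
        amp = rng.uniform(*bump_amplitude)
        r2 = ((coords - c) ** 2).sum(axis=1)
        log_expr[:, g] += amp * np.exp(-r2 / (2.0 * bw ** 2))
        fields.append({"gene": int(g), "center": c.tolist(),
                       "bandwidth": float(bw), "amplitude": float(amp)})

    lam = np.exp(log_expr)
    if count_model == "lognormal":
        counts = np.rint(lam)
    elif count_model == "poisson":
        counts = rng.poisson(lam).astype(float)
    else:
        raise ValueError(f"unknown count_model {count_model!r}")
    counts = np.maximum(counts, 0.0)

    genes = [f"g{i:04d}" for i in range(n_genes)]
    ds = STDataset(X1=counts, X2=counts.copy(), coords=coords,
                   gene_names=genes, modality2_kind="rna_copy",
                   truth_labels=labels.astype(int))
    truth = SyntheticTruth(domain_labels=labels.astype(int),
                           svg_flags=svg_flags, domain_means=domain_means,
                           spatial_fields=fields)
    return ds, truth


def generate_multiomics(
    base: STDataset,
    truth: SyntheticTruth,
    coupling: float = 1.0,
    d2: int = 50,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> STDataset:
    """Attach a correlated second modality to a simulated dataset.

    ``X2`` is a linear map of the one-hot domain signal (loadings drawn
    ``Normal(0, coupling)``) plus ``Normal(0, noise_sd)`` noise;
    ``coupling=0`` yields a second modality carrying no domain
    information.
    """
    rng = np.random.default_rng(seed)
    labels = truth.domain_labels
    n_domains = labels.max() + 1
    onehot = np.eye(n_domains)[labels]
    loadings = rng.normal(0.0, coupling, size=(n_domains, d2)) if coupling > 0 \
        else np.zeros((n_domains, d2))
    X2 = onehot @ loadings + rng.normal(0.0, noise_sd,
                                        size=(base.n_spots, d2))
    return STDataset(X1=base.X1.copy(), X2=X2, coords=base.coords.copy(),
                     gene_names=list(base.gene_names),
                     modality2_kind="other",
                     truth_labels=None if base.truth_labels is None
                     else base.truth_labels.copy())
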