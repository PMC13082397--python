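"""Configuration containers for the dual-branch model.

All tunable dimensions, loss weights and optimizer settings live in
:class:`ModelConfig`; preprocessing thresholds live in
:class:`PreprocessParams`.  Both are plain dataclasses that round-trip
through dictionaries (and therefore YAML/JSON) for run manifests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace


@dataclass
class PreprocessParams:
    """Filtering/normalization settings for the primary expression matrix.

    min_cells_per_gene : genes detected in fewer spots are dropped.
    n_top_hvg          : number of highly variable genes retained
                         (dispersion-ranked); capped at the number of
                         genes surviving the filter.
    normalize_total    : scale each spot to the median library size.
    log1p              : apply log(1 + x) after normalization.
    """

    min_cells_per_gene: int = 3
    n_top_hvg: int = 3000
    normalize_total: bool = True
    log1p: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


MODES = ("domain", "svg")


@dataclass
class ModelConfig:
    """Hyper-parameters of the dual-branch model and its training loop.

    Dimensions
    ----------
    d3 : GCN hidden width of the spatial branch.
    d4 : latent width per branch (the fused embedding has the same width;
         the concatenated embedding used for gene scoring has 2*d4).
    nsb_hidden / disc_hidden / dec_hidden : hidden widths of the
        non-spatial MLP encoder, the modality discriminator, and the
        expression decoder.

    Loss weights
    ------------
    lambda1..lambda4 weight (graph ELBO, local-global contrast,
    adversarial alignment, attention-fusion reconstruction) in domain
    mode; beta1..beta4 weight the same first three plus the linear
    reconstruction term in svg mode.

    The gradient-reversal scale warms up linearly from 0 to
    ``grl_lambda_max`` over the first ``grl_warmup_frac`` of epochs,
    the usual stabilization for adversarial alignment.
    """

    # architecture
    d3: int = 64
    d4: int = 32
    nsb_hidden: int = 64
    disc_hidden: int = 64
    dec_hidden: int = 64
    use_bn: bool = True

    # spatial graph
    k_neighbors: int = 6

    # composite loss weights (domain mode)
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    lambda4: float = 1.0
    # composite loss weights (svg mode)
    beta1: float = 1.0
    beta2: float = 1.0
    beta3: float = 1.0
    beta4: float = 1.0

    # optimisation
    epochs: int = 600
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0
    mode: str = "domain"

    # adversarial alignment
    grl_lambda_max: float = 1.0
    grl_warmup_frac: float = 0.3

    # numerics
    eps_clip: float = 1e-7

    # secondary-modality (ATAC) latent-semantic projection width
    lsi_dim: int = 50

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("lambda1", "lambda2", "lambda3", "lambda4",
                     "beta1", "beta2", "beta3", "beta4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.grl_warmup_frac <= 1.0):
            raise ValueError("grl_warmup_frac must lie in [0, 1]")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return cls(**d)

    def with_overrides(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    @classmethod
    def for_svg(cls, **overrides) -> "ModelConfig":
        """Defaults tuned for spatial-relevance scoring.

        Gene scoring decomposes the linear decoder over the two latent
        subspaces, so it benefits from a wider latent (more room for
        per-gene spatial features before the KL prunes them) and a
        gentler adversarial pull (less homogenization between the
        subspaces) than domain clustering does.
        """
        base = dict(mode="svg", d4=64, grl_lambda_max=0.3)
        base.update(overrides)
        return cls(**base)

    @property
    def loss_weights(self) -> tuple[float, float, float, float]:
        """Active composite-loss weights for the configured mode."""
        if self.mode == "domain":
            return (self.lambda1, self.lambda2, self.lambda3, self.lambda4)
        return (self.beta1, self.beta2, self.beta3, self.beta4)
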