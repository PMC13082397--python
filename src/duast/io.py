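"""Readers and preprocessing for spatial-omics inputs.

The tool consumes a spot-by-gene expression matrix ``X1`` with 2-D spot
coordinates, plus an optional second modality ``X2`` (protein/ADT counts,
ATAC features, or — in single-omics mode — a copy of the expression
matrix fed to the non-spatial branch).  Supported containers: ``.h5ad``
(AnnData), a MatrixMarket triplet (``matrix.mtx`` + ``features.tsv`` +
``barcodes.tsv`` with a coordinates CSV), and plain delimited text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import PreprocessParams

MODALITY2_KINDS = ("rna_copy", "adt", "atac", "other")


@dataclass
class STDataset:
    """A spatial-omics dataset: expression, coordinates, optional truth.

    Rows of ``X1``, ``X2`` and ``coords`` are aligned spot-for-spot; the
    row order is preserved through every downstream stage.
    """

    X1: np.ndarray                       # N x d1
    X2: np.ndarray                       # N x d2
    coords: np.ndarray                   # N x 2
    gene_names: list = field(default_factory=list)
    modality2_kind: str = "rna_copy"
    truth_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X1 = _to_dense(self.X1)
        self.X2 = _to_dense(self.X2)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.X1.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"coords rows ({self.coords.shape[0]}) != X1 rows ({self.X1.shape[0]})"
            )
        if self.X1.shape[0] != self.X2.shape[0]:
            raise ValueError(
                f"X2 rows ({self.X2.shape[0]}) != X1 rows ({self.X1.shape[0]})"
            )
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be N x 2")
        if self.modality2_kind not in MODALITY2_KINDS:
            raise ValueError(f"modality2_kind must be one of {MODALITY2_KINDS}")

    @property
    def n_spots(self) -> int:
        return self.X1.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X1.shape[1]


def _to_dense(X) -> np.ndarray:
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_dataset(
    path,
    format_hint: Optional[str] = None,
    coords_key: str = "spatial",
    coords_path=None,
    truth_key: Optional[str] = None,
    secondary_path=None,
    modality2_kind: str = "rna_copy",
) -> STDataset:
    """Load a raw (unprocessed) dataset from disk.

    Parameters
    ----------
    path
        An ``.h5ad`` file, a directory holding a MatrixMarket triplet
        (``matrix.mtx``, ``features.tsv``, ``barcodes.tsv`` and
        ``coords.csv`` unless ``coords_path`` is given), or a delimited
        text matrix (spots x genes, header row, first column spot ids;
        requires ``coords_path``).
    coords_key
        ``obsm`` key holding coordinates in the h5ad route.
    truth_key
        Optional ``obs`` column with reference domain labels (h5ad).
    secondary_path
        Optional second-modality matrix (h5ad/MTX-dir/delimited); must
        have the same number of rows.  Without it ``X2`` is a copy of
        the raw ``X1`` (single-omics mode).
    """
    path = Path(path)
    fmt = format_hint or _sniff_format(path)
    if fmt == "h5ad":
        X1, genes, coords, truth = _load_h5ad(path, coords_key, truth_key)
    elif fmt == "mtx":
        X1, genes, coords = _load_mtx_dir(path, coords_path)
        truth = None
    elif fmt == "csv":
        X1, genes, coords = _load_delimited(path, coords_path)
        truth = None
    else:
        raise ValueError(f"unrecognized format {fmt!r}")

    if coords is None:
        raise ValueError("dataset has no spatial coordinates "
                         f"(looked for {coords_key!r} / coords table)")
    if coords.shape[0] != X1.shape[0]:
        raise ValueError("coordinate table does not match matrix row count")

    if secondary_path is not None:
        X2 = _load_matrix_only(Path(secondary_path), coords_path)
        if X2.shape[0] != X1.shape[0]:
            raise ValueError("secondary modality row count differs from X1")
    else:
        X2 = X1.copy()
        modality2_kind = "rna_copy"

    return STDataset(X1=X1, X2=X2, coords=coords, gene_names=list(genes),
                     modality2_kind=modality2_kind, truth_labels=truth)


def _sniff_format(path: Path) -> str:
    if path.is_dir():
        return "mtx"
    if path.suffix == ".h5ad":
        return "h5ad"
    if path.suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer format of {path}")


def _load_h5ad(path: Path, coords_key: str, truth_key: Optional[str]):
    import anndata

    adata = anndata.read_h5ad(path)
    X1 = _to_dense(adata.X)
    genes = list(adata.var_names)
    coords = None
    if coords_key in adata.obsm:
        coords = np.asarray(adata.obsm[coords_key], dtype=float)
    truth = None
    if truth_key is not None:
        if truth_key not in adata.obs:
            raise ValueError(f"obs column {truth_key!r} not found")
        truth = pd.Categorical(adata.obs[truth_key]).codes.astype(int)
    return X1, genes, coords, truth


def _load_mtx_dir(path: Path, coords_path):
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        cands = sorted(path.glob("*.mtx"))
        if not cands:
            raise FileNotFoundError(f"no .mtx file in {path}")
        mtx = cands[0]
    M = scipy.io.mmread(str(mtx))
    M = _to_dense(M)
    genes = _read_single_column(path / "features.tsv")
    barcodes = _read_single_column(path / "barcodes.tsv")
    # CellRanger convention stores genes x barcodes; orient to spots x genes
    if M.shape[0] == len(genes) and M.shape[1] == len(barcodes):
        M = M.T
    elif not (M.shape[0] == len(barcodes) and M.shape[1] == len(genes)):
        raise ValueError("matrix shape matches neither features x barcodes "
                         "nor barcodes x features")
    cpath = Path(coords_path) if coords_path else path / "coords.csv"
    if not cpath.exists():
        raise ValueError(f"coordinates table {cpath} not found")
    coords = _read_coords(cpath)
    return M, genes, coords


def _read_single_column(path: Path) -> list:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=None)
    return list(df.iloc[:, 0].astype(str))


def _read_coords(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c for c in df.columns if c.lower() in ("x", "y")]
    if len(cols) == 2:
        return df[sorted(cols, key=str.lower)].to_numpy(dtype=float)
    return df.iloc[:, -2:].to_numpy(dtype=float)


def _load_delimited(path: Path, coords_path):
    if coords_path is None:
        raise ValueError("delimited-text input requires a coordinates table")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    coords = _read_coords(Path(coords_path))
    return df.to_numpy(dtype=float), list(df.columns), coords


def _load_matrix_only(path: Path, coords_path) -> np.ndarray:
    fmt = _sniff_format(path)
    if fmt == "h5ad":
        import anndata

        return _to_dense(anndata.read_h5ad(path).X)
    if fmt == "mtx":
        return _load_mtx_dir(path, coords_path)[0]
    return pd.read_csv(path, sep=None, engine="python", index_col=0).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_expression(
    raw: np.ndarray, params: Optional[PreprocessParams] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Filter, select HVGs, normalize and log-transform raw counts.

    Pipeline: (1) drop genes detected in fewer than
    ``min_cells_per_gene`` spots; (2) scale each spot to the median
    library size; (3) rank genes by normalized dispersion
    (variance/mean of the normalized matrix, ties broken by gene index)
    and keep the top ``n_top_hvg``; (4) log(1 + x).

    Returns the processed matrix and the indices (into the raw gene
    axis) of the retained genes.
    """
    params = params or PreprocessParams()
    X = _to_dense(raw)
    if X.size == 0:
        raise ValueError("empty expression matrix")
    if np.any(X < 0):
        raise ValueError("raw expression must be nonnegative")

    detected = (X > 0).sum(axis=0)
    keep = np.flatnonzero(detected >= params.min_cells_per_gene)
    if keep.size == 0:
        raise ValueError("all genes removed by the low-expression filter")
    X = X[:, keep]

    if params.normalize_total:
        lib = X.sum(axis=1)
        target = np.median(lib[lib > 0]) if np.any(lib > 0) else 1.0
        scale = np.divide(target, lib, out=np.zeros_like(lib), where=lib > 0)
        X = X * scale[:, None]

    n_hvg = min(params.n_top_hvg, X.shape[1])
    if n_hvg < X.shape[1]:
        mean = X.mean(axis=0)
        var = X.var(axis=0)
        disp = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
        # stable sort on -disp: ties resolved by lower gene index
        order = np.argsort(-disp, kind="stable")
        sel = np.sort(order[:n_hvg])
        X = X[:, sel]
        keep = keep[sel]

    if params.log1p:
        X = np.log1p(X)

    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values after preprocessing")
    return X, keep


def preprocess_secondary(
    raw: np.ndarray,
    kind: str,
    params: Optional[PreprocessParams] = None,
    lsi_dim: int = 50,
) -> np.ndarray:
    """Modality-appropriate preprocessing for the second matrix.

    - ``rna_copy``: same pipeline as :func:`preprocess_expression`.
    - ``adt``: per-spot centered log-ratio transform, the standard for
      antibody-derived tag counts.
    - ``atac``: TF-IDF weighting followed by a truncated latent-semantic
      (SVD) projection to ``lsi_dim`` components.
    - ``other``: column standardization (z-score) only.
    """
    if kind not in MODALITY2_KINDS:
        raise ValueError(f"kind must be one of {MODALITY2_KINDS}")
    X = _to_dense(raw)

    if kind == "rna_copy":
        return preprocess_expression(X, params)[0]

    if kind == "adt":
        if np.any(X < 0):
            raise ValueError("ADT counts must be nonnegative")
        logged = np.log1p(X)
        return logged - logged.mean(axis=1, keepdims=True)

    if kind == "atac":
        if np.any(X < 0):
            raise ValueError("ATAC features must be nonnegative")
        return _tfidf_lsi(X, lsi_dim)

    # "other": pass-through with standardization
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _tfidf_lsi(X: np.ndarray, n_components: int) -> np.ndarray:
    n, p = X.shape
    rowsum = X.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    tf = X / rowsum
    df = (X > 0).sum(axis=0).astype(float)
    df[df == 0] = 1.0
    idf = np.log(1.0 + n / df)
    T = tf * idf
    k = min(n_components, min(n, p) - 1)
    if k < 1:
        raise ValueError("matrix too small for latent-semantic projection")
    from sklearn.decomposition import TruncatedSVD

    svd = TruncatedSVD(n_components=k, algorithm="arpack")
    return svd.fit_transform(T)


def preprocess_dataset(
    dataset: STDataset,
    params: Optional[PreprocessParams] = None,
    lsi_dim: int = 50,
) -> tuple[STDataset, np.ndarray]:
    """Apply the full preprocessing to both modalities of a raw dataset.

    Returns the processed dataset (aligned row order, filtered genes)
    and the kept-gene index vector for ``X1``.
    """
    params = params or PreprocessParams()
    X1p, kept = preprocess_expression(dataset.X1, params)
    if dataset.modality2_kind == "rna_copy":
        X2p = X1p.copy()
    else:
        X2p = preprocess_secondary(dataset.X2, dataset.modality2_kind,
                                   params, lsi_dim=lsi_dim)
    genes = [dataset.gene_names[i] for i in kept] if dataset.gene_names else []
    out = STDataset(X1=X1p, X2=X2p, coords=dataset.coords.copy(),
                    gene_names=genes, modality2_kind=dataset.modality2_kind,
                    truth_labels=None if dataset.truth_labels is None
                    else np.asarray(dataset.truth_labels).copy())
    return out, kept


# ---------------------------------------------------------------------------
# writers (used by the simulator and the CLI)
# ---------------------------------------------------------------------------

def save_h5ad(dataset: STDataset, path, extra_var: Optional[dict] = None) -> None:
    import anndata

    adata = anndata.AnnData(X=dataset.X1.astype(np.float32))
    adata.var_names = [str(g) for g in dataset.gene_names] or [
        f"g{i}" for i in range(dataset.n_genes)
    ]
    adata.obsm["spatial"] = dataset.coords
    if dataset.X2 is not None and dataset.modality2_kind != "rna_copy":
        adata.obsm["X2"] = dataset.X2.astype(np.float32)
    adata.uns["modality2_kind"] = dataset.modality2_kind
    if dataset.truth_labels is not None:
        adata.obs["domain"] = pd.Categorical(dataset.truth_labels.astype(int))
    for key, vec in (extra_var or {}).items():
        adata.var[key] = vec
    adata.write_h5ad(Path(path))


def save_mtx(dataset: STDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"),
                     sp.csr_matrix(dataset.X1.T))  # genes x barcodes
    genes = dataset.gene_names or [f"g{i}" for i in range(dataset.n_genes)]
    pd.Series(genes).to_csv(outdir / "features.tsv", sep="\t",
                            index=False, header=False)
    pd.Series([f"spot{i}" for i in range(dataset.n_spots)]).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.DataFrame(dataset.coords, columns=["x", "y"]).to_csv(
        outdir / "coords.csv", index=False)
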