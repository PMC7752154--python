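"""Learning latent expression signatures with an autoencoder.

A signature is one latent dimension of an autoencoder trained on a
(preprocessed) cells x genes matrix: its decoder row gives per-gene loadings,
and projecting any expression matrix through the encoder gives per-observation
signature scores. The default architecture is the simplest that supports the
downstream analyses — a single hidden layer (genes -> K -> genes), linear by
default with an optional ReLU bottleneck — trained by full- or mini-batch Adam
on mean-squared reconstruction error. In the linear, unregularized limit the
decoder rows span the top-K principal subspace of the (gene-centred) data,
which anchors the model against a classical-PCA oracle.

Latent dimensions are sign-indeterminate; :func:`orient_signatures` fixes each
signature's direction so its mean loading over a reference gene set is
non-negative, giving downstream odds ratios a stable direction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import h5py
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GeneOverlapError, TrainingDivergenceError

logger = logging.getLogger(__name__)

_NORM_KEY = "normalization"


@dataclass
class NormalizationSpec:
    """Recorded pre-processing, reapplied verbatim when projecting new data."""

    target_total: float = 1e4
    log1p: bool = True
    n_top_genes: int | None = None

    def to_dict(self) -> dict:
        return {"target_total": self.target_total, "log1p": self.log1p,
                "n_top_genes": self.n_top_genes}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(**d)


def preprocess(adata: ad.AnnData, spec: NormalizationSpec | None = None) -> ad.AnnData:
    """Library-size normalize, log1p-transform and optionally restrict genes.

    Each observation is scaled to ``spec.target_total`` counts, then
    log1p-transformed. With ``n_top_genes`` set, the matrix is restricted to
    the most variable genes (variance of the normalized values). All-zero
    observations and genes are dropped with a warning. The applied spec is
    recorded in ``.uns`` so bulk data can later be pushed through the
    identical transform; calling preprocess on an already-normalized matrix
    is the identity.
    """
    if spec is None:
        spec = NormalizationSpec()
    if adata.uns.get(_NORM_KEY) is not None:
        return adata

    X = np.asarray(adata.X, dtype=np.float64)
    obs_tot = X.sum(axis=1)
    keep_obs = obs_tot > 0
    if not keep_obs.all():
        warnings.warn(f"dropping {int((~keep_obs).sum())} all-zero observation(s)")
        adata = adata[keep_obs].copy()
        X = X[keep_obs]
        obs_tot = obs_tot[keep_obs]
    gene_tot = X.sum(axis=0)
    keep_gene = gene_tot > 0
    if not keep_gene.all():
        warnings.warn(f"dropping {int((~keep_gene).sum())} all-zero gene(s)")
        adata = adata[:, keep_gene].copy()
        X = X[:, keep_gene]

    X = X * (spec.target_total / X.sum(axis=1, keepdims=True))
    if spec.log1p:
        X = np.log1p(X)
    if spec.n_top_genes is not None and spec.n_top_genes < X.shape[1]:
        order = np.argsort(X.var(axis=0))[::-1][: spec.n_top_genes]
        order = np.sort(order)
        adata = adata[:, order].copy()
        X = X[:, order]

    out = ad.AnnData(X=X, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns[_NORM_KEY] = spec.to_dict()
    return out


@dataclass
class TrainingConfig:
    """Optimizer and architecture knobs for :func:`train_signature_model`."""

    epochs: int = 300
    batch_size: int = 0          # 0 = full batch
    learning_rate: float = 1e-2
    activation: str = "linear"   # "linear" | "relu"
    weight_decay: float = 0.0
    seed: int = 0


@dataclass
class SignatureModel:
    """Trained encoder/decoder defining K latent expression signatures."""

    gene_ids: list[str]
    K: int
    enc_weights: np.ndarray      # genes x K
    enc_bias: np.ndarray         # K
    dec_weights: np.ndarray      # K x genes, rows L2-normalized
    dec_bias: np.ndarray         # genes
    gene_means: np.ndarray       # genes; centring applied before encoding
    activation: str
    normalization_spec: dict
    training_log: list[float] = field(default_factory=list)
    training_activations: np.ndarray | None = None
    training_obs_ids: list[str] | None = None

    @property
    def signature_ids(self) -> list[str]:
        return [f"s{k + 1}" for k in range(self.K)]

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dec_weights.T, index=self.gene_ids,
                            columns=self.signature_ids)


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return z
    if kind == "relu":
        return np.maximum(z, 0.0)
    raise ConfigurationError(f"activation must be 'linear' or 'relu', got {kind!r}")


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train_signature_model(
    adata: ad.AnnData,
    K: int,
    config: TrainingConfig | None = None,
) -> SignatureModel:
    """Fit the autoencoder and return its weights as a :class:`SignatureModel`.

    The input should be preprocessed (see :func:`preprocess`); genes are
    centred internally. Training is deterministic given ``config.seed``.
    After training, decoder rows are rescaled to unit L2 norm — with the
    positively homogeneous activations used here this leaves the
    reconstruction unchanged while making loading magnitudes comparable
    across signatures. Raises :class:`TrainingDivergenceError`, reporting the
    last finite epoch, if the loss leaves the reals.
    """
    cfg = config or TrainingConfig()
    X = np.asarray(adata.X, dtype=np.float64)
    n, g = X.shape
    if K < 1 or K > g:
        raise ConfigurationError(f"K must satisfy 1 <= K <= n_genes ({g}), got {K}")

    rng = np.random.default_rng(cfg.seed)
    gene_means = X.mean(axis=0)
    Xc = X - gene_means

    We = rng.normal(0.0, 1.0 / np.sqrt(g), size=(g, K))
    be = np.zeros(K)
    Wd = rng.normal(0.0, 1.0 / np.sqrt(K), size=(K, g))
    bd = np.zeros(g)
    opt = _Adam([We, be, Wd, bd], cfg.learning_rate)

    batch = n if cfg.batch_size in (0, None) or cfg.batch_size >= n else cfg.batch_size
    log: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        sse = 0.0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xb = Xc[idx]
            z = xb @ We + be
            h = _activate(z, cfg.activation)
            recon = h @ Wd + bd
            resid = recon - xb
            sse += float((resid ** 2).sum())
            m = len(idx)
            d_recon = 2.0 * resid / (m * g)
            gWd = h.T @ d_recon + cfg.weight_decay * Wd
            gbd = d_recon.sum(axis=0)
            d_h = d_recon @ Wd.T
            if cfg.activation == "relu":
                d_h = d_h * (z > 0)
            gWe = xb.T @ d_h + cfg.weight_decay * We
            gbe = d_h.sum(axis=0)
            opt.step([gWe, gbe, gWd, gbd])
        loss = sse / (n * g)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(
                f"non-finite loss at epoch {epoch}; last good epoch "
                f"{len(log) - 1} with loss {log[-1] if log else float('nan')}")
        log.append(loss)

    # unit-norm decoder rows; compensate in the encoder (valid because the
    # activation is positively homogeneous)
    norms = np.linalg.norm(Wd, axis=1)
    norms[norms == 0] = 1.0
    Wd /= norms[:, None]
    We *= norms
    be *= norms

    model = SignatureModel(
        gene_ids=list(map(str, adata.var_names)), K=K,
        enc_weights=We, enc_bias=be, dec_weights=Wd, dec_bias=bd,
        gene_means=gene_means, activation=cfg.activation,
        normalization_spec=dict(adata.uns.get(_NORM_KEY) or {}),
        training_log=log,
    )
    model.training_activations = _activate(Xc @ We + be, cfg.activation)
    model.training_obs_ids = list(map(str, adata.obs_names))
    return model


def encode(
    adata: ad.AnnData,
    model: SignatureModel,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Project an expression matrix onto the model's K signatures.

    Genes are aligned to the model's universe by identifier: extra genes are
    dropped, missing genes imputed at the normalized-zero value. If the input
    is not flagged as normalized, the model's recorded normalization is
    applied first, so bulk counts and single-cell counts travel through the
    identical transform. Returns an observations x K score frame with columns
    ``s1..sK``.
    """
    model_index = pd.Index(model.gene_ids)
    overlap = model_index.intersection(adata.var_names)
    frac = len(overlap) / len(model_index)
    if frac < min_overlap:
        raise GeneOverlapError(
            f"only {len(overlap)}/{len(model_index)} model genes present "
            f"({frac:.1%} < required {min_overlap:.0%})")
    if frac < 1.0:
        logger.info("gene mapping: %d/%d model genes found; %d imputed as zero",
                    len(overlap), len(model_index), len(model_index) - len(overlap))

    if adata.uns.get(_NORM_KEY) is None:
        adata = preprocess(adata, NormalizationSpec.from_dict(model.normalization_spec)
                           if model.normalization_spec else None)

    X = np.asarray(adata.X, dtype=np.float64)
    pos = pd.Index(adata.var_names).get_indexer(model_index)
    aligned = np.zeros((X.shape[0], len(model_index)))
    found = pos >= 0
    aligned[:, found] = X[:, pos[found]]

    H = _activate((aligned - model.gene_means) @ model.enc_weights + model.enc_bias,
                  model.activation)
    return pd.DataFrame(H, index=list(map(str, adata.obs_names)),
                        columns=model.signature_ids)


def orient_signatures(model: SignatureModel, reference_genes: Sequence[str]) -> SignatureModel:
    """Flip sign-indeterminate signatures so each has non-negative mean loading
    over ``reference_genes``; encoder columns and stored activations flip with
    the decoder so scores stay consistent."""
    idx = [i for i, gid in enumerate(model.gene_ids) if gid in set(reference_genes)]
    if not idx:
        return model
    signs = np.sign(model.dec_weights[:, idx].mean(axis=1))
    signs[signs == 0] = 1.0
    out = SignatureModel(
        gene_ids=list(model.gene_ids), K=model.K,
        enc_weights=model.enc_weights * signs,
        enc_bias=model.enc_bias * signs,
        dec_weights=model.dec_weights * signs[:, None],
        dec_bias=model.dec_bias.copy(),
        gene_means=model.gene_means.copy(),
        activation=model.activation,
        normalization_spec=dict(model.normalization_spec),
        training_log=list(model.training_log),
    )
    if model.training_activations is not None:
        out.training_activations = model.training_activations * signs
        out.training_obs_ids = list(model.training_obs_ids or [])
    return out


def save_model(model: SignatureModel, path: str) -> None:
    """Write a SignatureModel to HDF5 (weights) with JSON-encoded metadata."""
    with h5py.File(path, "w") as f:
        for name in ("enc_weights", "enc_bias", "dec_weights", "dec_bias", "gene_means"):
            f.create_dataset(name, data=getattr(model, name))
        f.create_dataset("training_log", data=np.asarray(model.training_log))
        f.create_dataset("gene_ids", data=np.array(model.gene_ids, dtype="S"))
        f.attrs["K"] = model.K
        f.attrs["activation"] = model.activation
        f.attrs["normalization_spec"] = json.dumps(model.normalization_spec)


def load_model(path: str) -> SignatureModel:
    with h5py.File(path, "r") as f:
        return SignatureModel(
            gene_ids=[s.decode() for s in f["gene_ids"][()]],
            K=int(f.attrs["K"]),
            enc_weights=f["enc_weights"][()],
            enc_bias=f["enc_bias"][()],
            dec_weights=f["dec_weights"][()],
            dec_bias=f["dec_bias"][()],
            gene_means=f["gene_means"][()],
            activation=str(f.attrs["activation"]),
            normalization_spec=json.loads(f.attrs["normalization_spec"]),
            training_log=list(f["training_log"][()]),
        )
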