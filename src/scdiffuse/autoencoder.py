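"""Autoencoder bridging expression space and the diffusion latent space.

A symmetric pair of MLPs maps log-normalized expression to a compact
latent code (default 128-D) and back. The decoder output is clamped at
zero through a ReLU, so reconstructions are non-negative and carry exact
zeros like real log-normalized counts.

Finetuning follows the layer-replacement contract used when transferring
a trained model to data with a different gene set: every layer is reused
except the encoder's first and the decoder's last, which are re-initialized
at the new gene count before the whole model is trained further.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import MLP, Adam, Linear
from .data_io import ExpressionMatrix, LOGNORM


@dataclass
class TrainingConfig:
    hidden_widths: list[int] = field(default_factory=lambda: [512, 256])
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 128
    seed: int = 0


@dataclass
class AutoencoderModel:
    encoder: MLP
    decoder: MLP
    latent_dim: int
    gene_names: list[str]
    config: TrainingConfig

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


def build_autoencoder(n_genes: int, latent_dim: int = 128,
                      hidden_widths: list[int] | None = None,
                      seed: int = 0) -> AutoencoderModel:
    """Symmetric encoder/decoder MLPs; deterministic init under fixed seed.

    ``hidden_widths=[]`` degenerates to a single linear map per side.
    """
    if n_genes <= 0 or latent_dim <= 0:
        raise ValueError("n_genes and latent_dim must be positive")
    if latent_dim >= n_genes:
        warnings.warn(f"latent_dim {latent_dim} >= n_genes {n_genes}: no compression")
    cfg = TrainingConfig(seed=seed)
    if hidden_widths is not None:
        cfg.hidden_widths = list(hidden_widths)
    rng = np.random.default_rng(seed)
    enc = MLP([n_genes, *cfg.hidden_widths, latent_dim], rng)
    dec = MLP([latent_dim, *reversed(cfg.hidden_widths), n_genes], rng,
              out_activation="leaky_relu")
    genes = [f"gene{j}" for j in range(n_genes)]
    return AutoencoderModel(enc, dec, latent_dim, genes, cfg)


def _check_lognorm(X: ExpressionMatrix, model: AutoencoderModel) -> np.ndarray:
    if X.layer_tag != LOGNORM:
        raise ValueError("autoencoder expects log-normalized expression")
    if X.n_genes != model.n_genes:
        raise ValueError(f"data has {X.n_genes} genes, model expects {model.n_genes}")
    return X.values


def train_autoencoder(model: AutoencoderModel, X: ExpressionMatrix,
                      epochs: int | None = None, batch_size: int | None = None,
                      learning_rate: float | None = None,
                      seed: int | None = None,
                      latent_noise: float = 0.0) -> tuple[AutoencoderModel, list[float]]:
    """Minimize reconstruction MSE with Adam; returns per-epoch loss history.

    ``latent_noise`` > 0 perturbs each latent code during training by that
    fraction of the batch's per-dimension latent spread before decoding, so
    the decoder stays well-behaved for codes slightly off the encoded
    manifold (the situation every diffusion-sampled code is in).

    ``epochs=0`` is a no-op with an empty history. Aborts on non-finite loss.
    """
    V = _check_lognorm(X, model)
    model.gene_names = list(X.gene_names)
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    batch_size = cfg.batch_size if batch_size is None else batch_size
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    params = model.encoder.params() + model.decoder.params()
    opt = Adam(params, lr=lr)
    history: list[float] = []
    n = V.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        total, nb = 0.0, 0
        for start in range(0, n, batch_size):
            xb = V[order[start:start + batch_size]]
            model.encoder.zero_grad()
            model.decoder.zero_grad()
            z = model.encoder.forward(xb)
            if latent_noise > 0.0:
                spread = z.std(axis=0, keepdims=True)
                z = z + latent_noise * spread * rng.standard_normal(z.shape)
            recon = model.decoder.forward(z)
            diff = recon - xb
            loss = float(np.mean(diff * diff))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite reconstruction loss at epoch {epoch} (lr={lr})")
            g = (2.0 / diff.size) * diff
            model.encoder.backward(model.decoder.backward(g))
            opt.step()
            total += loss
            nb += 1
        history.append(total / nb)
    return model, history


def finetune_autoencoder(pretrained: AutoencoderModel, X_new: ExpressionMatrix,
                         epochs: int | None = None, seed: int = 0,
                         **train_kwargs) -> AutoencoderModel:
    """Transfer a trained model to a (possibly different) gene set.

    All layers are reused except the encoder's first and the decoder's last
    linear layer, which are re-initialized for the new gene count; the whole
    model is then trained on ``X_new``.
    """
    if X_new.layer_tag != LOGNORM:
        raise ValueError("finetuning expects log-normalized expression")
    n_new = X_new.n_genes
    cfg = TrainingConfig(hidden_widths=list(pretrained.config.hidden_widths),
                         learning_rate=pretrained.config.learning_rate,
                         epochs=pretrained.config.epochs,
                         batch_size=pretrained.config.batch_size, seed=seed)
    model = build_autoencoder(n_new, pretrained.latent_dim, cfg.hidden_widths, seed=seed)
    model.config = cfg
    model.gene_names = list(X_new.gene_names)

    # copy every pretrained parameter except the two boundary linear layers
    enc_lin = [l for l in model.encoder.layers if isinstance(l, Linear)]
    dec_lin = [l for l in model.decoder.layers if isinstance(l, Linear)]
    pre_enc = [l for l in pretrained.encoder.layers if isinstance(l, Linear)]
    pre_dec = [l for l in pretrained.decoder.layers if isinstance(l, Linear)]
    if len(enc_lin) != len(pre_enc) or len(dec_lin) != len(pre_dec):
        raise ValueError("hidden architectures incompatible for finetuning")
    for new, old in zip(enc_lin[1:], pre_enc[1:]):
        if new.W.shape != old.W.shape:
            raise ValueError("hidden layer shape mismatch in encoder")
        new.W[...] = old.W
        new.b[...] = old.b
    for new, old in zip(dec_lin[:-1], pre_dec[:-1]):
        if new.W.shape != old.W.shape:
            raise ValueError("hidden layer shape mismatch in decoder")
        new.W[...] = old.W
        new.b[...] = old.b

    model, _ = train_autoencoder(model, X_new, epochs=epochs, seed=seed, **train_kwargs)
    return model


def encode(model: AutoencoderModel, X: ExpressionMatrix) -> np.ndarray:
    """Map lognorm expression to latent codes; pure function of (params, input)."""
    V = _check_lognorm(X, model)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite values in input")
    return model.encoder.forward(V)


def decode(model: AutoencoderModel, Z: np.ndarray) -> ExpressionMatrix:
    """Map latent codes back to (non-negative) lognorm expression."""
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite values in latent input")
    if Z.ndim != 2 or Z.shape[1] != model.latent_dim:
        raise ValueError(f"latent input must be (n, {model.latent_dim})")
    V = np.maximum(model.decoder.forward(Z), 0.0)
    return ExpressionMatrix(V, list(model.gene_names), layer_tag=LOGNORM)


# ---------------------------------------------------------------------------
# Checkpointing: one .npz per model with parameters, gene names and config.
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_autoencoder(model: AutoencoderModel, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "version": _CKPT_VERSION,
        "latent_dim": model.latent_dim,
        "gene_names": model.gene_names,
        "hidden_widths": model.config.hidden_widths,
        "learning_rate": model.config.learning_rate,
        "epochs": model.config.epochs,
        "batch_size": model.config.batch_size,
        "seed": model.config.seed,
    }
    arrays = {f"enc_{i}": a for i, a in enumerate(model.encoder.state_arrays())}
    arrays.update({f"dec_{i}": a for i, a in enumerate(model.decoder.state_arrays())})
    np.savez(path, meta=json.dumps(meta), **arrays)
    return path


def load_autoencoder(path: str | Path) -> AutoencoderModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["version"] != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        model = build_autoencoder(len(meta["gene_names"]), meta["latent_dim"],
                                  meta["hidden_widths"], seed=meta["seed"])
        model.gene_names = meta["gene_names"]
        model.config.learning_rate = meta["learning_rate"]
        model.config.epochs = meta["epochs"]
        model.config.batch_size = meta["batch_size"]
        n_enc = len(model.encoder.state_arrays())
        model.encoder.load_state_arrays([data[f"enc_{i}"] for i in range(n_enc)])
        n_dec = len(model.decoder.state_arrays())
        model.decoder.load_state_arrays([data[f"dec_{i}"] for i in range(n_dec)])
    return model
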