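"""Low-dimensional embedding of the joint multi-omics matrix.

Two interchangeable embedders are provided, both sklearn-style
transformers:

* :class:`AutoencoderEmbedder` — a compact fully connected autoencoder
  (mirrored encoder/decoder, ReLU hidden units, identity output, MSE
  loss, Adam optimizer, 90/10 train/validation split, early stopping on
  validation loss with best-weights restore).  The default encoder
  widths 4000 -> 1500 -> 800 -> 400 treat the last entry as the
  bottleneck; the latent representation is the bottleneck activation.
* :class:`PCAEmbedder` — deterministic projection onto the top principal
  axes, with the sign of each axis fixed so that its largest-magnitude
  loading is positive.  Useful as a fast, exactly reproducible stand-in
  for the autoencoder when testing the downstream clustering stages.

All randomness (weight init, data split, minibatch shuffling) derives
from the config seed, so fit -> transform is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .datatypes import check_finite


@dataclass
class AEConfig:
    hidden_dims: list[int] = field(default_factory=lambda: [4000, 1500, 800, 400])
    activation: str = "relu"
    loss: str = "mse"
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not self.hidden_dims or any(h < 1 for h in self.hidden_dims):
            raise ValueError("hidden_dims must be nonempty with all widths >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.activation != "relu":
            raise ValueError("only the rectifier activation is supported")
        if self.loss != "mse":
            raise ValueError("only mean squared error loss is supported")


@dataclass
class EmbeddingResult:
    latent: pd.DataFrame             # samples x bottleneck
    train_history: pd.DataFrame      # per-epoch train/val loss (may be empty)
    stopped_epoch: int
    config_echo: object


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


class AutoencoderEmbedder(TransformerMixin, BaseEstimator):
    """Fully connected autoencoder; ``transform`` returns the bottleneck."""

    def __init__(
        self,
        hidden_dims=(4000, 1500, 800, 400),
        learning_rate: float = 0.001,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 5,
        val_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.hidden_dims = hidden_dims
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    # ---------------------------------------------------------- internals

    def _layer_widths(self, d_in: int) -> list[int]:
        hidden = list(self.hidden_dims)
        # encoder d -> h1 -> ... -> bottleneck, decoder mirrored back to d
        return [d_in] + hidden + hidden[-2::-1] + [d_in]

    def _init_params(self, widths: list[int], rng: np.random.Generator):
        Ws, bs = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            Ws.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
            bs.append(np.zeros(fan_out))
        return Ws, bs

    def _forward(self, X, Ws, bs):
        acts = [X]
        n_layers = len(Ws)
        for i, (W, b) in enumerate(zip(Ws, bs)):
            z = acts[-1] @ W + b
            acts.append(z if i == n_layers - 1 else _relu(z))
        return acts

    def _loss(self, X, Ws, bs) -> float:
        recon = self._forward(X, Ws, bs)[-1]
        return float(np.mean((recon - X) ** 2))

    # -------------------------------------------------------------- sklearn

    def fit(self, X, y=None):
        cfg = AEConfig(
            hidden_dims=list(self.hidden_dims),
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            seed=self.seed,
        )
        cfg.validate()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 samples")
        check_finite(X, "autoencoder input")
        n, d = X.shape
        self.n_features_in_ = d

        rng = np.random.default_rng(cfg.seed)
        perm = rng.permutation(n)
        n_val = max(1, int(round(cfg.val_fraction * n)))
        if n_val >= n:
            n_val = n - 1
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        X_train, X_val = X[train_idx], X[val_idx]

        batch_size = cfg.batch_size
        if batch_size > len(train_idx):
            warnings.warn(
                f"batch_size {batch_size} exceeds training-set size "
                f"{len(train_idx)}; clamping",
                stacklevel=2,
            )
            batch_size = len(train_idx)

        widths = self._layer_widths(d)
        Ws, bs = self._init_params(widths, rng)
        mW = [np.zeros_like(W) for W in Ws]
        vW = [np.zeros_like(W) for W in Ws]
        mb = [np.zeros_like(b) for b in bs]
        vb = [np.zeros_like(b) for b in bs]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_val = np.inf
        best = None
        bad_epochs = 0
        history = []
        n_layers = len(Ws)

        epoch = 0
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(len(train_idx))
            epoch_loss, n_seen = 0.0, 0
            for start in range(0, len(order), batch_size):
                batch = X_train[order[start : start + batch_size]]
                acts = self._forward(batch, Ws, bs)
                recon = acts[-1]
                m = batch.shape[0]
                # dL/drecon for MSE averaged over entries
                delta = 2.0 * (recon - batch) / (m * d)
                epoch_loss += float(np.mean((recon - batch) ** 2)) * m
                n_seen += m
                t += 1
                for i in range(n_layers - 1, -1, -1):
                    a_prev = acts[i]
                    gW = a_prev.T @ delta
                    gb = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ Ws[i].T) * (acts[i] > 0)
                    # Adam update
                    mW[i] = beta1 * mW[i] + (1 - beta1) * gW
                    vW[i] = beta2 * vW[i] + (1 - beta2) * gW**2
                    mb[i] = beta1 * mb[i] + (1 - beta1) * gb
                    vb[i] = beta2 * vb[i] + (1 - beta2) * gb**2
                    lr_t = cfg.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                    Ws[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                    bs[i] -= lr_t * mb[i] / (np.sqrt(vb[i]) + eps)
            val_loss = self._loss(X_val, Ws, bs)
            history.append(
                {"epoch": epoch, "train_loss": epoch_loss / max(n_seen, 1),
                 "val_loss": val_loss}
            )
            if val_loss < best_val:  # strict improvement
                best_val = val_loss
                best = ([W.copy() for W in Ws], [b.copy() for b in bs])
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break

        if best is not None:
            Ws, bs = best
        self.weights_, self.biases_ = Ws, bs
        self.bottleneck_dim_ = list(self.hidden_dims)[-1]
        self.n_encoder_layers_ = len(list(self.hidden_dims))
        self.best_val_loss_ = best_val
        self.stopped_epoch_ = epoch
        self.history_ = pd.DataFrame(history)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("fit the embedder first")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input width {X.shape[1]} != model input width {self.n_features_in_}"
            )
        a = X
        for i in range(self.n_encoder_layers_):
            a = _relu(a @ self.weights_[i] + self.biases_[i])
        return a

    def reconstruct(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._forward(X, self.weights_, self.biases_)[-1]


class PCAEmbedder(TransformerMixin, BaseEstimator):
    """Top-d principal-axis projection with deterministic axis signs."""

    def __init__(self, n_components: int = 50, seed: int = 0):
        self.n_components = n_components
        self.seed = seed

    def fit(self, X, y=None):
        Xa = np.asarray(X, dtype=float)
        check_finite(Xa, "PCA input")
        d_max = min(Xa.shape[0] - 1, Xa.shape[1])
        if not 1 <= self.n_components <= d_max:
            raise ValueError(
                f"n_components must lie in [1, {d_max}] for a "
                f"{Xa.shape[0]}x{Xa.shape[1]} matrix"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(Xa)
        # sign convention: largest-|loading| entry of each axis is positive
        comps = pca.components_.copy()
        for j in range(comps.shape[0]):
            lead = np.argmax(np.abs(comps[j]))
            if comps[j, lead] < 0:
                comps[j] = -comps[j]
        pca.components_ = comps
        self.pca_ = pca
        self.n_features_in_ = Xa.shape[1]
        self.explained_variance_ = pca.explained_variance_
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input width {X.shape[1]} != fitted width {self.n_features_in_}"
            )
        return self.pca_.transform(X)


# ------------------------------------------------------- function wrappers

def train_autoencoder(joint: pd.DataFrame, config: AEConfig | None = None):
    """Fit an :class:`AutoencoderEmbedder` on the joint matrix."""
    config = config or AEConfig()
    config.validate()
    est = AutoencoderEmbedder(
        hidden_dims=list(config.hidden_dims),
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        val_fraction=config.val_fraction,
        seed=config.seed,
    )
    return est.fit(joint)


def encode(model: AutoencoderEmbedder, matrix: pd.DataFrame) -> EmbeddingResult:
    """Deterministic forward pass through the fitted encoder."""
    latent = model.transform(matrix)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else range(len(latent))
    latent_df = pd.DataFrame(
        latent, index=index, columns=[f"latent_{j}" for j in range(latent.shape[1])]
    )
    return EmbeddingResult(
        latent=latent_df,
        train_history=model.history_,
        stopped_epoch=model.stopped_epoch_,
        config_echo=model.get_params(),
    )


def pca_embed(matrix: pd.DataFrame, d: int) -> EmbeddingResult:
    """Deterministic PCA embedding onto the top-d axes."""
    est = PCAEmbedder(n_components=d).fit(matrix)
    latent = est.transform(matrix)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else range(len(latent))
    latent_df = pd.DataFrame(
        latent, index=index, columns=[f"latent_{j}" for j in range(d)]
    )
    return EmbeddingResult(
        latent=latent_df,
        train_history=pd.DataFrame(columns=["epoch", "train_loss", "val_loss"]),
        stopped_epoch=0,
        config_echo={"method": "pca", "n_components": d},
    )
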