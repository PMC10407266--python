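"""BiGRU encoder-decoder with additive attention for scalar prediction.

The encoder is a single bidirectional GRU layer producing per-position
hidden states h_1..h_T (forward and backward states concatenated). An
additive attention mechanism scores every encoder state against the
decoder's incoming state — which, before the single decoding step, is the
encoder's final hidden state — normalises the scores with a softmax into
weights alpha_j, and forms the context vector c = sum_j alpha_j h_j. The
decoder runs exactly one BiGRU step on the context vector concatenated
with a one-hot start element, initialised from the encoder final state,
and a one-unit dense layer maps the decoder output to the predicted
(scaled, log-transformed) intensity.

Because the output is a scalar rather than a sequence, the attention
weights of the single decoding step give one relevance value per sequence
position, which downstream interpretation averages per amino acid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .alphabet import Alphabet, PEPTIDE_ALPHABET
from .encoding import encode_batch

__all__ = ["ModelConfig", "PredictionResult", "AttentionIntensityModel"]


@dataclass
class ModelConfig:
    """Hyperparameters of the attention encoder-decoder.

    ``units`` is the GRU width per direction (encoder states have dimension
    2*units); the attention layer uses ``units`` hidden units. Training
    minimises MSE with Adam at its default settings and monitors MAE on a
    validation subset; the weights from the best validation epoch are kept.
    """

    units: int = 64
    max_len: int = 40
    alphabet_size: int = 21
    batch_size: int = 64
    epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0
    mask_padding: bool = False
    patience: int | None = None  # early stopping; None trains all epochs
    restore_best: bool = True

    def __post_init__(self):
        if self.units <= 0:
            raise ValueError("units must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")


@dataclass
class PredictionResult:
    """Scalar prediction plus the attention weights that produced it."""

    y_hat: float
    alpha: np.ndarray  # (max_len,), non-negative, sums to 1


class AttentionIntensityModel:
    """Sequence-to-scalar regressor with interpretable attention weights."""

    def __init__(self, config: ModelConfig, alphabet: Alphabet = PEPTIDE_ALPHABET,
                 dtype=np.float32):
        if alphabet.size != config.alphabet_size:
            raise ValueError(
                f"alphabet has {alphabet.size} channels but config declares "
                f"{config.alphabet_size}"
            )
        self.config = config
        self.alphabet = alphabet
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        U, A = config.units, config.alphabet_size
        # decoder input = context (2U) ++ one-hot start element (A + 1)
        self.start_dim = A + 1
        dec_in = 2 * U + self.start_dim
        self.params = {
            "enc_f": nn.gru_params(rng, A, U, dtype),
            "enc_b": nn.gru_params(rng, A, U, dtype),
            "att": nn.attention_params(rng, 2 * U, U, dtype),
            "dec_f": nn.gru_params(rng, dec_in, U, dtype),
            "dec_b": nn.gru_params(rng, dec_in, U, dtype),
            "out": nn.dense_params(rng, 2 * U, 1, dtype),
        }
        self.rng = rng
        self.history: dict[str, list[float]] = {}

    # -- architecture pieces (also exposed for inspection/testing) ---------

    def _check_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3 or X.shape[1] != self.config.max_len or \
                X.shape[2] != self.config.alphabet_size:
            raise ValueError(
                f"expected batch of shape (n, {self.config.max_len}, "
                f"{self.config.alphabet_size}), got {X.shape}"
            )
        return X

    def encode(self, X: np.ndarray):
        """Encoder states H (n, T, 2*units) and final state s (n, 2*units)."""
        X = self._check_batch(X)
        H, s, _ = self._encode_with_cache(X)
        return H, s

    def _encode_with_cache(self, X):
        Hf, cf = nn.gru_forward(X, self._h0(X.shape[0]), self.params["enc_f"])
        Hb_r, cb = nn.gru_forward(X[:, ::-1], self._h0(X.shape[0]),
                                  self.params["enc_b"])
        Hb = Hb_r[:, ::-1]
        H = np.concatenate([Hf, Hb], axis=2)
        s = np.concatenate([Hf[:, -1], Hb[:, 0]], axis=1)
        return H, s, (cf, cb, Hf, Hb)

    def _h0(self, n):
        return np.zeros((n, self.config.units), dtype=self.dtype)

    def attention(self, s: np.ndarray, H: np.ndarray, pad_mask=None):
        """Context vector, weights and raw scores for query ``s`` over ``H``."""
        context, alpha, scores, _ = nn.attention_forward(
            s, H, self.params["att"], pad_mask
        )
        return context, alpha, scores

    def _start_block(self, n):
        block = np.zeros((n, self.start_dim), dtype=self.dtype)
        block[:, -1] = 1.0  # dedicated start symbol channel (distinct from pad)
        return block

    def _forward(self, X):
        """Full forward pass; returns predictions, attention and a cache."""
        n = X.shape[0]
        H, s, enc_cache = self._encode_with_cache(X)
        pad_mask = None
        if self.config.mask_padding:
            pad_mask = X[:, :, self.alphabet.pad_index] > 0.5
        context, alpha, _, att_cache = nn.attention_forward(
            s, H, self.params["att"], pad_mask
        )
        u = np.concatenate([context, self._start_block(n)], axis=1)[:, None, :]
        cf, cb, Hf, Hb = enc_cache
        Df, cdf = nn.gru_forward(u, Hf[:, -1], self.params["dec_f"])
        Db, cdb = nn.gru_forward(u, Hb[:, 0], self.params["dec_b"])
        d = np.concatenate([Df[:, 0], Db[:, 0]], axis=1)
        y, dense_cache = nn.dense_forward(d, self.params["out"])
        cache = (cf, cb, att_cache, cdf, cdb, dense_cache)
        return y[:, 0], alpha, cache

    def _backward(self, dy, cache):
        cf, cb, att_cache, cdf, cdb, dense_cache = cache
        U = self.config.units
        dd, g_out = nn.dense_backward(dy[:, None], dense_cache)
        du_f, dh0f, g_decf = nn.gru_backward(dd[:, None, :U], None, cdf)
        du_b, dh0b, g_decb = nn.gru_backward(dd[:, None, U:], None, cdb)
        du = du_f[:, 0] + du_b[:, 0]
        dcontext = du[:, : 2 * U]
        ds, dH, g_att = nn.attention_backward(dcontext, att_cache)
        dHf_ext = np.ascontiguousarray(dH[:, :, :U])
        dHb_ext = np.ascontiguousarray(dH[:, :, U:])
        # the encoder final state feeds attention query and both decoder inits
        dHf_last = ds[:, :U] + dh0f
        dHb_first = ds[:, U:] + dh0b
        _, _, g_encf = nn.gru_backward(dHf_ext, dHf_last, cf)
        _, _, g_encb = nn.gru_backward(dHb_ext[:, ::-1], dHb_first, cb)
        return {
            "enc_f": g_encf, "enc_b": g_encb, "att": g_att,
            "dec_f": g_decf, "dec_b": g_decb, "out": g_out,
        }

    # -- training ----------------------------------------------------------

    def fit(self, X_train, y_train, X_val=None, y_val=None,
            verbose: bool = False):
        """Minimise MSE on (X_train, y_train); track MAE per epoch.

        ``y`` values are expected already transformed and scaled. Returns the
        per-epoch history dict (loss, mae, val_mae). When a validation set is
        given, the parameters from the epoch with the lowest validation MAE
        are restored at the end (and training stops early after
        ``config.patience`` epochs without improvement, if set).
        """
        X_train = self._check_batch(X_train)
        y_train = np.asarray(y_train, dtype=self.dtype)
        if X_train.shape[0] == 0:
            raise ValueError("empty training set")
        if X_train.shape[0] != y_train.shape[0]:
            raise ValueError("X and y length mismatch")
        has_val = X_val is not None and len(X_val) > 0
        if has_val:
            X_val = self._check_batch(X_val)
            y_val = np.asarray(y_val, dtype=self.dtype)

        flat = nn.flatten_params(self.params)
        opt = nn.Adam(flat, lr=self.config.learning_rate)
        n = X_train.shape[0]
        bs = min(self.config.batch_size, n)
        history = {"loss": [], "mae": [], "val_mae": []}
        best_val = np.inf
        best_weights = None
        stale = 0
        for epoch in range(self.config.epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            epoch_mae = 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                Xb, yb = X_train[idx], y_train[idx]
                y_hat, _, cache = self._forward(Xb)
                resid = y_hat - yb
                loss = float(np.mean(resid ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch "
                        f"{start // bs}: {loss!r}"
                    )
                grads = self._backward(
                    (2.0 / len(idx)) * resid.astype(self.dtype), cache
                )
                opt.step(nn.flatten_params(grads))
                epoch_loss += loss * len(idx)
                epoch_mae += float(np.abs(resid).sum())
            history["loss"].append(epoch_loss / n)
            history["mae"].append(epoch_mae / n)
            if has_val:
                val_pred = self.predict_values(X_val)
                val_mae = float(np.mean(np.abs(val_pred - y_val)))
                history["val_mae"].append(val_mae)
                if val_mae < best_val:
                    best_val = val_mae
                    best_weights = {k: v.copy() for k, v in flat.items()}
                    stale = 0
                else:
                    stale += 1
                    if self.config.patience is not None and stale >= self.config.patience:
                        break
            if verbose:
                msg = (f"epoch {epoch + 1}: loss={history['loss'][-1]:.3e} "
                       f"mae={history['mae'][-1]:.3e}")
                if has_val:
                    msg += f" val_mae={history['val_mae'][-1]:.3e}"
                print(msg)
        if has_val and self.config.restore_best and best_weights is not None:
            for k, v in best_weights.items():
                flat[k][...] = v
        self.history = history
        return history

    # -- inference ---------------------------------------------------------

    def predict_values(self, X) -> np.ndarray:
        """Predicted scalars only, batched to bound memory."""
        X = self._check_batch(X)
        out = np.empty(X.shape[0], dtype=self.dtype)
        bs = max(self.config.batch_size, 256)
        for start in range(0, X.shape[0], bs):
            y_hat, _, _ = self._forward(X[start : start + bs])
            out[start : start + bs] = y_hat
        return out

    def predict_with_attention(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Predicted scalars and attention weights, as arrays (n,), (n, T)."""
        X = self._check_batch(X)
        ys = np.empty(X.shape[0], dtype=self.dtype)
        alphas = np.empty((X.shape[0], self.config.max_len), dtype=self.dtype)
        bs = max(self.config.batch_size, 256)
        for start in range(0, X.shape[0], bs):
            y_hat, alpha, _ = self._forward(X[start : start + bs])
            ys[start : start + bs] = y_hat
            alphas[start : start + bs] = alpha
        return ys, alphas

    def predict(self, X) -> list[PredictionResult]:
        y_hat, alpha = self.predict_with_attention(X)
        return [PredictionResult(float(y), a.copy()) for y, a in zip(y_hat, alpha)]

    def predict_sequences(self, sequences) -> list[PredictionResult]:
        X = encode_batch(sequences, self.alphabet, self.config.max_len)
        return self.predict(X)

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        """Weights as .npz plus a JSON sidecar with config and alphabet."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **nn.flatten_params(self.params))
        sidecar = {
            "config": asdict(self.config),
            "alphabet": {
                "residues": self.alphabet.residues,
                "pad_symbol": self.alphabet.pad_symbol,
                "start_symbol": self.alphabet.start_symbol,
            },
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "AttentionIntensityModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        config = ModelConfig(**sidecar["config"])
        alphabet = Alphabet(**sidecar["alphabet"])
        model = cls(config, alphabet)
        flat = nn.flatten_params(model.params)
        with np.load(directory / "weights.npz") as weights:
            for k in flat:
                flat[k][...] = weights[k]
        return model
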