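"""NumPy building blocks for the recurrent attention model.

Implements exactly what the architecture needs, with analytic gradients:

* a batched GRU layer (update gate z, reset gate r, candidate state h')
  with backprop through time,
* additive (Bahdanau-style) attention  e_j = v . tanh(W s + U h_j + b),
  softmax-normalised into weights and a context vector,
* a dense layer and the Adam optimizer with its standard defaults.

Gate convention (Cho-style):

    z_t = sigmoid(x_t Wx_z + h_{t-1} Wh_z + b_z)
    r_t = sigmoid(x_t Wx_r + h_{t-1} Wh_r + b_r)
    h'_t = tanh(x_t Wx_c + (r_t * h_{t-1}) Wh_c + b_c)
    h_t = (1 - z_t) * h_{t-1} + z_t * h'_t

All forward functions return a cache consumed by the matching backward
function; gradients are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# initializers


def glorot_uniform(rng: np.random.Generator, shape, dtype=np.float32):
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(rng: np.random.Generator, n: int, dtype=np.float32):
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # make the decomposition unique
    return q.astype(dtype)


def gru_params(rng, input_dim: int, units: int, dtype=np.float32) -> dict:
    """Initialise one GRU layer: Glorot input kernels, orthogonal recurrent."""
    return {
        "Wx": glorot_uniform(rng, (input_dim, 3 * units), dtype),
        "Wh_zr": np.concatenate(
            [orthogonal(rng, units, dtype), orthogonal(rng, units, dtype)], axis=1
        ),
        "Wh_c": orthogonal(rng, units, dtype),
        "b": np.zeros(3 * units, dtype=dtype),
    }


# ---------------------------------------------------------------------------
# GRU layer


def gru_forward(X: np.ndarray, h0: np.ndarray, p: dict):
    """Run a GRU over ``X`` (B, T, I) from initial state ``h0`` (B, U).

    Returns the per-step hidden states (B, T, U) and a backprop cache. The
    input projection for all steps and gates is batched into one matmul.
    """
    B, T, _ = X.shape
    U = p["Wh_c"].shape[0]
    G = X @ p["Wx"] + p["b"]  # (B, T, 3U) pre-activations from input
    H = np.empty((B, T, U), dtype=G.dtype)
    Z = np.empty_like(H)
    R = np.empty_like(H)
    C = np.empty_like(H)
    h = h0
    for t in range(T):
        g = G[:, t]
        zr = sigmoid(g[:, : 2 * U] + h @ p["Wh_zr"])
        z, r = zr[:, :U], zr[:, U:]
        c = np.tanh(g[:, 2 * U :] + (r * h) @ p["Wh_c"])
        Z[:, t], R[:, t], C[:, t] = z, r, c
        h = (1.0 - z) * h + z * c
        H[:, t] = h
    cache = (X, h0, H, Z, R, C, p)
    return H, cache


def gru_backward(dH_ext: np.ndarray, dh_last: np.ndarray | None, cache):
    """Backprop through time.

    ``dH_ext`` holds the external gradient flowing into each hidden state
    (B, T, U); ``dh_last`` is an extra gradient on the final state (or None).
    Returns (dX, dh0, grads).
    """
    X, h0, H, Z, R, C, p = cache
    B, T, U = H.shape
    dG = np.empty((B, T, 3 * U), dtype=H.dtype)
    dWh_zr = np.zeros_like(p["Wh_zr"])
    dWh_c = np.zeros_like(p["Wh_c"])
    dh = np.zeros_like(h0) if dh_last is None else dh_last.copy()
    for t in range(T - 1, -1, -1):
        dh = dh + dH_ext[:, t]
        h_prev = H[:, t - 1] if t > 0 else h0
        z, r, c = Z[:, t], R[:, t], C[:, t]
        dz = dh * (c - h_prev)
        dc = dh * z
        dh_prev = dh * (1.0 - z)
        dc_pre = dc * (1.0 - c * c)
        dWh_c += (r * h_prev).T @ dc_pre
        drh = dc_pre @ p["Wh_c"].T
        dr = drh * h_prev
        dh_prev += drh * r
        dz_pre = dz * z * (1.0 - z)
        dr_pre = dr * r * (1.0 - r)
        dzr_pre = np.concatenate([dz_pre, dr_pre], axis=1)
        dWh_zr += h_prev.T @ dzr_pre
        dh_prev += dzr_pre @ p["Wh_zr"].T
        dG[:, t, : 2 * U] = dzr_pre
        dG[:, t, 2 * U :] = dc_pre
        dh = dh_prev
    I = X.shape[2]
    grads = {
        "Wx": X.reshape(-1, I).T @ dG.reshape(-1, 3 * U),
        "Wh_zr": dWh_zr,
        "Wh_c": dWh_c,
        "b": dG.sum(axis=(0, 1)),
    }
    dX = dG @ p["Wx"].T
    return dX, dh, grads


# ---------------------------------------------------------------------------
# additive attention


def attention_params(rng, state_dim: int, att_units: int, dtype=np.float32) -> dict:
    return {
        "Wa": glorot_uniform(rng, (state_dim, att_units), dtype),
        "Ua": glorot_uniform(rng, (state_dim, att_units), dtype),
        "ba": np.zeros(att_units, dtype=dtype),
        "v": glorot_uniform(rng, (att_units, 1), dtype)[:, 0],
    }


def attention_forward(s: np.ndarray, H: np.ndarray, p: dict, pad_mask=None):
    """Additive attention of query state ``s`` (B, D) over ``H`` (B, T, D).

    ``pad_mask`` (B, T, boolean, True at padded positions) optionally
    excludes positions from the softmax. Returns context (B, D), weights
    (B, T), scores (B, T) and a cache.
    """
    u = np.tanh((s @ p["Wa"] + p["ba"])[:, None, :] + H @ p["Ua"])  # (B,T,K)
    e = u @ p["v"]  # (B, T)
    e_masked = np.where(pad_mask, np.float32(-1e9), e) if pad_mask is not None else e
    e_shift = e_masked - e_masked.max(axis=1, keepdims=True)
    expe = np.exp(e_shift)
    alpha = expe / expe.sum(axis=1, keepdims=True)
    context = np.einsum("bt,btd->bd", alpha, H)
    cache = (s, H, u, alpha, pad_mask, p)
    return context, alpha, e, cache


def attention_backward(dcontext: np.ndarray, cache):
    """Gradients of the context vector w.r.t. query, states and parameters."""
    s, H, u, alpha, pad_mask, p = cache
    B, T, K = u.shape
    dalpha = np.einsum("bd,btd->bt", dcontext, H)
    dH = alpha[:, :, None] * dcontext[:, None, :]
    de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    if pad_mask is not None:
        de = np.where(pad_mask, 0.0, de)
    dv = np.einsum("btk,bt->k", u, de)
    du_pre = de[:, :, None] * p["v"] * (1.0 - u * u)  # (B,T,K)
    D = H.shape[2]
    dUa = H.reshape(-1, D).T @ du_pre.reshape(-1, K)
    dH += du_pre @ p["Ua"].T
    ds_pre = du_pre.sum(axis=1)  # (B, K)
    grads = {"Wa": s.T @ ds_pre, "Ua": dUa, "ba": ds_pre.sum(axis=0), "v": dv}
    ds = ds_pre @ p["Wa"].T
    return ds, dH, grads


# ---------------------------------------------------------------------------
# dense head


def dense_params(rng, input_dim: int, units: int = 1, dtype=np.float32) -> dict:
    return {
        "W": glorot_uniform(rng, (input_dim, units), dtype),
        "b": np.zeros(units, dtype=dtype),
    }


def dense_forward(x: np.ndarray, p: dict):
    return x @ p["W"] + p["b"], (x, p)


def dense_backward(dy: np.ndarray, cache):
    x, p = cache
    grads = {"W": x.T @ dy, "b": dy.sum(axis=0)}
    return dy @ p["W"].T, grads


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with the standard defaults (lr 1e-3, beta 0.9/0.999, eps 1e-7).

    Operates on a flat dict of parameter arrays, updated in place.
    """

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def flatten_params(tree: dict, prefix: str = "") -> dict:
    """Flatten a nested dict of arrays into {'path/leaf': array}."""
    flat = {}
    for k, v in tree.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            flat.update(flatten_params(v, key + "/"))
        else:
            flat[key] = v
    return flat
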