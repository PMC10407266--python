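"""Target transforms, sequence encodings and cross-validation splits.

Intensities are natural-log transformed and min-max scaled to a target
range before model fitting; sequences are one-hot encoded to a fixed
``max_len`` with a pad channel. The positional tabular encoding used by
the random-forest / ridge baselines is the row-flattened one-hot matrix:
one binary variable per (position, symbol) pair, 40 x 21 = 840 for
peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold
from sklearn.preprocessing import MinMaxScaler

from .alphabet import Alphabet, PEPTIDE_ALPHABET

MAX_LEN = 40


def log_transform(intensity):
    """Natural log of positive intensities (array or scalar)."""
    x = np.asarray(intensity, dtype=float)
    if np.any(x <= 0):
        raise ValueError("log_transform requires strictly positive intensities")
    return np.log(x)


def inverse_log_transform(log_intensity):
    return np.exp(np.asarray(log_intensity, dtype=float))


@dataclass(frozen=True)
class ScalerParams:
    """Affine min-max scaling: observed [min, max] -> [target_lo, target_hi].

    The transform extrapolates linearly outside the fitted range, which
    matters because test folds may contain intensities beyond the training
    range.
    """

    observed_min: float
    observed_max: float
    target_lo: float = 0.0
    target_hi: float = 1.0

    def __post_init__(self):
        if not self.observed_max > self.observed_min:
            raise ValueError("constant input: observed_max must exceed observed_min")
        if not self.target_hi > self.target_lo:
            raise ValueError("target_hi must exceed target_lo")

    @property
    def scale(self) -> float:
        return (self.target_hi - self.target_lo) / (self.observed_max - self.observed_min)

    def apply(self, values):
        v = np.asarray(values, dtype=float)
        return self.target_lo + (v - self.observed_min) * self.scale

    def invert(self, scaled):
        s = np.asarray(scaled, dtype=float)
        return self.observed_min + (s - self.target_lo) / self.scale


def fit_minmax(values, target_lo: float = 0.0, target_hi: float = 1.0) -> ScalerParams:
    """Fit min-max scaling on training values (sklearn MinMaxScaler semantics)."""
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if v.size < 2:
        raise ValueError("need at least 2 values to fit a scaler")
    sk = MinMaxScaler(feature_range=(target_lo, target_hi)).fit(v)
    return ScalerParams(
        observed_min=float(sk.data_min_[0]),
        observed_max=float(sk.data_max_[0]),
        target_lo=target_lo,
        target_hi=target_hi,
    )


def one_hot_encode(
    sequence: str,
    alphabet: Alphabet = PEPTIDE_ALPHABET,
    max_len: int = MAX_LEN,
) -> np.ndarray:
    """Encode a sequence as a ``max_len x alphabet.size`` 0/1 matrix.

    Row *t* is one-hot at the channel of residue *t*; positions past the
    sequence end are one-hot at the pad channel, so every row sums to 1.
    """
    if len(sequence) > max_len:
        raise ValueError(
            f"sequence of length {len(sequence)} exceeds max_len={max_len}"
        )
    mat = np.zeros((max_len, alphabet.size), dtype=np.float32)
    for t, symbol in enumerate(sequence):
        mat[t, alphabet.index(symbol)] = 1.0
    mat[len(sequence):, alphabet.pad_index] = 1.0
    return mat


def one_hot_decode(matrix: np.ndarray, alphabet: Alphabet = PEPTIDE_ALPHABET) -> str:
    """Inverse of :func:`one_hot_encode`; strips trailing pad positions."""
    symbols = alphabet.residues + alphabet.pad_symbol
    seq = "".join(symbols[i] for i in np.argmax(matrix, axis=1))
    return seq.rstrip(alphabet.pad_symbol)


def encode_batch(
    sequences,
    alphabet: Alphabet = PEPTIDE_ALPHABET,
    max_len: int = MAX_LEN,
) -> np.ndarray:
    """Stack one-hot encodings into a ``n x max_len x alphabet.size`` array."""
    return np.stack([one_hot_encode(s, alphabet, max_len) for s in sequences])


def positional_tabular_encode(
    sequence: str,
    alphabet: Alphabet = PEPTIDE_ALPHABET,
    max_len: int = MAX_LEN,
) -> np.ndarray:
    """Flat binary vector with one variable per (position, symbol) pair.

    For the peptide alphabet this is the 840-variable encoding (40 positions
    x 21 symbols) used by the random-forest and ridge baselines. Equals the
    one-hot matrix flattened position-major, so exactly ``max_len`` entries
    are 1.
    """
    return one_hot_encode(sequence, alphabet, max_len).reshape(-1)


def tabular_design_matrix(
    sequences,
    alphabet: Alphabet = PEPTIDE_ALPHABET,
    max_len: int = MAX_LEN,
) -> np.ndarray:
    return np.stack(
        [positional_tabular_encode(s, alphabet, max_len) for s in sequences]
    )


@dataclass(frozen=True)
class FoldAssignment:
    """k-fold split with a per-fold validation subset of the training items.

    ``fold_index[i]`` is the test fold of item *i*. ``val_mask[f, i]`` marks
    item *i* as validation inside the training split of fold *f*; it is only
    meaningful where ``fold_index[i] != f``.
    """

    fold_index: np.ndarray
    val_mask: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero((self.fold_index != fold) & ~self.val_mask[fold])

    def val_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero((self.fold_index != fold) & self.val_mask[fold])


def kfold_split(
    n_items: int,
    k: int = 5,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> FoldAssignment:
    """Shuffled k-fold assignment with a validation subset per training split.

    Folds are disjoint, exhaustive and differ in size by at most one. Within
    each training split, ``val_fraction`` of the items (randomly, seeded) are
    held out to monitor overfitting during training.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if n_items < k:
        raise ValueError(f"need at least k={k} items, got {n_items}")
    fold_index = np.empty(n_items, dtype=np.int64)
    for f, (_, test_idx) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n_items))
    ):
        fold_index[test_idx] = f
    rng = np.random.default_rng(seed)
    val_mask = np.zeros((k, n_items), dtype=bool)
    for f in range(k):
        train = np.flatnonzero(fold_index != f)
        n_val = int(round(val_fraction * train.size))
        chosen = rng.choice(train, size=n_val, replace=False)
        val_mask[f, chosen] = True
    return FoldAssignment(fold_index=fold_index, val_mask=val_mask, k=k, seed=seed)
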