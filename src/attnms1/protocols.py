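"""Canned end-to-end protocols for the proof-of-concept datasets.

These wire the standard pipeline together: generate a synthetic preset,
transform targets (natural log for the exponential preset, identity for
the linear ones), min-max scale on the training data, train the attention
model with a validation subset, and evaluate on held-out data. Used by the
example scripts, the benchmark CLI and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention_model import AttentionIntensityModel, ModelConfig
from .encoding import encode_batch, fit_minmax, kfold_split, log_transform
from .evaluation import mape, pearson
from .interpretation import AttentionProfile, mean_attention_per_aa
from .synthetic import SyntheticDataset, generate, preset, recovery_score

#: Training protocol defaults for the proof-of-concept runs: GRU width 64
#: per direction, minibatch 64, at most 30 epochs with early stopping once
#: validation MAE stops improving for 5 epochs (best-epoch weights kept).
POC_UNITS = 64
POC_BATCH = 64
POC_EPOCHS = 30
POC_PATIENCE = 5


@dataclass
class PocRunResult:
    """Held-out metrics of one proof-of-concept run.

    ``mape`` / ``pcc`` are computed on the evaluation scale: the natural
    target scale for linear presets, the log scale for the exponential one.
    """

    mape: float
    pcc: float
    profile: AttentionProfile
    ground_truth: dict[str, float]
    n_epochs: int

    def recovery(self) -> tuple[float, float]:
        return recovery_score(self.profile, self.ground_truth)


def _poc_config(ds: SyntheticDataset, seed: int, units: int, epochs: int) -> ModelConfig:
    return ModelConfig(units=units, max_len=ds.spec.max_len,
                       alphabet_size=ds.spec.channels, batch_size=POC_BATCH,
                       epochs=epochs, seed=seed, patience=POC_PATIENCE)


def _eval_targets(ds: SyntheticDataset) -> np.ndarray:
    if ds.spec.transform == "exponential":
        return log_transform(ds.targets)
    return np.asarray(ds.targets, dtype=float)


def _run_split(ds, y, train_idx, val_idx, test_idx, seed, units, epochs):
    X = encode_batch(ds.sequences, ds.spec.alphabet, ds.spec.max_len)
    scaler = fit_minmax(y[np.concatenate([train_idx, val_idx])])
    model = AttentionIntensityModel(_poc_config(ds, seed, units, epochs),
                                    ds.spec.alphabet)
    history = model.fit(X[train_idx], scaler.apply(y[train_idx]),
                        X[val_idx], scaler.apply(y[val_idx]))
    pred = scaler.invert(model.predict_values(X[test_idx]))
    _, alphas = model.predict_with_attention(X[test_idx])
    test_seqs = [ds.sequences[i] for i in test_idx]
    profile = mean_attention_per_aa(test_seqs, alphas)
    return PocRunResult(
        mape=mape(y[test_idx], pred), pcc=pearson(y[test_idx], pred),
        profile=profile, ground_truth=ds.ground_truth,
        n_epochs=len(history["loss"]),
    )


def poc_holdout(preset_name: str, n_sequences: int = 10_000, seed: int = 0,
                units: int = POC_UNITS, epochs: int = POC_EPOCHS) -> PocRunResult:
    """Single 80/20 train/test split (20% of training held out as validation)."""
    ds = generate(preset(preset_name, n_sequences=n_sequences, seed=seed))
    y = _eval_targets(ds)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_sequences)
    n_test = n_sequences // 5
    test_idx = order[:n_test]
    rest = order[n_test:]
    n_val = int(round(0.2 * rest.size))
    val_idx, train_idx = rest[:n_val], rest[n_val:]
    return _run_split(ds, y, train_idx, val_idx, test_idx, seed, units, epochs)


def poc_crossval(preset_name: str, n_sequences: int = 10_000, seed: int = 0,
                 k: int = 5, units: int = POC_UNITS,
                 epochs: int = POC_EPOCHS) -> list[PocRunResult]:
    """Full k-fold cross-validation; returns one result per fold."""
    ds = generate(preset(preset_name, n_sequences=n_sequences, seed=seed))
    y = _eval_targets(ds)
    folds = kfold_split(n_sequences, k=k, seed=seed)
    results = []
    for f in range(k):
        results.append(_run_split(
            ds, y, folds.train_indices(f), folds.val_indices(f),
            folds.test_indices(f), seed * 100 + f, units, epochs))
    return results


def average_profile(results: list[PocRunResult]) -> AttentionProfile:
    """Residue-wise mean of per-run attention profiles (noise reduction)."""
    keys = sorted(set().union(*(r.profile.mean_weight for r in results)))
    mean_weight = {}
    n_seqs = {}
    for aa in keys:
        vals = [r.profile.mean_weight[aa] for r in results
                if aa in r.profile.mean_weight]
        mean_weight[aa] = float(np.mean(vals))
        n_seqs[aa] = int(sum(r.profile.n_sequences_containing.get(aa, 0)
                             for r in results))
    return AttentionProfile(mean_weight=mean_weight,
                            n_sequences_containing=n_seqs)
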