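"""Metrics and the cross-validation / baseline benchmarking harness.

Performance is reported as MAPE (mean absolute percentage error), MAE,
MSE and the Pearson correlation between predicted and observed values,
both on the (natural-log) transformed scale the model is trained on and
on the exponentiated real intensity scale. Cross-validation trains one
model per fold and aggregates fold metrics as mean +/- sample SD.

The random-forest and ridge baselines consume the positional tabular
encoding (one binary variable per position x symbol pair; 840 variables
for 40-long peptides over 21 channels) and run through the same harness
so their reports are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge

from .alphabet import Alphabet, PEPTIDE_ALPHABET
from .attention_model import AttentionIntensityModel, ModelConfig
from .encoding import (FoldAssignment, encode_batch, fit_minmax, kfold_split,
                       log_transform, tabular_design_matrix)

__all__ = ["mape", "mae_mse", "pearson", "MetricReport", "crossval", "baseline"]


def mape(y, y_hat) -> float:
    """100 * mean(|y - y_hat| / |y|); requires all true values nonzero."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if np.any(y == 0):
        raise ValueError("MAPE undefined for zero true values")
    return float(100.0 * np.mean(np.abs(y - y_hat) / np.abs(y)))


def mae_mse(y, y_hat) -> tuple[float, float]:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    resid = y - y_hat
    return float(np.mean(np.abs(resid))), float(np.mean(resid ** 2))


def pearson(y, y_hat) -> float:
    return float(stats.pearsonr(np.asarray(y, float),
                                np.asarray(y_hat, float)).statistic)


@dataclass
class MetricReport:
    """Per-fold metrics with mean +/- sample SD aggregation."""

    model: str
    folds: list[dict] = field(default_factory=list)

    def add_fold(self, **metrics) -> None:
        self.folds.append(metrics)

    def mean(self, key: str) -> float:
        return float(np.mean([f[key] for f in self.folds]))

    def sd(self, key: str) -> float:
        vals = [f[key] for f in self.folds]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict:
        keys = self.folds[0].keys() if self.folds else ()
        return {k: {"mean": self.mean(k), "sd": self.sd(k)} for k in keys}

    def to_dict(self) -> dict:
        return {"model": self.model, "folds": self.folds,
                "summary": self.summary()}

    def format_table(self) -> str:
        s = self.summary()
        lines = [f"Model: {self.model}",
                 f"{'metric':<12}{'mean':>12}{'sd':>12}"]
        for k, v in s.items():
            lines.append(f"{k:<12}{v['mean']:>12.4g}{v['sd']:>12.4g}")
        return "\n".join(lines)


def _fold_metrics(y_true_t, y_pred_t, use_log: bool) -> dict:
    """Metrics on the transformed (possibly log) scale and the real scale."""
    if use_log:
        y_log, p_log = y_true_t, y_pred_t
        y_real, p_real = np.exp(y_true_t), np.exp(y_pred_t)
    else:
        y_real, p_real = y_true_t, y_pred_t
        y_log, p_log = np.log(y_true_t), np.log(np.maximum(y_pred_t, 1e-300))
    mae, mse = mae_mse(y_true_t, y_pred_t)
    return {
        "mape_log": mape(y_log, p_log),
        "mape_real": mape(y_real, p_real),
        "pcc_log": pearson(y_log, p_log),
        "pcc_real": pearson(y_real, p_real),
        "mae": mae,
        "mse": mse,
    }


def _prepare_targets(targets, use_log: bool):
    t = np.asarray(targets, dtype=float)
    return log_transform(t) if use_log else t


def crossval(
    sequences,
    targets,
    config: ModelConfig,
    alphabet: Alphabet = PEPTIDE_ALPHABET,
    k: int = 5,
    seed: int = 0,
    use_log: bool = True,
    scale_range: tuple[float, float] = (0.0, 1.0),
    folds: FoldAssignment | None = None,
    verbose: bool = False,
) -> MetricReport:
    """k-fold cross-validation of the attention model.

    Per fold: the target transform's min-max scaler is fitted on the
    training split only; the model trains on scaled (log-)targets with a
    validation subset for overfitting control; test predictions are
    inverted back to the log and real scales before computing metrics.
    """
    y_t = _prepare_targets(targets, use_log)
    X = encode_batch(sequences, alphabet, config.max_len)
    if folds is None:
        folds = kfold_split(len(sequences), k=k, seed=seed)
    report = MetricReport(model="attention")
    for f in range(folds.k):
        tr, va, te = folds.train_indices(f), folds.val_indices(f), folds.test_indices(f)
        scaler = fit_minmax(y_t[np.concatenate([tr, va])], *scale_range)
        model = AttentionIntensityModel(
            _with_seed(config, config.seed + f), alphabet
        )
        model.fit(X[tr], scaler.apply(y_t[tr]), X[va], scaler.apply(y_t[va]),
                  verbose=verbose)
        try:
            pred_t = scaler.invert(model.predict_values(X[te]))
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"evaluation failed in fold {f}") from exc
        report.add_fold(**_fold_metrics(y_t[te], pred_t, use_log))
    return report


def _with_seed(config: ModelConfig, seed: int) -> ModelConfig:
    from dataclasses import replace

    return replace(config, seed=seed)


_BASELINES = {
    "random_forest": lambda seed, params: RandomForestRegressor(
        n_estimators=params.get("n_estimators", 100),
        max_depth=params.get("max_depth"),
        random_state=seed,
        n_jobs=params.get("n_jobs", 1),
    ),
    "ridge": lambda seed, params: Ridge(alpha=params.get("alpha", 1.0)),
}


def baseline(
    sequences,
    targets,
    kind: str,
    alphabet: Alphabet = PEPTIDE_ALPHABET,
    max_len: int = 40,
    k: int = 5,
    seed: int = 0,
    use_log: bool = True,
    scale_range: tuple[float, float] = (0.0, 1.0),
    folds: FoldAssignment | None = None,
    **params,
) -> MetricReport:
    """Random-forest or ridge baseline on the positional tabular encoding.

    Uses the same fold structure, target transform and scaling as
    :func:`crossval`; the validation subset is folded back into training
    (the baselines have no epoch-wise overfitting control).
    """
    if kind not in _BASELINES:
        raise ValueError(f"unknown baseline {kind!r}; choose from {sorted(_BASELINES)}")
    y_t = _prepare_targets(targets, use_log)
    X = tabular_design_matrix(sequences, alphabet, max_len)
    if folds is None:
        folds = kfold_split(len(sequences), k=k, seed=seed)
    report = MetricReport(model=kind)
    for f in range(folds.k):
        tr = np.flatnonzero(folds.fold_index != f)
        te = folds.test_indices(f)
        scaler = fit_minmax(y_t[tr], *scale_range)
        est = _BASELINES[kind](seed + f, params)
        try:
            est.fit(X[tr], scaler.apply(y_t[tr]))
            pred_t = scaler.invert(est.predict(X[te]))
        except Exception as exc:
            raise RuntimeError(f"baseline {kind} failed in fold {f}") from exc
        report.add_fold(**_fold_metrics(y_t[te], pred_t, use_log))
    return report
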