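"""Synthetic sequence datasets with known per-symbol contributions.

These emulate the structure of the peptide-intensity task while providing
ground truth: each symbol of the alphabet carries a fixed contribution
c(a); a sequence's target is the sum of its symbols' contributions,
optionally passed through an exponential to create the large dynamic range
seen in real MS1 intensities, plus Gaussian noise. Because the ground
truth is known, the attention weights a trained model assigns to each
symbol can be checked against the true contributions.

Four presets cover the proof-of-concept study conditions:

* POC1 - fixed length 8 over a 10-symbol alphabet, linear, noise-free
  (encoder input n x 8 x 10);
* POC2 - variable length 4-8 over 9 symbols + pad, linear, small noise
  (n x 8 x 10);
* POC3 - variable length 8-40 over 20 symbols + pad, linear, small noise
  (n x 40 x 21);
* POC4 - as POC3 but the target is exp(beta * sum) with beta chosen so
  targets span more than three orders of magnitude (n x 40 x 21).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alphabet import AMINO_ACIDS, Alphabet

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "preset",
           "recovery_score", "ols_contribution_fit"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``length_range`` is (lo, hi) inclusive; lo == hi gives fixed-length
    sequences (and then the alphabet needs no pad channel, mirroring the
    8 x 10 input format). ``transform`` is "linear" (target = sum + noise)
    or "exponential" (target = exp(beta * (sum + noise))). Contributions
    default to seeded uniform draws on [0.5, 5] per symbol.
    """

    alphabet: Alphabet
    length_range: tuple[int, int]
    max_len: int
    contributions: dict[str, float] = field(default=None)
    transform: str = "linear"
    beta: float = 1.0
    noise_sd: float = 0.0
    n_sequences: int = 10_000
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        lo, hi = self.length_range
        if not (1 <= lo <= hi <= self.max_len):
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.transform not in ("linear", "exponential"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        if self.contributions is None:
            rng = np.random.default_rng(self.seed)
            draws = rng.uniform(0.5, 5.0, size=len(self.alphabet.residues))
            object.__setattr__(
                self, "contributions",
                {a: float(c) for a, c in zip(self.alphabet.residues, draws)},
            )
        missing = set(self.alphabet.residues) - set(self.contributions)
        if missing:
            raise ValueError(f"contributions missing for symbols {sorted(missing)}")

    @property
    def channels(self) -> int:
        """Input channels: residues + pad (pad present even if unused)."""
        return self.alphabet.size


@dataclass(frozen=True)
class SyntheticDataset:
    sequences: list[str]
    targets: np.ndarray  # positive reals
    ground_truth: dict[str, float]
    spec: SyntheticSpec


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw sequences uniformly over symbols/lengths and compute targets.

    linear:      target = sum_t c(x_t) + eps
    exponential: target = exp(beta * (sum_t c(x_t) + eps))
    with eps ~ Normal(0, noise_sd). Fully deterministic given the spec
    (the spec seed drives both the contribution draws and the sampling).
    """
    rng = np.random.default_rng(spec.seed)
    rng.uniform(0.5, 5.0, size=len(spec.alphabet.residues))  # skip contribution draws
    lo, hi = spec.length_range
    residues = spec.alphabet.residues
    lengths = rng.integers(lo, hi + 1, size=spec.n_sequences)
    symbol_idx = rng.integers(0, len(residues), size=(spec.n_sequences, hi))
    contrib = np.array([spec.contributions[a] for a in residues])
    sums = np.array([
        contrib[symbol_idx[i, : lengths[i]]].sum() for i in range(spec.n_sequences)
    ])
    eps = rng.normal(0.0, spec.noise_sd, size=spec.n_sequences) if spec.noise_sd else 0.0
    if spec.transform == "linear":
        targets = sums + eps
    else:
        targets = np.exp(spec.beta * (sums + eps))
    sequences = [
        "".join(residues[j] for j in symbol_idx[i, : lengths[i]])
        for i in range(spec.n_sequences)
    ]
    if np.any(targets <= 0):
        raise ValueError(
            "non-positive targets generated; lower noise_sd or adjust contributions"
        )
    return SyntheticDataset(sequences, targets, dict(spec.contributions), spec)


_POC_ALPHABET_9 = Alphabet(residues=AMINO_ACIDS[:9])  # 9 residues + pad = 10 ch.
_PRESETS = {
    # both 8-long presets share the 10-channel (9 residues + pad) format so
    # the encoder input is n x 8 x 10; POC1 is fixed-length, pad never fires
    "POC1": dict(alphabet=_POC_ALPHABET_9, length_range=(8, 8), max_len=8,
                 transform="linear", noise_sd=0.0),
    "POC2": dict(alphabet=_POC_ALPHABET_9, length_range=(4, 8), max_len=8,
                 transform="linear", noise_sd=0.1),
    "POC3": dict(alphabet=Alphabet(), length_range=(8, 40), max_len=40,
                 transform="linear", noise_sd=0.5),
    "POC4": dict(alphabet=Alphabet(), length_range=(8, 40), max_len=40,
                 transform="exponential", beta=0.08, noise_sd=0.5),
}


def preset(name: str, n_sequences: int = 10_000, seed: int = 0) -> SyntheticSpec:
    """Named proof-of-concept recipe (POC1..POC4); see the module docstring."""
    try:
        kwargs = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return SyntheticSpec(n_sequences=n_sequences, seed=seed, name=name, **kwargs)


def recovery_score(profile, truth: dict[str, float]) -> tuple[float, float]:
    """Pearson and Spearman correlation of mean attention vs true contributions.

    ``profile`` is an :class:`~attnms1.interpretation.AttentionProfile` or a
    plain mapping symbol -> mean attention weight. Symbols present in both
    are compared; fewer than 3 shared symbols is an error.
    """
    weights = getattr(profile, "mean_weight", profile)
    shared = sorted(set(weights) & set(truth))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared symbols; need at least 3")
    x = np.array([weights[a] for a in shared])
    y = np.array([truth[a] for a in shared])
    pcc = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return pcc, rho


def ols_contribution_fit(dataset: SyntheticDataset) -> dict[str, float]:
    """Least-squares contributions from symbol counts (independent oracle).

    For linear targets the model target = sum_t c(x_t) is linear in the
    per-sequence symbol counts, so OLS on the count matrix recovers the
    contributions exactly when noise is zero (the count matrix may be
    rank-deficient for fixed-length sequences, where a constant can be
    traded across symbols; lstsq returns the minimum-norm solution, so
    compare fits up to that gauge).
    """
    residues = dataset.spec.alphabet.residues
    counts = np.array([[s.count(a) for a in residues] for s in dataset.sequences],
                      dtype=float)
    y = dataset.targets
    if dataset.spec.transform == "exponential":
        y = np.log(y) / dataset.spec.beta
    coef, *_ = np.linalg.lstsq(counts, y, rcond=None)
    return {a: float(c) for a, c in zip(residues, coef)}
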