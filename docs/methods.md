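# Methods

## Problem

Electrospray MS is not inherently quantitative: two peptides present at
the same molar concentration can produce MS1 precursor signals differing
by orders of magnitude, because ionization efficiency depends on sequence.
Equimolar synthetic peptide pools (as deposited with the ProteomeTools /
Prosit resources) remove the abundance confound, so the remaining
intensity variation is sequence-dependent response. `attnms1` models that
response: it regresses a peptide's MS1 intensity on its amino acid
sequence alone, and uses the attention weights of the model to ask which
residues — and which physicochemical properties — drive the response.

## Data pipeline

MaxQuant peptide-level output is ingested per pool (`peptides.txt` for
sequence, summed MS1 intensity and PEP; `summary.txt` for the declared
enzyme and enzyme mode; SDRF for pool/run metadata) and joined into
unified records. Filtering then proceeds in an auditable cascade:

1. quality: drop PEP ≥ 0.01 (boundary inclusive on removal), reverse
   (decoy) hits, potential contaminants, zero intensities;
2. optional segmentation by search metadata (e.g. Trypsin / specific),
   applied before merging when building enzyme-specific sets — "tryptic"
   always means *searched as* tryptic, never a C-terminal K/R pattern test
   (an audit helper reports disagreement between the two definitions);
3. replicate merging: one record per unique sequence, summarised by the
   median of its per-pool intensities;
4. variation: drop peptides with CV > 0.3, where CV uses the sample
   (n−1) standard deviation divided by the mean; single-pool peptides
   (CV undefined) are dropped by default for modeling datasets.

Each stage records (input, removed, surviving) counts; the counts must
compose exactly, which the test suite checks against an independent
predicate-enumeration oracle.

Intensities are natural-log transformed (they span several orders of
magnitude) and min-max scaled; the scaler is always fitted on the
training portion only and extrapolates linearly for out-of-range test
values. The scaled range defaults to [0, 1] and is configurable (a
reasonable sweep is part of model tuning). Error metrics (MAPE) are never
computed on the scaled values — a scaled minimum of 0 would make MAPE
undefined — but on the unscaled log scale and the exponentiated real
scale.

## Model

The regressor is a sequence-to-scalar encoder–decoder:

* **Encoder**: one bidirectional GRU layer (`units` per direction,
  default 64). Per-position states h_j are the concatenation of forward
  and backward states (dimension 2·units); the encoder final state s is
  the concatenation of the two directions' final states.
* **Attention** (additive / Bahdanau-style): scores
  e_j = vᵀ tanh(W s + U h_j + b), with the encoder final state as the
  query (it is the decoder's incoming state before the single decoding
  step); weights α = softmax(e); context c = Σ_j α_j h_j. Padding
  positions are not masked from the softmax by default (configurable);
  profile averaging excludes them regardless.
* **Decoder**: exactly one BiGRU step on [c ; one-hot start element],
  initialised from the encoder final state, followed by a one-unit linear
  dense layer producing the scaled log-intensity. The start element is a
  dedicated symbol distinct from padding. Because the output is a scalar,
  attention is computed once, giving one weight per input position.

Gate convention: z (update) and r (reset) gates with
h_t = (1−z)·h_{t−1} + z·tanh(W_c x + U_c (r∘h_{t−1}) + b_c). Forward and
backward states are combined by concatenation; the dense head is linear
(regression on scaled values).

The implementation is pure NumPy with hand-derived backpropagation
through time; analytic gradients are validated against central finite
differences in the test suite (float64, relative tolerance 1e-3 at step
1e-6). Input kernels use Glorot-uniform initialisation, recurrent kernels
orthogonal, biases zero. Training minimises MSE with Adam at its standard
defaults (lr 1e-3, β₁ 0.9, β₂ 0.999), monitors MAE on a validation subset
(20% of the training split), and keeps the weights from the best
validation epoch; optional early stopping (`patience`) halts after that
many non-improving epochs. One integer seed drives weight initialisation
and batch shuffling; fold assignment takes its own seed.

## Interpretation

For each prediction the attention weights are averaged per amino acid:
first within a sequence over positions holding the same residue (pad
positions excluded), then across sequences. The across-sequence mean
divides by the number of sequences *containing* the residue (dividing by
the total count would deflate rare residues toward zero); the
unconditioned variant is available behind a flag. The 20-value profile is
correlated (Pearson, two-sided p from the t transform with n−2 df,
pairwise deletion of missing values) with each AAindex1 index; indices
with |PCC| ≥ 0.7 — equivalently p < 1e-3 at n = 20 — are reported as
significant, sorted by |PCC| with ties broken by accession. No
multiple-testing correction is applied to the cutoff (a fixed-threshold
screen); a Benjamini–Hochberg column can be derived from the emitted
p-values if desired.

Sequence descriptors for sanity checks: counts of R/K/H, net charge at a
given pH by Henderson–Hasselbalch summation over ionizable side chains
plus free termini (pKa: Asp 3.65, Glu 4.25, His 6.0, Cys 8.3, Tyr 10.07,
Lys 10.53, Arg 12.48, N-term 9.0, C-term 2.0), per-residue index sums and
means, and length-normalised variants.

## Synthetic proof-of-concept datasets

The generator draws sequences uniformly over the alphabet with lengths
from a fixed or uniform distribution; each symbol carries a fixed
contribution, drawn once per dataset from Uniform(0.5, 5) (seeded, or
supplied explicitly). Targets are

* linear: t = Σ c(x_i) + ε,
* exponential: t = exp(β·(Σ c(x_i) + ε)),

with ε ~ N(0, σ). Presets: POC1 (fixed length 8, 10 channels, linear,
σ=0), POC2 (length 4–8, 10 channels, linear, σ=0.1), POC3 (length 8–40,
21 channels, linear, σ=0.5), POC4 (as POC3, exponential with β=0.08 so
targets span > 3 orders of magnitude, matching real MS1 dynamic range).
The two short presets share the 10-channel format (9 content symbols +
pad); POC1 is fixed-length so its pad channel never fires. β and σ are
the generator's study conditions, not tuning knobs.

For linear targets the generator admits an exact independent oracle:
ordinary least squares on per-sequence symbol counts recovers the
contribution map to machine precision when σ = 0 (for fixed-length data
the count matrix is rank-deficient by one — a constant can be traded
across symbols — and the minimum-norm solution is used). This oracle
defines what the network is supposed to learn, independently of the
network.

What the synthetic data does *not* emulate: chromatography and ionization
physics, charge states, residue-residue interaction effects (targets are
strictly additive per symbol), compositional biases of real digests, and
measurement error structure beyond i.i.d. Gaussian noise on the
contribution sum. Passing the proof-of-concept checks therefore shows the
architecture and pipeline work end-to-end on additive sequence-to-scalar
structure with realistic dynamic range — not that real MS1 response is
predictable to the same accuracy.

## Standard protocol and problem sizes

Proof-of-concept runs use: units 64, batch 64, ≤ 30 epochs with patience
5, scale range [0, 1], 5-fold cross-validation (or a single 80/20 split
where stated), validation = 20% of each training split. The reproduction
script (`scripts/acceptance.py`) uses 10,000 sequences per dataset; the
test suite's cross-validated end-to-end checks use 6,000 to keep the
default run fast — the accuracy bars are unchanged, and less training
data only makes them harder.

Typical results (seed 1): simple linear data — held-out MAPE ≈ 0.05–0.2%,
PCC > 0.999; complex exponential data — MAPE ≈ 0.8–1.0% on log targets.

## Attention-recovery behaviour: a known limitation

On the noise-free fixed-length linear preset the per-symbol mean
attention correlates only weakly with the true contributions (fold- and
seed-averaged Spearman observed between ≈ 0.2 and 0.8, usually positive
but occasionally sign-flipped in individual runs). The cause is
architectural: the decoder's initial state is the encoder final state,
which for short fixed-length additive targets already encodes the answer,
so uniform attention is optimal and nothing forces the attention
distribution to align with the contributions — any residual alignment is
a transient of early training. On variable-length, large-dynamic-range
data (POC4) the final state is lossier, attention carries more of the
load, and alignment is stronger (per-run Pearson up to ≈ 0.8), though
still run-dependent. Consequences for practice: attention profiles should
be averaged over several runs/folds, treated as hypothesis-generating,
and validated against independent descriptors — which is exactly what the
AAindex1 screen and the charge/hydrophobicity descriptors are for.

## Numerical choices

* float32 model arithmetic (float64 available; used for gradient checks);
* softmax computed with max-subtraction; padded-position masking (when
  enabled) uses additive −1e9 before the softmax;
* CV filter keeps peptides with CV ≤ 0.3 (boundary inclusive on keep);
  PEP filter removes ≥ 0.01 (boundary inclusive on removal);
* k-fold splits are shuffled and seeded; folds differ in size by ≤ 1;
* MAPE guards against zero true values (cannot occur after the
  zero-intensity filter and log transform);
* degenerate inputs fail loudly: constant scaler input, non-finite
  training loss, empty datasets, alphabet/shape mismatches.

## Baselines

Random forest (100 trees by default) and ridge regression (α = 1) from
scikit-learn, on the positional tabular encoding (position × symbol
binary indicators; 40 × 21 = 840 variables for peptides). Hyperparameters
are exposed and recorded in reports. On linear synthetic data ridge is
near-exact by construction (the target is linear in the features), which
makes it a useful lower bound on achievable error there.
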