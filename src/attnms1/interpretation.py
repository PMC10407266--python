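"""From attention weights to physicochemical interpretation.

A trained model assigns one attention weight per sequence position for
every prediction. To ask *which amino acids* the model attends to, the
weights are averaged twice: first within each sequence over positions
holding the same residue, then across all sequences containing that
residue. The resulting 20-value profile is correlated (Pearson) against
each AAindex1 index — a public collection of 566 numerical scales
assigning one value per amino acid to a physicochemical or structural
property — and indices with |PCC| >= 0.7 (two-sided p below 1e-3 at
n = 20) are reported as significant.

Sequence descriptors (hydrophobicity sums, positive-residue counts, net
charge at a given pH via Henderson-Hasselbalch) support sanity checks of
what the profiles highlight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .alphabet import AMINO_ACIDS

__all__ = [
    "PropertyIndex", "parse_aaindex1", "AttentionProfile",
    "mean_attention_per_aa", "pearson_with_p", "CorrelationResult",
    "rank_significant", "peptide_descriptors", "PKA_SIDE_CHAINS",
    "PKA_NTERM", "PKA_CTERM",
]

#: Row order of the two value lines in an AAindex1 "I" block.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


@dataclass(frozen=True)
class PropertyIndex:
    """One AAindex1 index: accession, description, per-residue values.

    ``values`` may omit residues recorded as NA in the flat file.
    """

    accession: str
    description: str
    values: dict[str, float]

    def vector(self, residues=AMINO_ACIDS) -> np.ndarray:
        """Values in the given residue order, NaN where missing."""
        return np.array([self.values.get(a, np.nan) for a in residues])


def parse_aaindex1(path) -> list[PropertyIndex]:
    """Parse an AAindex1 flat file (records delimited by ``//``).

    Each record contributes one :class:`PropertyIndex` built from its H
    (accession), D (description) and I (amino-acid value) fields. The I
    block lays values out in two rows of ten, ordered A R N D C Q E G H I /
    L K M F P S T W Y V; ``NA`` entries become missing values.
    """
    indices = []
    record_lines: list[str] = []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("//"):
            if record_lines:
                indices.append(_parse_record(record_lines))
            record_lines = []
        else:
            record_lines.append(raw)
    if any(line.strip() for line in record_lines):
        indices.append(_parse_record(record_lines))
    return indices


def _parse_record(lines: list[str]) -> PropertyIndex:
    accession = ""
    description_parts: list[str] = []
    value_lines: list[str] = []
    section = ""
    for line in lines:
        if line[:1].strip():
            section = line[0]
            body = line[1:].strip()
        else:
            body = line.strip()
        if section == "H" and body:
            accession = accession or body
        elif section == "D" and body:
            description_parts.append(body)
        elif section == "I":
            if line[:1] != "I":  # continuation rows hold the numbers
                value_lines.append(body)
    if len(value_lines) != 2:
        raise ValueError(
            f"malformed value block in AAindex record {accession or '<unknown>'}: "
            f"expected 2 value rows, got {len(value_lines)}"
        )
    values: dict[str, float] = {}
    for residues, row in zip((_AAINDEX_ROW1, _AAINDEX_ROW2), value_lines):
        fields = row.split()
        if len(fields) != len(residues):
            raise ValueError(
                f"malformed value row in AAindex record {accession}: {row!r}"
            )
        for aa, tok in zip(residues, fields):
            if tok.upper() != "NA":
                values[aa] = float(tok)
    return PropertyIndex(accession=accession,
                         description=" ".join(description_parts), values=values)


@dataclass(frozen=True)
class AttentionProfile:
    """Mean attention weight per residue across a dataset.

    Residues never observed are absent (not zero). ``n_sequences_containing``
    counts the sequences contributing to each residue's mean.
    """

    mean_weight: dict[str, float]
    n_sequences_containing: dict[str, int]

    def vector(self, residues=AMINO_ACIDS) -> np.ndarray:
        return np.array([self.mean_weight.get(a, np.nan) for a in residues])


def mean_attention_per_aa(
    sequences,
    alphas,
    condition_on_presence: bool = True,
) -> AttentionProfile:
    """Two-level average of attention weights per residue.

    Within each sequence, positions holding the same residue are averaged
    (pad positions — anything past the sequence length — are ignored); the
    per-sequence means are then averaged across sequences. By default the
    across-sequence mean divides by the number of sequences *containing*
    the residue; ``condition_on_presence=False`` divides by the total
    sequence count instead (treating absence as zero attention).
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    n_total = 0
    for seq, alpha in zip(sequences, alphas):
        alpha = np.asarray(alpha, dtype=float)
        if alpha.ndim != 1 or alpha.size < len(seq):
            raise ValueError(
                f"attention vector of size {alpha.size} shorter than "
                f"sequence of length {len(seq)}"
            )
        n_total += 1
        per_res: dict[str, list[float]] = {}
        for t, aa in enumerate(seq):
            per_res.setdefault(aa, []).append(alpha[t])
        for aa, w in per_res.items():
            sums[aa] = sums.get(aa, 0.0) + float(np.mean(w))
            counts[aa] = counts.get(aa, 0) + 1
    denom = counts if condition_on_presence else {a: n_total for a in sums}
    mean_weight = {a: sums[a] / denom[a] for a in sums}
    return AttentionProfile(mean_weight=mean_weight, n_sequences_containing=counts)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p (t transform, n-2 df); pairwise-deletes NaN.

    Requires at least 3 complete pairs and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationResult:
    accession: str
    description: str
    pcc: float
    p_value: float
    n: int


def rank_significant(
    profile: AttentionProfile,
    indices,
    threshold: float = 0.7,
) -> list[CorrelationResult]:
    """Indices whose correlation with the profile passes |PCC| >= threshold.

    The boundary is inclusive. Results are sorted by |PCC| descending with
    ties broken by accession; indices sharing fewer than 3 residues with
    the profile are skipped.
    """
    results = []
    for index in indices:
        shared = sorted(set(profile.mean_weight) & set(index.values))
        if len(shared) < 3:
            continue
        x = np.array([profile.mean_weight[a] for a in shared])
        y = np.array([index.values[a] for a in shared])
        try:
            pcc, p = pearson_with_p(x, y)
        except ValueError:
            continue
        if abs(pcc) >= threshold:
            results.append(CorrelationResult(index.accession, index.description,
                                             pcc, p, len(shared)))
    return sorted(results, key=lambda r: (-abs(r.pcc), r.accession))


def correlate_all(profile: AttentionProfile, indices) -> list[CorrelationResult]:
    """Correlation of the profile with every index (no threshold)."""
    return rank_significant(profile, indices, threshold=0.0)


# Henderson-Hasselbalch pKa set used for net-charge descriptors.
PKA_SIDE_CHAINS = {
    "D": 3.65, "E": 4.25, "H": 6.0, "C": 8.3, "Y": 10.07,
    "K": 10.53, "R": 12.48,
}
PKA_NTERM = 9.0
PKA_CTERM = 2.0
_POSITIVE_SIDE_CHAINS = frozenset("RKH")
_BASIC = frozenset("RKH")  # protonated below their pKa -> positive
_ACIDIC = frozenset("DECY")  # deprotonated above their pKa -> negative


def net_charge(sequence: str, pH: float) -> float:
    """Peptide net charge at the given pH (side chains plus free termini)."""
    charge = 1.0 / (1.0 + 10.0 ** (pH - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - pH))
    for aa in sequence:
        pka = PKA_SIDE_CHAINS.get(aa)
        if pka is None:
            continue
        if aa in _BASIC:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return charge


@dataclass(frozen=True)
class PeptideDescriptors:
    sequence: str
    length: int
    n_positive: int
    n_positive_per_length: float
    net_charge: float | None = None
    net_charge_per_length: float | None = None
    index_sum: float | None = None
    index_mean: float | None = None


def peptide_descriptors(
    sequence: str,
    index: PropertyIndex | None = None,
    pH: float | None = None,
) -> PeptideDescriptors:
    """Per-peptide descriptors: R/K/H count, net charge, index sum/mean.

    The net charge (when ``pH`` is given) uses Henderson-Hasselbalch
    summation over ionizable side chains and the free termini with the
    module's declared pKa table. When ``index`` misses a residue present in
    the sequence, the index descriptors are marked missing (None).
    """
    if not sequence:
        raise ValueError("empty sequence")
    unknown = set(sequence) - set(AMINO_ACIDS)
    if unknown:
        raise ValueError(f"non-standard residues in sequence: {sorted(unknown)}")
    n = len(sequence)
    n_pos = sum(1 for aa in sequence if aa in _POSITIVE_SIDE_CHAINS)
    charge = charge_norm = None
    if pH is not None:
        charge = net_charge(sequence, pH)
        charge_norm = charge / n
    idx_sum = idx_mean = None
    if index is not None and all(aa in index.values for aa in sequence):
        idx_sum = float(sum(index.values[aa] for aa in sequence))
        idx_mean = idx_sum / n
    return PeptideDescriptors(
        sequence=sequence, length=n, n_positive=n_pos,
        n_positive_per_length=n_pos / n, net_charge=charge,
        net_charge_per_length=charge_norm, index_sum=idx_sum,
        index_mean=idx_mean,
    )
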