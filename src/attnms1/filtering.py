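"""Quality, replication and variation filters for peptide measurements.

The cascade mirrors standard MS1-quantification hygiene on equimolar
peptide-pool data:

1. quality filters — drop identifications with PEP >= 0.01, reverse
   (decoy) hits, potential contaminants, and zero intensities;
2. replicate merging — collapse each unique sequence across pools to its
   median intensity;
3. variation filter — drop peptides whose intensities across pools have a
   coefficient of variation (sample SD / mean) above 0.3;
4. optional segmentation by search metadata (enzyme, enzyme mode), applied
   *before* merging when building enzyme-specific modeling sets.

Every stage records (input, removed, surviving) counts in a FilterReport
so the cascade is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .maxquant_io import PeptideMeasurement

__all__ = ["FilterReport", "MergedPeptide", "apply_quality_filters",
           "coefficient_of_variation", "merge_replicates", "segment_dataset"]


@dataclass
class FilterReport:
    """Per-stage (input, removed, surviving) counts, in application order."""

    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, n_input: int, n_removed: int) -> None:
        surviving = n_input - n_removed
        if surviving < 0:
            raise ValueError(f"stage {name}: removed more than input")
        if self.stages and self.stages[-1]["surviving"] != n_input:
            raise ValueError(
                f"stage {name}: input {n_input} does not match previous "
                f"surviving count {self.stages[-1]['surviving']}"
            )
        self.stages.append(
            {"stage": name, "input": n_input, "removed": n_removed,
             "surviving": surviving}
        )

    def extend(self, other: "FilterReport") -> None:
        for st in other.stages:
            self.add_stage(st["stage"], st["input"], st["removed"])

    @property
    def n_surviving(self) -> int:
        return self.stages[-1]["surviving"] if self.stages else 0

    def to_json(self, **kwargs) -> str:
        return json.dumps({"stages": self.stages}, **kwargs)

    def format_log(self) -> str:
        lines = [f"{'stage':<24}{'input':>10}{'removed':>10}{'surviving':>10}"]
        for st in self.stages:
            lines.append(f"{st['stage']:<24}{st['input']:>10}"
                         f"{st['removed']:>10}{st['surviving']:>10}")
        return "\n".join(lines)


@dataclass(frozen=True)
class MergedPeptide:
    """A unique sequence after replicate merging.

    ``cv`` is NaN for single-measurement peptides (undefined). ``enzyme`` /
    ``enzyme_mode`` hold the single observed value, or None when pools
    disagree; the full observed sets are kept alongside.
    """

    sequence: str
    median_intensity: float
    cv: float
    n_measurements: int
    enzyme: str | None
    enzyme_mode: str | None
    enzymes: frozenset = frozenset()
    enzyme_modes: frozenset = frozenset()


def apply_quality_filters(
    records: list[PeptideMeasurement],
    pep_max: float = 0.01,
) -> tuple[list[PeptideMeasurement], FilterReport]:
    """Sequentially drop high-PEP, reverse, contaminant and zero-intensity rows.

    The PEP boundary is inclusive on removal (pep >= pep_max is dropped).
    Counts are attributed to the first failing criterion in the stated
    order; the surviving *set* is order-independent since the criteria are
    independent predicates.
    """
    report = FilterReport()
    stages = [
        ("pep", lambda r: r.pep >= pep_max),
        ("reverse", lambda r: r.reverse_flag),
        ("contaminant", lambda r: r.contaminant_flag),
        ("zero_intensity", lambda r: r.intensity == 0),
    ]
    current = list(records)
    for name, is_bad in stages:
        survivors = [r for r in current if not is_bad(r)]
        report.add_stage(name, len(current), len(current) - len(survivors))
        current = survivors
    return current, report


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"CV needs at least 2 values, got {v.size}")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / mean)


def merge_replicates(
    records: list[PeptideMeasurement],
    cv_max: float = 0.3,
    require_replicates: bool = True,
) -> tuple[list[MergedPeptide], FilterReport]:
    """Collapse records to one MergedPeptide per unique sequence.

    Median intensity summarises the per-pool measurements; peptides with
    CV > cv_max are removed, and (by default) so are peptides observed in
    only one pool, whose CV is undefined. The report counts the records
    absorbed by merging, then the peptides removed by each criterion.
    """
    groups: dict[str, list[PeptideMeasurement]] = {}
    order: list[str] = []
    for r in records:
        if r.sequence not in groups:
            order.append(r.sequence)
        groups.setdefault(r.sequence, []).append(r)

    report = FilterReport()
    report.add_stage("merge", len(records), len(records) - len(groups))

    merged: list[MergedPeptide] = []
    n_singletons = 0
    for seq in order:
        grp = groups[seq]
        intensities = [g.intensity for g in grp]
        n = len(grp)
        cv = coefficient_of_variation(intensities) if n >= 2 else float("nan")
        enzymes = frozenset(g.enzyme for g in grp)
        modes = frozenset(g.enzyme_mode for g in grp)
        merged.append(MergedPeptide(
            sequence=seq,
            median_intensity=float(np.median(intensities)),
            cv=cv,
            n_measurements=n,
            enzyme=next(iter(enzymes)) if len(enzymes) == 1 else None,
            enzyme_mode=next(iter(modes)) if len(modes) == 1 else None,
            enzymes=enzymes,
            enzyme_modes=modes,
        ))
    if require_replicates:
        kept = [m for m in merged if m.n_measurements >= 2]
        report.add_stage("require_replicates", len(merged), len(merged) - len(kept))
        merged = kept
    survivors = [m for m in merged
                 if not (np.isfinite(m.cv) and m.cv > cv_max)]
    report.add_stage("cv", len(merged), len(merged) - len(survivors))
    return survivors, report


def segment_dataset(records, enzyme: str = "any", mode: str = "any"):
    """Subset records by search metadata (not by sequence pattern).

    Works on PeptideMeasurement or MergedPeptide lists; "any" disables a
    selector. "Tryptic" therefore means *searched with* Trypsin, which for
    merged records requires an unambiguous enzyme tag.
    """
    out = []
    for r in records:
        if enzyme != "any" and getattr(r, "enzyme", None) != enzyme:
            continue
        if mode != "any" and getattr(r, "enzyme_mode", None) != mode:
            continue
        out.append(r)
    return out


def tryptic_terminus_audit(records) -> int:
    """Count records where metadata-tryptic disagrees with a K/R C-terminus.

    Diagnostic only: segmentation is always metadata-based.
    """
    n = 0
    for r in records:
        is_meta_tryptic = getattr(r, "enzyme", None) == "Trypsin"
        ends_kr = r.sequence.endswith(("K", "R"))
        if is_meta_tryptic != ends_kr:
            n += 1
    return n
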