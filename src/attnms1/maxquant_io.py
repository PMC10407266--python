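"""Readers for MaxQuant peptide-level output and SDRF metadata.

A pool's ``peptides.txt`` supplies identified sequences, summed MS1
intensities and PEP scores; its ``summary.txt`` declares the search enzyme
and enzyme mode; the deposition's SDRF file relates pools to their runs.
These are joined into per-pool unified records carrying everything the
filtering cascade needs.

Column names vary across MaxQuant versions, so the peptides reader takes a
configurable column map with the common defaults. Flag columns follow
MaxQuant semantics: any non-empty value (normally "+") means flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .alphabet import AMINO_ACIDS

__all__ = ["RawPeptideRow", "PoolMetadata", "PeptideMeasurement",
           "read_peptides_table", "read_summary", "read_sdrf",
           "assemble_records", "write_unified_csv", "read_unified_csv"]

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "sequence": "Sequence",
    "intensity": "Intensity",
    "pep": "PEP",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
}

ENZYMES = ("Trypsin", "LysN", "AspN", "other")
ENZYME_MODES = ("specific", "semi-specific", "unspecific")

_VALID_RESIDUES = set(AMINO_ACIDS)


@dataclass(frozen=True)
class RawPeptideRow:
    sequence: str
    intensity: float
    pep: float
    reverse_flag: bool
    contaminant_flag: bool
    pool_id: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.intensity < 0:
            raise ValueError(f"negative intensity for {self.sequence}")
        if not 0.0 <= self.pep <= 1.0:
            raise ValueError(f"PEP {self.pep} outside [0, 1] for {self.sequence}")


@dataclass(frozen=True)
class PoolMetadata:
    pool_id: str
    enzyme: str
    enzyme_mode: str

    def __post_init__(self):
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.enzyme_mode not in ENZYME_MODES:
            raise ValueError(f"unknown enzyme mode {self.enzyme_mode!r}")


@dataclass(frozen=True)
class PeptideMeasurement:
    sequence: str
    intensity: float
    pep: float
    reverse_flag: bool
    contaminant_flag: bool
    pool_id: str
    enzyme: str
    enzyme_mode: str


def _flag(value) -> bool:
    return bool(str(value).strip()) and str(value).strip().lower() != "nan"


def read_peptides_table(
    path,
    pool_id: str = "",
    columns: dict | None = None,
) -> list[RawPeptideRow]:
    """Read a MaxQuant ``peptides.txt`` into validated rows.

    Missing intensity cells parse as 0 (they are dropped later by the
    zero-intensity filter). Sequences containing any of the non-standard
    letters B/J/Z/X/U/O are rejected here with a logged count, since the
    model alphabet has exactly the 20 standard residues.
    """
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [colmap["sequence"], colmap["intensity"], colmap["pep"]]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    rows: list[RawPeptideRow] = []
    n_nonstandard = 0
    for i, rec in enumerate(df.to_dict("records")):
        seq = rec[colmap["sequence"]].strip().upper()
        if set(seq) - _VALID_RESIDUES:
            n_nonstandard += 1
            continue
        try:
            intensity_str = rec[colmap["intensity"]].strip()
            intensity = float(intensity_str) if intensity_str else 0.0
            pep = float(rec[colmap["pep"]])
        except ValueError as exc:
            raise ValueError(f"unparseable numeric at {path} line {i + 2}: {exc}"
                             ) from None
        rows.append(RawPeptideRow(
            sequence=seq,
            intensity=intensity,
            pep=pep,
            reverse_flag=_flag(rec.get(colmap["reverse"], "")),
            contaminant_flag=_flag(rec.get(colmap["contaminant"], "")),
            pool_id=pool_id,
        ))
    if n_nonstandard:
        logger.info("%s: rejected %d sequences with non-standard residues",
                    path, n_nonstandard)
    return rows


_ENZYME_ALIASES = {"trypsin": "Trypsin", "trypsin/p": "Trypsin",
                   "lysn": "LysN", "aspn": "AspN"}
_MODE_ALIASES = {"specific": "specific", "semispecific": "semi-specific",
                 "semi-specific": "semi-specific", "semi specific": "semi-specific",
                 "unspecific": "unspecific"}


def _normalise_enzyme(raw: str) -> str:
    return _ENZYME_ALIASES.get(raw.strip().lower(), "other")


def _normalise_mode(raw: str) -> str:
    key = raw.strip().lower()
    if key not in _MODE_ALIASES:
        raise ValueError(f"unknown enzyme mode {raw!r}")
    return _MODE_ALIASES[key]


def read_summary(path, pool_id: str = "") -> PoolMetadata:
    """Extract the declared enzyme and enzyme mode from ``summary.txt``.

    MaxQuant writes one row per raw file plus a Total row; the enzyme
    declaration must be unambiguous across rows, otherwise the distinct
    values are reported in the error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    enzyme_col = next((c for c in df.columns if c.lower() == "enzyme"), None)
    mode_col = next((c for c in df.columns
                     if c.lower() in ("enzyme mode", "enzyme_mode")), None)
    if df.empty or enzyme_col is None or mode_col is None:
        raise ValueError(f"{path}: no Enzyme / Enzyme mode declaration found")
    raw_file_col = next((c for c in df.columns if c.lower() == "raw file"), None)
    if raw_file_col is not None:
        df = df[df[raw_file_col].str.strip().str.lower() != "total"]
    enzymes = sorted({v.strip() for v in df[enzyme_col] if v.strip()})
    modes = sorted({v.strip() for v in df[mode_col] if v.strip()})
    if len(enzymes) != 1 or len(modes) != 1:
        raise ValueError(
            f"{path}: ambiguous enzyme declaration: enzymes={enzymes}, "
            f"modes={modes}"
        )
    return PoolMetadata(pool_id=pool_id,
                        enzyme=_normalise_enzyme(enzymes[0]),
                        enzyme_mode=_normalise_mode(modes[0]))


def read_sdrf(path, pool_column: str | None = None) -> dict[str, dict]:
    """Read an SDRF-Proteomics TSV into pool_id -> annotation mappings.

    ``pool_column`` names the column identifying the pool (defaults to
    ``comment[data file]`` when present, else the first column). All other
    columns are preserved as opaque annotations. Duplicate pool rows are
    allowed only when their annotations agree.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        return {}
    if pool_column is None:
        lower = {c.lower(): c for c in df.columns}
        pool_column = lower.get("comment[data file]", df.columns[0])
    if pool_column not in df.columns:
        raise ValueError(f"{path}: no column {pool_column!r}")
    out: dict[str, dict] = {}
    for rec in df.to_dict("records"):
        key = rec[pool_column].strip()
        annotations = {k: v for k, v in rec.items() if k != pool_column}
        if key in out and out[key] != annotations:
            raise ValueError(f"{path}: conflicting duplicate rows for {key!r}")
        out[key] = annotations
    return out


def assemble_records(
    rows: list[RawPeptideRow],
    meta: PoolMetadata,
) -> list[PeptideMeasurement]:
    """Join peptide rows with their pool's metadata."""
    out = []
    for r in rows:
        if r.pool_id != meta.pool_id:
            raise ValueError(
                f"pool_id mismatch: row {r.sequence} belongs to "
                f"{r.pool_id!r}, metadata is for {meta.pool_id!r}"
            )
        out.append(PeptideMeasurement(
            sequence=r.sequence, intensity=r.intensity, pep=r.pep,
            reverse_flag=r.reverse_flag, contaminant_flag=r.contaminant_flag,
            pool_id=r.pool_id, enzyme=meta.enzyme, enzyme_mode=meta.enzyme_mode,
        ))
    return out


_UNIFIED_COLUMNS = ["sequence", "intensity", "pep", "reverse", "contaminant",
                    "pool_id", "enzyme", "enzyme_mode"]


def write_unified_csv(records: list[PeptideMeasurement], path) -> None:
    df = pd.DataFrame([{
        "sequence": r.sequence, "intensity": r.intensity, "pep": r.pep,
        "reverse": r.reverse_flag, "contaminant": r.contaminant_flag,
        "pool_id": r.pool_id, "enzyme": r.enzyme, "enzyme_mode": r.enzyme_mode,
    } for r in records], columns=_UNIFIED_COLUMNS)
    df.to_csv(path, index=False)


def read_unified_csv(path) -> list[PeptideMeasurement]:
    df = pd.read_csv(path, dtype={"sequence": str, "pool_id": str,
                                  "enzyme": str, "enzyme_mode": str})
    missing = set(_UNIFIED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing unified CSV columns {sorted(missing)}")
    return [PeptideMeasurement(
        sequence=rec["sequence"], intensity=float(rec["intensity"]),
        pep=float(rec["pep"]), reverse_flag=bool(rec["reverse"]),
        contaminant_flag=bool(rec["contaminant"]), pool_id=str(rec["pool_id"]),
        enzyme=rec["enzyme"], enzyme_mode=rec["enzyme_mode"],
    ) for rec in df.to_dict("records")]
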