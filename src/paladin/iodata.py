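"""Readers and writers for the package's on-disk formats.

Canonical formats are plain TSV/CSV with headers (delimiter sniffed from the
file, overridable), YAML for weights and propensity/solvation scales, and
standard FASTA for sequences.  Readers validate strictly, report violations
with row numbers, and never drop rows silently: exclusions are enumerated in
the returned :class:`Dataset` provenance.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .core import (
    AMINO_ACIDS,
    SITE_LABELS,
    SITES,
    EnergyTermMatrix,
    PSSM,
    PaladinError,
    StructuralError,
    WeightSet,
)
from .energetics import FrameEnergyTrace, PropensityScales, SolvationScale
from .evaluation import StructureBenchmarkRecord
from .training import PeptideArrayRecord, TrainingError

logger = logging.getLogger(__name__)

#: Fixed numeric precision for all tabular output (kcal/mol implied).
FLOAT_FORMAT = "%.6f"


class ParseError(PaladinError, ValueError):
    pass


@dataclass
class Dataset:
    """Parsed records plus provenance (path, dialect, exclusions)."""

    records: list
    path: str = ""
    dialect: str = ""
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.records)

    @property
    def n_total(self) -> int:
        return len(self.records) + len(self.excluded)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    sample = Path(path).read_text().splitlines()[0] if Path(path).exists() else ""
    if not sample:
        raise ParseError(f"{path}: empty file")
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def _read_table(path, sep: str | None = None) -> tuple[pd.DataFrame, str]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    sep = _sniff_sep(path, sep)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: failed to parse as delimited text: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: table has no data rows")
    return df, sep


# -- FASTA -------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a (possibly multi-record) FASTA file into (id, SEQUENCE) pairs."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    if not text.lstrip().startswith(">"):
        raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append((rec.id, seq))
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n{seq}\n")


def read_peptide_list(path) -> list[tuple[str, str]]:
    """One-sequence-per-line text; ids are synthesized as pep0001..."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    seqs = [ln for ln in lines if ln and not ln.startswith("#")]
    if not seqs:
        raise ParseError(f"{path}: no sequences found")
    return [(f"pep{i + 1:04d}", s.upper()) for i, s in enumerate(seqs)]


# -- PSSM --------------------------------------------------------------------


def read_pssm(path, sep: str | None = None) -> PSSM:
    """Read a 5-site x 20-residue score matrix.

    Rows are labelled -2, -1, 0, +1, +2 (first column), columns are the 20
    residues; a transposed file is rejected rather than silently misread.
    """
    df, _ = _read_table(path, sep)
    df = df.set_index(df.columns[0])
    if df.shape[0] == 20 and df.shape[1] == 5:
        raise StructuralError(
            f"{path}: matrix appears transposed (20 rows x 5 columns); "
            "expected 5 site rows x 20 residue columns"
        )
    try:
        return PSSM.from_frame(df, provenance=f"loaded from {path}")
    except StructuralError as exc:
        raise StructuralError(f"{path}: {exc}") from exc


def write_pssm(pssm: PSSM, path, sep: str = "\t") -> None:
    pssm.to_frame().to_csv(path, sep=sep, float_format=FLOAT_FORMAT)


# -- raw term matrix ---------------------------------------------------------


def read_terms(path, sep: str | None = None) -> EnergyTermMatrix:
    """Read a tidy term table: columns site, residue, term, value[, sem]."""
    df, _ = _read_table(path, sep)
    try:
        return EnergyTermMatrix.from_frame(df)
    except (StructuralError, PaladinError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_terms(terms: EnergyTermMatrix, path, sep: str = "\t") -> None:
    df = terms.to_frame()
    if terms.uncertainties is None:
        df = df.drop(columns=["sem"])
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


# -- peptide array -----------------------------------------------------------


def read_array_table(path, sep: str | None = None) -> Dataset:
    """Read a classed peptide-array table: columns sequence, label[, protein_id].

    Invalid rows (wrong length, unknown class, non-standard residues) are
    excluded with a reason and logged, never silently dropped.
    """
    df, dialect = _read_table(path, sep)
    missing = {"sequence", "label"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns: {sorted(missing)}")
    records: list[PeptideArrayRecord] = []
    excluded: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            records.append(
                PeptideArrayRecord(
                    sequence=str(row.sequence),
                    label=str(row.label),
                    protein_id=str(getattr(row, "protein_id", "") or ""),
                )
            )
        except TrainingError as exc:
            excluded.append((i, str(exc)))
            logger.warning("%s: row %d excluded: %s", path, i, exc)
    ds = Dataset(records, path=str(path), dialect=dialect, excluded=excluded)
    if not records:
        raise ParseError(f"{path}: all {len(excluded)} rows invalid")
    return ds


def write_array_table(records, path, sep: str = "\t") -> None:
    pd.DataFrame(
        [
            {"sequence": r.sequence, "label": r.label, "protein_id": r.protein_id}
            for r in records
        ]
    ).to_csv(path, sep=sep, index=False)


# -- structure benchmark -----------------------------------------------------


def read_benchmark_table(path, sep: str | None = None) -> Dataset:
    """Read a structure benchmark table.

    Columns: sequence, orientation, core, offset[, structure_id].  Rows whose
    core is not the stated substring, or with unknown orientation, are
    excluded with reasons; peptides with non-standard residues (e.g. the
    cyclohexylalanine 'Z') are kept but flagged by downstream benchmarks.
    """
    df, dialect = _read_table(path, sep)
    missing = {"sequence", "orientation", "core", "offset"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns: {sorted(missing)}")
    records: list[StructureBenchmarkRecord] = []
    excluded: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                StructureBenchmarkRecord(
                    sequence=str(row.sequence),
                    orientation=str(row.orientation),
                    core=str(row.core),
                    offset=int(row.offset),
                    structure_id=str(getattr(row, "structure_id", "") or ""),
                )
            )
        except (PaladinError, ValueError) as exc:
            excluded.append((i, str(exc)))
            logger.warning("%s: row %d excluded: %s", path, i, exc)
    ds = Dataset(records, path=str(path), dialect=dialect, excluded=excluded)
    if not records:
        raise ParseError(f"{path}: all {len(excluded)} rows invalid")
    return ds


def write_benchmark_table(records, path, sep: str = "\t") -> None:
    pd.DataFrame(
        [
            {
                "sequence": r.sequence,
                "orientation": r.orientation,
                "core": r.core,
                "offset": r.offset,
                "structure_id": r.structure_id,
            }
            for r in records
        ]
    ).to_csv(path, sep=sep, index=False)


# -- frame energy traces -----------------------------------------------------


def read_trace(path, sep: str | None = None, metadata: dict | None = None) -> FrameEnergyTrace:
    """Read a per-frame trace: columns frame, vdw, elec, restraint, sasa, total."""
    df, _ = _read_table(path, sep)
    required = {"vdw", "elec", "restraint", "sasa", "total"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns: {sorted(missing)}")
    try:
        return FrameEnergyTrace(df.reset_index(drop=True), metadata=metadata or {})
    except PaladinError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_trace(trace: FrameEnergyTrace, path, sep: str = "\t") -> None:
    df = trace.frames.copy()
    if "frame" not in df.columns:
        df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


# -- weights and scales ------------------------------------------------------


def read_weights(path) -> WeightSet:
    """Read a weight set from a flat YAML/JSON mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping of weight fields")
    try:
        return WeightSet.from_dict(data)
    except PaladinError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_weights(weights: WeightSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(weights.to_dict(), fh, sort_keys=False)


def read_solvation_scale(path) -> SolvationScale:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SolvationScale({str(k).upper(): float(v) for k, v in data.items()})


def read_propensity_scales(path) -> PropensityScales:
    """YAML with top-level keys 'helical' (res -> [0,1]) and 'rotamer'
    (res -> [P_r, P_0])."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "helical" not in data or "rotamer" not in data:
        raise ParseError(f"{path}: expected keys 'helical' and 'rotamer'")
    return PropensityScales(
        helical={str(k).upper(): float(v) for k, v in data["helical"].items()},
        rotamer={
            str(k).upper(): (float(v[0]), float(v[1]))
            for k, v in data["rotamer"].items()
        },
    )


# -- scan output -------------------------------------------------------------


def scan_to_frame(result) -> pd.DataFrame:
    """Flatten a ScanResult into the canonical windows table."""
    rows = []
    for s in result.scores:
        row = {
            "seq_id": result.seq_id,
            "start": s.start,
            "window": s.window,
            "orientation": s.orientation,
        }
        for site in SITES:
            row[f"site{SITE_LABELS[site]}"] = s.site_assignment[site]
        for site in SITES:
            row[f"E_site{SITE_LABELS[site]}"] = s.site_contributions[site]
        row["E_cp"] = s.e_cp_contribution
        row["total"] = s.total
        rows.append(row)
    return pd.DataFrame(rows)
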