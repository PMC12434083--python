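"""On-disk artifacts: peptide reports, FASTA databases, result tables, configs.

The canonical peptide report is a long-format, tab-delimited text file with
one row per peptide ion per run. A ``column_map`` adapts vendor exports
(two-channel DIA search-engine reports) whose header names differ, without
code changes. Ratios are ingested in the heavy/light orientation the search
engine exports; inversion to light/heavy is a pipeline step
(:mod:`isopull.ratio_quant`), so the file on disk stays faithful to its
source.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import EmptyInputError, FormatError, SchemaError

log = logging.getLogger(__name__)

#: Logical fields of a peptide measurement; the first five are required.
REQUIRED_FIELDS = ["sample_id", "protein_id", "peptide_seq", "ratio_hl", "q_value"]
OPTIONAL_FIELDS = ["light_quantity", "heavy_quantity"]

MIN_PEPTIDE_LENGTH = 5


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinDB:
    """Accession-keyed protein sequence database."""

    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.records

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self.records[protein_id]

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, protein_id: str) -> str:
        return self.records[protein_id].sequence


def read_peptide_report(
    path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Load a long-format peptide quantification report.

    ``column_map`` maps logical field names (``sample_id``, ``protein_id``,
    ``peptide_seq``, ``ratio_hl``, ``q_value``, optionally
    ``light_quantity``/``heavy_quantity``) to the source file's column
    headers; identity mapping by default.

    Rows violating the measurement invariants (non-finite or non-positive
    H/L ratio, q-value outside [0, 1], peptide shorter than
    ``MIN_PEPTIDE_LENGTH``) are dropped, counted, and logged — never
    silently discarded. Returns ``(frame, rejection_counts)``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"peptide report {path} is empty") from None
    if raw.empty:
        raise EmptyInputError(f"peptide report {path} has a header but no rows")

    column_map = dict(column_map or {})
    rename = {}
    for logical in REQUIRED_FIELDS + OPTIONAL_FIELDS:
        source = column_map.get(logical, logical)
        if source in raw.columns:
            rename[source] = logical
        elif logical in REQUIRED_FIELDS:
            raise SchemaError(
                f"peptide report {path} lacks column {source!r} "
                f"(mapped from logical field {logical!r})"
            )
    df = raw.rename(columns=rename)
    df = df[[c for c in REQUIRED_FIELDS + OPTIONAL_FIELDS if c in df.columns]].copy()

    df["peptide_seq"] = df["peptide_seq"].astype(str).str.strip().str.upper()
    for col in ["ratio_hl", "q_value"] + [c for c in OPTIONAL_FIELDS if c in df.columns]:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    rejections = {"nonfinite_ratio": 0, "bad_q_value": 0, "short_peptide": 0}
    ratio_ok = np.isfinite(df["ratio_hl"]) & (df["ratio_hl"] > 0)
    q_ok = df["q_value"].notna() & df["q_value"].between(0.0, 1.0)
    len_ok = df["peptide_seq"].str.len() >= MIN_PEPTIDE_LENGTH
    rejections["nonfinite_ratio"] = int((~ratio_ok).sum())
    rejections["bad_q_value"] = int((ratio_ok & ~q_ok).sum())
    rejections["short_peptide"] = int((ratio_ok & q_ok & ~len_ok).sum())

    keep = ratio_ok & q_ok & len_ok
    dropped = int((~keep).sum())
    if dropped:
        log.warning(
            "rejected %d/%d rows from %s: %s", dropped, len(df), path, rejections
        )
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        raise EmptyInputError(f"peptide report {path}: no rows survived ingest QC")
    return out, rejections


def read_fasta(path) -> ProteinDB:
    """Load a FASTA protein database; accession = header token before whitespace."""
    db = ProteinDB()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} in {path} has an empty sequence")
        if rec.id in db:
            raise FormatError(f"duplicate accession {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        db.records[rec.id] = ProteinRecord(rec.id, seq, desc)
    if n == 0:
        raise EmptyInputError(f"FASTA file {path} contains no records")
    return db


def compute_sequence_coverage(protein_seq: str, peptide_seqs: Iterable[str]) -> float:
    """Percent of protein residues covered by exact peptide substring matches.

    Every occurrence of every peptide contributes its residue span; spans are
    unioned, so overlapping peptides are not double-counted. Peptides that do
    not occur in the protein contribute nothing (not an error). I and L are
    treated as distinct residues.
    """
    if not protein_seq:
        raise FormatError("protein sequence is empty")
    covered = np.zeros(len(protein_seq), dtype=bool)
    for pep in set(peptide_seqs):
        if not pep:
            continue
        start = protein_seq.find(pep)
        while start != -1:
            covered[start : start + len(pep)] = True
            start = protein_seq.find(pep, start + 1)
    # integer-first arithmetic keeps e.g. 70/200 residues at exactly 35.0
    return int(covered.sum()) * 100.0 / len(protein_seq)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as TSV with 12-significant-digit reals."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_run_metadata(path, **payload) -> None:
    """JSON sidecar with parameters, rejection counts, software version."""
    from . import __version__

    payload = {"isopull_version": __version__, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def load_config(path) -> dict:
    """Read a YAML or JSON run configuration (by file extension)."""
    import yaml

    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def save_config(config: dict, path) -> None:
    import yaml

    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
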