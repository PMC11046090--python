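"""File-format helpers: FASTA (via Biopython), CSV/TSV tables, YAML configs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import QconCATConstruct, SelectionReport

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_constructs_fasta",
    "selection_to_frame",
    "manifest_frame",
    "read_yaml",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein ID -> sequence, preserving file order."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences line-wrapped at 60 columns."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_constructs_fasta(constructs: list[QconCATConstruct], path: str | Path) -> None:
    write_fasta({c.construct_id: c.full_sequence for c in constructs}, path)


def selection_to_frame(report: SelectionReport) -> pd.DataFrame:
    """Flatten a selection report to (protein_id, peptide, status/reason)."""
    rows = [
        {"protein_id": pid, "peptide": p.sequence, "status": "selected"}
        for pid, peps in report.chosen.items()
        for p in peps
    ]
    rows += [
        {"protein_id": pid, "peptide": "", "status": f"failed: {reason}"}
        for pid, reason in report.failures.items()
    ]
    return pd.DataFrame(rows, columns=["protein_id", "peptide", "status"])


def manifest_frame(constructs: list[QconCATConstruct]) -> pd.DataFrame:
    """Construct manifest: one row per peptide with its position."""
    rows = []
    for c in constructs:
        for pos, pep in enumerate(c.peptides, start=1):
            rows.append({
                "protein_id": pep.parent_protein or "",
                "peptide": pep.sequence,
                "construct_id": c.construct_id,
                "position": pos,
            })
    return pd.DataFrame(rows, columns=["protein_id", "peptide", "construct_id", "position"])


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
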