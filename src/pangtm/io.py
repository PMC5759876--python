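"""Readers and writers for the pipeline's external formats.

Fixed dialects keep outputs bit-exact: tab-separated matrices, comma-
separated long-format growth curves, UTF-8, Unix newlines.  FASTA goes
through Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clustering import FamilySet, SimilarityRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_families",
    "read_families",
    "write_matrix",
    "read_matrix",
    "write_growth_curves",
    "read_growth_curves",
    "write_phenotype_matrix",
    "read_annotations",
    "write_annotations",
]

BLAST_TAB_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {id: sequence}; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def read_blast_tab(path: str | Path) -> list[SimilarityRecord]:
    """Parse a 12-column BLAST tabular (outfmt 6) file.

    Comment lines starting with ``#`` are skipped; a row with the wrong
    column count raises with its line number.
    """
    records: list[SimilarityRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST_TAB_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(BLAST_TAB_COLUMNS)} "
                    f"tab-separated columns, found {len(parts)}"
                )
            records.append(
                SimilarityRecord(
                    query=parts[0],
                    subject=parts[1],
                    pct_identity=float(parts[2]),
                    aln_len=int(parts[3]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            )
    return records


def write_families(families: FamilySet, path: str | Path) -> None:
    """Families as TSV (family_id, genome_id, gene_id), sorted."""
    with open(path, "w", newline="\n") as fh:
        fh.write("family_id\tgenome_id\tgene_id\n")
        for fid in sorted(families.families):
            for genome in sorted(families.families[fid]):
                for gene in sorted(families.families[fid][genome]):
                    fh.write(f"{fid}\t{genome}\t{gene}\n")


def read_families(path: str | Path, provenance: dict | None = None) -> FamilySet:
    fams: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["family_id", "genome_id", "gene_id"]:
            raise ValueError(f"{path}: unexpected family-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            fid, genome, gene = parts
            fams.setdefault(fid, {}).setdefault(genome, []).append(gene)
    return FamilySet(families=fams, provenance=provenance or {})


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_growth_curves(curves: pd.DataFrame, path: str | Path) -> None:
    curves.to_csv(path, index=False, lineterminator="\n")


def read_growth_curves(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_phenotype_matrix(calls: pd.DataFrame, path: str | Path) -> None:
    """Phenotype calls as TSV with NA for indeterminate readings."""
    calls.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")


def read_annotations(path: str | Path) -> dict[str, str]:
    """Two-column TSV (gene_id, function) -> dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts == ["gene_id", "function"]:
                continue
            out[parts[0]] = parts[1]
    return out


def write_annotations(annotations: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tfunction\n")
        for gene in sorted(annotations):
            fh.write(f"{gene}\t{annotations[gene]}\n")


def write_json(payload, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
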