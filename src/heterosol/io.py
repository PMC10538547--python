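"""Readers and writers for the plain-text interchange formats.

FASTA handling goes through Biopython; tables are TSV via pandas. The
feature table stores one row per observed (peptide, run) with linear
intensity; missing observations are simply absent.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orthoproteome import CollapsedProteome, OrthogroupCatalog


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_collapsed_fasta(proteome: CollapsedProteome, path) -> None:
    """Collapsed proteome as FASTA; header = orthogroup id, member spans in
    the description for traceability."""
    records = []
    for og, entry in proteome.items():
        spans = ";".join(
            f"{b.protein_id}:{b.start}-{b.end}" for b in entry.boundaries
        )
        records.append(SeqRecord(Seq(entry.sequence), id=og, description=spans))
    SeqIO.write(records, str(path), "fasta")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"run_id": str, "genotype": str,
                                                "fraction": str})
    required = {"run_id", "genotype", "fraction", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return design


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"peptide": str, "orthogroup_id": str, "subgenome_specific": str,
               "run_id": str},
    )


def write_tsv(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", float_format="%.10g")


def read_catalog(path) -> OrthogroupCatalog:
    return OrthogroupCatalog.from_tsv(path)
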