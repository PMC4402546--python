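"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated with a header row. Counts tables use the schema
``organelle, gene, site_label, genomic_pos_0based, strand, library_id, nC, nT,
nOther``; the experiment design maps ``library_id`` to one of the three
conditions (uninoculated, gfp_silenced, treatment).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import InputError
from .sites import ANNOTATION_COLUMNS, SITE_COLUMNS

COUNT_COLUMNS = SITE_COLUMNS + ["library_id", "nC", "nT", "nOther"]

CONDITIONS = ("uninoculated", "gfp_silenced", "treatment")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a name → uppercase-sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InputError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=ANNOTATION_COLUMNS)


def read_counts(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=COUNT_COLUMNS)


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column design table (library_id, condition)."""
    df = read_table(path, required=["library_id", "condition"])
    design = dict(zip(df["library_id"].astype(str), df["condition"]))
    check_design(design)
    return design


def check_design(design: Mapping[str, str]) -> None:
    unknown = sorted(set(design.values()) - set(CONDITIONS))
    if unknown:
        raise InputError(f"unknown conditions in design: {unknown}; expected one of {CONDITIONS}")
    if len(design) != len(set(design)):  # dict keys are unique, kept for Mapping impls
        raise InputError("duplicate library_id in design")


def write_design(design: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"library_id": list(design), "condition": [design[k] for k in design]}
    ).to_csv(path, sep="\t", index=False)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
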