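"""Editing-site model and gene-relative coordinate labels.

A candidate editing site is a cytidine on the sense strand of an annotated
organelle transcript. Sites are labelled with gene-relative 1-based CDS
coordinates ("C77"); positions upstream of the start codon (in the 5' leader)
are negative with no position 0 ("C-73"), so the first base of the start codon
is C1 and the base immediately upstream is C-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import InputError

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: canonical column order for a site table
SITE_COLUMNS = ["organelle", "gene", "site_label", "genomic_pos_0based", "strand"]
#: columns that uniquely identify a site
SITE_KEY = ["organelle", "genomic_pos_0based", "strand"]

ANNOTATION_COLUMNS = [
    "gene",
    "organelle",
    "start_0based",
    "end_exclusive",
    "strand",
    "cds_start_0based",
]


@dataclass(frozen=True)
class EditingSite:
    """A candidate or called C position on a transcript strand."""

    organelle: str
    gene: str
    site_label: str
    genomic_pos: int  # 0-based on the reference forward strand
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"invalid strand {self.strand!r} for site {self.gene} {self.site_label}")


def label_from_position(genomic_pos: int, cds_start: int, strand: str) -> str:
    """Gene-relative label for a genomic position.

    ``cds_start`` is the genomic 0-based position of the first base of the
    start codon; for '-' strand genes this is the highest coordinate of the CDS.
    """
    offset = genomic_pos - cds_start if strand == "+" else cds_start - genomic_pos
    n = offset + 1 if offset >= 0 else offset
    return f"C{n}"


def position_from_label(label: str, cds_start: int, strand: str) -> int:
    """Invert :func:`label_from_position`. Raises on malformed labels."""
    if not label.startswith("C"):
        raise InputError(f"malformed site label {label!r}")
    try:
        n = int(label[1:])
    except ValueError as exc:
        raise InputError(f"malformed site label {label!r}") from exc
    if n == 0:
        raise InputError("site labels have no position 0")
    offset = n - 1 if n > 0 else n
    return cds_start + offset if strand == "+" else cds_start - offset


def scan_candidate_sites(reference: dict[str, str], annotation: pd.DataFrame) -> pd.DataFrame:
    """Enumerate every C on the sense strand of every annotated transcript.

    Genomic Cs on '+' transcripts and genomic Gs on '-' transcripts are
    sense-strand cytidines. Positions shared by overlapping transcripts are
    collapsed to one site (first gene in positional order wins). The result is
    sorted by (organelle, genomic position).

    Parameters
    ----------
    reference : mapping of organelle name to forward-strand sequence
    annotation : table with columns ``gene, organelle, start_0based,
        end_exclusive, strand, cds_start_0based``

    Returns
    -------
    DataFrame with :data:`SITE_COLUMNS`.
    """
    rows: list[tuple] = []
    for rec in annotation.itertuples(index=False):
        if rec.organelle not in reference:
            raise InputError(f"annotation references unknown sequence {rec.organelle!r}")
        seq = reference[rec.organelle]
        if not (0 <= rec.start_0based <= rec.end_exclusive <= len(seq)):
            raise InputError(
                f"transcript {rec.gene} [{rec.start_0based}, {rec.end_exclusive}) "
                f"outside reference {rec.organelle} of length {len(seq)}"
            )
        sense_c = "C" if rec.strand == "+" else "G"
        region = seq[rec.start_0based : rec.end_exclusive].upper()
        for i, base in enumerate(region):
            if base == sense_c:
                pos = rec.start_0based + i
                rows.append(
                    (
                        rec.organelle,
                        rec.gene,
                        label_from_position(pos, rec.cds_start_0based, rec.strand),
                        pos,
                        rec.strand,
                    )
                )
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if sites.empty:
        return sites
    sites = sites.drop_duplicates(subset=SITE_KEY, keep="first")
    return sites.sort_values(["organelle", "genomic_pos_0based"]).reset_index(drop=True)
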