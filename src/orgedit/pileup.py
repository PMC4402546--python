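"""Pileup of strand- and transcript-specific alignments at candidate C sites.

Counting is done in transcript-strand orientation: at a '-' strand site, a
read base A on the genome forward strand is a sense-strand T (an edited
molecule), and a forward-strand G is a sense C. Reads that place a base other
than C or T at the site — including deletions and Ns — contribute to
``nOther``: they are evidence of coverage but not of C/T state.

No base-quality or mapping-quality filtering is applied by default; optional
thresholds are exposed for stricter upstream alignments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .exceptions import InputError, UndefinedExtentError
from .sites import COMPLEMENT, SITE_COLUMNS
from .io import COUNT_COLUMNS

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
TALLY_COLUMNS = ["organelle", "pos_0based", "sense_ref", "nA", "nC", "nG", "nT", "nOther"]


def editing_extent(nC: int, nT: int) -> float:
    """Editing extent T/(C+T); reads in other categories carry no C/T signal."""
    total = nC + nT
    if total <= 0:
        raise UndefinedExtentError("editing extent undefined: no C or T reads")
    return nT / total


def extent_series(df: pd.DataFrame) -> pd.Series:
    """Vectorised T/(C+T) over a counts table; NaN where nC + nT = 0."""
    denom = df["nC"] + df["nT"]
    return (df["nT"] / denom.where(denom > 0)).astype(float)


def _sense_base(fwd_base: str | None, strand: str) -> str | None:
    if fwd_base is None:
        return None
    if strand == "-":
        return COMPLEMENT.get(fwd_base.upper(), "N")
    return fwd_base.upper()


def _check_references(sam: pysam.AlignmentFile, reference: dict[str, str], path) -> None:
    missing = [r for r in sam.references if r not in reference]
    if missing:
        raise InputError(f"{path}: alignment references {missing} absent from FASTA")


def pileup_counts(
    sam_path: str | Path,
    sites: pd.DataFrame,
    reference: dict[str, str],
    library_id: str | None = None,
    min_base_quality: int = 0,
    min_mapping_quality: int = 0,
) -> pd.DataFrame:
    """Count C/T/other read bases at each candidate site in one SAM library.

    Parameters
    ----------
    sam_path : SAM file of one library, aligned to ``reference``
    sites : candidate site table (``scan_candidate_sites`` output)
    library_id : value for the output ``library_id`` column; defaults to the
        first read-group ID in the header, else the file stem
    min_base_quality, min_mapping_quality : optional filters, both off (0)
        by default

    Returns a counts table with :data:`orgedit.io.COUNT_COLUMNS`; sites with
    no overlapping reads report (0, 0, 0).
    """
    sam_path = str(sam_path)
    lookup: dict[tuple[str, int], int] = {
        (row.organelle, int(row.genomic_pos_0based)): i
        for i, row in enumerate(sites.itertuples(index=False))
    }
    strands = sites["strand"].to_numpy()
    counts = np.zeros((len(sites), 3), dtype=np.int64)  # C, T, other

    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        _check_references(sam, reference, sam_path)
        if library_id is None:
            rgs = sam.header.to_dict().get("RG", [])
            library_id = rgs[0]["ID"] if rgs else Path(sam_path).stem
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.query_sequence is None:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            ref = read.reference_name
            quals = read.query_qualities
            covered: set[int] = set()
            for qpos, rpos in read.get_aligned_pairs():
                if rpos is None:
                    continue
                idx = lookup.get((ref, rpos))
                if idx is None:
                    continue
                covered.add(idx)
                if qpos is None:  # deletion over the site
                    counts[idx, 2] += 1
                    continue
                if quals is not None and min_base_quality and quals[qpos] < min_base_quality:
                    counts[idx, 2] += 1
                    continue
                base = _sense_base(read.query_sequence[qpos], strands[idx])
                if base == "C":
                    counts[idx, 0] += 1
                elif base == "T":
                    counts[idx, 1] += 1
                else:
                    counts[idx, 2] += 1

    out = sites[SITE_COLUMNS].reset_index(drop=True).copy()
    out["library_id"] = library_id
    out["nC"] = counts[:, 0]
    out["nT"] = counts[:, 1]
    out["nOther"] = counts[:, 2]
    return out[COUNT_COLUMNS]


def pileup_base_tallies(
    sam_path: str | Path,
    reference: dict[str, str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Tally observed bases at every covered reference position of one library.

    Bases and reference are reported in transcript-strand (sense) orientation,
    using the annotation to orient each position; positions outside any
    annotated transcript default to the forward strand. This genome-wide table
    is the input to empirical error-rate estimation.
    """
    sam_path = str(sam_path)
    strand_by_org: dict[str, np.ndarray] = {}
    for org, seq in reference.items():
        arr = np.full(len(seq), "+", dtype="U1")
        strand_by_org[org] = arr
    for rec in annotation.itertuples(index=False):
        if rec.organelle not in strand_by_org:
            raise InputError(f"annotation references unknown sequence {rec.organelle!r}")
        if rec.strand == "-":
            strand_by_org[rec.organelle][rec.start_0based : rec.end_exclusive] = "-"

    tallies = {org: np.zeros((len(seq), 5), dtype=np.int64) for org, seq in reference.items()}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        _check_references(sam, reference, sam_path)
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.query_sequence is None:
                continue
            org = read.reference_name
            tally = tallies[org]
            strand = strand_by_org[org]
            qseq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs():
                if rpos is None:
                    continue
                if qpos is None:
                    tally[rpos, 4] += 1
                    continue
                base = _sense_base(qseq[qpos], strand[rpos])
                tally[rpos, _BASE_INDEX.get(base, 4) if base in _BASE_INDEX else 4] += 1

    rows = []
    for org, tally in tallies.items():
        covered = np.flatnonzero(tally.sum(axis=1))
        seq = reference[org]
        strand = strand_by_org[org]
        for pos in covered:
            ref_base = seq[pos] if strand[pos] == "+" else COMPLEMENT.get(seq[pos], "N")
            rows.append((org, int(pos), ref_base, *tally[pos]))
    return pd.DataFrame(rows, columns=TALLY_COLUMNS)
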