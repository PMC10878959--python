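"""File formats used across the pipeline.

Tabular data is plain TSV (tab-separated, UTF-8, ``#`` comment lines).
Feature matrices are stored features-as-rows with the feature id in the
first column and one column per sample.  Alignments use a restricted SAM
dialect ("SAM-lite"): forward-strand reads aligned to pre-miRNA
references, CIGAR limited to M and S operations.  FASTA sequences are
normalized to the uppercase RNA alphabet on input (T becomes U).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = ("A", "C", "G", "U")


class ParseError(ValueError):
    """A malformed input file; the message names the offending record."""


@dataclasses.dataclass(frozen=True)
class SamRead:
    """One forward-strand alignment of a small-RNA read to a pre-miRNA.

    ``pos`` is the 1-based leftmost reference coordinate.  The CIGAR may
    only contain M (alignment match) and S (soft clip) operations.
    """

    qname: str
    rname: str
    pos: int
    cigar: str
    seq: str

    def cigar_ops(self) -> list[tuple[str, int]]:
        ops: list[tuple[str, int]] = []
        num = ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
            else:
                if not num or ch not in "MS":
                    raise ParseError(
                        f"read {self.qname!r}: unsupported CIGAR {self.cigar!r}"
                    )
                ops.append((ch, int(num)))
                num = ""
        if num:
            raise ParseError(f"read {self.qname!r}: truncated CIGAR {self.cigar!r}")
        return ops


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> RNA sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = normalize_rna(str(rec.seq))
    return records


def write_fasta(references: Mapping[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in references.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_samlite(path: str | Path) -> list[SamRead]:
    """Read SAM-lite alignments via pysam, keeping the fields we consume."""
    reads: list[SamRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            reads.append(
                SamRead(
                    qname=rec.query_name,
                    rname=rec.reference_name,
                    pos=rec.reference_start + 1,
                    cigar=rec.cigarstring or "",
                    seq=normalize_rna(rec.query_sequence or ""),
                )
            )
    return reads


def write_samlite(
    reads: Iterable[SamRead], references: Mapping[str, str], path: str | Path
) -> None:
    """Write SAM-lite with a proper @SQ header so standard tools accept it."""
    names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(references[n])} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = read.qname
            rec.flag = 0
            rec.reference_id = names.index(read.rname)
            rec.reference_start = read.pos - 1
            rec.mapping_quality = 255
            rec.cigarstring = read.cigar
            rec.query_sequence = read.seq
            fh.write(rec)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV into a samples x features DataFrame.

    The on-disk layout has features as rows (first column = feature id);
    in memory we keep the samples x features orientation used by the
    modelling code.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ParseError(f"duplicate feature id {dup[0]!r} in {path}")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ParseError(f"non-numeric cell in column {col!r}, feature row {row!r}")
    df.index = df.index.astype(str)
    df.index.name = "feature"
    return df.T


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x features DataFrame as a features x samples TSV."""
    out = matrix.T
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (sample, batch, class) indexed by sample."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "batch", "class"}
    missing = required - set(meta.columns)
    if missing:
        raise ParseError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].iloc[0]
        raise ParseError(f"duplicate sample id {dup!r}")
    return meta.set_index("sample")


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_mature_coords_tsv(path: str | Path) -> pd.DataFrame:
    """Read the mature-miRNA coordinate table (premirna, start, end, arm)."""
    tab = pd.read_csv(path, sep="\t", comment="#", dtype={"premirna": str})
    required = {"premirna", "mature_start", "mature_end"}
    missing = required - set(tab.columns)
    if missing:
        raise ParseError(f"coordinate table missing columns: {sorted(missing)}")
    return tab.set_index("premirna")
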