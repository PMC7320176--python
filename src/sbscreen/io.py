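"""Plain-text readers/writers for the pipeline's tabular and sequence formats.

Insertion tables travel as TSV with the fixed schema (chrom, pos,
transposon_orient, tumour_id, strain, cre, support); a BED6 export is
provided for genome-browser use (0-based half-open, name = tumour id,
strand = transposon orientation). FASTA/FASTQ go through Bio.SeqIO.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .simulate import INSERTION_COLUMNS


def write_insertions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_insertions(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"insertion table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    missing = set(INSERTION_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """BED6 export: start = pos-1 (0-based half-open), score = support."""
    with Path(path).open("w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos - 1}\t{row.pos + 1}\t{row.tumour_id}"
                f"\t{row.support}\t{row.transposon_orient}\n"
            )


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA not found: {path}")
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTQ not found: {path}")
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
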