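"""Thin I/O helpers over Biopython and pandas.

FASTA/FASTQ go through Bio.SeqIO; GFF3 is read as the tab-separated
table it is (attributes kept verbatim) and written 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


@dataclass
class FastqRead:
    id: str
    sequence: str
    quality: list[int]  # Phred scores


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Parse Phred+33 FASTQ; malformed records are reported by index."""
    reads: list[FastqRead] = []
    parser = SeqIO.parse(str(path), "fastq")
    index = 0
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc
        reads.append(
            FastqRead(rec.id, str(rec.seq).upper(),
                      list(rec.letter_annotations["phred_quality"]))
        )
        index += 1
    return reads


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_gff3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str, "type": str, "strand": str, "attributes": str},
    )
    return df


def write_gff3(path: str | Path, features: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        features.to_csv(fh, sep="\t", header=False, index=False)


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(str(path), sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", **kwargs)
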