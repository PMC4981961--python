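"""Reading and writing the standard formats used across the pipeline.

Sequences live in RNA space (ACGU) inside the package; FASTA/FASTQ on disk
use the DNA convention (ACGT).  Conversion happens only at these
boundaries.  Parsing goes through Biopython.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGU", "UGCA")


def revcomp(seq: str) -> str:
    """Reverse complement in RNA space (G:C, A:U)."""
    return seq.translate(COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA file -> {id: RNA-space sequence}, preserving order."""
    return {rec.id: to_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, seqs: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(to_dna(s)), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """FASTQ file -> [(id, RNA-space sequence, quality string)]."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, to_rna(str(rec.seq)), quals))
    return out


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{to_dna(seq)}\n+\n{qual}\n")


def write_tsv(path: str | os.PathLike, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
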