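"""Sequence alphabet helpers and plain-text I/O (FASTA/FASTQ, collapsed FASTA).

Internally all small-RNA sequences are handled as uppercase RNA (U alphabet);
genomes and transcriptomes are kept in the DNA (T) alphabet. Conversion is a
pure T<->U swap — no complementation.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Iterator, List, Tuple

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, records: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def iter_fastq_seqs(path: str | os.PathLike) -> Iterator[str]:
    with open(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq.upper()


def write_fastq(path: str | os.PathLike, seqs: Iterable[str], prefix: str = "read") -> None:
    """Write reads with a constant Phred-33 quality ('I' = Q40)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs, 1):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def iter_reads(path: str | os.PathLike) -> Iterator[str]:
    """Yield read sequences from a FASTA or FASTQ file (sniffed from the first byte)."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        yield from iter_fastq_seqs(path)
    else:
        for rec in SeqIO.parse(str(path), "fasta"):
            yield str(rec.seq).upper()


def write_collapsed_fasta(path: str | os.PathLike, collapsed, dialect: str = "rna") -> None:
    """Write collapsed reads as ``>seq<rank>_x<count>`` FASTA.

    ``dialect`` selects the output alphabet ("rna" or "dna"); sequences are
    stored internally as RNA.
    """
    conv = to_dna if dialect == "dna" else to_rna
    with open(path, "w") as fh:
        for rank, rec in enumerate(collapsed, 1):
            fh.write(f">seq{rank}_x{rec.count}\n{conv(rec.sequence)}\n")


def read_collapsed_fasta(path: str | os.PathLike, library_id: str = "") -> List:
    from .profiling import CollapsedRead

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        out.append(CollapsedRead(sequence=to_rna(str(rec.seq)), count=count,
                                 library_id=library_id))
    return out
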