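"""FASTA/FASTQ readers and writers used throughout the pipeline.

Thin, streaming wrappers around Bio.SeqIO with the package's normalization
rules applied on read: bases are uppercased and RNA 'U' becomes 'T' (the
genomes are handled as cDNA). Qualities are phred scores; files are encoded
phred+33 (Illumina 1.8+) with a configurable offset.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import normalize

PathOrHandle = Union[str, Path, IO[str]]


class SequenceParseError(ValueError):
    """Malformed FASTA/FASTQ input; message names the offending record."""


@dataclass
class FastqRecord:
    """One sequencing read: id, bases over {A,C,G,T,N}, phred qualities."""

    id: str
    bases: str
    qualities: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise SequenceParseError(
                f"record {self.id!r}: sequence length {len(self.bases)} != "
                f"quality length {len(self.qualities)}"
            )
        if any(q < 0 or q > 93 for q in self.qualities):
            raise SequenceParseError(f"record {self.id!r}: phred score out of [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0

    def n_fraction(self) -> float:
        return self.bases.count("N") / len(self.bases) if self.bases else 0.0


def _open(path: PathOrHandle, mode: str = "rt") -> IO[str]:
    if hasattr(path, "read") or hasattr(path, "write"):
        return path  # already a handle
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode)
    return open(p, mode)


def read_fasta(path: PathOrHandle) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs; sequences uppercased, U->T."""
    handle = _open(path)
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, normalize(str(rec.seq))
    finally:
        if handle is not path:
            handle.close()


def write_fasta(path: PathOrHandle, records: Iterable[tuple[str, str]], width: int = 60) -> int:
    """Write (id, sequence) pairs, 60-column wrapped. Returns record count."""
    handle = _open(path, "wt")
    n = 0
    try:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
            n += 1
    finally:
        if handle is not path:
            handle.close()
    return n


def read_fastq(path: PathOrHandle, offset: int = 33) -> Iterator[FastqRecord]:
    """Stream FastqRecords; constant memory in the number of records.

    Raises SequenceParseError (naming the record) on truncated records or
    sequence/quality length mismatches.
    """
    handle = _open(path)
    last_id = "<start of file>"
    try:
        while True:
            header = handle.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header:
                continue
            if not header.startswith("@"):
                raise SequenceParseError(
                    f"expected '@' header after record {last_id!r}, got {header[:30]!r}"
                )
            rid = header[1:].split()[0] if len(header) > 1 else ""
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not plus or not plus.startswith("+") or (not qual and seq):
                raise SequenceParseError(f"truncated FASTQ record {rid!r}")
            if len(qual) != len(seq):
                raise SequenceParseError(
                    f"record {rid!r}: quality line length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            last_id = rid
            yield FastqRecord(rid, normalize(seq), [ord(c) - offset for c in qual])
    finally:
        if handle is not path:
            handle.close()


def write_fastq(path: PathOrHandle, records: Iterable[FastqRecord], offset: int = 33) -> int:
    handle = _open(path, "wt")
    n = 0
    try:
        for rec in records:
            quals = "".join(chr(q + offset) for q in rec.qualities)
            handle.write(f"@{rec.id}\n{rec.bases}\n+\n{quals}\n")
            n += 1
    finally:
        if handle is not path:
            handle.close()
    return n


def to_seqrecord(rec: FastqRecord) -> SeqRecord:
    """Bridge to Biopython for callers that want SeqRecord objects."""
    sr = SeqRecord(Seq(rec.bases), id=rec.id, description="")
    sr.letter_annotations["phred_quality"] = list(rec.qualities)
    return sr
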