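"""FASTQ I/O and the paired-read container used across the pipelines.

Reading goes through Biopython's fast FASTQ iterator, wrapped so that a
malformed or truncated record reports its record index. Paths ending in
``.gz`` are handled transparently on both read and write.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass
class ReadPair:
    """One paired-end amplicon read, optionally tagged with its cell."""

    name: str
    seq1: str
    seq2: str
    cell_id: str | None = None

    def __post_init__(self) -> None:
        if not self.seq1 or not self.seq2:
            raise ValueError(f"read pair {self.name!r}: both mates must be non-empty")


class FastqFormatError(ValueError):
    pass


def _open(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into (name, sequence) tuples."""
    out: list[tuple[str, str]] = []
    with _open(path, "r") as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                rec = next(it, None)
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: malformed FASTQ at record {len(out) + 1}: {exc}"
                ) from exc
            if rec is None:
                break
            title, seq, _qual = rec
            out.append((title.split()[0], seq))
    return out


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> None:
    """Write (name, sequence) records as 4-line FASTQ with constant quality."""
    with _open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_pairs(pairs: Iterable[ReadPair], r1_path: str | Path,
                r2_path: str | Path) -> None:
    pairs = list(pairs)
    write_fastq(((p.name, p.seq1) for p in pairs), r1_path)
    write_fastq(((p.name, p.seq2) for p in pairs), r2_path)


def read_pairs(r1_path: str | Path, r2_path: str | Path,
               cell_id: str | None = None) -> list[ReadPair]:
    """Read mate files back into pairs; mates are matched by record order."""
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise FastqFormatError(
            f"mate files differ in record count ({len(r1)} vs {len(r2)})"
        )
    out = []
    for (n1, s1), (n2, s2) in zip(r1, r2):
        if n1 != n2:
            raise FastqFormatError(f"mate name mismatch: {n1!r} vs {n2!r}")
        out.append(ReadPair(name=n1, seq1=s1, seq2=s2, cell_id=cell_id))
    return out
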