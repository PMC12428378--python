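"""FASTA input and tabular output.

Sequences are normalized to uppercase {A,C,G,T,N}: soft-masked lowercase
bases are uppercased and IUPAC ambiguity codes other than N are mapped to N,
so the downstream N-gap filter handles them uniformly.  All genomic
intervals in this package are 0-based half-open; strand is '+' or '-'.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "normalize_bases",
    "read_fasta",
    "write_bed",
    "write_tsv",
    "write_json",
    "FastaParseError",
]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (no header, empty record)."""


_NORM = {c: c for c in "ACGTN"}
_NORM.update({c.lower(): c for c in "ACGTN"})


def normalize_bases(raw: str) -> str:
    """Uppercase and map any non-ACGTN character (IUPAC codes etc.) to N."""
    return "".join(_NORM.get(c, "N") for c in raw)


@dataclass(frozen=True)
class GenomeSequence:
    """One named DNA sequence over the alphabet {A,C,G,T,N}."""

    name: str
    bases: str

    @property
    def length(self) -> int:
        return len(self.bases)

    def __post_init__(self) -> None:
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise ValueError(f"non-normalized bases in {self.name!r}: {sorted(bad)}")


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a plain or gzipped FASTA file into normalized GenomeSequences.

    Record order is preserved.  Raises :class:`FastaParseError` when the file
    is empty, does not start with a header, or contains an empty record.
    """
    path = Path(path)
    with _open_text(path) as fh:
        text_head = ""
        for line in fh:
            if line.strip():
                text_head = line
                break
        if not text_head:
            raise FastaParseError(f"{path}: empty FASTA file")
        if not text_head.startswith(">"):
            raise FastaParseError(f"{path}: does not start with a '>' header")
    out: list[GenomeSequence] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            bases = normalize_bases(str(rec.seq))
            if not bases:
                raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
            out.append(GenomeSequence(name=rec.id, bases=bases))
    if not out:
        raise FastaParseError(f"{path}: no FASTA records found")
    return out


def write_bed(records: Iterable[Sequence], path: str | Path) -> None:
    """Write 6-column BED (name, start, end, label, score, strand).

    Coordinates are 0-based half-open; start must be < end.
    """
    path = Path(path)
    lines = []
    for rec in records:
        name, start, end, label, score, strand = rec
        if not int(start) < int(end):
            raise ValueError(f"degenerate BED interval {name}:{start}-{end}")
        if strand not in ("+", "-"):
            raise ValueError(f"invalid strand {strand!r}")
        lines.append(f"{name}\t{int(start)}\t{int(end)}\t{label}\t{score}\t{strand}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def write_tsv(df, path: str | Path) -> None:
    """Write a pandas DataFrame as TSV without the index."""
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
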