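"""Small FASTA / group-file / name-list helpers (Biopython-backed)."""

from __future__ import annotations

import io
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "parse_fasta",
    "write_fasta",
    "read_group_file",
    "write_group_file",
    "read_accnos",
    "reverse_complement",
    "translate",
]


def parse_fasta(source) -> Iterator[tuple[str, str]]:
    """Yield ``(header, sequence)`` pairs from a path, handle, or FASTA string."""
    if hasattr(source, "read"):
        handle = source
    elif isinstance(source, str) and source.lstrip().startswith(">"):
        handle = io.StringIO(source)
    else:
        handle = open(source, "r", encoding="utf-8")
    try:
        for record in SeqIO.parse(handle, "fasta"):
            yield record.description, str(record.seq)
    finally:
        if handle is not source:
            handle.close()


def write_fasta(records: Iterable[tuple[str, str]], path=None) -> str:
    """Render ``(header, sequence)`` pairs as FASTA; write to ``path`` if given."""
    text = "".join(f">{name}\n{seq}\n" for name, seq in records)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def read_group_file(source) -> dict[str, str]:
    """Read a two-column ``read_id<TAB>sample`` group file."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    groups: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        read_id, sample = line.split("\t")
        groups[read_id.strip()] = sample.strip()
    return groups


def write_group_file(groups: dict[str, str], path=None) -> str:
    text = "".join(f"{rid}\t{sample}\n" for rid, sample in groups.items())
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def read_accnos(source) -> set[str]:
    """Read a one-id-per-line removal list (mothur accnos dialect)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    return {line.strip() for line in text.splitlines() if line.strip()}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide string (frame 1, standard code, '*' for stops).

    Trailing bases that do not fill a codon are ignored, so a 408-nt fragment
    yields 136 residues.
    """
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())
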