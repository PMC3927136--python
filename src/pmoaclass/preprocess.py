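"""Quality filtering of raw amplicon reads.

Pyrosequencing amplicon surveys are filtered before classification: short reads
carry too little signal, ambiguity codes indicate low base quality, and long
homopolymer runs are the platform's characteristic error mode.  Chimera
detection is delegated to external tools; their output (a list of read ids) is
applied here with :func:`remove_by_name`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = ["ReadRecord", "FilterConfig", "quality_filter", "remove_by_name"]

_ACGT = frozenset("ACGT")


@dataclass
class ReadRecord:
    """A single amplicon read, optionally tagged with its sample of origin."""

    read_id: str
    sequence: str
    sample: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterConfig:
    """Quality-filter thresholds.

    Defaults drop reads shorter than 300 bp, reads with any ambiguous base, and
    reads containing a single-base run longer than eight.
    """

    min_length: int = 300
    max_homopolymer: int = 8
    max_ambiguous: int = 0

    def __post_init__(self) -> None:
        if min(self.min_length, self.max_homopolymer, self.max_ambiguous) < 0:
            raise ValueError("filter thresholds must be nonnegative")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _longest_homopolymer(seq: str) -> int:
    best = run = 0
    prev = ""
    for base in seq:
        run = run + 1 if base == prev else 1
        prev = base
        if run > best:
            best = run
    return best


def quality_filter(
    reads: Iterable[ReadRecord], cfg: Optional[FilterConfig] = None
) -> tuple[list[ReadRecord], list[tuple[ReadRecord, str]]]:
    """Partition reads into kept and rejected-with-reason, preserving order.

    When several rules fire the reported reason is the first of ``length``,
    ``ambiguity``, ``homopolymer`` — a deterministic accounting so rejection
    counts are reproducible.  Sequences are uppercased and U mapped to T before
    checking; the normalized sequence is what is kept.
    """
    cfg = cfg or FilterConfig()
    kept: list[ReadRecord] = []
    rejected: list[tuple[ReadRecord, str]] = []
    for read in reads:
        seq = _normalize(read.sequence)
        record = ReadRecord(read.read_id, seq, read.sample)
        if len(seq) < cfg.min_length:
            rejected.append((record, "length"))
        elif sum(1 for b in seq if b not in _ACGT) > cfg.max_ambiguous:
            rejected.append((record, "ambiguity"))
        elif _longest_homopolymer(seq) > cfg.max_homopolymer:
            rejected.append((record, "homopolymer"))
        else:
            kept.append(record)
    return kept, rejected


def remove_by_name(
    reads: Iterable[ReadRecord], names: set[str]
) -> tuple[list[ReadRecord], list[str]]:
    """Drop reads whose id is in ``names`` (e.g. an external chimera list).

    Returns the surviving reads and the sorted list of names that matched
    nothing (unmatched names are ignored but reported for logging).
    """
    reads = list(reads)
    ids = {r.read_id for r in reads}
    survivors = [r for r in reads if r.read_id not in names]
    unmatched = sorted(names - ids)
    return survivors, unmatched
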