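"""Scored local search of reads against the reference database.

Two native modes are provided, both seed-and-extend: a nucleotide mode that
requires an exact shared word of 28 nt (the megablast-style seeding that makes
highly divergent sequences invisible), and a six-frame translated mode seeding
on 3-residue words (far more sensitive, because protein sequences are more
conserved than nucleotide sequences).  Whenever a pair shares a seed word the
alignment itself is computed exactly — full-matrix affine Smith–Waterman — so
raw scores are optimal under the configured scheme.  Raw scores are converted
to bit scores with Karlin–Altschul parameters; bit scores are the comparison
currency of the downstream LCA and novelty procedures.

A parser for externally produced 12-column tabular search output is also
provided, so results from a standalone search engine can be fed into the same
downstream steps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
from Bio.Align import substitution_matrices

from ._sw import affine_local_align
from .preprocess import ReadRecord
from .seqio import reverse_complement, translate
from .taxonomy import ReferenceDB

__all__ = [
    "SearchConfig",
    "Hit",
    "HitSet",
    "search_nucleotide",
    "search_translated",
    "parse_external_tabular",
    "write_hits_tabular",
    "raw_score_to_bits",
    "expected_bit_score",
]

logger = logging.getLogger(__name__)

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# Karlin-Altschul parameters: +1/-2 with gap 5/2 for nucleotide (megablast-style
# defaults), BLOSUM62 with gap 11/1 for protein.
_NT_LAMBDA, _NT_K = 1.28, 0.46
_AA_LAMBDA, _AA_K = 0.267, 0.041


@dataclass(frozen=True)
class SearchConfig:
    """Scoring and seeding parameters for the native search engine.

    ``mismatch_penalty``, ``gap_open`` and ``gap_extend`` are positive
    magnitudes; a gap of length L costs ``gap_open + L * gap_extend`` raw-score
    units.  ``lambda_`` and ``k_const`` rescale raw scores into bits:
    ``bits = (lambda_ * raw - ln(k_const)) / ln(2)``.
    """

    word_size: int = 28
    match_reward: int = 1
    mismatch_penalty: int = 2
    gap_open: int = 5
    gap_extend: int = 2
    lambda_: float = _NT_LAMBDA
    k_const: float = _NT_K
    min_report_bits: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.word_size < 2:
            raise ValueError("word_size must be at least 2")

    @classmethod
    def translated(cls, **overrides) -> "SearchConfig":
        """Defaults for the six-frame translated mode (BLOSUM62, word size 3)."""
        cfg = cls(
            word_size=3,
            gap_open=11,
            gap_extend=1,
            lambda_=_AA_LAMBDA,
            k_const=_AA_K,
        )
        return replace(cfg, **overrides) if overrides else cfg


def raw_score_to_bits(raw_score: float, cfg: SearchConfig) -> float:
    return (cfg.lambda_ * raw_score - math.log(cfg.k_const)) / math.log(2.0)


def expected_bit_score(
    alignment_length: int, divergence: float, cfg: Optional[SearchConfig] = None
) -> float:
    """Expected bit score of an ungapped alignment at a given divergence.

    Used to translate a nucleotide-divergence level into the bit-score currency
    of this engine, e.g. when calibrating the "new clade" flag to the taxonomy's
    granularity (reference taxa are mutually >5% divergent, so a best hit
    implying more than ~5% divergence is candidate novelty).
    """
    cfg = cfg or SearchConfig()
    mismatches = round(alignment_length * divergence)
    raw = (alignment_length - mismatches) * cfg.match_reward
    raw -= mismatches * cfg.mismatch_penalty
    return raw_score_to_bits(raw, cfg)


@dataclass
class Hit:
    """One scored local alignment of a read against one reference sequence.

    ``query_span``/``subject_span`` are 1-based inclusive; for minus-strand
    nucleotide hits the query span is given on the original read with
    ``strand == '-'``.  Translated hits carry amino-acid coordinates within the
    indicated frames and ``strand`` like ``'+2/-1'`` (query frame / subject
    frame).  ``aligned_query``/``aligned_subject`` use ``'-'`` for gaps and are
    ``None`` for hits parsed from external tabular output.
    """

    query_id: str
    subject_accession: str
    subject_taxon: str
    raw_score: int
    bit_score: float
    identity_pct: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    strand: str = "+"
    aligned_query: Optional[str] = None
    aligned_subject: Optional[str] = None
    alignment_length: int = 0


class HitSet:
    """Best hit per subject taxon for one query, sorted by descending bit score."""

    def __init__(self, query_id: str, hits: Iterable[Hit] = ()):
        self.query_id = query_id
        self._by_taxon: dict[str, Hit] = {}
        for hit in hits:
            self.add(hit)

    def add(self, hit: Hit) -> None:
        incumbent = self._by_taxon.get(hit.subject_taxon)
        if incumbent is None or hit.bit_score > incumbent.bit_score:
            self._by_taxon[hit.subject_taxon] = hit

    @property
    def hits(self) -> list[Hit]:
        return sorted(
            self._by_taxon.values(),
            key=lambda h: (-h.bit_score, h.subject_taxon),
        )

    @property
    def best(self) -> Optional[Hit]:
        hits = self.hits
        return hits[0] if hits else None

    def __len__(self) -> int:
        return len(self._by_taxon)

    def __bool__(self) -> bool:
        return bool(self._by_taxon)

    def __iter__(self):
        return iter(self.hits)


# ---------------------------------------------------------------------------
# encodings and cached per-database indexes


def _encode_nt(seq: str) -> np.ndarray:
    return np.fromiter((_NT_CODE.get(b, 4) for b in seq), np.int64, len(seq))


def _nt_submat(cfg: SearchConfig) -> np.ndarray:
    sub = np.full((5, 5), -cfg.mismatch_penalty, np.int64)
    for i in range(4):
        sub[i, i] = cfg.match_reward
    sub[4, :] = -cfg.mismatch_penalty  # ambiguity codes never match
    sub[:, 4] = -cfg.mismatch_penalty
    return sub


_B62 = substitution_matrices.load("BLOSUM62")
_AA_ALPHABET = str(_B62.alphabet)
_AA_CODE = {aa: i for i, aa in enumerate(_AA_ALPHABET)}
_STOP = _AA_CODE["*"]


def _aa_submat(stop_score: int = -1000) -> np.ndarray:
    n = len(_AA_ALPHABET)
    sub = np.zeros((n, n), np.int64)
    for i, a in enumerate(_AA_ALPHABET):
        for j, b in enumerate(_AA_ALPHABET):
            sub[i, j] = int(_B62[a, b])
    sub[_STOP, :] = stop_score  # stop codons truncate any extension
    sub[:, _STOP] = stop_score
    return sub


_AA_SUBMAT = _aa_submat()


def _encode_aa(seq: str) -> np.ndarray:
    x = _AA_CODE["X"]
    return np.fromiter((_AA_CODE.get(a, x) for a in seq), np.int64, len(seq))


def _words(seq: str, size: int) -> set[str]:
    return {seq[i : i + size] for i in range(len(seq) - size + 1)}


def _six_frames(seq: str) -> list[tuple[str, str]]:
    rc = reverse_complement(seq)
    return [
        ("+1", translate(seq)),
        ("+2", translate(seq[1:])),
        ("+3", translate(seq[2:])),
        ("-1", translate(rc)),
        ("-2", translate(rc[1:])),
        ("-3", translate(rc[2:])),
    ]


class _NucleotideIndex:
    def __init__(self, db: ReferenceDB, word_size: int):
        self.encoded = [_encode_nt(rec.sequence.upper()) for rec in db.records]
        self.word_index: dict[str, list[int]] = {}
        for idx, rec in enumerate(db.records):
            for word in _words(rec.sequence.upper(), word_size):
                self.word_index.setdefault(word, []).append(idx)


class _TranslatedIndex:
    def __init__(self, db: ReferenceDB, word_size: int):
        self.frames: list[list[tuple[str, str, np.ndarray]]] = []
        self.word_index: dict[str, set[tuple[int, int]]] = {}
        for idx, rec in enumerate(db.records):
            frames = []
            for fno, (label, prot) in enumerate(_six_frames(rec.sequence.upper())):
                frames.append((label, prot, _encode_aa(prot)))
                for word in _words(prot, word_size):
                    if "*" in word or "X" in word:
                        continue
                    self.word_index.setdefault(word, set()).add((idx, fno))
            self.frames.append(frames)


def _cached_index(db: ReferenceDB, kind: str, word_size: int):
    cache = getattr(db, "_pmoaclass_index_cache", None)
    if cache is None:
        cache = {}
        db._pmoaclass_index_cache = cache
    key = (kind, word_size)
    if key not in cache:
        cache[key] = (
            _NucleotideIndex(db, word_size)
            if kind == "nt"
            else _TranslatedIndex(db, word_size)
        )
    return cache[key]


# ---------------------------------------------------------------------------
# native search


def _alignment_strings(
    pairs: list[tuple[int, int]], a: str, b: str
) -> tuple[str, str, int]:
    qa, qb, ident = [], [], 0
    for i, j in pairs:
        ca = a[i - 1] if i else "-"
        cb = b[j - 1] if j else "-"
        qa.append(ca)
        qb.append(cb)
        if i and j and ca == cb:
            ident += 1
    return "".join(qa), "".join(qb), ident


def search_nucleotide(
    read: ReadRecord, db: ReferenceDB, cfg: Optional[SearchConfig] = None
) -> HitSet:
    """Seed-and-extend nucleotide search of one read against the database.

    Both strands of the read are searched.  A reference is aligned only if it
    shares at least one exact word of ``cfg.word_size`` with the read; a read
    sharing no word with any reference yields an empty :class:`HitSet` ("no
    hits"), which downstream novelty detection treats as its own signal.
    """
    cfg = cfg or SearchConfig()
    index: _NucleotideIndex = _cached_index(db, "nt", cfg.word_size)
    submat = _nt_submat(cfg)
    seq = read.sequence.upper()
    hitset = HitSet(read.read_id)

    oriented = [("+", seq), ("-", reverse_complement(seq))]
    for strand, oseq in oriented:
        candidates: set[int] = set()
        for word in _words(oseq, cfg.word_size):
            candidates.update(index.word_index.get(word, ()))
        if not candidates:
            continue
        encoded = _encode_nt(oseq)
        for ref_idx in sorted(candidates):
            rec = db.records[ref_idx]
            score, q_span, s_span, pairs = affine_local_align(
                encoded, index.encoded[ref_idx], submat, cfg.gap_open, cfg.gap_extend
            )
            if score <= 0:
                continue
            bits = raw_score_to_bits(score, cfg)
            if bits < cfg.min_report_bits:
                continue
            aq, asub, ident = _alignment_strings(pairs, oseq, rec.sequence.upper())
            if strand == "-":
                n = len(seq)
                q_span = (n - q_span[1] + 1, n - q_span[0] + 1)
            hitset.add(
                Hit(
                    query_id=read.read_id,
                    subject_accession=rec.accession,
                    subject_taxon=rec.taxon_name,
                    raw_score=score,
                    bit_score=bits,
                    identity_pct=100.0 * ident / len(pairs),
                    query_span=q_span,
                    subject_span=s_span,
                    strand=strand,
                    aligned_query=aq,
                    aligned_subject=asub,
                    alignment_length=len(pairs),
                )
            )
    return hitset


def search_translated(
    read: ReadRecord, db: ReferenceDB, cfg: Optional[SearchConfig] = None
) -> HitSet:
    """Six-frame translated search (query frames x reference frames).

    Seeds on exact shared amino-acid words and extends with BLOSUM62; stop
    codons truncate extensions.  Used to rescue highly divergent CuMMO reads
    that produce no nucleotide hits: genuine but deeply divergent homologs
    still reach significant protein-level bit scores, whereas unrelated
    contaminants do not.
    """
    cfg = cfg or SearchConfig.translated()
    index: _TranslatedIndex = _cached_index(db, "aa", cfg.word_size)
    seq = read.sequence.upper()
    hitset = HitSet(read.read_id)

    query_frames = [
        (label, prot, _encode_aa(prot)) for label, prot in _six_frames(seq)
    ]
    for q_label, q_prot, q_enc in query_frames:
        pair_candidates: set[tuple[int, int]] = set()
        for word in _words(q_prot, cfg.word_size):
            if "*" in word or "X" in word:
                continue
            pair_candidates.update(index.word_index.get(word, ()))
        for ref_idx, fno in sorted(pair_candidates):
            rec = db.records[ref_idx]
            s_label, s_prot, s_enc = index.frames[ref_idx][fno]
            score, q_span, s_span, pairs = affine_local_align(
                q_enc, s_enc, _AA_SUBMAT, cfg.gap_open, cfg.gap_extend
            )
            if score <= 0:
                continue
            bits = raw_score_to_bits(score, cfg)
            if bits < cfg.min_report_bits:
                continue
            aq, asub, ident = _alignment_strings(pairs, q_prot, s_prot)
            hitset.add(
                Hit(
                    query_id=read.read_id,
                    subject_accession=rec.accession,
                    subject_taxon=rec.taxon_name,
                    raw_score=score,
                    bit_score=bits,
                    identity_pct=100.0 * ident / len(pairs),
                    query_span=q_span,
                    subject_span=s_span,
                    strand=f"{q_label}/{s_label}",
                    aligned_query=aq,
                    aligned_subject=asub,
                    alignment_length=len(pairs),
                )
            )
    return hitset


# ---------------------------------------------------------------------------
# external tabular results


def parse_external_tabular(text, db: ReferenceDB) -> list[HitSet]:
    """Parse 12-column tabular search output into best-per-taxon HitSets.

    Expected columns: query id, subject id, % identity, alignment length,
    mismatches, gap opens, query start/end, subject start/end, e-value, bit
    score.  Subject ids are mapped to taxa through the reference database; rows
    with unknown subjects are dropped (and counted in the log).  HitSets are
    returned in order of first appearance of each query.
    """
    if hasattr(text, "read"):
        text = text.read()
    taxon_of = {rec.accession: rec.taxon_name for rec in db.records}
    hitsets: dict[str, HitSet] = {}
    dropped = 0
    for lineno, line in enumerate(str(text).splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, "
                f"got {len(fields)}"
            )
        try:
            qid, sid = fields[0], fields[1]
            identity = float(fields[2])
            length = int(fields[3])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            bits = float(fields[11])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed field ({exc})") from None
        taxon = taxon_of.get(sid)
        if taxon is None:
            dropped += 1
            logger.warning("line %d: unknown subject %r dropped", lineno, sid)
            continue
        strand = "+"
        if sstart > send:
            sstart, send = send, sstart
            strand = "-"
        hit = Hit(
            query_id=qid,
            subject_accession=sid,
            subject_taxon=taxon,
            raw_score=0,
            bit_score=bits,
            identity_pct=identity,
            query_span=(qstart, qend),
            subject_span=(sstart, send),
            strand=strand,
            alignment_length=length,
        )
        hitsets.setdefault(qid, HitSet(qid)).add(hit)
    if dropped:
        logger.info("dropped %d rows with unknown subject accessions", dropped)
    return list(hitsets.values())


def write_hits_tabular(hitsets: Iterable[HitSet], path=None) -> str:
    """Render HitSets in the 12-column tabular dialect plus a taxon column.

    The e-value column is written as ``NA``: the procedure works in bit scores.
    """
    lines = []
    for hs in hitsets:
        for hit in hs.hits:
            mismatches = 0
            gaps = 0
            if hit.aligned_query is not None:
                for a, b in zip(hit.aligned_query, hit.aligned_subject):
                    if a == "-" or b == "-":
                        gaps += 1
                    elif a != b:
                        mismatches += 1
            lines.append(
                "\t".join(
                    [
                        hs.query_id,
                        hit.subject_accession,
                        f"{hit.identity_pct:.2f}",
                        str(hit.alignment_length),
                        str(mismatches),
                        str(gaps),
                        str(hit.query_span[0]),
                        str(hit.query_span[1]),
                        str(hit.subject_span[0]),
                        str(hit.subject_span[1]),
                        "NA",
                        f"{hit.bit_score:.1f}",
                        hit.subject_taxon,
                    ]
                )
            )
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
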