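"""Synthetic amplicon reads with known taxonomy, divergence and error structure.

Real curated pmoA reference sets are thousands of sequences; for self-contained
testing this module builds a small mock reference database over the packaged
taxonomy and simulates the read classes an amplicon survey produces:

* clean reads of known taxa at low divergence (sequencing-error level),
* moderately divergent reads emulating new clades below a known taxon,
* deeply divergent reads with synonymous bias (protein conserved, nucleotide
  unrecognizable — the megablast-invisible, translated-search-visible class),
* groups carrying *planted shared substitutions* (ground truth for
  conserved-mismatch analysis),
* unrelated random contaminants, chimeric joins, and homopolymer indels.

The mock database is generated by evolving one coding-like ancestor down the
taxonomy with codon-aware substitutions (no in-frame stops), so different taxa
are mutually >=10% divergent — a caricature of the real database's >5%
inter-taxon separation — and one taxon (gp23) is a single, highly divergent
reference, reproducing the naive-Bayes attractor configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .preprocess import ReadRecord
from .taxonomy import (
    ReferenceDB,
    ReferenceRecord,
    TaxonomyTree,
    load_packaged_taxonomy,
)

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "TruthEntry",
    "GroundTruth",
    "mock_reference_db",
    "generate",
    "MOCK_DB_TAXA",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# populated leaves of the mock database: (taxon, n references); gp23 is the
# deliberately divergent singleton
MOCK_DB_TAXA: tuple[tuple[str, int], ...] = (
    ("Mbacter", 4),
    ("Mmonas", 4),
    ("Msarcina", 4),
    ("Mcoccus", 4),
    ("JRC_3", 4),
    ("RPC_1", 4),
    ("USCg", 4),
    ("Msinus", 4),
    ("Mcystis", 4),
    ("Msinus_Mcystis", 4),
    ("Mcapsa", 4),
    ("pmoA2", 4),
    ("USCa", 4),
    ("TUSC", 4),
    ("RA21", 4),
    ("gp23", 1),
    ("Crenothrix", 4),
    ("AOB_like", 4),
)


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        codon = "".join(_BASES[i] for i in rng.integers(0, 4, 3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def _mutate_coding(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply ``n_subs`` distinct-position substitutions, never creating stops."""
    bases = list(seq)
    positions = rng.permutation(len(bases))
    done = 0
    for pos in positions:
        if done == n_subs:
            break
        old = bases[pos]
        choices = [b for b in _BASES if b != old]
        rng.shuffle(choices)
        for new in choices:
            bases[pos] = new
            codon_start = (pos // 3) * 3
            if "".join(bases[codon_start : codon_start + 3]) not in _STOPS:
                done += 1
                break
            bases[pos] = old
    return "".join(bases)


def mock_reference_db(
    tree: Optional[TaxonomyTree] = None,
    seed: int = 20140218,
    seq_length: int = 525,
) -> ReferenceDB:
    """Build the deterministic mock reference database (~60 sequences).

    One ancestor sequence is evolved down the taxonomy: ~10% substitutions on
    the edge to each top-level group, ~7% to each subgroup, ~6% to each leaf,
    then ~1.5% per individual reference, giving sister taxa ~11% mutual
    divergence and distant taxa far more.  The gp23 reference diverges 25% from
    its subgroup ancestor.
    """
    tree = tree or load_packaged_taxonomy()
    rng = np.random.default_rng(seed)
    n = seq_length - seq_length % 3
    root_seq = _random_coding(rng, n // 3)

    ancestors: dict[str, str] = {tree.root.name: root_seq}

    def ancestor_for(name: str) -> str:
        node = tree.node(name)
        path = [p.name for p in node.path()]
        for depth, node_name in enumerate(path):
            if node_name in ancestors:
                continue
            parent_seq = ancestors[path[depth - 1]]
            # edge length by depth below the root
            frac = {1: 0.10, 2: 0.07}.get(depth, 0.06)
            ancestors[node_name] = _mutate_coding(
                parent_seq, round(frac * n), rng
            )
        return ancestors[path[-1]]

    records: list[ReferenceRecord] = []
    for taxon, count in MOCK_DB_TAXA:
        node = tree.node(taxon)
        parent_chain = [p.name for p in node.path()][:-1]
        for name in parent_chain:
            ancestor_for(name)
        if taxon == "gp23":
            leaf_anc = _mutate_coding(ancestors[parent_chain[-1]], round(0.25 * n), rng)
        else:
            leaf_anc = _mutate_coding(ancestors[parent_chain[-1]], round(0.06 * n), rng)
        ancestors[taxon] = leaf_anc
        for i in range(count):
            seq = _mutate_coding(leaf_anc, round(0.015 * n), rng)
            records.append(ReferenceRecord(f"{taxon}_ref{i + 1}", taxon, seq))
    return ReferenceDB(records, tree)


# ---------------------------------------------------------------------------
# read generation


Divergence = Union[float, tuple[float, float]]


@dataclass(frozen=True)
class GroupSpec:
    """One simulated read group.

    ``divergence_pct`` is a percent or an inclusive (low, high) percent range
    sampled uniformly per read.  ``substitution_model`` is ``"uniform"`` or
    ``"synonymous_biased"`` (mutations placed as synonymous third-position
    changes first, emulating clades whose protein is conserved while the
    nucleotide sequence has diverged beyond word-seeding range).
    ``planted_shared_substitutions`` plants that many identical substitutions in
    every read of the group (all reads then share one reference window), the
    ground truth for conserved-mismatch analysis.
    """

    source_taxon: str
    divergence_pct: Divergence = 0.0
    substitution_model: str = "uniform"
    planted_shared_substitutions: Optional[int] = None
    expected_tiers: Optional[tuple[str, ...]] = None

    def divergence_range(self) -> tuple[float, float]:
        if isinstance(self.divergence_pct, (int, float)):
            return (float(self.divergence_pct), float(self.divergence_pct))
        lo, hi = self.divergence_pct
        return (float(lo), float(hi))

    def default_expected_tiers(self) -> tuple[str, ...]:
        if self.planted_shared_substitutions is not None:
            return ("leaf_assigned",)
        lo, hi = self.divergence_range()
        if hi <= 5.0:
            return ("leaf_assigned",)
        if hi <= 15.0:
            return ("internal_node_candidate", "moderately_divergent")
        return ("divergent_CuMMO",)


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_reads_per_group: int = 10
    read_length: int = 400
    groups: tuple[GroupSpec, ...] = ()
    contaminant_fraction: float = 0.0
    chimera_fraction: float = 0.0
    homopolymer_indel_rate: float = 0.0

    def __post_init__(self) -> None:
        for frac in (
            self.contaminant_fraction,
            self.chimera_fraction,
            self.homopolymer_indel_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class TruthEntry:
    read_id: str
    label: str  # taxon name, "contaminant", or "chimera"
    expected_tiers: tuple[str, ...]
    source_accession: str = ""
    window_start: int = 0  # 0-based offset of the window in the reference
    planted_positions: tuple[int, ...] = ()  # 1-based reference coordinates


class GroundTruth:
    """Per-read ground-truth labels covering every generated read."""

    def __init__(self) -> None:
        self.entries: dict[str, TruthEntry] = {}

    def add(self, entry: TruthEntry) -> None:
        self.entries[entry.read_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, read_id: str) -> TruthEntry:
        return self.entries[read_id]

    def to_tsv(self, path=None) -> str:
        lines = ["read_id\tlabel\texpected_tiers\tsource\twindow_start\tplanted"]
        for e in self.entries.values():
            lines.append(
                f"{e.read_id}\t{e.label}\t{'|'.join(e.expected_tiers)}\t"
                f"{e.source_accession}\t{e.window_start}\t"
                + ",".join(map(str, e.planted_positions))
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


_SYN_TABLE: dict[str, list[str]] = {}


def _synonymous_third_position_variants(codon: str) -> list[str]:
    """Synonymous codons differing from ``codon`` only at the third position."""
    if not _SYN_TABLE:
        from Bio.Seq import Seq

        for b1 in _BASES:
            for b2 in _BASES:
                for b3 in _BASES:
                    c = b1 + b2 + b3
                    if c in _STOPS:
                        continue
                    aa = str(Seq(c).translate())
                    _SYN_TABLE[c] = [
                        c[:2] + alt
                        for alt in _BASES
                        if alt != b3
                        and c[:2] + alt not in _STOPS
                        and str(Seq(c[:2] + alt).translate()) == aa
                    ]
    return _SYN_TABLE[codon]


def _mutate_uniform(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    bases = list(seq)
    for pos in rng.choice(len(bases), size=min(n_subs, len(bases)), replace=False):
        bases[pos] = rng.choice([b for b in _BASES if b != bases[pos]])
    return "".join(bases)


def _mutate_synonymous_biased(
    seq: str, n_subs: int, rng: np.random.Generator
) -> str:
    """Spend the substitution budget on synonymous third-position changes first."""
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    budget = n_subs
    order = rng.permutation(len(codons))
    for idx in order:
        if budget == 0:
            break
        variants = _synonymous_third_position_variants(codons[idx])
        if variants:
            codons[idx] = variants[int(rng.integers(0, len(variants)))]
            budget -= 1
    out = "".join(codons) + seq[len(codons) * 3 :]
    if budget > 0:
        # leftover budget: conservative first/second-position changes
        out = _mutate_coding(out, budget, rng)
    return out


def _apply_homopolymer_indels(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    """Extend or contract each homopolymer run of >=3 with probability ``rate``."""
    out: list[str] = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if len(run) >= 3 and rng.random() < rate:
            run = run + run[0] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        i = j
    return "".join(out)


def _plant_positions(
    rng: np.random.Generator, length: int, count: int, min_sep: int = 5,
    edge: int = 5, min_clean_run: int = 32,
) -> list[int]:
    """Choose planted substitution columns (1-based within the window).

    Positions keep ``edge`` clear bases at the window ends and ``min_sep``
    between one another, so the optimal local alignment retains every planted
    column; one clean run of ``min_clean_run`` guarantees a seed word.  The
    columns are built by sampling the clean-gap composition directly: minimum
    gaps are reserved (one randomly chosen internal gap is widened to the seed
    corridor) and the remaining slack is spread multinomially over all gaps.
    """
    if count <= 0:
        return []
    base = [edge] + [min_sep - 1] * (count - 1) + [edge]
    corridor = int(rng.integers(1, count)) if count > 1 else 0
    base[corridor] = max(base[corridor], min_clean_run)
    slack = length - count - sum(base)
    if slack < 0:
        raise ValueError(
            f"cannot place {count} planted substitutions in a {length}-bp window"
        )
    extra = rng.multinomial(slack, np.full(count + 1, 1.0 / (count + 1)))
    positions = []
    pos = 0
    for i in range(count):
        pos += int(base[i] + extra[i]) + 1
        positions.append(pos)
    return positions


def generate(
    db: ReferenceDB, spec: SyntheticSpec
) -> tuple[list[ReadRecord], GroundTruth]:
    """Generate reads and their ground truth; byte-deterministic for a seed.

    Reads of a group are windows of ``read_length`` drawn from references of
    the source taxon at codon-aligned offsets (so the reference reading frame
    is preserved within the window).  Planted groups share a single window and
    reference.  Contaminant and chimera counts are fractions of the grouped
    read total, rounded.
    """
    rng = np.random.default_rng(spec.seed)
    reads: list[ReadRecord] = []
    truth = GroundTruth()
    by_taxon = db.by_taxon()

    for group in spec.groups:
        if group.source_taxon not in by_taxon:
            raise ValueError(
                f"source taxon {group.source_taxon!r} has no reference sequences"
            )
        recs = by_taxon[group.source_taxon]
        lo, hi = group.divergence_range()
        expected = group.expected_tiers or group.default_expected_tiers()
        planted = group.planted_shared_substitutions

        if min(len(r.sequence) for r in recs) < spec.read_length:
            raise ValueError(
                f"read_length {spec.read_length} exceeds a reference of "
                f"{group.source_taxon!r}"
            )

        shared_rec = recs[int(rng.integers(0, len(recs)))]
        max_start = (len(shared_rec.sequence) - spec.read_length) // 3
        shared_start = 3 * int(rng.integers(0, max_start + 1))
        planted_cols: list[int] = []
        planted_bases: dict[int, str] = {}
        if planted is not None:
            planted_cols = _plant_positions(rng, spec.read_length, planted)
            window = shared_rec.sequence[
                shared_start : shared_start + spec.read_length
            ]
            for col in planted_cols:
                old = window[col - 1]
                planted_bases[col] = str(
                    rng.choice([b for b in _BASES if b != old])
                )

        for i in range(spec.n_reads_per_group):
            if planted is not None:
                rec, start = shared_rec, shared_start
            else:
                rec = recs[int(rng.integers(0, len(recs)))]
                max_start = (len(rec.sequence) - spec.read_length) // 3
                start = 3 * int(rng.integers(0, max_start + 1))
            window = rec.sequence[start : start + spec.read_length]

            if planted is not None:
                bases = list(window)
                for col, base in planted_bases.items():
                    bases[col - 1] = base
                seq = "".join(bases)
            else:
                d = rng.uniform(lo, hi) / 100.0
                n_subs = round(d * spec.read_length)
                if group.substitution_model == "synonymous_biased":
                    seq = _mutate_synonymous_biased(window, n_subs, rng)
                elif group.substitution_model == "uniform":
                    seq = _mutate_uniform(window, n_subs, rng)
                else:
                    raise ValueError(
                        f"unknown substitution model "
                        f"{group.substitution_model!r}"
                    )
            if spec.homopolymer_indel_rate > 0:
                seq = _apply_homopolymer_indels(
                    seq, spec.homopolymer_indel_rate, rng
                )
            read_id = f"{group.source_taxon}_{i:03d}"
            reads.append(ReadRecord(read_id, seq, sample=group.source_taxon))
            truth.add(
                TruthEntry(
                    read_id=read_id,
                    label=group.source_taxon,
                    expected_tiers=expected,
                    source_accession=rec.accession,
                    window_start=start,
                    planted_positions=tuple(start + c for c in planted_cols),
                )
            )

    n_grouped = len(reads)
    n_contaminant = round(spec.contaminant_fraction * n_grouped)
    for i in range(n_contaminant):
        seq = "".join(
            _BASES[b] for b in rng.integers(0, 4, spec.read_length)
        )
        read_id = f"contam_{i:03d}"
        reads.append(ReadRecord(read_id, seq, sample="contaminant"))
        truth.add(TruthEntry(read_id, "contaminant", ("contaminant",)))

    n_chimera = round(spec.chimera_fraction * n_grouped)
    grouped = reads[:n_grouped]
    for i in range(n_chimera):
        if len({r.sample for r in grouped}) < 2:
            break
        while True:
            a, b = (
                grouped[int(rng.integers(0, n_grouped))],
                grouped[int(rng.integers(0, n_grouped))],
            )
            if a.sample != b.sample:
                break
        point = int(
            rng.integers(spec.read_length // 3, 2 * spec.read_length // 3)
        )
        read_id = f"chimera_{i:03d}"
        reads.append(
            ReadRecord(read_id, a.sequence[:point] + b.sequence[point:],
                       sample="chimera")
        )
        truth.add(TruthEntry(read_id, "chimera", ()))

    return reads, truth
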