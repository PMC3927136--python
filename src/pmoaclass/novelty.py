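"""Four-tier novelty detection layered on the search and LCA outputs.

The tiers run from most to least divergent:

1. **contaminant / divergent_CuMMO** — reads with no nucleotide hits at all
   (no shared 28-nt word with any reference) are re-queried with the translated
   search; genuine but deeply divergent CuMMO reads reach significant protein
   bit scores, unrelated contaminants do not.
2. **moderately_divergent** — reads whose best nucleotide bit score falls below
   a "new clade" threshold, even when the LCA still lands on a leaf.  The
   threshold depends on the scoring scheme and on how distinct the reference
   taxa are, so it is configuration, not a constant;
   :func:`pmoaclass.search.expected_bit_score` converts a divergence level into
   this engine's bit-score currency.
3. **internal_node_candidate** — reads whose LCA assignment lands on an
   internal node: near-equal best hits to several taxa suggest a lineage
   branching between or below them.
4. **leaf_assigned** — everything else; genus-level novelty inside such a group
   shows up as *conserved mismatches*: alignment columns where most reads of
   the group share the same non-reference base against the group's top
   reference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .lca import Assignment, LCAConfig, assign_lca
from .preprocess import ReadRecord
from .search import Hit, HitSet, SearchConfig, search_nucleotide, search_translated
from .taxonomy import ReferenceDB, ReferenceRecord, TaxonomyTree

__all__ = [
    "NoveltyConfig",
    "NoveltyReport",
    "ConservedMismatchProfile",
    "tier_reads",
    "conserved_mismatches",
    "profile_leaf_groups",
    "TIERS",
]

TIERS = (
    "contaminant",
    "divergent_CuMMO",
    "moderately_divergent",
    "internal_node_candidate",
    "leaf_assigned",
)


@dataclass(frozen=True)
class NoveltyConfig:
    """Thresholds for the novelty tiers.

    ``translated_rescue_min_bits`` separates divergent CuMMO from contaminants
    among no-hit reads.  ``divergent_flag_max_bits`` flags new-clade candidates
    by low nucleotide bit score; its useful value is tied to the scoring scheme
    and read length (see module docstring).  The conserved-mismatch settings
    define a column as conserved when at least ``conserved_mismatch_fraction``
    of the covering reads (and at least ``conserved_mismatch_min_coverage``
    reads) share one non-reference base.
    """

    translated_rescue_min_bits: float = 50.0
    divergent_flag_max_bits: float = 150.0
    conserved_mismatch_fraction: float = 0.8
    conserved_mismatch_min_coverage: int = 5

    def __post_init__(self) -> None:
        if self.translated_rescue_min_bits <= 0 or self.divergent_flag_max_bits <= 0:
            raise ValueError("bit-score thresholds must be positive")
        if not 0.5 < self.conserved_mismatch_fraction <= 1.0:
            raise ValueError("conserved_mismatch_fraction must be in (0.5, 1]")


@dataclass
class ConservedMismatchProfile:
    """Shared non-reference columns of one leaf group vs its top reference."""

    taxon: str
    reference_accession: str
    positions: list[int]  # 1-based reference coordinates
    coverage: dict[int, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass
class NoveltyReport:
    """Per-read tiers plus optional per-leaf-group mismatch profiles."""

    tiers: dict[str, str]
    order: list[str]
    best_nt_bits: dict[str, float]
    best_translated_bits: dict[str, float]
    assignments: dict[str, Assignment]
    hitsets: dict[str, HitSet] = field(default_factory=dict)
    group_profiles: dict[str, ConservedMismatchProfile] = field(default_factory=dict)

    def tier_counts(self) -> Counter:
        return Counter(self.tiers[rid] for rid in self.order)

    def reads_in_tier(self, tier: str) -> list[str]:
        return [rid for rid in self.order if self.tiers[rid] == tier]

    def write_tier_table(self, path=None) -> str:
        lines = ["read_id\ttier\tbest_nt_bits\tbest_translated_bits\tassigned_node"]
        for rid in self.order:
            a = self.assignments.get(rid)
            node = a.node.name if a is not None and a.node is not None else "-"
            nt = self.best_nt_bits.get(rid)
            tx = self.best_translated_bits.get(rid)
            lines.append(
                f"{rid}\t{self.tiers[rid]}\t"
                f"{'-' if nt is None else format(nt, '.1f')}\t"
                f"{'-' if tx is None else format(tx, '.1f')}\t{node}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def tier_reads(
    reads: Iterable[ReadRecord],
    nt_hits: Iterable[HitSet],
    db: ReferenceDB,
    tree: TaxonomyTree,
    ncfg: Optional[NoveltyConfig] = None,
    lcfg: Optional[LCAConfig] = None,
    scfg: Optional[SearchConfig] = None,
) -> NoveltyReport:
    """Assign every read exactly one novelty tier.

    Tier precedence is fixed: the no-hit test runs first, then the low-score
    flag (on best nucleotide bits, regardless of how deep the LCA would land),
    then the internal-node test; the remainder are leaf-assigned.  ``nt_hits``
    must hold the already-computed nucleotide HitSets; translated searches are
    run here only for the no-hit reads.
    """
    ncfg = ncfg or NoveltyConfig()
    lcfg = lcfg or LCAConfig()
    tcfg = SearchConfig.translated(min_report_bits=0.0)

    hit_by_read: dict[str, HitSet] = {hs.query_id: hs for hs in nt_hits}
    tiers: dict[str, str] = {}
    order: list[str] = []
    nt_bits: dict[str, float] = {}
    tx_bits: dict[str, float] = {}
    assignments: dict[str, Assignment] = {}

    for read in reads:
        order.append(read.read_id)
        hitset = hit_by_read.get(read.read_id, HitSet(read.read_id))
        if not hitset:
            translated = search_translated(read, db, tcfg)
            best_tx = translated.best.bit_score if translated else 0.0
            tx_bits[read.read_id] = best_tx
            tiers[read.read_id] = (
                "divergent_CuMMO"
                if best_tx >= ncfg.translated_rescue_min_bits
                else "contaminant"
            )
            continue
        best = hitset.best.bit_score
        nt_bits[read.read_id] = best
        if best < ncfg.divergent_flag_max_bits:
            tiers[read.read_id] = "moderately_divergent"
            continue
        assignment = assign_lca(hitset, tree, lcfg)
        assignments[read.read_id] = assignment
        if assignment.node is None:
            # hits exist but all fell below the LCA reporting floor
            tiers[read.read_id] = "moderately_divergent"
        elif assignment.is_internal:
            tiers[read.read_id] = "internal_node_candidate"
        else:
            tiers[read.read_id] = "leaf_assigned"

    return NoveltyReport(tiers, order, nt_bits, tx_bits, assignments, hit_by_read)


def conserved_mismatches(
    hits: Iterable[Hit], ncfg: Optional[NoveltyConfig] = None
) -> ConservedMismatchProfile:
    """Find reference columns where the group shares one non-reference base.

    All hits must align against the same reference sequence (the group's top
    reference); alignments are projected onto reference coordinates.  Read gap
    columns are excluded from the tally and reference-gap (insertion) columns
    are never counted, so homopolymer indel noise does not inflate counts.
    """
    ncfg = ncfg or NoveltyConfig()
    hits = list(hits)
    if not hits:
        raise ValueError("conserved_mismatches needs at least one hit")
    accessions = {h.subject_accession for h in hits}
    if len(accessions) > 1:
        raise ValueError(
            "hits align to mixed references "
            f"({', '.join(sorted(accessions))}); split the group by top reference"
        )
    taxa = {h.subject_taxon for h in hits}

    ref_base: dict[int, str] = {}
    base_counts: dict[int, Counter] = {}
    for hit in hits:
        if hit.aligned_query is None:
            raise ValueError("hits must carry alignment strings")
        pos = hit.subject_span[0] - 1
        for q, s in zip(hit.aligned_query, hit.aligned_subject):
            if s == "-":
                continue  # insertion in the read; not a reference column
            pos += 1
            ref_base[pos] = s
            if q == "-":
                continue  # read gap columns do not vote
            base_counts.setdefault(pos, Counter())[q] += 1

    positions = []
    coverage = {}
    for pos in sorted(base_counts):
        votes = base_counts[pos]
        cov = sum(votes.values())
        if cov < ncfg.conserved_mismatch_min_coverage:
            continue
        base, freq = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        if base != ref_base[pos] and freq >= ncfg.conserved_mismatch_fraction * cov:
            positions.append(pos)
            coverage[pos] = cov
    return ConservedMismatchProfile(
        taxon=taxa.pop() if len(taxa) == 1 else "",
        reference_accession=accessions.pop(),
        positions=positions,
        coverage=coverage,
    )


def profile_leaf_groups(
    report: NoveltyReport,
    reads: Iterable[ReadRecord],
    db: ReferenceDB,
    ncfg: Optional[NoveltyConfig] = None,
    scfg: Optional[SearchConfig] = None,
) -> dict[str, ConservedMismatchProfile]:
    """Conserved-mismatch profiles for every sufficiently large leaf group.

    For each leaf taxon with enough leaf-assigned reads, the group's top
    reference is the modal best-hit accession; every read is re-aligned against
    that single reference so all alignments project onto the same coordinates.
    Profiles are stored on ``report.group_profiles`` and returned.
    """
    ncfg = ncfg or NoveltyConfig()
    scfg = scfg or SearchConfig()
    read_by_id = {r.read_id: r for r in reads}

    groups: dict[str, list[str]] = {}
    for rid in report.reads_in_tier("leaf_assigned"):
        node = report.assignments[rid].node
        groups.setdefault(node.name, []).append(rid)

    profiles: dict[str, ConservedMismatchProfile] = {}
    for taxon, rids in groups.items():
        if len(rids) < ncfg.conserved_mismatch_min_coverage:
            continue
        # modal top reference among the group's best hits
        top_accs = Counter()
        for rid in rids:
            best = report.hitsets[rid].best
            if best is not None:
                top_accs[best.subject_accession] += 1
        if not top_accs:
            continue
        top_acc = max(top_accs.items(), key=lambda kv: (kv[1], kv[0]))[0]
        record = db.record(top_acc)
        mini_db = ReferenceDB(
            [ReferenceRecord(record.accession, record.taxon_name, record.sequence)],
            db.tree,
        )
        group_hits = []
        for rid in rids:
            hs = search_nucleotide(read_by_id[rid], mini_db, scfg)
            if hs.best is not None:
                group_hits.append(hs.best)
        if len(group_hits) >= ncfg.conserved_mismatch_min_coverage:
            profiles[taxon] = conserved_mismatches(group_hits, ncfg)
    report.group_profiles.update(profiles)
    return profiles
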