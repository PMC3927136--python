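"""Lowest-common-ancestor assignment from bit-scored hits.

A read is placed on the deepest taxonomy node consistent with its near-best
hits: every taxon whose best bit score is within a multiplicative margin
("top percent") of the read's best bit score is retained, and the read is
assigned to the lowest common ancestor of the retained taxa.  A single retained
taxon gives a leaf assignment; competing taxa push the read up the tree, which
is exactly the conservative behaviour that turns genuinely intermediate or
novel reads into internal-node assignments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .search import HitSet
from .taxonomy import TaxonNode, TaxonomyTree

__all__ = ["LCAConfig", "Assignment", "assign_lca", "summarize_assignments",
           "write_assignment_table"]


@dataclass(frozen=True)
class LCAConfig:
    """``top_percent`` retains hits with ``bits >= (1 - top_percent/100) * best``.

    ``min_bit_score`` is a reporting floor: hits below it never contribute to an
    assignment.  It defaults to 0 so that score-based novelty thresholds stay a
    separate concern.
    """

    top_percent: float = 5.0
    min_bit_score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.top_percent <= 100.0:
            raise ValueError("top_percent must be in [0, 100]")


@dataclass
class Assignment:
    """A read's resolved node (or none) with provenance.

    ``status`` distinguishes reads with no hits at all (``"no-hit"``) from reads
    whose hits all fell below ``min_bit_score`` (``"low-score"``); both leave
    ``node`` unset.  Assigned reads have status ``"assigned"``.
    """

    read_id: str
    node: Optional[TaxonNode]
    method: str = "lca"
    retained_taxa: tuple[str, ...] = ()
    best_bits: float = 0.0
    status: str = "assigned"

    @property
    def is_internal(self) -> bool:
        return self.node is not None and not self.node.is_leaf


def assign_lca(
    hits: HitSet, tree: TaxonomyTree, cfg: Optional[LCAConfig] = None
) -> Assignment:
    """Assign one read from its best-per-taxon hits.

    Deterministic: no randomness is involved.  Raising ``top_percent`` can only
    enlarge the retained set, so the assigned node moves (weakly) rootward.
    """
    cfg = cfg or LCAConfig()
    if not hits:
        return Assignment(hits.query_id, None, status="no-hit")
    for hit in hits:
        if hit.subject_taxon not in tree:
            raise ValueError(
                f"hit taxon {hit.subject_taxon!r} is missing from the taxonomy"
            )
    best = hits.best.bit_score
    threshold = (1.0 - cfg.top_percent / 100.0) * best
    retained = tuple(
        sorted(
            h.subject_taxon
            for h in hits
            if h.bit_score >= threshold and h.bit_score >= cfg.min_bit_score
        )
    )
    if not retained:
        return Assignment(
            hits.query_id, None, retained_taxa=(), best_bits=best, status="low-score"
        )
    node = (
        tree.node(retained[0]) if len(retained) == 1 else tree.lca(retained)
    )
    return Assignment(
        hits.query_id, node, retained_taxa=retained, best_bits=best
    )


def summarize_assignments(
    assignments: Iterable[Assignment], tree: TaxonomyTree
) -> tuple[Counter, int]:
    """Count reads assigned exactly at each node; internal nodes included.

    Returns ``(per-node counts, unassigned count)``; the two always conserve
    the number of input reads.
    """
    counts: Counter = Counter()
    unassigned = 0
    for a in assignments:
        if a.node is None:
            unassigned += 1
        else:
            counts[a.node.name] += 1
    return counts, unassigned


def write_assignment_table(assignments: Iterable[Assignment], path=None) -> str:
    lines = ["read_id\tnode\tdepth\tbest_bits\tstatus\tretained_taxa"]
    for a in assignments:
        name = a.node.name if a.node is not None else "-"
        depth = len(a.node.path()) - 1 if a.node is not None else -1
        lines.append(
            f"{a.read_id}\t{name}\t{depth}\t{a.best_bits:.1f}\t{a.status}\t"
            + ",".join(a.retained_taxa)
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
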