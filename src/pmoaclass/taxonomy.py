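"""Hierarchical CuMMO/pmoA taxonomy: tree structure, import, validation, export.

The taxonomy is a rooted, labelled hierarchy of copper-containing membrane-bound
monooxygenase (CuMMO) gene clades.  At the top level sequences split into
``MOB_like`` (methanotroph pmoA and relatives) and ``AOB_like`` (betaproteobacterial
ammonia monooxygenase, commonly co-amplified by broad pmoA primers).  Leaves are
genus-level clades, either named after a cultivated representative (``Mcystis``) or
after the environment in which they were first found (``USCa``).

A bundled transcription of the curated reference taxonomy (54 leaf clades, 6628
reference sequences) ships with the package and is loaded by
:func:`load_packaged_taxonomy`.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Optional

__all__ = [
    "TaxonNode",
    "TaxonomyTree",
    "ReferenceRecord",
    "ReferenceDB",
    "TaxonomyError",
    "load_taxonomy_table",
    "load_packaged_taxonomy",
    "validate_db_sizes",
    "write_tree_and_map",
    "parse_tree_and_map",
    "write_mothur_style_files",
    "parse_mothur_style_files",
]


class TaxonomyError(ValueError):
    """Raised for structural problems in a taxonomy table or tree."""


@dataclass
class TaxonNode:
    """One taxon in the hierarchy.

    ``level_code`` is the dotted integer path of the source table (e.g.
    ``"0.1.1.1.5"``); a child's code extends its parent's by one component.
    ``db_size`` is the number of curated reference sequences and is populated on
    leaf rows only.
    """

    level_code: str
    name: str
    parent: Optional["TaxonNode"] = None
    children: list["TaxonNode"] = field(default_factory=list)
    db_size: int = 0
    representative_accession: str = ""
    cultivated_representative: str = ""
    habitat_note: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def path(self) -> list["TaxonNode"]:
        """Root-to-self node list."""
        nodes = [self]
        while nodes[0].parent is not None:
            nodes.insert(0, nodes[0].parent)
        return nodes

    def iter_subtree(self) -> Iterator["TaxonNode"]:
        """Depth-first preorder traversal of the subtree rooted here."""
        yield self
        for child in self.children:
            yield from child.iter_subtree()

    def leaves(self) -> list["TaxonNode"]:
        return [n for n in self.iter_subtree() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonNode({self.level_code!r}, {self.name!r})"


class TaxonomyTree:
    """Rooted taxonomy with unique node names and a name -> node index."""

    def __init__(self, root: TaxonNode, stated_total: Optional[int] = None):
        self.root = root
        #: reference-sequence total stated by the source table for the whole
        #: database (if any); checked by :func:`validate_db_sizes`.
        self.stated_total = stated_total
        self.index: dict[str, TaxonNode] = {}
        for node in root.iter_subtree():
            if node.name in self.index:
                raise TaxonomyError(
                    f"duplicate taxon name {node.name!r} "
                    f"(level codes {self.index[node.name].level_code!r} and "
                    f"{node.level_code!r})"
                )
            self.index[node.name] = node

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def node(self, name: str) -> TaxonNode:
        try:
            return self.index[name]
        except KeyError:
            raise TaxonomyError(f"unknown taxon {name!r}") from None

    def leaves(self) -> list[TaxonNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def lineage(self, name: str) -> list[str]:
        """Root-to-node list of names."""
        return [n.name for n in self.node(name).path()]

    def lca(self, names: Iterable[str]) -> TaxonNode:
        """Lowest common ancestor of the named taxa."""
        paths = [self.node(n).path() for n in names]
        if not paths:
            raise TaxonomyError("lca of an empty taxon set")
        ancestor = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            nodes = {id(p[depth]) for p in paths}
            if len(nodes) > 1:
                break
            ancestor = paths[0][depth]
        return ancestor

    def is_ancestor_or_self(self, ancestor: str, descendant: str) -> bool:
        node = self.node(descendant)
        target = self.node(ancestor)
        while node is not None:
            if node is target:
                return True
            node = node.parent
        return False


@dataclass
class ReferenceRecord:
    """A taxon-labelled reference nucleotide sequence."""

    accession: str
    taxon_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise TaxonomyError(f"reference {self.accession!r} has empty sequence")


class ReferenceDB:
    """Taxon-labelled reference sequences tied to a :class:`TaxonomyTree`."""

    def __init__(self, records: list[ReferenceRecord], tree: TaxonomyTree):
        for rec in records:
            if rec.taxon_name not in tree:
                raise TaxonomyError(
                    f"reference {rec.accession!r} labelled with unknown taxon "
                    f"{rec.taxon_name!r}"
                )
        self.records = list(records)
        self.tree = tree

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def by_taxon(self) -> dict[str, list[ReferenceRecord]]:
        out: dict[str, list[ReferenceRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.taxon_name, []).append(rec)
        return out

    def record(self, accession: str) -> ReferenceRecord:
        for rec in self.records:
            if rec.accession == accession:
                return rec
        raise KeyError(accession)


# ---------------------------------------------------------------------------
# import


def _parse_code(code: str) -> tuple[int, ...]:
    if not re.fullmatch(r"\d+(\.\d+)*", code):
        raise TaxonomyError(f"malformed level code {code!r}")
    return tuple(int(part) for part in code.split("."))


def load_taxonomy_table(source) -> TaxonomyTree:
    """Build a validated :class:`TaxonomyTree` from a delimited taxonomy table.

    ``source`` is a path, file-like object, or string of tab-separated text with
    columns ``level_code`` and ``name`` (leaf rows may also carry ``db_size``,
    ``accession``/``cultivated_representative``/``habitat``).  Rows may appear in
    any order; every non-root row must have a parent row whose code is its dotted
    prefix.  A ``db_size`` on the root row is interpreted as the stated total of
    the whole database, not a leaf count.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        except (OSError, ValueError):
            # a raw table passed as a string
            text = str(source)

    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    rows = [row for row in reader if row.get("level_code")]
    if not rows:
        raise TaxonomyError("empty taxonomy table")

    nodes: dict[tuple[int, ...], TaxonNode] = {}
    names_seen: dict[str, str] = {}
    for row in rows:
        code = row["level_code"].strip()
        key = _parse_code(code)
        name = (row.get("name") or "").strip()
        if not name:
            raise TaxonomyError(f"row {code!r} has no name")
        if name in names_seen:
            raise TaxonomyError(
                f"duplicate taxon name {name!r} "
                f"(level codes {names_seen[name]!r} and {code!r})"
            )
        if key in nodes:
            raise TaxonomyError(f"duplicate level code {code!r}")
        names_seen[name] = code
        size_text = (row.get("db_size") or "").strip()
        db_size = int(size_text) if size_text else 0
        if db_size < 0:
            raise TaxonomyError(f"negative db_size on {name!r}")
        nodes[key] = TaxonNode(
            level_code=code,
            name=name,
            db_size=db_size,
            representative_accession=(row.get("accession") or "").strip(),
            cultivated_representative=(
                row.get("cultivated_representative") or ""
            ).strip(),
            habitat_note=(row.get("habitat") or "").strip(),
        )

    roots = [key for key in nodes if len(key) == 1]
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one root row, found {len(roots)}")

    for key in sorted(nodes):
        if len(key) == 1:
            continue
        parent = nodes.get(key[:-1])
        if parent is None:
            raise TaxonomyError(
                f"orphan level code {nodes[key].level_code!r}: "
                f"no parent row {'.'.join(map(str, key[:-1]))!r}"
            )
        nodes[key].parent = parent
        parent.children.append(nodes[key])

    root = nodes[roots[0]]
    stated_total = root.db_size or None
    root.db_size = 0  # db_size is a leaf property; the root figure is the total
    tree = TaxonomyTree(root, stated_total=stated_total)
    for node in tree.root.iter_subtree():
        if not node.is_leaf and node.db_size:
            raise TaxonomyError(
                f"internal node {node.name!r} carries a db_size; "
                "sizes belong to leaf rows"
            )
    return tree


def load_packaged_taxonomy() -> TaxonomyTree:
    """Load the bundled 54-leaf pmoA taxonomy (6628 reference sequences)."""
    ref = resources.files("pmoaclass.data") / "pmoa_taxonomy.tsv"
    return load_taxonomy_table(io.StringIO(ref.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# validation


def validate_db_sizes(tree: TaxonomyTree) -> int:
    """Sum leaf ``db_size`` values, checking them against the stated total.

    Returns the leaf total.  If the table stated a whole-database total and it
    disagrees with the leaf sum, a :class:`TaxonomyError` naming the per-subtree
    discrepancy is raised.
    """
    for leaf in tree.leaves():
        if leaf.db_size < 0:
            raise TaxonomyError(f"negative db_size on leaf {leaf.name!r}")
    total = sum(leaf.db_size for leaf in tree.leaves())
    if tree.stated_total is not None and total != tree.stated_total:
        diff = total - tree.stated_total
        raise TaxonomyError(
            f"leaf db_size total {total} differs from stated total "
            f"{tree.stated_total} by {diff:+d}; "
            f"leaf sizes: "
            + ", ".join(f"{l.name}={l.db_size}" for l in tree.leaves())
        )
    return total


# ---------------------------------------------------------------------------
# export: Newick + map (the MEGAN "alternative taxonomy" dialect)


def _preorder_ids(tree: TaxonomyTree) -> dict[int, TaxonNode]:
    return dict(enumerate(tree.root.iter_subtree()))


def write_tree_and_map(tree: TaxonomyTree) -> tuple[str, str]:
    """Emit a Newick tree of numeric node identifiers and an id->name map.

    Identifiers are assigned by depth-first preorder starting at 0, so output is
    deterministic and diffable.  The pair round-trips through
    :func:`parse_tree_and_map`.
    """
    ids = _preorder_ids(tree)
    node_id = {id(node): i for i, node in ids.items()}

    def render(node: TaxonNode) -> str:
        if node.is_leaf:
            return str(node_id[id(node)])
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){node_id[id(node)]}"

    newick = render(tree.root) + ";"
    map_lines = "".join(f"{i}\t{node.name}\n" for i, node in ids.items())
    return newick, map_lines


def parse_tree_and_map(newick: str, map_text: str) -> TaxonomyTree:
    """Reconstruct a tree from :func:`write_tree_and_map` output."""
    id_to_name: dict[str, str] = {}
    for line in map_text.splitlines():
        if not line.strip():
            continue
        ident, name = line.split("\t")
        id_to_name[ident.strip()] = name.strip()

    text = newick.strip()
    if not text.endswith(";"):
        raise TaxonomyError("newick string must end with ';'")
    text = text[:-1]

    pos = 0

    def parse_node(code_prefix: tuple[int, ...]) -> TaxonNode:
        nonlocal pos
        children: list[TaxonNode] = []
        if pos < len(text) and text[pos] == "(":
            pos += 1
            child_index = 1
            while True:
                children.append(parse_node(code_prefix + (child_index,)))
                child_index += 1
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ",();":
            pos += 1
        label = text[start:pos]
        if not label:
            raise TaxonomyError(f"unlabelled node at offset {start}")
        node = TaxonNode(
            level_code=".".join(map(str, code_prefix)),
            name=id_to_name.get(label, label),
        )
        for child in children:
            child.parent = node
        node.children = children
        return node

    root = parse_node((0,))
    if pos != len(text):
        raise TaxonomyError(f"trailing characters in newick at offset {pos}")
    return TaxonomyTree(root)


# ---------------------------------------------------------------------------
# export: reference FASTA + mothur-style taxonomy file


def write_mothur_style_files(db: ReferenceDB) -> tuple[str, str]:
    """Emit reference FASTA and a two-column sequence-taxonomy file.

    The taxonomy file maps each sequence id to the semicolon-joined
    root-to-leaf path of its taxon (trailing semicolon included), the dialect
    consumed by mothur-style naive Bayesian classifiers.  Records must be
    labelled with leaf taxa.
    """
    fasta_parts: list[str] = []
    tax_parts: list[str] = []
    for rec in db.records:
        node = db.tree.node(rec.taxon_name)
        if not node.is_leaf:
            raise TaxonomyError(
                f"reference {rec.accession!r} is labelled with internal node "
                f"{rec.taxon_name!r}; references must carry leaf taxa"
            )
        fasta_parts.append(f">{rec.accession} [{rec.taxon_name}]\n{rec.sequence}\n")
        path = ";".join(db.tree.lineage(rec.taxon_name)) + ";"
        tax_parts.append(f"{rec.accession}\t{path}\n")
    return "".join(fasta_parts), "".join(tax_parts)


def parse_mothur_style_files(
    fasta_text: str, tax_text: str, tree: TaxonomyTree
) -> ReferenceDB:
    """Inverse of :func:`write_mothur_style_files`."""
    from .seqio import parse_fasta

    taxon_of: dict[str, str] = {}
    for line in tax_text.splitlines():
        if not line.strip():
            continue
        acc, path = line.split("\t")
        parts = [p for p in path.strip().split(";") if p]
        taxon_of[acc.strip()] = parts[-1]

    records = []
    for name, seq in parse_fasta(fasta_text):
        acc = name.split()[0]
        records.append(ReferenceRecord(acc, taxon_of[acc], seq))
    return ReferenceDB(records, tree)
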