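"""Naive Bayesian k-mer classifier with bootstrap confidence.

The classifier follows the word-presence model of the RDP-style "wang" method,
trained here on the leaf taxa of the pmoA reference database.  Each training
sequence contributes the *set* of k-mers it contains (multiplicity is ignored).
With N training sequences of which n(w) contain word w, the word prior is

    P(w) = (n(w) + 0.5) / (N + 1)

and for a leaf taxon G with M sequences of which m(w) contain w,

    P(w | G) = (m(w) + P(w)) / (M + 1).

A read with word set V is assigned to the leaf maximizing sum(log P(w|G)) over
w in V.  Confidence comes from bootstrap resampling: each iteration draws
ceil(|V| * subsample_fraction) words with replacement and records the winning
leaf; a node's confidence is the percentage of iterations won by any of its
descendant leaves, so confidences are non-increasing from root to leaf and the
read is reported at the deepest node reaching the cutoff ("unclassified
TypeIb"-style roll-up when the leaf itself is uncertain).

The small-pseudocount structure of P(w|G) gives sparsely represented taxa a
weaker penalty for absent words (division by M+1).  A taxon represented by a
single divergent reference therefore acts as an attractor for non-target
reads — the known failure mode this package's novelty tiers exist to catch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .preprocess import ReadRecord
from .seqio import reverse_complement
from .taxonomy import ReferenceDB

__all__ = ["NBCConfig", "NBCModel", "NBCResult", "train", "classify",
           "classify_many", "write_classification_table"]

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class NBCConfig:
    kmer_size: int = 8
    bootstrap_iterations: int = 100
    subsample_fraction: float = 0.125
    confidence_cutoff: float = 80.0

    def __post_init__(self) -> None:
        if self.kmer_size < 1:
            raise ValueError("kmer_size must be >= 1")
        if not 0.0 <= self.confidence_cutoff <= 100.0:
            raise ValueError("confidence_cutoff must be in [0, 100]")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")


def _kmer_set(seq: str, k: int) -> set[str]:
    """Distinct k-mers, skipping any window containing a non-ACGT character."""
    out = set()
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if set(word) <= _VALID:
            out.add(word)
    return out


class NBCModel:
    """Trained word-probability tables over the leaf taxa.

    ``taxa`` is lexicographically sorted; argmax ties therefore resolve to the
    lexicographically smallest taxon, keeping classification deterministic.
    """

    version = 1

    def __init__(
        self,
        kmer_size: int,
        taxa: list[str],
        lineages: dict[str, list[str]],
        kmer_index: dict[str, int],
        log_cond: np.ndarray,
        unseen_log_cond: np.ndarray,
        training_counts: dict[str, int],
    ):
        self.kmer_size = kmer_size
        self.taxa = taxa
        self.lineages = lineages  # leaf name -> root..leaf name path
        self.kmer_index = kmer_index
        self.log_cond = log_cond  # (n_kmers, n_taxa) log P(w|G)
        self.unseen_log_cond = unseen_log_cond  # (n_taxa,) for unseen words
        self.training_counts = training_counts

    # -- serialization (versioned flat file) --------------------------------
    def save(self, path: str) -> None:
        meta = {
            "version": self.version,
            "kmer_size": self.kmer_size,
            "taxa": self.taxa,
            "lineages": self.lineages,
            "training_counts": self.training_counts,
            "kmers": sorted(self.kmer_index, key=self.kmer_index.get),
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            log_cond=self.log_cond,
            unseen_log_cond=self.unseen_log_cond,
        )

    @classmethod
    def load(cls, path: str) -> "NBCModel":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["version"] != cls.version:
            raise ValueError(f"unsupported model version {meta['version']}")
        return cls(
            kmer_size=meta["kmer_size"],
            taxa=meta["taxa"],
            lineages=meta["lineages"],
            kmer_index={w: i for i, w in enumerate(meta["kmers"])},
            log_cond=data["log_cond"],
            unseen_log_cond=data["unseen_log_cond"],
            training_counts={k: int(v) for k, v in meta["training_counts"].items()},
        )


@dataclass
class NBCResult:
    """Classification of one read: per-rank confidences and the reported node."""

    read_id: str
    path: list[tuple[str, float]]  # (node name, bootstrap confidence %)
    reported_taxon: str
    winner_leaf: str = ""

    @property
    def display_name(self) -> str:
        if not self.path:
            return self.reported_taxon
        deepest_leaf = self.path[-1][0]
        if self.reported_taxon == deepest_leaf:
            return self.reported_taxon
        return f"unclassified {self.reported_taxon}"


def train(db: ReferenceDB, cfg: Optional[NBCConfig] = None) -> NBCModel:
    """Estimate the word-probability tables from a taxon-labelled database.

    Every populated leaf taxon becomes a class; leaves without training
    sequences are simply absent from the model.  Only the forward strand of
    references is indexed; orientation is handled at classification time.
    """
    cfg = cfg or NBCConfig()
    by_taxon = db.by_taxon()
    leaf_names = set(db.tree.leaf_names())
    for taxon in by_taxon:
        if taxon not in leaf_names:
            raise ValueError(f"training label {taxon!r} is not a leaf taxon")
    taxa = sorted(t for t, recs in by_taxon.items() if recs)

    seq_kmers: dict[str, list[set[str]]] = {
        t: [_kmer_set(r.sequence.upper(), cfg.kmer_size) for r in by_taxon[t]]
        for t in taxa
    }
    n_total = sum(len(v) for v in seq_kmers.values())

    all_kmers = sorted(set().union(*(s for v in seq_kmers.values() for s in v)))
    kmer_index = {w: i for i, w in enumerate(all_kmers)}

    n_w = np.zeros(len(all_kmers), np.float64)
    for sets in seq_kmers.values():
        for s in sets:
            for w in s:
                n_w[kmer_index[w]] += 1.0
    prior = (n_w + 0.5) / (n_total + 1.0)
    unseen_prior = 0.5 / (n_total + 1.0)

    log_cond = np.empty((len(all_kmers), len(taxa)), np.float64)
    unseen = np.empty(len(taxa), np.float64)
    for g, taxon in enumerate(taxa):
        sets = seq_kmers[taxon]
        m_big = len(sets)
        m_w = np.zeros(len(all_kmers), np.float64)
        for s in sets:
            for w in s:
                m_w[kmer_index[w]] += 1.0
        log_cond[:, g] = np.log((m_w + prior) / (m_big + 1.0))
        unseen[g] = math.log(unseen_prior / (m_big + 1.0))

    lineages = {t: db.tree.lineage(t) for t in taxa}
    return NBCModel(
        kmer_size=cfg.kmer_size,
        taxa=taxa,
        lineages=lineages,
        kmer_index=kmer_index,
        log_cond=log_cond,
        unseen_log_cond=unseen,
        training_counts={t: len(by_taxon[t]) for t in taxa},
    )


def _contribution_matrix(model: NBCModel, kmers: set[str]) -> np.ndarray:
    rows = [model.kmer_index[w] for w in kmers if w in model.kmer_index]
    n_unknown = len(kmers) - len(rows)
    parts = []
    if rows:
        parts.append(model.log_cond[np.array(rows, np.intp)])
    if n_unknown:
        parts.append(np.tile(model.unseen_log_cond, (n_unknown, 1)))
    return np.vstack(parts)


def classify(
    read: ReadRecord,
    model: NBCModel,
    cfg: Optional[NBCConfig] = None,
    seed: int = 0,
) -> NBCResult:
    """Classify one read, scoring both orientations and keeping the better.

    Deterministic for a fixed ``seed``.  Reads shorter than the k-mer size (or
    containing no valid k-mer) are returned as ``unclassified``.
    """
    cfg = cfg or NBCConfig()
    if cfg.kmer_size != model.kmer_size:
        raise ValueError("config kmer_size does not match the trained model")
    seq = read.sequence.upper()
    best_contrib = None
    best_score = -math.inf
    for oriented in (seq, reverse_complement(seq)):
        kmers = _kmer_set(oriented, model.kmer_size)
        if not kmers:
            continue
        contrib = _contribution_matrix(model, kmers)
        score = float(contrib.sum(axis=0).max())
        if score > best_score:
            best_score = score
            best_contrib = contrib
    if best_contrib is None:
        return NBCResult(read.read_id, [], "unclassified")

    totals = best_contrib.sum(axis=0)
    winner = model.taxa[int(np.argmax(totals))]

    rng = np.random.default_rng(seed)
    n_kmers = best_contrib.shape[0]
    draw_size = max(1, math.ceil(n_kmers * cfg.subsample_fraction))
    idx = rng.integers(0, n_kmers, size=(cfg.bootstrap_iterations, draw_size))
    draw_scores = best_contrib[idx].sum(axis=1)  # (iters, taxa)
    draw_winners = np.argmax(draw_scores, axis=1)

    leaf_pct = np.zeros(len(model.taxa))
    for g in range(len(model.taxa)):
        leaf_pct[g] = 100.0 * np.count_nonzero(draw_winners == g)
    leaf_pct /= cfg.bootstrap_iterations

    # confidence of each node on the winner's lineage = summed confidence of
    # the node's descendant leaves among the modelled taxa
    lineage = model.lineages[winner]
    path: list[tuple[str, float]] = []
    for depth, node_name in enumerate(lineage):
        conf = 0.0
        for g, taxon in enumerate(model.taxa):
            lin = model.lineages[taxon]
            if len(lin) > depth and lin[depth] == node_name:
                conf += leaf_pct[g]
        path.append((node_name, conf))

    reported = "unclassified"
    for node_name, conf in path:
        if conf >= cfg.confidence_cutoff:
            reported = node_name
        else:
            break
    return NBCResult(read.read_id, path, reported, winner_leaf=winner)


def classify_many(
    reads: Iterable[ReadRecord],
    model: NBCModel,
    cfg: Optional[NBCConfig] = None,
    seed: int = 0,
) -> list[NBCResult]:
    """Classify reads with per-read seeds derived deterministically from ``seed``."""
    cfg = cfg or NBCConfig()
    root = np.random.SeedSequence(seed)
    reads = list(reads)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(reads))]
    return [classify(r, model, cfg, s) for r, s in zip(reads, child_seeds)]


def write_classification_table(results: Iterable[NBCResult], path=None) -> str:
    """Tabular output: read id, rank path with confidences, reported taxon."""
    lines = []
    for res in results:
        rank_text = ";".join(f"{name}({conf:.0f})" for name, conf in res.path)
        lines.append(f"{res.read_id}\t{rank_text}\t{res.display_name}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
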