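"""Cross-sample summaries: count tables, rarefaction subsampling, distances.

Counts are reads assigned exactly at each taxonomy node per sample.  Because
libraries differ in depth, comparisons are usually made after subsampling every
sample to a common depth (drawing without replacement).  Five ecological
distance measures are provided; note Bray–Curtis and Kulczynski are
semi-metrics (the triangle inequality is not guaranteed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .lca import Assignment
from .taxonomy import TaxonomyTree

__all__ = ["CountTable", "DistanceMatrix", "build_count_table", "subsample",
           "distance", "MEASURES"]


@dataclass
class CountTable:
    """Samples x nodes matrix of assigned-read counts."""

    frame: pd.DataFrame  # index = samples, columns = node names, int counts

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def nodes(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.frame.to_numpy()

    def row_sums(self) -> pd.Series:
        return self.frame.sum(axis=1)

    def to_tsv(self, path=None) -> str:
        text = self.frame.to_csv(sep="\t")
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, source) -> "CountTable":
        frame = pd.read_csv(source, sep="\t", index_col=0)
        return cls(frame.astype(int))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances under one measure."""

    labels: list[str]
    matrix: np.ndarray
    measure: str

    def to_tsv(self, path=None) -> str:
        frame = pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)
        text = frame.to_csv(sep="\t")
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def build_count_table(
    assignments_by_sample: Mapping[str, Iterable[Assignment]],
    tree: TaxonomyTree,
    include_internal: bool = True,
) -> CountTable:
    """Tabulate per-sample assignment counts at each node.

    Only nodes with at least one read in at least one sample become columns.
    ``include_internal=False`` drops internal-node assignments (reducing row
    sums accordingly), mirroring comparison views that show leaf taxa only.
    """
    samples = list(assignments_by_sample)
    if len(samples) != len(set(samples)):
        raise ValueError("duplicate sample labels")
    counts: dict[str, dict[str, int]] = {}
    for sample, assignments in assignments_by_sample.items():
        row: dict[str, int] = {}
        for a in assignments:
            if a.node is None:
                continue
            if not include_internal and not a.node.is_leaf:
                continue
            row[a.node.name] = row.get(a.node.name, 0) + 1
        counts[sample] = row

    # column order follows the taxonomy's preorder traversal
    order = [n.name for n in tree.root.iter_subtree()]
    seen = set().union(*(row.keys() for row in counts.values())) if counts else set()
    columns = [name for name in order if name in seen]
    columns += sorted(seen - set(columns))  # nodes outside the tree order
    frame = pd.DataFrame(
        [[counts[s].get(c, 0) for c in columns] for s in samples],
        index=samples,
        columns=columns,
        dtype=int,
    )
    return CountTable(frame)


def subsample(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Each row is replaced by a multivariate hypergeometric draw from its count
    multiset, so row sums all equal ``depth``.  Deterministic for fixed seed.
    """
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    for sample, total in table.row_sums().items():
        if depth > total:
            raise ValueError(
                f"depth {depth} exceeds the {total} assigned reads of "
                f"sample {sample!r}"
            )
    rng = np.random.default_rng(seed)
    rows = [
        rng.multivariate_hypergeometric(row, depth)
        for row in table.counts.astype(np.int64)
    ]
    frame = pd.DataFrame(
        np.array(rows, dtype=int), index=table.samples, columns=table.nodes
    )
    return CountTable(frame)


# ---------------------------------------------------------------------------
# distance measures


def _euclidean(x: np.ndarray, y: np.ndarray, col_mass: np.ndarray) -> float:
    return float(np.sqrt(((x - y) ** 2).sum()))


def _bray_curtis(x: np.ndarray, y: np.ndarray, col_mass: np.ndarray) -> float:
    denom = (x + y).sum()
    if denom == 0:
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def _hellinger(x: np.ndarray, y: np.ndarray, col_mass: np.ndarray) -> float:
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("hellinger distance needs nonzero sample totals")
    px = np.sqrt(x / x.sum())
    py = np.sqrt(y / y.sum())
    return float(np.sqrt(((px - py) ** 2).sum()))

def _chi_square(x: np.ndarray, y: np.ndarray, col_mass: np.ndarray) -> float:
    """Weighted Euclidean on profiles with inverse column-mass weights."""
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("chi-square distance needs nonzero sample totals")
    px = x / x.sum()
    py = y / y.sum()
    keep = col_mass > 0
    return float(
        np.sqrt((((px - py) ** 2)[keep] / col_mass[keep]).sum())
    )


def _kulczynski(x: np.ndarray, y: np.ndarray, col_mass: np.ndarray) -> float:
    """Distance form: 1 - mean of the two min-overlap ratios."""
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("kulczynski distance needs nonzero sample totals")
    overlap = np.minimum(x, y).sum()
    return float(1.0 - 0.5 * (overlap / x.sum() + overlap / y.sum()))


MEASURES = {
    "euclidean": _euclidean,
    "bray_curtis": _bray_curtis,
    "hellinger": _hellinger,
    "chi_square": _chi_square,
    "kulczynski": _kulczynski,
}


def distance(table: CountTable, measure: str) -> DistanceMatrix:
    """Pairwise sample distances under ``measure``.

    ``chi_square`` weights squared profile differences by the inverse relative
    column mass (column total / grand total) computed over the whole table.
    All measures return symmetric matrices with zero diagonals; Bray-Curtis and
    Kulczynski lie in [0, 1], Hellinger in [0, sqrt(2)].
    """
    try:
        func = MEASURES[measure]
    except KeyError:
        raise ValueError(
            f"unknown measure {measure!r}; choose from {sorted(MEASURES)}"
        ) from None
    counts = table.counts.astype(np.float64)
    grand = counts.sum()
    col_mass = counts.sum(axis=0) / grand if grand > 0 else counts.sum(axis=0)
    n = len(table.samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = func(counts[i], counts[j], col_mass)
    return DistanceMatrix(table.samples, out, measure)
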