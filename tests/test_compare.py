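"""Count tables, rarefaction, and ecological distance measures.

Distances are validated against independent plain-loop implementations of the
textbook formulas, plus scipy where it provides the same measure.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import distance as sp_distance

from pmoaclass.compare import (
    CountTable,
    MEASURES,
    build_count_table,
    distance,
    subsample,
)
from pmoaclass.lca import LCAConfig, assign_lca
from pmoaclass.search import Hit, HitSet


def _table(rows, samples=None, nodes=None):
    rows = np.asarray(rows, dtype=int)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    nodes = nodes or [f"t{j}" for j in range(rows.shape[1])]
    return CountTable(pd.DataFrame(rows, index=samples, columns=nodes))


# -- independent textbook-formula oracles (plain loops) ----------------------

def oracle_euclidean(x, y, counts):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def oracle_bray_curtis(x, y, counts):
    return sum(abs(a - b) for a, b in zip(x, y)) / sum(a + b for a, b in zip(x, y))


def oracle_hellinger(x, y, counts):
    sx, sy = sum(x), sum(y)
    return math.sqrt(
        sum((math.sqrt(a / sx) - math.sqrt(b / sy)) ** 2 for a, b in zip(x, y))
    )


def oracle_chi_square(x, y, counts):
    grand = counts.sum()
    sx, sy = sum(x), sum(y)
    total = 0.0
    for j in range(len(x)):
        col = counts[:, j].sum()
        if col == 0:
            continue
        total += (x[j] / sx - y[j] / sy) ** 2 / (col / grand)
    return math.sqrt(total)


def oracle_kulczynski(x, y, counts):
    overlap = sum(min(a, b) for a, b in zip(x, y))
    return 1.0 - 0.5 * (overlap / sum(x) + overlap / sum(y))


ORACLES = {
    "euclidean": oracle_euclidean,
    "bray_curtis": oracle_bray_curtis,
    "hellinger": oracle_hellinger,
    "chi_square": oracle_chi_square,
    "kulczynski": oracle_kulczynski,
}


class TestDistances:
    @pytest.mark.parametrize("measure", sorted(MEASURES))
    def test_identical_rows_are_zero(self, measure):
        table = _table([[3, 1, 4], [3, 1, 4]])
        assert distance(table, measure).matrix[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_bray_curtis_disjoint_profiles(self):
        assert distance(_table([[1, 0], [0, 1]]), "bray_curtis").matrix[0, 1] == 1.0

    @pytest.mark.parametrize("measure", sorted(MEASURES))
    def test_agrees_with_textbook_oracle(self, measure):
        rng = np.random.default_rng(42)
        for trial in range(5):
            counts = rng.integers(1, 50, size=(5, 8))
            table = _table(counts)
            got = distance(table, measure).matrix
            for i in range(5):
                for j in range(5):
                    expected = (
                        0.0 if i == j
                        else ORACLES[measure](counts[i], counts[j], counts)
                    )
                    assert got[i, j] == pytest.approx(expected, abs=1e-12)

    def test_scipy_cross_checks(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 50, size=(3, 6))
        table = _table(counts)
        bc = distance(table, "bray_curtis").matrix
        eu = distance(table, "euclidean").matrix
        for i in range(3):
            for j in range(3):
                assert bc[i, j] == pytest.approx(
                    sp_distance.braycurtis(counts[i], counts[j]) if i != j else 0.0,
                    abs=1e-12,
                )
                assert eu[i, j] == pytest.approx(
                    sp_distance.euclidean(counts[i], counts[j]), abs=1e-12
                )

    @pytest.mark.parametrize("measure", sorted(MEASURES))
    def test_symmetry_zero_diagonal_and_ranges(self, measure):
        rng = np.random.default_rng(4)
        table = _table(rng.integers(0, 30, size=(4, 7)) + (measure != "euclidean"))
        mat = distance(table, measure).matrix
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 0.0)
        if measure in ("bray_curtis", "kulczynski"):
            assert mat.max() <= 1.0 + 1e-12
        if measure == "hellinger":
            assert mat.max() <= math.sqrt(2) + 1e-12

    def test_unknown_measure(self):
        with pytest.raises(ValueError, match="unknown measure"):
            distance(_table([[1], [2]]), "goodall")


class TestSubsample:
    def test_row_sums_equal_depth(self):
        table = _table([[50, 30, 20], [10, 10, 80]])
        out = subsample(table, 40, seed=1)
        assert (out.row_sums() == 40).all()

    def test_depth_equal_to_row_sum_is_identity(self):
        table = _table([[5, 3, 2], [4, 4, 2]])
        out = subsample(table, 10, seed=0)
        np.testing.assert_array_equal(out.counts, table.counts)

    def test_depth_zero(self):
        out = subsample(_table([[5, 3], [2, 6]]), 0, seed=0)
        assert out.counts.sum() == 0

    def test_excess_depth_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            subsample(_table([[50, 50], [10, 10]]), 40, seed=0)

    def test_determinism(self):
        table = _table([[50, 30, 20]])
        a = subsample(table, 25, seed=7).counts
        b = subsample(table, 25, seed=7).counts
        np.testing.assert_array_equal(a, b)

    def test_hypergeometric_expectation(self):
        # E[count_t] = depth * count_t / total; check the empirical mean
        table = _table([[50, 30, 20]])
        depth, total = 40, 100
        draws = np.array(
            [subsample(table, depth, seed=s).counts[0] for s in range(1000)]
        )
        for j, count in enumerate([50, 30, 20]):
            p = count / total
            expected = depth * p
            var = depth * p * (1 - p) * (total - depth) / (total - 1)
            se = math.sqrt(var / 1000)
            assert abs(draws[:, j].mean() - expected) < 3 * se + 1e-9


class TestCountTable:
    @staticmethod
    def _assign(tree, rid, taxon_bits):
        hs = HitSet(rid)
        for taxon, bits in taxon_bits.items():
            hs.add(Hit(rid, f"{taxon}_r", taxon, 0, bits, 99.0, (1, 9), (1, 9)))
        return assign_lca(hs, tree, LCAConfig())

    def test_disjoint_taxa_block_table(self, tree):
        table = build_count_table(
            {
                "s1": [self._assign(tree, "a", {"Mcystis": 700.0})],
                "s2": [self._assign(tree, "b", {"USCa": 700.0})],
            },
            tree,
        )
        assert table.frame.loc["s1", "Mcystis"] == 1
        assert table.frame.loc["s1", "USCa"] == 0
        assert table.frame.loc["s2", "USCa"] == 1

    def test_internal_drop_option_reduces_row_sums(self, tree):
        assignments = [
            self._assign(tree, "a", {"Mcystis": 700.0}),
            self._assign(tree, "b", {"Mcystis": 700.0, "pmoA2": 699.0}),
        ]
        full = build_count_table({"s": assignments}, tree)
        leaf_only = build_count_table({"s": assignments}, tree,
                                      include_internal=False)
        assert full.row_sums()["s"] == 2
        assert leaf_only.row_sums()["s"] == 1
        assert "TypeII" not in leaf_only.nodes

    def test_roundtrips_summarize(self, tree):
        from pmoaclass.lca import summarize_assignments

        assignments = [
            self._assign(tree, f"r{i}", {"Mcystis": 700.0}) for i in range(3)
        ]
        table = build_count_table({"s": assignments}, tree)
        counts, _ = summarize_assignments(assignments, tree)
        assert dict(counts) == {
            node: int(table.frame.loc["s", node]) for node in table.nodes
        }

    def test_duplicate_sample_rejected(self, tree):
        class WeirdMapping(dict):
            def __iter__(self):
                return iter(["s", "s"])

        with pytest.raises(ValueError, match="duplicate"):
            build_count_table(WeirdMapping(s=[]), tree)

    def test_tsv_roundtrip(self, tree):
        table = _table([[1, 2], [3, 4]])
        text = table.to_tsv()
        import io

        back = CountTable.from_tsv(io.StringIO(text))
        np.testing.assert_array_equal(back.counts, table.counts)
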