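"""Search engine: seeding, exact extension scores, bit conversion, parsers.

The extension stage is validated against Biopython's PairwiseAligner in local
mode with the same scoring scheme — an independent exhaustive Smith-Waterman.
"""

import math

import numpy as np
import pytest
from Bio import Align

from pmoaclass.preprocess import ReadRecord
from pmoaclass.search import (
    Hit,
    HitSet,
    SearchConfig,
    expected_bit_score,
    parse_external_tabular,
    raw_score_to_bits,
    search_nucleotide,
    search_translated,
    write_hits_tabular,
)
from pmoaclass.seqio import reverse_complement
from pmoaclass.synthetic import _mutate_synonymous_biased
from pmoaclass.taxonomy import ReferenceDB, ReferenceRecord


def sw_oracle(read, ref, cfg):
    """Exhaustive local alignment score under the engine's scheme."""
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=cfg.match_reward,
        mismatch_score=-cfg.mismatch_penalty,
        open_gap_score=-(cfg.gap_open + cfg.gap_extend),
        extend_gap_score=-cfg.gap_extend,
    )
    return int(aligner.score(read, ref))


def _shares_word(a, b, size):
    words = {a[i : i + size] for i in range(len(a) - size + 1)}
    return any(b[i : i + size] in words for i in range(len(b) - size + 1))


def _single_ref_db(tree, seq, taxon="Mcystis", acc="REF"):
    return ReferenceDB([ReferenceRecord(acc, taxon, seq)], tree)


class TestNucleotideSearch:
    def test_self_alignment(self, tree):
        rng = np.random.default_rng(0)
        ref = "".join("ACGT"[b] for b in rng.integers(0, 4, 400))
        db = _single_ref_db(tree, ref)
        hs = search_nucleotide(ReadRecord("q", ref), db)
        hit = hs.best
        assert hit.raw_score == 400
        assert hit.identity_pct == 100.0
        assert hit.query_span == (1, 400) and hit.subject_span == (1, 400)

    def test_no_shared_word_gives_empty_hitset(self, mock_db):
        rng = np.random.default_rng(1)
        while True:
            read = "".join("ACGT"[b] for b in rng.integers(0, 4, 400))
            rc = reverse_complement(read)
            if not any(
                _shares_word(read, r.sequence, 28) or _shares_word(rc, r.sequence, 28)
                for r in mock_db.records
            ):
                break
        assert not search_nucleotide(ReadRecord("q", read), mock_db)

    def test_scattered_substitutions_score_and_identity(self, tree, mock_db):
        ref = mock_db.records[0].sequence
        window = ref[:200]
        bases = list(window)
        for pos in (20, 60, 100, 140, 180):
            bases[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bases[pos]]
        read = "".join(bases)
        db = _single_ref_db(tree, ref)
        hit = search_nucleotide(ReadRecord("q", read), db).best
        assert hit.raw_score == 195 - 2 * 5  # 185
        assert hit.identity_pct == pytest.approx(97.5)
        assert hit.raw_score == sw_oracle(read, ref, SearchConfig())
        assert hit.bit_score == pytest.approx(
            raw_score_to_bits(185, SearchConfig())
        )

    def test_strand_symmetry(self, mock_db):
        read = ReadRecord("q", mock_db.records[3].sequence[50:450])
        rc = ReadRecord("q", reverse_complement(read.sequence))
        fwd = search_nucleotide(read, mock_db).best
        rev = search_nucleotide(rc, mock_db).best
        assert fwd.bit_score == pytest.approx(rev.bit_score)
        assert rev.strand == "-"

    def test_best_hit_per_taxon_unique(self, mock_db):
        # every reference taxon has several sequences; the HitSet keeps one each
        hs = search_nucleotide(
            ReadRecord("q", mock_db.records[0].sequence), mock_db
        )
        taxa = [h.subject_taxon for h in hs]
        assert len(taxa) == len(set(taxa))

    @pytest.mark.parametrize("n_edits", [0, 4, 10])
    def test_matches_exhaustive_oracle_when_seeded(self, tree, n_edits):
        cfg = SearchConfig(word_size=8)
        rng = np.random.default_rng(100 + n_edits)
        checked = 0
        for _ in range(40):
            ref = "".join("ACGT"[b] for b in rng.integers(0, 4, 180))
            start = int(rng.integers(0, 80))
            read = list(ref[start : start + 100])
            for _ in range(n_edits):
                p = int(rng.integers(0, len(read)))
                op = rng.random()
                if op < 0.7:
                    read[p] = "ACGT"[int(rng.integers(0, 4))]
                elif op < 0.85 and len(read) > 40:
                    del read[p]
                else:
                    read.insert(p, "ACGT"[int(rng.integers(0, 4))])
            read = "".join(read)
            db = _single_ref_db(tree, ref)
            hit = search_nucleotide(ReadRecord("q", read), db, cfg).best
            if hit is None:
                continue
            oracle = max(
                sw_oracle(oriented, ref, cfg)
                for oriented in (read, reverse_complement(read))
                if _shares_word(oriented, ref, cfg.word_size)
            )
            assert hit.raw_score == oracle
            checked += 1
        assert checked >= 30  # the property must actually exercise alignments


class TestBitScores:
    def test_monotone_in_raw_score(self):
        cfg = SearchConfig()
        bits = [raw_score_to_bits(s, cfg) for s in range(0, 500, 7)]
        assert all(b2 > b1 for b1, b2 in zip(bits, bits[1:]))

    def test_karlin_altschul_formula(self):
        cfg = SearchConfig()
        expected = (cfg.lambda_ * 100 - math.log(cfg.k_const)) / math.log(2)
        assert raw_score_to_bits(100, cfg) == pytest.approx(expected)

    def test_expected_bit_score_tracks_divergence(self):
        assert expected_bit_score(400, 0.0) > expected_bit_score(400, 0.05)
        assert expected_bit_score(400, 0.05) > expected_bit_score(400, 0.12)


class TestTranslatedSearch:
    def test_in_frame_copy_full_protein_identity(self, tree, mock_db):
        ref = mock_db.records[0].sequence
        db = _single_ref_db(tree, ref)
        hit = search_translated(ReadRecord("q", ref[:399]), db).best
        assert hit.identity_pct == 100.0

    def test_synonymous_divergence_rescued_by_translation(self, tree, mock_db):
        rng = np.random.default_rng(7)
        ref = mock_db.records[0].sequence
        read = _mutate_synonymous_biased(ref[:399], 120, rng)  # ~30% nt divergence
        db = _single_ref_db(tree, ref)
        nt = search_nucleotide(ReadRecord("q", read), db)
        tx = search_translated(ReadRecord("q", read), db)
        nt_bits = nt.best.bit_score if nt else 0.0
        assert tx.best.bit_score > nt_bits
        assert tx.best.bit_score > 50.0

    def test_random_reads_stay_below_rescue_threshold(self, mock_db):
        rng = np.random.default_rng(8)
        for _ in range(3):
            read = "".join("ACGT"[b] for b in rng.integers(0, 4, 400))
            hs = search_translated(ReadRecord("q", read), mock_db)
            best = hs.best.bit_score if hs else 0.0
            assert best < 50.0


class TestExternalTabular:
    ROW = "q1\t{acc}\t97.00\t400\t12\t0\t1\t400\t1\t400\tNA\t{bits}"

    def test_best_per_taxon_reduction(self, mock_db):
        acc = mock_db.records[0].accession
        text = "\n".join(
            [self.ROW.format(acc=acc, bits=700.0), self.ROW.format(acc=acc, bits=650.0)]
        )
        (hs,) = parse_external_tabular(text, mock_db)
        assert len(hs) == 1 and hs.best.bit_score == 700.0

    def test_empty_input(self, mock_db):
        assert parse_external_tabular("", mock_db) == []

    def test_unknown_subject_dropped(self, mock_db):
        text = self.ROW.format(acc="UNKNOWN_ACC", bits=500.0)
        assert parse_external_tabular(text, mock_db) == []

    def test_malformed_row_names_line(self, mock_db):
        with pytest.raises(ValueError, match="line 1"):
            parse_external_tabular("q1\tonly\tthree", mock_db)

    def test_native_output_parses_back(self, mock_db):
        hs = search_nucleotide(
            ReadRecord("q1", mock_db.records[0].sequence), mock_db
        )
        text = write_hits_tabular([hs])
        (parsed,) = parse_external_tabular(text, mock_db)
        assert {h.subject_taxon for h in parsed} == {h.subject_taxon for h in hs}
        assert parsed.best.bit_score == pytest.approx(hs.best.bit_score, abs=0.1)


def test_hitset_orders_by_bits_then_name():
    hs = HitSet("q")
    for taxon, bits in [("B", 10.0), ("A", 10.0), ("C", 20.0)]:
        hs.add(
            Hit("q", f"{taxon}_ref", taxon, 10, bits, 99.0, (1, 10), (1, 10))
        )
    assert [h.subject_taxon for h in hs.hits] == ["C", "A", "B"]
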