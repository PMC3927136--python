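"""Naive Bayesian classifier: probability tables, scoring, bootstrap confidence.

The word-probability tables are checked against an independent brute-force
implementation of the presence-count definitions on tiny databases.
"""

import math

import numpy as np
import pytest

from pmoaclass.nbc import NBCConfig, NBCModel, classify, classify_many, train
from pmoaclass.preprocess import ReadRecord
from pmoaclass.seqio import reverse_complement
from pmoaclass.taxonomy import ReferenceDB, ReferenceRecord


def _db(tree, **taxon_seqs):
    records = [
        ReferenceRecord(f"{taxon}_{i}", taxon, seq)
        for taxon, seqs in taxon_seqs.items()
        for i, seq in enumerate(seqs)
    ]
    return ReferenceDB(records, tree)


def _kmers(seq, k):
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def brute_force_tables(db, k):
    """Word probabilities computed directly from the presence-count definitions."""
    seqs = [(r.taxon_name, _kmers(r.sequence, k)) for r in db.records]
    n_total = len(seqs)
    words = sorted(set().union(*(s for _, s in seqs)))
    prior = {
        w: (sum(1 for _, s in seqs if w in s) + 0.5) / (n_total + 1) for w in words
    }
    taxa = sorted({t for t, _ in seqs})
    cond = {}
    for taxon in taxa:
        own = [s for t, s in seqs if t == taxon]
        m_big = len(own)
        for w in words:
            m = sum(1 for s in own if w in s)
            cond[(w, taxon)] = (m + prior[w]) / (m_big + 1)
    return words, taxa, prior, cond


class TestTraining:
    def test_prior_and_conditional_single_sequence(self, tree):
        # N = 1 and the word is present: prior 1.5/2, conditional (1+0.75)/2
        db = _db(tree, Mcystis=["ACGTAC"])
        model = train(db, NBCConfig(kmer_size=4))
        assert set(model.kmer_index) == {"ACGT", "CGTA", "GTAC"}
        np.testing.assert_allclose(np.exp(model.log_cond), 0.875)

    def test_unseen_word_floor_positive(self, tree):
        db = _db(tree, Mcystis=["ACGTAC"])
        model = train(db, NBCConfig(kmer_size=4))
        # absent everywhere: P(w)/(M+1) = (0.5/2)/2
        assert math.exp(model.unseen_log_cond[0]) == pytest.approx(0.125)

    def test_identical_singleton_taxa_have_identical_tables(self, tree):
        db = _db(tree, Mcystis=["ACGTACGTAA"], Msinus=["ACGTACGTAA"])
        model = train(db, NBCConfig(kmer_size=4))
        np.testing.assert_array_equal(model.log_cond[:, 0], model.log_cond[:, 1])

    def test_tables_match_brute_force(self, tree):
        rng = np.random.default_rng(5)
        seqs = {
            t: ["".join("ACGT"[b] for b in rng.integers(0, 4, 40)) for _ in range(2)]
            for t in ("Mcystis", "Msinus", "USCa")
        }
        db = _db(tree, **seqs)
        model = train(db, NBCConfig(kmer_size=4))
        words, taxa, prior, cond = brute_force_tables(db, 4)
        assert taxa == model.taxa
        for w in words:
            for g, taxon in enumerate(taxa):
                expected = math.log(cond[(w, taxon)])
                got = model.log_cond[model.kmer_index[w], g]
                assert got == pytest.approx(expected, abs=1e-12)

    def test_internal_training_label_rejected(self, tree):
        with pytest.raises(ValueError, match="TypeIIa"):
            train(_db(tree, TypeIIa=["ACGTACGT"]), NBCConfig(kmer_size=4))


class TestClassification:
    def test_self_classification_full_confidence(self, mock_db, nbc_model):
        for rec in mock_db.records[::10]:
            res = classify(
                ReadRecord("q", rec.sequence), nbc_model, NBCConfig(), seed=3
            )
            assert res.reported_taxon == rec.taxon_name
            assert res.path[-1] == (rec.taxon_name, 100.0)

    def test_reverse_complement_same_assignment(self, mock_db, nbc_model):
        rec = mock_db.records[0]
        res = classify(
            ReadRecord("q", reverse_complement(rec.sequence)),
            nbc_model,
            NBCConfig(),
            seed=3,
        )
        assert res.reported_taxon == rec.taxon_name

    def test_near_identical_read_confident_and_matches_brute_force(self, tree):
        rng = np.random.default_rng(17)
        a = "".join("ACGT"[b] for b in rng.integers(0, 4, 60))
        b = "".join("ACGT"[b] for b in rng.integers(0, 4, 60))
        db = _db(tree, Mcystis=[a], USCa=[b])
        cfg = NBCConfig(kmer_size=4)
        model = train(db, cfg)
        read = "C" + a[1:] if a[0] != "C" else "G" + a[1:]
        res = classify(ReadRecord("q", read), model, cfg, seed=9)
        assert res.winner_leaf == "Mcystis"
        assert res.path[-1][1] >= 80.0

        # independent full-score winner from the brute-force tables
        words, taxa, prior, cond = brute_force_tables(db, 4)
        p_unseen = 0.5 / (len(db.records) + 1)
        best = None
        for taxon in taxa:
            m_big = sum(1 for r in db.records if r.taxon_name == taxon)
            score = 0.0
            for w in _kmers(read, 4) | _kmers(reverse_complement(read), 4):
                if w in prior:
                    score_w = cond[(w, taxon)]
                else:
                    score_w = p_unseen / (m_big + 1)
                score += math.log(score_w)
            # forward orientation dominates; the model takes the better one
            if best is None or score > best[1]:
                best = (taxon, score)
        assert best[0] == "Mcystis"

    def test_confidences_non_increasing_root_to_leaf(self, mock_db, nbc_model):
        rng = np.random.default_rng(2)
        read = "".join("ACGT"[b] for b in rng.integers(0, 4, 400))
        res = classify(ReadRecord("q", read), nbc_model, NBCConfig(), seed=4)
        confs = [c for _, c in res.path]
        assert confs[0] == 100.0
        assert all(a >= b for a, b in zip(confs, confs[1:]))

    def test_determinism_under_seed(self, mock_db, nbc_model):
        read = ReadRecord("q", mock_db.records[5].sequence[:350])
        r1 = classify(read, nbc_model, NBCConfig(), seed=11)
        r2 = classify(read, nbc_model, NBCConfig(), seed=11)
        assert r1.path == r2.path and r1.reported_taxon == r2.reported_taxon

    def test_short_read_unclassified(self, nbc_model):
        res = classify(ReadRecord("q", "ACGT"), nbc_model, NBCConfig(), seed=0)
        assert res.reported_taxon == "unclassified" and res.path == []

    def test_classify_many_deterministic(self, mock_db, nbc_model):
        reads = [ReadRecord(f"q{i}", r.sequence) for i, r in
                 enumerate(mock_db.records[:4])]
        out1 = classify_many(reads, nbc_model, NBCConfig(), seed=21)
        out2 = classify_many(reads, nbc_model, NBCConfig(), seed=21)
        assert [r.path for r in out1] == [r.path for r in out2]


def test_model_roundtrip(tmp_path, tree):
    db = _db(tree, Mcystis=["ACGTACGTAC"], USCa=["TTGCATGCAT"])
    model = train(db, NBCConfig(kmer_size=4))
    path = tmp_path / "model.npz"
    model.save(str(path))
    loaded = NBCModel.load(str(path))
    assert loaded.taxa == model.taxa
    assert loaded.kmer_index == model.kmer_index
    np.testing.assert_array_equal(loaded.log_cond, model.log_cond)
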