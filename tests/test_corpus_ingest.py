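"""Ingestion, preprocessing, and document-term matrix construction."""

import collections

import numpy as np
import pytest

from genecontext import (
    DocumentRecord,
    build_dtm,
    merge_documents,
    porter_stem,
    preprocess_text,
    prune_rare_tokens,
    read_gmt,
    write_gmt,
)
from genecontext.corpus_ingest import GeneSet, TokenizedDoc, read_stopwords


class TestGmt:
    def test_duplicate_genes_collapsed_preserving_order(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("S1\tdesc\tA\tB\tA\n")
        (s,) = read_gmt(p)
        assert s.set_id == "S1" and s.genes == ("A", "B")

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("")
        assert read_gmt(p) == []

    def test_hand_counted_fixture(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text(
            "S1\tone\tTP53\tEGFR\n"
            "S2\ttwo\tTP53\tKRAS\tBRAF\tEGFR\n"
            "S3\tthree\tMYC\n"
        )
        sets = read_gmt(p)
        assert [len(s.genes) for s in sets] == [2, 4, 1]

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("S1\tok\tA\nS2\tonly-two-fields\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(p)

    def test_duplicate_set_id_rejected(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("S1\ta\tA\nS1\tb\tB\n")
        with pytest.raises(ValueError, match="duplicate set id"):
            read_gmt(p)

    def test_write_read_round_trip(self, tmp_path):
        sets = [
            GeneSet("S1", "alpha", ("TP53", "EGFR")),
            GeneSet("S2", "beta", ("KRAS",)),
        ]
        p = tmp_path / "rt.gmt"
        write_gmt(sets, p)
        back = read_gmt(p)
        assert [(s.set_id, s.name, s.genes) for s in back] == [
            (s.set_id, s.name, s.genes) for s in sets
        ]


class TestMergeDocuments:
    def test_abstracts_concatenated_in_input_order(self):
        recs = [
            DocumentRecord("d1", "S1", "a b", "abstract"),
            DocumentRecord("d2", "S1", "c", "abstract"),
        ]
        (m,) = merge_documents(recs)
        assert m.text == "a b c" and m.set_id == "S1"

    def test_single_record_text_unchanged(self):
        recs = [DocumentRecord("d1", "S1", "hello", "description")]
        (m,) = merge_documents(recs)
        assert m.text == "hello" and m.source == "description"

    def test_abstract_takes_precedence_over_description(self):
        recs = [
            DocumentRecord("d1", "S1", "the description", "description"),
            DocumentRecord("d2", "S1", "the abstract", "abstract"),
        ]
        (m,) = merge_documents(recs)
        assert m.text == "the abstract" and m.source == "abstract"

    def test_one_record_per_set(self):
        recs = [
            DocumentRecord(f"d{i}", f"S{i % 3}", f"t{i}", "abstract")
            for i in range(9)
        ]
        merged = merge_documents(recs)
        assert sorted(m.set_id for m in merged) == ["S0", "S1", "S2"]


class TestPreprocess:
    def test_reference_sentence(self):
        doc = preprocess_text("DNA Repair and damage-response 2001", {"and"})
        assert doc.tokens == ["dna", "repair", "damag", "respons"]

    def test_empty_text(self):
        assert preprocess_text("", frozenset()).tokens == []

    def test_all_stopword_input(self):
        sw = {"the", "of", "and"}
        assert preprocess_text("the of and", sw).tokens == []

    def test_greek_and_digits_removed(self):
        doc = preprocess_text("TGF-β signalling 42 pathways", frozenset())
        assert "42" not in doc.tokens
        assert all(c.islower() and c.isalpha() for t in doc.tokens for c in t)

    def test_idempotent_on_own_output(self):
        # Porter stemming can shorten a handful of already-stemmed forms
        # again (e.g. divis -> divi), so idempotence is checked on inputs
        # whose stems are stable: ordinary biomedical phrasing and the
        # synthetic consonant-token corpus the pipeline tests run on.
        from genecontext import SyntheticConfig, generate_corpus

        texts = [
            "Oxidative stress; lipid metabolism & inflammation!",
            "vesicle trafficking, membrane fusion (SNARE complexes)",
        ]
        docs, _ = generate_corpus(SyntheticConfig(docs_per_topic=2, seed=0))
        texts += [d.text for d in docs]
        for raw in texts:
            once = preprocess_text(raw, frozenset()).tokens
            twice = preprocess_text(" ".join(once), frozenset()).tokens
            assert twice == once

    def test_porter_canonical_pairs(self):
        # examples from the algorithm's defining description
        pairs = {
            "caresses": "caress", "ponies": "poni", "relational": "relat",
            "conditional": "condit", "agreed": "agre", "hopping": "hop",
            "sized": "size", "happy": "happi", "replacement": "replac",
            "triplicate": "triplic", "dependent": "depend", "probate": "probat",
            "controll": "control", "electriciti": "electr",
        }
        assert {w: porter_stem(w) for w in pairs} == pairs


class TestStopwords:
    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = tmp_path / "sw.txt"
        p.write_text("# a comment\nthe\n\nand\n")
        assert read_stopwords(p) == {"the", "and"}


class TestDtm:
    def test_small_counts(self):
        docs = [TokenizedDoc("d1", ["a", "b", "a"]), TokenizedDoc("d2", ["b"])]
        dtm = build_dtm(docs)
        assert dtm.vocabulary == ["a", "b"]
        assert dtm.counts.toarray().tolist() == [[2, 1], [0, 1]]

    def test_empty_doc_row_all_zero(self):
        docs = [TokenizedDoc("d1", ["a"]), TokenizedDoc("d2", [])]
        dtm = build_dtm(docs)
        assert dtm.counts.toarray()[1].sum() == 0

    def test_column_sums_match_independent_tally(self):
        rng = np.random.default_rng(11)
        vocab = [f"tok{i}" for i in range(12)]
        docs = [
            TokenizedDoc(f"d{i}", list(rng.choice(vocab, size=30)))
            for i in range(5)
        ]
        dtm = build_dtm(docs)
        tally = collections.Counter(t for d in docs for t in d.tokens)
        for j, tok in enumerate(dtm.vocabulary):
            assert dtm.counts[:, j].sum() == tally[tok]

    def test_vocabulary_sorted(self):
        dtm = build_dtm([TokenizedDoc("d", ["zz", "aa", "mm"])])
        assert dtm.vocabulary == sorted(dtm.vocabulary)


class TestPrune:
    def _dtm(self, rows, vocab):
        docs = [
            TokenizedDoc(f"d{i}", [v for v, c in zip(vocab, row) for _ in range(c)])
            for i, row in enumerate(rows)
        ]
        return build_dtm(docs)

    def test_frequency_threshold_is_strict(self):
        dtm = self._dtm([[5, 4]], ["keep", "drop"])
        pruned = prune_rare_tokens(dtm, min_freq=5)
        assert pruned.vocabulary == ["keep"]

    def test_fixpoint_identity(self):
        dtm = self._dtm([[5, 6], [2, 1]], ["aa", "bb"])
        once = prune_rare_tokens(dtm, min_freq=5)
        twice = prune_rare_tokens(once, min_freq=5)
        assert once.vocabulary == twice.vocabulary
        assert once.doc_ids == twice.doc_ids
        assert (once.counts != twice.counts).nnz == 0

    def test_cascade_drops_emptied_document(self):
        # doc d1 holds only a rare token; dropping the token empties d1,
        # whose removal leaves the other frequencies unchanged
        dtm = self._dtm([[5, 5, 0], [0, 0, 4]], ["aa", "bb", "rare"])
        pruned = prune_rare_tokens(dtm, min_freq=5)
        assert pruned.doc_ids == ["d0"]
        assert pruned.vocabulary == ["aa", "bb"]

    def test_retained_token_totals_preserved(self):
        dtm = self._dtm([[6, 1, 3], [2, 1, 4]], ["aa", "bb", "cc"])
        pruned = prune_rare_tokens(dtm, min_freq=5)
        before = dict(zip(dtm.vocabulary, dtm.token_frequencies()))
        after = dict(zip(pruned.vocabulary, pruned.token_frequencies()))
        for tok, freq in after.items():
            assert freq == before[tok]

    def test_emptied_corpus_raises(self):
        dtm = self._dtm([[1], [2]], ["only"])
        with pytest.raises(ValueError, match="corpus emptied by pruning"):
            prune_rare_tokens(dtm, min_freq=5)
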