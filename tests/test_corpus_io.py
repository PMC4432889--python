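import json

import numpy as np
import pytest

from atmbiblio import (
    CitationRecord,
    TfidfPolicy,
    build_author_set,
    load_corpus,
    normalize_author_name,
    porter_stem,
    preprocess_corpus,
    read_citations,
    save_corpus,
    tokenize,
)
from atmbiblio.corpus_io import record_author_set

from conftest import build_corpus


@pytest.mark.parametrize("word,stem", [
    ("caresses", "caress"), ("ponies", "poni"), ("cats", "cat"),
    ("agreed", "agre"), ("plastered", "plaster"), ("motoring", "motor"),
    ("hopping", "hop"), ("falling", "fall"), ("filing", "file"),
    ("happy", "happi"), ("relational", "relat"), ("conditional", "condit"),
    ("operator", "oper"), ("decisiveness", "decis"), ("hopeful", "hope"),
    ("inference", "infer"), ("adjustable", "adjust"), ("replacement", "replac"),
    ("dependent", "depend"), ("smoking", "smoke"), ("cigarettes", "cigarett"),
    ("nicotine", "nicotin"), ("effective", "effect"), ("rate", "rate"),
    ("sky", "sky"), ("controll", "control"),
])
def test_porter_reference_pairs(word, stem):
    """The stemmer reproduces the classic algorithm's published behavior."""
    assert porter_stem(word) == stem


def test_porter_idempotent_on_vocab():
    from atmbiblio import synthetic_vocabulary

    for w in synthetic_vocabulary(200):
        assert porter_stem(w) == w


class TestReadCitations:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        records, report = read_citations(path, "jsonl")
        assert records == [] and report.n_read == 0

    def test_jsonl_drops_empty_abstract(self, jsonl_records_file):
        records, report = read_citations(jsonl_records_file, "jsonl")
        assert len(records) == 2
        assert report.n_read == 3
        assert report.n_dropped_no_abstract == 1
        assert records[0].record_id == "r1"
        assert records[0].mesh_terms == ["Smoking", "Humans"]

    def test_jsonl_malformed_line_skipped(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"record_id": "ok", "abstract": "text here", "authors": ["A B"]}\n'
                        "{not json}\n")
        records, report = read_citations(path, "jsonl")
        assert len(records) == 1 and report.n_malformed == 1

    def test_pubmed_xml_mesh_and_abstract_filter(self, pubmed_xml_file):
        records, report = read_citations(pubmed_xml_file, "pubmed-xml")
        # second citation has no abstract and is dropped
        assert len(records) == 1 and report.n_dropped_no_abstract == 1
        rec = records[0]
        assert len(rec.mesh_terms) == 4
        assert rec.year == 2004
        assert rec.authors == ["Hatsukami D", "Cummings K"]
        assert rec.journal == "Nicotine & Tobacco Research"

    def test_tsv_roundtrip_of_fields(self, tmp_path):
        path = tmp_path / "records.tsv"
        header = "record_id\ttitle\tabstract\tauthors\tjournal\tyear\tmesh_terms"
        row = "r9\ttitle\tsome abstract text\tSmith J;Lee C\tJ Nic\t2010\tSmoking;Humans"
        path.write_text(header + "\n" + row + "\n")
        records, _ = read_citations(path, "tsv")
        assert records[0].authors == ["Smith J", "Lee C"]
        assert records[0].mesh_terms == ["Smoking", "Humans"]
        assert records[0].year == 2010

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_citations(tmp_path / "nope.jsonl", "jsonl")


class TestAuthorSet:
    def test_roster_plus_last_author(self):
        rec = CitationRecord("r", "", "a", ["X Q", "Y R", "Z S"], "J", 2000)
        assert record_author_set(rec, {"y r"}) == {"y r", "z s"}

    def test_single_roster_author_no_duplicate(self):
        rec = CitationRecord("r", "", "a", ["Y R"], "J", 2000)
        assert record_author_set(rec, {"y r"}) == {"y r"}

    def test_index_matches_hand_enumeration(self):
        records = [
            CitationRecord("1", "", "a", ["Able A", "Baker B", "Chen C"], "J", 2000),
            CitationRecord("2", "", "a", ["Baker B", "Dole D"], "J", 2001),
            CitationRecord("3", "", "a", ["Egan E"], "J", 2002),
        ]
        index = build_author_set(records, {"Baker B", "Able A"})
        # record 1: {able a, baker b, chen c}; record 2: {baker b, dole d};
        # record 3: {egan e} -> 5 distinct names
        assert len(index) == 5
        assert set(index.items) == {"able a", "baker b", "chen c", "dole d", "egan e"}

    def test_name_normalization(self):
        assert normalize_author_name("  Smith,  J.A. ") == "smith j a"
        assert normalize_author_name("SMITH JA") == "smith ja"


class TestPreprocess:
    def test_stopword_only_document_dropped(self):
        records = [
            CitationRecord("1", "", "the and of with", ["A B"], "J", 2000),
            CitationRecord("2", "", "nicotine nicotine tobacco tobacco", ["C D"], "J", 2000),
        ]
        corpus = preprocess_corpus(records, min_count=1, tfidf_policy=TfidfPolicy(None))
        assert corpus.D == 1

    def test_min_count_removes_singletons(self):
        records = [
            CitationRecord("1", "", "zzq tobacco tobacco", ["A B"], "J", 2000),
            CitationRecord("2", "", "tobacco nicotine nicotine", ["C D"], "J", 2000),
            CitationRecord("3", "", "nicotine tobacco", ["E F"], "J", 2000),
        ]
        corpus = preprocess_corpus(records, min_count=2, tfidf_policy=TfidfPolicy(None))
        assert "zzq" not in corpus.vocabulary
        assert "tobacco" in corpus.vocabulary

    def test_doc_freq_filter_removes_ubiquitous_stem(self):
        # 'tobacco' in all 4 docs -> df 1.0 > 0.75 cutoff; others survive
        records = [
            CitationRecord(str(i), "", f"tobacco snus snus cigar cigar", ["A B"], "J", 2000)
            for i in range(3)
        ] + [CitationRecord("4", "", "tobacco menthol menthol", ["C D"], "J", 2000)]
        corpus = preprocess_corpus(
            records, min_count=1, tfidf_policy=TfidfPolicy(max_doc_freq_fraction=0.75)
        )
        assert "tobacco" not in corpus.vocabulary
        assert "snu" in corpus.vocabulary or "snus" in corpus.vocabulary

    def test_deterministic_and_token_bounds(self, jsonl_records_file):
        records, _ = read_citations(jsonl_records_file, "jsonl")
        kw = dict(min_count=1, tfidf_policy=TfidfPolicy(None))
        c1 = preprocess_corpus(records, **kw)
        c2 = preprocess_corpus(records, **kw)
        assert c1 == c2
        for d in c1.documents:
            assert d.tokens.max() < c1.W and d.tokens.min() >= 0
        assert sum(len(d.tokens) for d in c1.documents) == c1.n_tokens

    def test_refiltering_detokenized_output_is_fixed_point(self):
        from atmbiblio import make_fixture_citations

        records = make_fixture_citations(12, seed=3)
        kw = dict(min_count=2, tfidf_policy=TfidfPolicy(None))
        c1 = preprocess_corpus(records, **kw)
        detok = [
            CitationRecord(d.record_id, "", " ".join(c1.vocabulary.items[t] for t in d.tokens),
                           [f"X {i}"], d.journal, d.year)
            for i, d in enumerate(c1.documents)
        ]
        c2 = preprocess_corpus(detok, **kw)
        assert set(c2.vocabulary.items) == set(c1.vocabulary.items)

    def test_empty_corpus_raises(self):
        records = [CitationRecord("1", "", "the of and", ["A B"], "J", 2000)]
        with pytest.raises(ValueError, match="empty corpus"):
            preprocess_corpus(records, min_count=1, tfidf_policy=TfidfPolicy(None))

    def test_tokenize_drops_digits_and_short(self):
        assert tokenize("CO2 levels rose 15% in s 2 years") == ["co", "levels", "rose", "in", "years"]


def test_corpus_bundle_roundtrip(tmp_path):
    corpus = build_corpus([([0, 1, 2], [0]), ([2, 2], [0, 1])])
    save_corpus(corpus, tmp_path / "bundle")
    assert load_corpus(tmp_path / "bundle") == corpus
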