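"""Citation-record ingestion and corpus preprocessing.

Reads bibliographic records (PubMed XML, JSONL or TSV), builds the author
universe (principal investigators plus each record's last author), and turns
abstracts into an integer-encoded bag-of-words corpus: lower-casing,
stop-word removal, Porter stemming, a corpus-wide minimum-count filter and a
document-frequency/TF-IDF filter.
"""

from __future__ import annotations

import json
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

from ._porter import porter_stem

logger = logging.getLogger("atmbiblio")

_TOKEN_RE = re.compile(r"[^a-z]+")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CitationRecord:
    """One bibliographic record: abstract text plus authorship metadata."""

    record_id: str
    title: str
    abstract: str
    authors: list[str]
    journal: str
    year: int | None
    mesh_terms: list[str] = field(default_factory=list)


@dataclass
class LoadReport:
    """Bookkeeping from :func:`read_citations`."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped_no_abstract: int = 0
    n_malformed: int = 0


class _Index:
    """Bijection between strings and contiguous integer ids."""

    def __init__(self, items: Iterable[str] = ()):  # insertion order = id order
        self._items: list[str] = []
        self._ids: dict[str, int] = {}
        for it in items:
            self.add(it)

    def add(self, item: str) -> int:
        if item not in self._ids:
            self._ids[item] = len(self._items)
            self._items.append(item)
        return self._ids[item]

    def __getitem__(self, item: str) -> int:
        return self._ids[item]

    def __contains__(self, item: str) -> bool:
        return item in self._ids

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    def get(self, item: str, default=None):
        return self._ids.get(item, default)

    @property
    def items(self) -> list[str]:
        return list(self._items)

    def __eq__(self, other) -> bool:
        return isinstance(other, _Index) and self._items == other._items


class Vocabulary(_Index):
    """Stem string <-> word id bijection; ids contiguous in [0, W)."""

    @property
    def W(self) -> int:
        return len(self)


class AuthorIndex(_Index):
    """Normalized author name <-> author id bijection; ids in [0, A)."""

    @property
    def A(self) -> int:
        return len(self)


@dataclass
class Document:
    """One tokenized document: word ids, author ids and metadata."""

    tokens: np.ndarray          # int32 word ids, document order
    authors: np.ndarray         # int32 author ids, sorted, non-empty
    year: int | None = None
    journal: str | None = None
    record_id: str | None = None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Document)
            and np.array_equal(self.tokens, other.tokens)
            and np.array_equal(self.authors, other.authors)
            and self.year == other.year
            and self.journal == other.journal
            and self.record_id == other.record_id
        )


@dataclass
class Corpus:
    """Integer-encoded document collection over a fixed vocabulary and author set."""

    documents: list[Document]
    vocabulary: Vocabulary
    authors: AuthorIndex

    @property
    def D(self) -> int:
        return len(self.documents)

    @property
    def W(self) -> int:
        return self.vocabulary.W

    @property
    def A(self) -> int:
        return self.authors.A

    @property
    def n_tokens(self) -> int:
        return sum(len(d.tokens) for d in self.documents)

    def doc_lengths(self) -> np.ndarray:
        return np.array([len(d.tokens) for d in self.documents], dtype=np.int64)

    def validate(self) -> None:
        for d in self.documents:
            if len(d.authors) == 0:
                raise ValueError("document with empty author set")
            if len(d.tokens) and (d.tokens.min() < 0 or d.tokens.max() >= self.W):
                raise ValueError("token id outside vocabulary")
            if d.authors.min() < 0 or d.authors.max() >= self.A:
                raise ValueError("author id outside index")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Corpus)
            and self.documents == other.documents
            and self.vocabulary == other.vocabulary
            and self.authors == other.authors
        )


@dataclass
class TfidfPolicy:
    """Vocabulary pruning by document frequency and/or mean TF-IDF.

    max_doc_freq_fraction: stems present in more than this fraction of
        documents are removed (None disables).
    min_mean_tfidf_quantile: stems whose mean TF-IDF falls below this quantile
        of the per-stem mean TF-IDF distribution are removed (None disables;
        disabled by default because no principled cutoff exists a priori).
    """

    max_doc_freq_fraction: float | None = 0.5
    min_mean_tfidf_quantile: float | None = None


# ---------------------------------------------------------------------------
# name normalization
# ---------------------------------------------------------------------------

def normalize_author_name(name: str) -> str:
    """Normalize to case-folded, whitespace-collapsed 'surname initials' form.

    'Smith, J.A.' and 'Smith JA' both map to 'smith ja'. Disambiguation
    beyond string equality is deliberately not attempted.
    """
    name = name.replace(",", " ").replace(".", " ")
    return " ".join(name.casefold().split())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _record_from_dict(obj: dict) -> CitationRecord:
    year = obj.get("year")
    if year is not None and year != "":
        year = int(year)
    else:
        year = None
    return CitationRecord(
        record_id=str(obj.get("record_id", "")),
        title=str(obj.get("title", "")),
        abstract=str(obj.get("abstract", "")),
        authors=list(obj.get("authors", [])),
        journal=str(obj.get("journal", "")),
        year=year,
        mesh_terms=list(obj.get("mesh_terms", [])),
    )


def _read_jsonl(path: Path, report: LoadReport) -> list[CitationRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            report.n_read += 1
            try:
                records.append(_record_from_dict(json.loads(line)))
            except (json.JSONDecodeError, ValueError, TypeError) as exc:
                report.n_malformed += 1
                logger.warning("skipping malformed JSONL line %d: %s", lineno, exc)
    return records


_TSV_COLUMNS = ["record_id", "title", "abstract", "authors", "journal", "year", "mesh_terms"]


def _read_tsv(path: Path, report: LoadReport) -> list[CitationRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        missing = [c for c in _TSV_COLUMNS if c not in col]
        if missing:
            raise ValueError(f"TSV missing columns: {missing}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            report.n_read += 1
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(header):
                report.n_malformed += 1
                logger.warning("skipping short TSV line %d", lineno)
                continue
            try:
                obj = {
                    "record_id": parts[col["record_id"]],
                    "title": parts[col["title"]],
                    "abstract": parts[col["abstract"]],
                    "authors": [a for a in parts[col["authors"]].split(";") if a],
                    "journal": parts[col["journal"]],
                    "year": parts[col["year"]] or None,
                    "mesh_terms": [m for m in parts[col["mesh_terms"]].split(";") if m],
                }
                records.append(_record_from_dict(obj))
            except (ValueError, TypeError) as exc:
                report.n_malformed += 1
                logger.warning("skipping malformed TSV line %d: %s", lineno, exc)
    return records


def _read_pubmed_xml(path: Path, report: LoadReport) -> list[CitationRecord]:
    tree = etree.parse(str(path))
    records = []
    for art in tree.iter("PubmedArticle"):
        report.n_read += 1
        try:
            cit = art.find("MedlineCitation")
            pmid = cit.findtext("PMID", default="")
            article = cit.find("Article")
            title = article.findtext("ArticleTitle", default="")
            abstract = " ".join(
                (t.text or "") for t in article.findall("Abstract/AbstractText")
            ).strip()
            journal = article.findtext("Journal/Title", default="")
            year_text = article.findtext("Journal/JournalIssue/PubDate/Year")
            year = int(year_text) if year_text else None
            authors = []
            for au in article.findall("AuthorList/Author"):
                last = au.findtext("LastName")
                initials = au.findtext("Initials")
                if last:
                    authors.append(f"{last} {initials}" if initials else last)
            mesh = [
                m.text for m in cit.findall("MeshHeadingList/MeshHeading/DescriptorName")
                if m.text
            ]
            records.append(CitationRecord(pmid, title, abstract, authors, journal, year, mesh))
        except (AttributeError, ValueError) as exc:
            report.n_malformed += 1
            logger.warning("skipping malformed PubmedArticle: %s", exc)
    return records


def read_citations(
    path: str | Path, format: str
) -> tuple[list[CitationRecord], LoadReport]:
    """Read citation records from *path* in the named dialect.

    Records lacking an abstract are dropped and counted in the report;
    malformed records are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = LoadReport()
    if format == "jsonl":
        records = _read_jsonl(path, report)
    elif format == "tsv":
        records = _read_tsv(path, report)
    elif format == "pubmed-xml":
        records = _read_pubmed_xml(path, report)
    else:
        raise ValueError(f"unknown format: {format!r}")
    kept = []
    for rec in records:
        if rec.abstract.strip():
            kept.append(rec)
        else:
            report.n_dropped_no_abstract += 1
    report.n_kept = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# author universe
# ---------------------------------------------------------------------------

def record_author_set(record: CitationRecord, roster: set[str]) -> set[str]:
    """Normalized author names retained for ATM: roster members plus the last author."""
    normalized = [normalize_author_name(a) for a in record.authors]
    keep = {a for a in normalized if a in roster}
    if normalized:
        keep.add(normalized[-1])
    return keep


def build_author_set(
    records: Sequence[CitationRecord], pi_roster: Iterable[str]
) -> AuthorIndex:
    """Index every author retained for modeling across *records*.

    A record contributes its listed authors that appear on the investigator
    roster, plus its last author. Records with an empty author list are
    excluded (logged).
    """
    roster = {normalize_author_name(a) for a in pi_roster}
    index = AuthorIndex()
    n_skipped = 0
    for rec in records:
        if not rec.authors:
            n_skipped += 1
            continue
        for name in sorted(record_author_set(rec, roster)):
            index.add(name)
    if n_skipped:
        logger.info("excluded %d records with empty author lists", n_skipped)
    return index


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def default_stopwords() -> frozenset[str]:
    """Default English stop list (scikit-learn's list; configurable)."""
    from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

    return frozenset(ENGLISH_STOP_WORDS)


def tokenize(text: str, min_token_len: int = 2) -> list[str]:
    """Lower-case and split on non-alphabetic characters.

    Pure digits disappear with the non-alphabetic split; tokens shorter than
    *min_token_len* are dropped.
    """
    return [t for t in _TOKEN_RE.split(text.casefold()) if len(t) >= min_token_len]


def preprocess_corpus(
    records: Sequence[CitationRecord],
    stopwords: Iterable[str] | None = None,
    min_count: int = 2,
    tfidf_policy: TfidfPolicy | None = None,
    pi_roster: Iterable[str] | None = None,
    author_index: AuthorIndex | None = None,
    min_token_len: int = 2,
) -> Corpus:
    """Build an integer-encoded corpus from citation records.

    Pipeline: lower-case tokenization -> stop-word removal -> Porter
    stemming -> corpus-wide count < *min_count* removal -> TF-IDF policy.
    Documents that end up empty (or have no retained author) are dropped with
    a logged count.

    The author universe is *author_index* if given, else built from the
    records via :func:`build_author_set` (roster defaults to empty, i.e.
    last authors only).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    stop = frozenset(stopwords) if stopwords is not None else default_stopwords()
    if tfidf_policy is None:
        tfidf_policy = TfidfPolicy()
    roster = {normalize_author_name(a) for a in (pi_roster or ())}
    if author_index is None:
        author_index = build_author_set(records, roster)

    # stop-word removal before stemming, per the stated pipeline order
    stemmed_docs: list[list[str]] = []
    kept_records: list[CitationRecord] = []
    for rec in records:
        if not rec.authors:
            continue
        stems = [porter_stem(t) for t in tokenize(rec.abstract, min_token_len) if t not in stop]
        stemmed_docs.append(stems)
        kept_records.append(rec)

    counts: Counter[str] = Counter()
    doc_freq: Counter[str] = Counter()
    for stems in stemmed_docs:
        counts.update(stems)
        doc_freq.update(set(stems))

    removed = {w for w, c in counts.items() if c < min_count}

    n_docs = len(stemmed_docs)
    if tfidf_policy.max_doc_freq_fraction is not None and n_docs > 0:
        cutoff = tfidf_policy.max_doc_freq_fraction * n_docs
        removed |= {w for w, dfreq in doc_freq.items() if dfreq > cutoff}
    if tfidf_policy.min_mean_tfidf_quantile is not None and n_docs > 0:
        survivors = [w for w in counts if w not in removed]
        if survivors:
            idf = {w: math.log(n_docs / doc_freq[w]) for w in survivors}
            mean_tfidf = {}
            totals = Counter()
            for stems in stemmed_docs:
                tf = Counter(s for s in stems if s not in removed)
                n = len(stems)
                for w, c in tf.items():
                    totals[w] += (c / n) * idf[w] if n else 0.0
            mean_tfidf = {w: totals[w] / n_docs for w in survivors}
            thresh = float(
                np.quantile(list(mean_tfidf.values()), tfidf_policy.min_mean_tfidf_quantile)
            )
            removed |= {w for w, v in mean_tfidf.items() if v < thresh}

    # vocabulary ids in deterministic (sorted) order
    vocab = Vocabulary(sorted(w for w in counts if w not in removed))

    documents: list[Document] = []
    n_empty = 0
    for rec, stems in zip(kept_records, stemmed_docs):
        token_ids = [vocab[w] for w in stems if w in vocab]
        auth_ids = sorted(
            author_index[a]
            for a in record_author_set(rec, roster)
            if a in author_index
        )
        if not token_ids or not auth_ids:
            n_empty += 1
            continue
        documents.append(
            Document(
                tokens=np.asarray(token_ids, dtype=np.int32),
                authors=np.asarray(auth_ids, dtype=np.int32),
                year=rec.year,
                journal=rec.journal,
                record_id=rec.record_id,
            )
        )
    if n_empty:
        logger.info("dropped %d documents empty after filtering", n_empty)
    if not documents:
        raise ValueError("empty corpus: every document removed by filtering")
    corpus = Corpus(documents, vocab, author_index)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# corpus bundle persistence (TSV + JSONL directory; bit-exact round trip)
# ---------------------------------------------------------------------------

def save_corpus(corpus: Corpus, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "vocabulary.tsv", "w", encoding="utf-8") as fh:
        for i, w in enumerate(corpus.vocabulary):
            fh.write(f"{i}\t{w}\n")
    with open(out / "authors.tsv", "w", encoding="utf-8") as fh:
        for i, a in enumerate(corpus.authors):
            fh.write(f"{i}\t{a}\n")
    with open(out / "documents.jsonl", "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            fh.write(json.dumps({
                "tokens": d.tokens.tolist(),
                "authors": d.authors.tolist(),
                "year": d.year,
                "journal": d.journal,
                "record_id": d.record_id,
            }) + "\n")


def load_corpus(in_dir: str | Path) -> Corpus:
    src = Path(in_dir)
    vocab = Vocabulary()
    with open(src / "vocabulary.tsv", encoding="utf-8") as fh:
        for line in fh:
            _, w = line.rstrip("\n").split("\t")
            vocab.add(w)
    authors = AuthorIndex()
    with open(src / "authors.tsv", encoding="utf-8") as fh:
        for line in fh:
            _, a = line.rstrip("\n").split("\t")
            authors.add(a)
    documents = []
    with open(src / "documents.jsonl", encoding="utf-8") as fh:
        for line in fh:
            obj = json.loads(line)
            documents.append(Document(
                tokens=np.asarray(obj["tokens"], dtype=np.int32),
                authors=np.asarray(obj["authors"], dtype=np.int32),
                year=obj["year"],
                journal=obj["journal"],
                record_id=obj["record_id"],
            ))
    return Corpus(documents, vocab, authors)
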