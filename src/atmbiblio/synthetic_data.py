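"""Synthetic corpora from the author-topic generative process.

Generates ground-truth parameter sets (θ*, φ* from symmetric Dirichlets),
samples corpora token by token (author uniform over the document's author
set, topic from the author's θ* column, word from the topic's φ* column),
and fabricates citation-record fixtures so ingestion and bibliometric
analytics are testable without any external data.

The synthetic vocabulary uses pronounceable fake stems chosen to be fixed
points of the Porter stemmer, so a synthetic abstract survives the
preprocessing pipeline with its vocabulary intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._porter import porter_stem
from .corpus_io import AuthorIndex, CitationRecord, Corpus, Document, Vocabulary


@dataclass
class GroundTruth:
    """Known ATM parameters plus the document frame they generate into."""

    theta: np.ndarray               # [T, A], author columns sum to 1
    phi: np.ndarray                 # [W, T], topic columns sum to 1
    author_pool: list[str]
    vocabulary: list[str]
    doc_author_sets: list[np.ndarray]   # per-document author ids, non-empty
    doc_lengths: list[int]
    seed: int
    years: list[int] | None = None      # optional per-document metadata
    journals: list[str] | None = None

    @property
    def T(self) -> int:
        return self.theta.shape[0]

    @property
    def W(self) -> int:
        return self.phi.shape[0]

    @property
    def A(self) -> int:
        return self.theta.shape[1]

    @property
    def D(self) -> int:
        return len(self.doc_author_sets)

    def validate(self) -> None:
        if not np.allclose(self.theta.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("theta columns must sum to 1")
        if not np.allclose(self.phi.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("phi columns must sum to 1")
        if any(len(s) == 0 for s in self.doc_author_sets):
            raise ValueError("empty document author set")
        if any(n <= 0 for n in self.doc_lengths):
            raise ValueError("zero-length document")


# ---------------------------------------------------------------------------
# fake stems stable under the Porter stemmer
# ---------------------------------------------------------------------------

_CONS = "bdfgklmnprtz"
_VOWS = "aeiou"


def synthetic_vocabulary(W: int) -> list[str]:
    """W distinct pronounceable CVCVC stems, each a Porter fixed point."""
    stems: list[str] = []
    seen = set()
    for c1 in _CONS:
        for v1 in _VOWS:
            for c2 in _CONS:
                for v2 in _VOWS:
                    for c3 in "kmpt":  # endings that trigger no suffix rule
                        w = c1 + v1 + c2 + v2 + c3
                        if w in seen or porter_stem(w) != w:
                            continue
                        seen.add(w)
                        stems.append(w)
                        if len(stems) == W:
                            return stems
    raise ValueError(f"cannot build {W} stable stems")


def _author_names(A: int) -> list[str]:
    surnames = ["varga", "okafor", "lindt", "moreau", "tanaka", "silva", "novak",
                "haddad", "bergman", "osei", "kumar", "petrov", "duran", "meier"]
    names = []
    for i in range(A):
        surname = surnames[i % len(surnames)]
        suffix = "" if i < len(surnames) else str(i // len(surnames))
        names.append(f"{surname}{suffix} {'abcdefghijklmnopqrstuvwxyz'[i % 26]}")
    return names


# ---------------------------------------------------------------------------
# scenario construction
# ---------------------------------------------------------------------------

def make_recovery_scenario(
    T: int, W: int, A: int, D: int, doc_len: int,
    concentration: float = 0.05, seed: int = 0,
) -> GroundTruth:
    """Ground truth for parameter-recovery experiments.

    θ* and φ* columns are drawn from symmetric Dirichlet(concentration); a
    low concentration yields well-separated, near-sparse topics. Each
    document gets 1-3 authors drawn without replacement.
    """
    if min(T, W, A, D, doc_len) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    theta = rng.dirichlet([concentration] * T, size=A).T        # [T, A]
    phi = rng.dirichlet([concentration] * W, size=T).T          # [W, T]
    doc_author_sets = []
    for _ in range(D):
        k = int(rng.integers(1, min(3, A) + 1))
        doc_author_sets.append(np.sort(rng.choice(A, size=k, replace=False)).astype(np.int32))
    truth = GroundTruth(
        theta=theta, phi=phi,
        author_pool=_author_names(A),
        vocabulary=synthetic_vocabulary(W),
        doc_author_sets=doc_author_sets,
        doc_lengths=[doc_len] * D,
        seed=int(seed),
    )
    truth.validate()
    return truth


def make_trend_scenario(
    years: list[int], target_stem: str, slope: float, base_truth: GroundTruth
) -> dict[int, GroundTruth]:
    """Per-year copies of base_truth with the target stem's φ mass growing.

    For year index i the target word's φ entry in every topic gains
    slope * i before column renormalization, so the analytic statistic
    Σ_k p(k) φ(target|k) strictly increases with year for any fixed p(k).
    """
    try:
        w = base_truth.vocabulary.index(target_stem)
    except ValueError:
        raise ValueError(f"target stem {target_stem!r} not in vocabulary") from None
    out: dict[int, GroundTruth] = {}
    for i, year in enumerate(years):
        phi = base_truth.phi.copy()
        phi[w, :] += slope * i
        if (phi < 0).any():
            raise ValueError("infeasible slope: negative probability mass")
        phi /= phi.sum(axis=0, keepdims=True)
        truth = GroundTruth(
            theta=base_truth.theta, phi=phi,
            author_pool=base_truth.author_pool,
            vocabulary=base_truth.vocabulary,
            doc_author_sets=base_truth.doc_author_sets,
            doc_lengths=base_truth.doc_lengths,
            seed=base_truth.seed + i,
            years=[year] * base_truth.D,
        )
        truth.validate()
        out[year] = truth
    return out


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_corpus(truth: GroundTruth) -> Corpus:
    """Draw a corpus from the generative chain author -> topic -> word."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    vocab = Vocabulary(truth.vocabulary)
    authors = AuthorIndex(truth.author_pool)
    theta_cdf = np.cumsum(truth.theta, axis=0)      # [T, A]
    phi_cdf = np.cumsum(truth.phi, axis=0)          # [W, T]
    documents = []
    for d in range(truth.D):
        auth_set = truth.doc_author_sets[d]
        n = truth.doc_lengths[d]
        chosen_authors = auth_set[rng.integers(0, len(auth_set), size=n)]
        u_t = rng.random(n)
        u_w = rng.random(n)
        topics = np.empty(n, dtype=np.int64)
        words = np.empty(n, dtype=np.int32)
        for i in range(n):
            topics[i] = np.searchsorted(theta_cdf[:, chosen_authors[i]], u_t[i])
            words[i] = np.searchsorted(phi_cdf[:, topics[i]], u_w[i])
        documents.append(Document(
            tokens=words,
            authors=np.asarray(auth_set, dtype=np.int32),
            year=truth.years[d] if truth.years else 2000 + d % 14,
            journal=truth.journals[d] if truth.journals else f"synthetic journal {d % 5}",
            record_id=f"SYN{d:06d}",
        ))
    corpus = Corpus(documents, vocab, authors)
    corpus.validate()
    return corpus


def author_word_marginal(truth: GroundTruth, author: int) -> np.ndarray:
    """Analytic word distribution for one author: Σ_t θ*_ta φ*_wt."""
    return truth.phi @ truth.theta[:, author]


# ---------------------------------------------------------------------------
# citation-record fixtures
# ---------------------------------------------------------------------------

def make_fixture_citations(
    n: int,
    n_journals: int = 3,
    year_range: tuple[int, int] = (2000, 2013),
    mesh_pool: list[str] | None = None,
    seed: int = 0,
    journal_quotas: dict[str, int] | None = None,
) -> list[CitationRecord]:
    """Synthetic citation records with abstracts drawn from an ATM corpus.

    journal_quotas, if given, fixes exact per-journal record counts
    (overriding n_journals; quota values must sum to n).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    if mesh_pool is None:
        mesh_pool = [f"Mesh Heading {i}" for i in range(12)]
    rng = np.random.default_rng(seed)
    truth = make_recovery_scenario(
        T=3, W=40, A=max(4, min(10, n)), D=n, doc_len=30,
        concentration=0.1, seed=seed,
    )
    corpus = sample_corpus(truth)
    if journal_quotas is not None:
        if sum(journal_quotas.values()) != n:
            raise ValueError("journal quotas must sum to n")
        journals = [j for j, q in journal_quotas.items() for _ in range(q)]
    else:
        labels = [f"Journal of Synthetic Studies {i}" for i in range(n_journals)]
        journals = [labels[int(rng.integers(n_journals))] for _ in range(n)]
    records = []
    for d in range(n):
        doc = corpus.documents[d]
        abstract = " ".join(truth.vocabulary[w] for w in doc.tokens)
        author_names = [truth.author_pool[a] for a in doc.authors]
        n_mesh = int(rng.integers(0, 6))
        mesh = sorted(rng.choice(mesh_pool, size=n_mesh, replace=False).tolist())
        records.append(CitationRecord(
            record_id=f"FIX{d:06d}",
            title=f"synthetic record {d}",
            abstract=abstract,
            authors=author_names,
            journal=journals[d],
            year=int(rng.integers(year_range[0], year_range[1] + 1)),
            mesh_terms=mesh,
        ))
    return records
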