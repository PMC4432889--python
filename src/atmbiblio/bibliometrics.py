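"""Descriptive and network analytics over records and fitted models.

Covers the reporting layer of an author-topic study: journal and yearly
distributions (with MeSH-heading diversity), and the author-topic bipartite
network derived from θ by thresholding — an author is linked to every topic
holding more than a threshold share (default 0.01) of their topic
distribution — plus the summaries read off that network: dominant-topic
counts, topic co-occurrence within authors, and the involvement histogram.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .corpus_io import CitationRecord


@dataclass
class AuthorTopicNetwork:
    """Bipartite author <-> topic edges (author id, topic id, weight θ_ta)."""

    edges: list[tuple[int, int, float]]
    threshold: float
    n_topics: int
    n_authors: int

    def author_degrees(self) -> Counter:
        deg: Counter = Counter()
        for a, _, _ in self.edges:
            deg[a] += 1
        return deg

    def author_topics(self) -> dict[int, list[int]]:
        topics: dict[int, list[int]] = {}
        for a, t, _ in self.edges:
            topics.setdefault(a, []).append(t)
        return topics


def top_author_network(theta: np.ndarray, threshold: float = 0.01) -> AuthorTopicNetwork:
    """Edge (a, t) iff θ_ta > threshold (strict: 'more than' the cutoff).

    theta is [T, A] with author columns normalized.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    T, A = theta.shape
    ts, as_ = np.nonzero(theta > threshold)
    edges = [(int(a), int(t), float(theta[t, a])) for t, a in zip(ts, as_)]
    edges.sort()
    return AuthorTopicNetwork(edges=edges, threshold=threshold, n_topics=T, n_authors=A)


def dominant_topic_counts(theta: np.ndarray) -> np.ndarray:
    """Per-topic count of authors whose maximal θ is that topic.

    Ties go to the lowest topic index; counts sum to the author count.
    """
    dominant = np.argmax(theta, axis=0)  # argmax takes the first max
    return np.bincount(dominant, minlength=theta.shape[0])


def author_topic_cooccurrence(network: AuthorTopicNetwork) -> dict[tuple[int, int], int]:
    """For each unordered topic pair, how many authors link to both.

    An author linked to k topics contributes to C(k, 2) pairs.
    """
    counts: Counter = Counter()
    for topics in network.author_topics().values():
        for t1, t2 in combinations(sorted(topics), 2):
            counts[(t1, t2)] += 1
    return dict(counts)


def topic_involvement_histogram(network: AuthorTopicNetwork) -> dict[int, int]:
    """{number of linked topics -> number of authors}, over authors with >= 1 edge."""
    return dict(Counter(network.author_degrees().values()))


def journal_distribution(
    records: Sequence[CitationRecord], min_articles: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Per-journal article counts and ratios, plus a coverage summary.

    The summary reports how many journals reach *min_articles*, their total
    article count and that total's share of all records.
    """
    counts = Counter(rec.journal for rec in records)
    total = sum(counts.values())
    table = pd.DataFrame(
        [(j, c, c / total if total else 0.0) for j, c in counts.items()],
        columns=["journal", "count", "ratio"],
    ).sort_values(["count", "journal"], ascending=[False, True], ignore_index=True)
    covered = table[table["count"] >= min_articles]
    summary = {
        "n_journals": int(len(table)),
        "n_journals_at_least_min": int(len(covered)),
        "covered_articles": int(covered["count"].sum()),
        "covered_share": float(covered["count"].sum() / total) if total else 0.0,
    }
    return table, summary


@dataclass
class YearlyDistribution:
    """Per-year record counts and distinct MeSH-heading counts, years ascending."""

    table: pd.DataFrame  # columns: year, n_records, n_distinct_mesh


def yearly_distribution(records: Sequence[CitationRecord]) -> YearlyDistribution:
    """Count records and distinct MeSH headings per year.

    Records without a year are excluded from this view; MeSH diversity uses
    only records that carry headings.
    """
    by_year_count: Counter = Counter()
    by_year_mesh: dict[int, set] = {}
    for rec in records:
        if rec.year is None:
            continue
        by_year_count[rec.year] += 1
        if rec.mesh_terms:
            by_year_mesh.setdefault(rec.year, set()).update(rec.mesh_terms)
    years = sorted(by_year_count)
    table = pd.DataFrame({
        "year": years,
        "n_records": [by_year_count[y] for y in years],
        "n_distinct_mesh": [len(by_year_mesh.get(y, ())) for y in years],
    })
    return YearlyDistribution(table=table)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def to_networkx(
    network: AuthorTopicNetwork,
    author_names: Sequence[str] | None = None,
    topic_labels: Sequence[str] | None = None,
) -> nx.Graph:
    """Bipartite graph with 'kind' node attributes ('author'/'topic')."""
    g = nx.Graph()
    def aname(a): return author_names[a] if author_names else f"author_{a}"
    def tname(t): return topic_labels[t] if topic_labels else f"T{t}"
    for a, t, w in network.edges:
        g.add_node(aname(a), kind="author")
        g.add_node(tname(t), kind="topic")
        g.add_edge(aname(a), tname(t), weight=w)
    return g


def export_network(
    network: AuthorTopicNetwork,
    out_dir: str | Path,
    author_names: Sequence[str] | None = None,
) -> None:
    """Write the edge list as TSV and the bipartite graph as GraphML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("author\ttopic\tweight\n")
        for a, t, w in network.edges:
            name = author_names[a] if author_names else str(a)
            fh.write(f"{name}\tT{t}\t{w:.17g}\n")
    nx.write_graphml(to_networkx(network, author_names), out / "network.graphml")
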