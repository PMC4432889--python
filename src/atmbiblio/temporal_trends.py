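"""Temporal keyword trends from per-year author-topic fits.

Records are sliced by publication year, an ATM is fitted to each year's
slice with a shared configuration, and each keyword w is scored by

    Σ_k p(k) · p(w|k)

where p(k) is the corpus-level proportion of topic k (token-assignment
share from the retained Gibbs samples) and p(w|k) = φ_wk. The series of
that statistic over years is the keyword's trend. Because each year is
fitted on its own vocabulary, proportions are not strictly comparable
across years when vocabularies differ; see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .atm_sampler import FitConfig, FittedATM, GibbsState, fit
from .corpus_io import CitationRecord, Corpus, TfidfPolicy, preprocess_corpus
from ._porter import porter_stem

logger = logging.getLogger("atmbiblio")


@dataclass
class TopicProportions:
    """Corpus-level topic shares p(k); non-negative, summing to 1."""

    p_k: np.ndarray


@dataclass
class TrendSeries:
    keyword: str
    points: list[tuple[int, float]]  # (year, proportion), years strictly increasing


def topic_proportions(state: GibbsState) -> TopicProportions:
    """p_k = (tokens assigned to topic k) / (total tokens)."""
    totals = state.topic_totals().astype(float)
    return TopicProportions(p_k=totals / totals.sum())


def topic_proportions_from_model(model: FittedATM) -> TopicProportions:
    """Mean of θ over authors — the alternative p(k) definition."""
    p = model.theta.mean(axis=1)
    return TopicProportions(p_k=p / p.sum())


def keyword_proportion(
    model: FittedATM, proportions: TopicProportions, keyword: str
) -> float:
    """Σ_k p(k) · φ_wk for the stemmed keyword; 0 if out of vocabulary.

    Multi-word keywords score as the mean of their constituent stems.
    """
    stems = [porter_stem(part.casefold()) for part in keyword.split()]
    values = []
    for stem in stems:
        try:
            w = model.vocabulary.index(stem)
        except ValueError:
            logger.warning("keyword stem %r not in vocabulary; scored 0", stem)
            values.append(0.0)
            continue
        values.append(float(proportions.p_k @ model.phi[w, :]))
    return float(np.mean(values)) if values else 0.0


def slice_by_year(
    records: Sequence[CitationRecord], year_range: tuple[int, int]
) -> dict[int, list[CitationRecord]]:
    """Partition dated records into per-year lists within [start, end]."""
    start, end = year_range
    slices: dict[int, list[CitationRecord]] = {}
    for rec in records:
        if rec.year is not None and start <= rec.year <= end:
            slices.setdefault(rec.year, []).append(rec)
    return dict(sorted(slices.items()))


def fit_yearly(
    corpora: dict[int, Corpus], T: int, fit_config: FitConfig, seed: int
) -> dict[int, tuple[FittedATM, TopicProportions]]:
    """Fit one ATM per year; T is clamped to the year's vocabulary if smaller."""
    out: dict[int, tuple[FittedATM, TopicProportions]] = {}
    for year, corpus in corpora.items():
        T_year = T
        if corpus.W < T:
            T_year = corpus.W
            logger.warning(
                "year %d vocabulary %d smaller than T=%d; clamping", year, corpus.W, T
            )
        hyper = fit_config.hyper(T_year)
        model, state = fit(
            corpus, hyper, n_sweeps=fit_config.n_sweeps,
            burn_in=fit_config.burn_in, thin=fit_config.thin, seed=seed,
            return_state=True,
        )
        out[year] = (model, topic_proportions(state))
    return out


def trend_series_from_corpora(
    corpora: dict[int, Corpus],
    keywords: Sequence[str],
    T: int,
    fit_config: FitConfig | None = None,
    seed: int = 0,
) -> list[TrendSeries]:
    """Per-keyword trend over pre-built yearly corpora (shared fit config)."""
    if fit_config is None:
        fit_config = FitConfig()
    fits = fit_yearly(dict(sorted(corpora.items())), T, fit_config, seed)
    series = []
    for kw in keywords:
        points = [
            (year, keyword_proportion(model, props, kw))
            for year, (model, props) in fits.items()
        ]
        series.append(TrendSeries(keyword=kw, points=points))
    return series


def trend_series(
    records: Sequence[CitationRecord],
    keywords: Sequence[str],
    year_range: tuple[int, int],
    T: int,
    fit_config: FitConfig | None = None,
    seed: int = 0,
    stopwords=None,
    min_count: int = 2,
    tfidf_policy: TfidfPolicy | None = None,
) -> list[TrendSeries]:
    """Slice records by year, preprocess and fit each slice, score keywords.

    Years with no usable records are skipped with a warning; an entirely
    empty range is an error.
    """
    slices = slice_by_year(records, year_range)
    corpora: dict[int, Corpus] = {}
    for year, recs in slices.items():
        try:
            corpora[year] = preprocess_corpus(
                recs, stopwords=stopwords, min_count=min_count, tfidf_policy=tfidf_policy
            )
        except ValueError:
            logger.warning("year %d: no usable documents; skipped", year)
    if not corpora:
        raise ValueError("no year in range produced a usable corpus")
    return trend_series_from_corpora(corpora, keywords, T, fit_config, seed)
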