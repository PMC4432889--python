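"""Model evaluation: held-out perplexity, PMI topic coherence, grid search.

Perplexity is exp of the negative mean held-out token log-likelihood,
    perplexity(D_test) = exp( -Σ_d log p(w_d) / Σ_d N_d ),
lower is better; a uniform single-topic model over W words scores exactly W.

Coherence of a topic's top-N words uses document-level co-occurrence:
    C = 2/(N(N-1)) Σ_{i<j} PMI(w_i, w_j),
    PMI(w_i, w_j) = log( (P(w_i, w_j) + ε) / (P(w_i) P(w_j)) ),
with P(.) the fraction of reference documents containing the word(s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .atm_sampler import FitConfig, FittedATM, fit
from .corpus_io import Corpus

logger = logging.getLogger("atmbiblio")


@dataclass
class PerplexityResult:
    value: float
    n_test_docs: int
    n_test_tokens: int
    method: str


@dataclass
class CoherenceConfig:
    top_n: int = 20
    epsilon: float = 1e-12

    def __post_init__(self):
        if self.top_n < 2:
            raise ValueError("top_n must be >= 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class GridSearchResult:
    candidates: list[int]
    per_T_perplexity: list[tuple[int, float]]
    selected_T: int
    models: dict[int, FittedATM] = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# perplexity
# ---------------------------------------------------------------------------

def perplexity(
    model: FittedATM, test_corpus: Corpus, method: str = "uniform-author-mixture",
    fold_in_sweeps: int = 50, seed: int = 0,
) -> PerplexityResult:
    """Held-out perplexity of *model* on *test_corpus*.

    'uniform-author-mixture' (default) scores each token by
    p(w|d) = (1/|A_d|) Σ_{a∈A_d} Σ_t θ_ta φ_wt, the marginal the generative
    process implies; authors with no training tokens carry the prior-mean
    uniform θ column. 'fold-in' resamples held-out assignments by Gibbs with
    φ frozen at the trained estimate, then scores the same mixture with the
    folded-in θ.

    Token ids must refer to the model's vocabulary (use a shared Vocabulary
    for train/test splits); ids outside it are dropped with a logged count.
    """
    if test_corpus.D == 0:
        raise ValueError("empty test corpus")
    if method == "uniform-author-mixture":
        theta = model.theta
    elif method == "fold-in":
        theta = _fold_in_theta(model, test_corpus, fold_in_sweeps, seed)
    else:
        raise ValueError(f"unknown perplexity method: {method!r}")

    word_given_author = model.phi @ theta  # [W, A]
    total_log = 0.0
    n_tokens = 0
    n_oov = 0
    for doc in test_corpus.documents:
        tokens = doc.tokens
        in_vocab = tokens < model.W
        n_oov += int((~in_vocab).sum())
        tokens = tokens[in_vocab]
        if tokens.size == 0:
            continue
        p_w = word_given_author[:, doc.authors].mean(axis=1)  # uniform over A_d
        total_log += float(np.log(p_w[tokens]).sum())
        n_tokens += tokens.size
    if n_oov:
        logger.info("dropped %d out-of-vocabulary test tokens", n_oov)
    if n_tokens == 0:
        raise ValueError("no scorable tokens in test corpus")
    return PerplexityResult(
        value=float(np.exp(-total_log / n_tokens)),
        n_test_docs=test_corpus.D,
        n_test_tokens=n_tokens,
        method=method,
    )


def _fold_in_theta(
    model: FittedATM, test_corpus: Corpus, n_sweeps: int, seed: int
) -> np.ndarray:
    """Gibbs over held-out (z, y) with φ frozen; returns the folded-in θ."""
    rng = np.random.default_rng(seed)
    T, A = model.T, model.A
    alpha = model.hyper.alpha
    n_ta = np.zeros((T, A))
    assignments = []  # (doc_idx, token_idx, t, a)
    for di, doc in enumerate(test_corpus.documents):
        for ti, w in enumerate(doc.tokens):
            if w >= model.W:
                continue
            t = int(rng.integers(T))
            a = int(doc.authors[rng.integers(len(doc.authors))])
            n_ta[t, a] += 1
            assignments.append([di, int(w), t, a])
    for _ in range(n_sweeps):
        for rec in assignments:
            di, w, t, a = rec
            doc = test_corpus.documents[di]
            n_ta[t, a] -= 1
            probs = model.phi[w, :, None] * (
                (n_ta[:, doc.authors] + alpha)
                / (n_ta[:, doc.authors].sum(axis=0) + T * alpha)
            )
            probs = probs.ravel() / probs.sum()
            sel = rng.choice(probs.size, p=probs)
            t, a = int(sel // len(doc.authors)), int(doc.authors[sel % len(doc.authors)])
            rec[2], rec[3] = t, a
            n_ta[t, a] += 1
    return (n_ta + alpha) / (n_ta.sum(axis=0, keepdims=True) + T * alpha)


# ---------------------------------------------------------------------------
# PMI coherence
# ---------------------------------------------------------------------------

def top_words(model: FittedATM, topic: int, top_n: int) -> np.ndarray:
    """Ids of the topic's top_n highest-φ words; ties broken by lower word id."""
    col = model.phi[:, topic]
    # stable sort on -phi keeps lower ids first among ties
    return np.argsort(-col, kind="stable")[:top_n]


def pmi_coherence(
    model: FittedATM, reference_corpus: Corpus, config: CoherenceConfig | None = None
) -> tuple[np.ndarray, float]:
    """Per-topic PMI coherence over the reference corpus and its mean.

    Probabilities are document-level occurrence frequencies. Every top word
    must occur somewhere in the reference corpus.
    """
    if config is None:
        config = CoherenceConfig()
    if config.top_n > model.W:
        raise ValueError("top_n exceeds vocabulary size")
    D = reference_corpus.D
    doc_sets = [set(doc.tokens.tolist()) for doc in reference_corpus.documents]
    scores = np.empty(model.T)
    for t in range(model.T):
        words = top_words(model, t, config.top_n)
        present = [[w in s for s in doc_sets] for w in words]
        p_single = np.array([sum(p) / D for p in present])
        if (p_single == 0).any():
            missing = [int(w) for w, p in zip(words, p_single) if p == 0]
            raise ValueError(f"top words {missing} absent from reference corpus")
        total = 0.0
        n = len(words)
        for i in range(n - 1):
            for j in range(i + 1, n):
                p_joint = sum(a and b for a, b in zip(present[i], present[j])) / D
                total += np.log((p_joint + config.epsilon) / (p_single[i] * p_single[j]))
        scores[t] = 2.0 * total / (n * (n - 1))
    return scores, float(scores.mean())


# ---------------------------------------------------------------------------
# topic alignment (label switching)
# ---------------------------------------------------------------------------

def align_topics(phi_est: np.ndarray, phi_ref: np.ndarray) -> np.ndarray:
    """Optimal topic matching between two [W, T] word-topic matrices.

    Solves the assignment problem on pairwise L1 distance (topic labels are
    exchangeable under the posterior, so estimates are compared up to
    permutation). Returns perm with perm[j] = estimated topic matched to
    reference topic j.
    """
    from scipy.optimize import linear_sum_assignment

    T = phi_ref.shape[1]
    cost = np.array([
        [np.abs(phi_est[:, i] - phi_ref[:, j]).sum() for j in range(T)]
        for i in range(T)
    ])
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(T, dtype=int)
    perm[cols] = rows
    return perm


# ---------------------------------------------------------------------------
# grid search over T
# ---------------------------------------------------------------------------

def holdout_split(corpus: Corpus, fraction: float, seed: int) -> tuple[Corpus, Corpus]:
    """Deterministic shuffle split sharing vocabulary and author index."""
    if not 0 < fraction < 1:
        raise ValueError("holdout fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(corpus.D)
    n_test = max(1, int(round(fraction * corpus.D)))
    if n_test >= corpus.D:
        raise ValueError("holdout fraction leaves no training documents")
    test_idx = set(order[:n_test].tolist())
    train = [d for i, d in enumerate(corpus.documents) if i not in test_idx]
    test = [d for i, d in enumerate(corpus.documents) if i in test_idx]
    return (
        Corpus(train, corpus.vocabulary, corpus.authors),
        Corpus(test, corpus.vocabulary, corpus.authors),
    )


def select_T(
    corpus: Corpus,
    candidates: list[int],
    split: float = 0.2,
    fit_config: FitConfig | None = None,
    seed: int = 0,
    method: str = "uniform-author-mixture",
    keep_models: bool = False,
) -> GridSearchResult:
    """Pick the topic number minimizing held-out perplexity (ties -> smallest T)."""
    if not candidates:
        raise ValueError("no candidate T values")
    if any(T <= 0 for T in candidates):
        raise ValueError("candidate T must be positive")
    if fit_config is None:
        fit_config = FitConfig()
    train, test = holdout_split(corpus, split, seed)
    results: list[tuple[int, float]] = []
    models: dict[int, FittedATM] = {}
    for T in candidates:
        model = fit(
            train, fit_config.hyper(T), n_sweeps=fit_config.n_sweeps,
            burn_in=fit_config.burn_in, thin=fit_config.thin, seed=seed,
        )
        value = perplexity(model, test, method=method, seed=seed).value
        results.append((T, value))
        if keep_models:
            models[T] = model
        logger.info("grid search T=%d: holdout perplexity %.3f", T, value)
    best = min(results, key=lambda tv: (tv[1], tv[0]))[0]
    return GridSearchResult(
        candidates=list(candidates), per_T_perplexity=results,
        selected_T=int(best), models=models,
    )
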