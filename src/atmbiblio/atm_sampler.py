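"""Collapsed Gibbs sampling for the author-topic model.

Each token of document d is explained by a latent (topic t, author a) pair
with a in the document's author set A_d. With the author-topic Dirichlet
priors integrated out, the Gibbs conditional for one token (word w, counts
with that token removed) is

    P(z=t, y=a | ...) ∝ (N_wt + β)/(N_.t + Wβ) · (N_ta + α)/(N_.a + Tα)

over the T × |A_d| support, where N^WT and N^TA are the word-topic and
topic-author count matrices. Point estimates follow the smoothed count
ratios

    θ_ta = (N_ta + α)/(N_.a + Tα)    (topic given author)
    φ_wt = (N_wt + β)/(N_.t + Wβ)    (word given topic)

averaged over thinned post-burn-in samples. A (t, a) pair is drawn jointly
as one categorical draw, matching the conditional exactly.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .corpus_io import Corpus

logger = logging.getLogger("atmbiblio")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hyperparameters:
    """Model dimensions and symmetric Dirichlet priors."""

    T: int
    alpha: float
    beta: float

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @classmethod
    def with_default_priors(cls, T: int, beta: float = 0.01) -> "Hyperparameters":
        """alpha = 50/T, beta = 0.01 — the conventional ATM settings."""
        return cls(T=T, alpha=50.0 / T, beta=beta)


@dataclass
class GibbsState:
    """Per-token assignments plus the count matrices they tally.

    Tokens are stored flattened in document order; ``doc_offsets[d]`` is the
    first flat index of document d, so (doc, pos) maps to
    ``doc_offsets[doc] + pos``.
    """

    z: np.ndarray            # int32[n] topic assignment per token
    y: np.ndarray            # int32[n] author assignment per token
    n_wt: np.ndarray         # int64[W, T] word-topic counts
    n_ta: np.ndarray         # int64[T, A] topic-author counts
    token_word: np.ndarray   # int32[n] word id per token
    token_doc: np.ndarray    # int32[n] document index per token
    doc_offsets: np.ndarray  # int64[D+1]
    auth_flat: np.ndarray    # int32 concatenated per-document author sets
    auth_offsets: np.ndarray  # int64[D+1]
    rng_seed: int
    n_sweeps_done: int = 0

    @property
    def n_tokens(self) -> int:
        return int(self.z.shape[0])

    def topic_totals(self) -> np.ndarray:
        return self.n_wt.sum(axis=0)

    def author_totals(self) -> np.ndarray:
        return self.n_ta.sum(axis=0)

    def recount(self) -> tuple[np.ndarray, np.ndarray]:
        """Re-tally N^WT and N^TA directly from (z, y); consistency oracle."""
        W, T = self.n_wt.shape
        A = self.n_ta.shape[1]
        n_wt = np.zeros((W, T), dtype=np.int64)
        n_ta = np.zeros((T, A), dtype=np.int64)
        for w, t, a in zip(self.token_word, self.z, self.y):
            n_wt[w, t] += 1
            n_ta[t, a] += 1
        return n_wt, n_ta

    def check_consistency(self) -> None:
        n_wt, n_ta = self.recount()
        if not (np.array_equal(n_wt, self.n_wt) and np.array_equal(n_ta, self.n_ta)):
            raise RuntimeError("corrupted state: counts disagree with assignments")


@dataclass
class FittedATM:
    """Posterior point estimates with their provenance."""

    theta: np.ndarray        # [T, A] p(t | a); columns sum to 1
    phi: np.ndarray          # [W, T] p(w | t); columns sum to 1
    hyper: Hyperparameters
    n_sweeps: int
    seed: int
    log_likelihood: np.ndarray = field(default_factory=lambda: np.empty(0))
    vocabulary: list[str] = field(default_factory=list)
    author_names: list[str] = field(default_factory=list)

    @property
    def T(self) -> int:
        return self.theta.shape[0]

    @property
    def W(self) -> int:
        return self.phi.shape[0]

    @property
    def A(self) -> int:
        return self.theta.shape[1]


@dataclass
class FitConfig:
    """Sweep schedule shared by grid search and per-year trend fits.

    alpha='auto' resolves to 50/T for each candidate T.
    """

    n_sweeps: int = 200
    burn_in: int | None = None      # None -> n_sweeps // 2
    thin: int = 5
    alpha: float | str = "auto"
    beta: float = 0.01

    def hyper(self, T: int) -> Hyperparameters:
        alpha = 50.0 / T if self.alpha == "auto" else float(self.alpha)
        return Hyperparameters(T=T, alpha=alpha, beta=self.beta)


# ---------------------------------------------------------------------------
# flattening and initialization
# ---------------------------------------------------------------------------

def _flatten(corpus: Corpus):
    doc_lens = corpus.doc_lengths()
    doc_offsets = np.zeros(corpus.D + 1, dtype=np.int64)
    np.cumsum(doc_lens, out=doc_offsets[1:])
    token_word = np.concatenate([d.tokens for d in corpus.documents]).astype(np.int32)
    token_doc = np.repeat(np.arange(corpus.D, dtype=np.int32), doc_lens)
    auth_lens = np.array([len(d.authors) for d in corpus.documents], dtype=np.int64)
    auth_offsets = np.zeros(corpus.D + 1, dtype=np.int64)
    np.cumsum(auth_lens, out=auth_offsets[1:])
    auth_flat = np.concatenate([d.authors for d in corpus.documents]).astype(np.int32)
    return token_word, token_doc, doc_offsets, auth_flat, auth_offsets


def init_state(corpus: Corpus, hyper: Hyperparameters, seed: int) -> GibbsState:
    """Uniform random topic per token and uniform author from its document's set."""
    if corpus.D == 0 or corpus.n_tokens == 0:
        raise ValueError("empty corpus")
    token_word, token_doc, doc_offsets, auth_flat, auth_offsets = _flatten(corpus)
    n = token_word.shape[0]
    rng = np.random.default_rng(seed)
    z = rng.integers(0, hyper.T, size=n).astype(np.int32)
    y = np.empty(n, dtype=np.int32)
    for d in range(corpus.D):
        lo, hi = doc_offsets[d], doc_offsets[d + 1]
        alo, ahi = auth_offsets[d], auth_offsets[d + 1]
        y[lo:hi] = auth_flat[alo + rng.integers(0, ahi - alo, size=hi - lo)]
    n_wt = np.zeros((corpus.W, hyper.T), dtype=np.int64)
    n_ta = np.zeros((hyper.T, corpus.A), dtype=np.int64)
    np.add.at(n_wt, (token_word, z), 1)
    np.add.at(n_ta, (z, y), 1)
    return GibbsState(
        z=z, y=y, n_wt=n_wt, n_ta=n_ta,
        token_word=token_word, token_doc=token_doc, doc_offsets=doc_offsets,
        auth_flat=auth_flat, auth_offsets=auth_offsets, rng_seed=int(seed),
    )


# ---------------------------------------------------------------------------
# conditional distribution (reference implementation, used by tests and
# single-token reasoning; the sweep kernel below applies the same formula)
# ---------------------------------------------------------------------------

def conditional_distribution(
    state: GibbsState, corpus: Corpus, doc: int, pos: int, hyper: Hyperparameters
) -> np.ndarray:
    """Joint conditional over (topic, author-slot) for one held-out token.

    Precondition: the token at (doc, pos) has already been removed from the
    count matrices (the ¬id convention). Returns a [T, |A_d|] table summing
    to 1; column j corresponds to the j-th author id in the document's
    sorted author set.
    """
    if (state.n_wt < 0).any() or (state.n_ta < 0).any():
        raise RuntimeError("corrupted state: negative count (decrement bug)")
    i = int(state.doc_offsets[doc]) + pos
    w = int(state.token_word[i])
    W, T = state.n_wt.shape
    authors = state.auth_flat[state.auth_offsets[doc]:state.auth_offsets[doc + 1]]
    word_factor = (state.n_wt[w, :] + hyper.beta) / (
        state.n_wt.sum(axis=0) + W * hyper.beta
    )  # [T]
    author_factor = (state.n_ta[:, authors] + hyper.alpha) / (
        state.n_ta.sum(axis=0)[authors] + hyper.T * hyper.alpha
    )  # [T, |A_d|]
    table = word_factor[:, None] * author_factor
    return table / table.sum()


# ---------------------------------------------------------------------------
# the sweep kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _chain_kernel(token_word, token_doc, auth_flat, auth_offsets,
                  z, y, n_wt, n_ta, n_t, n_a,
                  alpha, beta, n_sweeps, burn_in, thin, seed,
                  track, tally, loglik, theta_acc, phi_acc):  # pragma: no cover
    np.random.seed(seed)
    W, T = n_wt.shape
    A = n_ta.shape[1]
    n = token_word.shape[0]
    max_a = 0
    for d in range(auth_offsets.shape[0] - 1):
        k = auth_offsets[d + 1] - auth_offsets[d]
        if k > max_a:
            max_a = k
    cum = np.empty(T * max_a, dtype=np.float64)
    n_acc = 0
    for s in range(n_sweeps):
        for i in range(n):
            w = token_word[i]
            d = token_doc[i]
            t0 = z[i]
            a0 = y[i]
            n_wt[w, t0] -= 1
            n_ta[t0, a0] -= 1
            n_t[t0] -= 1
            n_a[a0] -= 1
            lo = auth_offsets[d]
            hi = auth_offsets[d + 1]
            k = hi - lo
            total = 0.0
            idx = 0
            for t in range(T):
                wf = (n_wt[w, t] + beta) / (n_t[t] + W * beta)
                for j in range(lo, hi):
                    a = auth_flat[j]
                    total += wf * (n_ta[t, a] + alpha) / (n_a[a] + T * alpha)
                    cum[idx] = total
                    idx += 1
            u = np.random.random() * total
            sel = idx - 1
            for q in range(idx):
                if u < cum[q]:
                    sel = q
                    break
            t1 = sel // k
            a1 = auth_flat[lo + sel % k]
            z[i] = t1
            y[i] = a1
            n_wt[w, t1] += 1
            n_ta[t1, a1] += 1
            n_t[t1] += 1
            n_a[a1] += 1
        ll = 0.0
        for t in range(T):
            ll += math.lgamma(W * beta) - math.lgamma(n_t[t] + W * beta)
            for w in range(W):
                ll += math.lgamma(n_wt[w, t] + beta) - math.lgamma(beta)
        for a in range(A):
            ll += math.lgamma(T * alpha) - math.lgamma(n_a[a] + T * alpha)
            for t in range(T):
                ll += math.lgamma(n_ta[t, a] + alpha) - math.lgamma(alpha)
        loglik[s] = ll
        if s >= burn_in and (s - burn_in) % thin == 0:
            n_acc += 1
            for a in range(A):
                denom = n_a[a] + T * alpha
                for t in range(T):
                    theta_acc[t, a] += (n_ta[t, a] + alpha) / denom
            for t in range(T):
                denom = n_t[t] + W * beta
                for w in range(W):
                    phi_acc[w, t] += (n_wt[w, t] + beta) / denom
        if track == 1 and s >= burn_in:
            for i in range(n):
                tally[i, z[i] * A + y[i]] += 1
    return n_acc


def _run_chain(state: GibbsState, hyper: Hyperparameters, n_sweeps: int,
               burn_in: int, thin: int, seed: int, track: bool = False):
    """Drive the kernel over an existing state, mutating it in place."""
    W, T = state.n_wt.shape
    A = state.n_ta.shape[1]
    n_t = state.topic_totals().copy()
    n_a = state.author_totals().copy()
    loglik = np.zeros(n_sweeps)
    theta_acc = np.zeros((T, A))
    phi_acc = np.zeros((W, T))
    tally = np.zeros((state.n_tokens if track else 1, T * A), dtype=np.int64)
    n_acc = _chain_kernel(
        state.token_word, state.token_doc, state.auth_flat, state.auth_offsets,
        state.z, state.y, state.n_wt, state.n_ta, n_t, n_a,
        float(hyper.alpha), float(hyper.beta),
        int(n_sweeps), int(burn_in), int(thin), int(seed),
        1 if track else 0, tally, loglik, theta_acc, phi_acc,
    )
    state.n_sweeps_done += n_sweeps
    return n_acc, loglik, theta_acc, phi_acc, tally


def _derive_seed(seed: int, stream: int) -> int:
    # distinct sub-streams below 2**31 for init vs chain vs continued sweeps
    return int((np.uint64(seed) * np.uint64(2654435761) + np.uint64(stream)) % np.uint64(2**31 - 1))


def gibbs_sweep(state: GibbsState, corpus: Corpus, hyper: Hyperparameters) -> GibbsState:
    """One full sweep: every token decremented, resampled jointly, re-added.

    Documents are visited in index order and tokens left to right. The state
    is mutated in place and returned.
    """
    seed = _derive_seed(state.rng_seed, 1 + state.n_sweeps_done)
    _run_chain(state, hyper, n_sweeps=1, burn_in=1, thin=1, seed=seed)
    return state


def fit(
    corpus: Corpus,
    hyper: Hyperparameters,
    n_sweeps: int,
    burn_in: int | None = None,
    thin: int = 5,
    seed: int = 0,
    return_state: bool = False,
) -> FittedATM | tuple[FittedATM, GibbsState]:
    """Fit by collapsed Gibbs sampling; θ and φ averaged over retained samples.

    burn_in defaults to n_sweeps // 2; samples are retained every *thin*
    sweeps after burn-in. (corpus, hyper, seed) determines the result
    bit-for-bit. With return_state=True the final chain state comes back
    alongside the model (for topic-proportion readouts).
    """
    if burn_in is None:
        burn_in = n_sweeps // 2
    if not (n_sweeps > burn_in >= 0):
        raise ValueError("need n_sweeps > burn_in >= 0")
    if hyper.T > corpus.n_tokens:
        logger.warning(
            "T=%d exceeds token count %d: model underdetermined", hyper.T, corpus.n_tokens
        )
    state = init_state(corpus, hyper, _derive_seed(seed, 0))
    n_acc, loglik, theta_acc, phi_acc, _ = _run_chain(
        state, hyper, n_sweeps, burn_in, thin, _derive_seed(seed, 1)
    )
    if not np.isfinite(loglik).all():
        raise RuntimeError("non-finite joint log-likelihood during sampling")
    model = FittedATM(
        theta=theta_acc / n_acc,
        phi=phi_acc / n_acc,
        hyper=hyper,
        n_sweeps=n_sweeps,
        seed=int(seed),
        log_likelihood=loglik,
        vocabulary=corpus.vocabulary.items,
        author_names=corpus.authors.items,
    )
    return (model, state) if return_state else model


# ---------------------------------------------------------------------------
# point estimators
# ---------------------------------------------------------------------------

def estimate_theta(state: GibbsState, hyper: Hyperparameters) -> np.ndarray:
    """θ_ta = (N_ta + α)/(N_.a + Tα); every author column sums to 1."""
    return (state.n_ta + hyper.alpha) / (
        state.author_totals()[None, :] + hyper.T * hyper.alpha
    )


def estimate_phi(state: GibbsState, hyper: Hyperparameters) -> np.ndarray:
    """φ_wt = (N_wt + β)/(N_.t + Wβ); every topic column sums to 1."""
    W = state.n_wt.shape[0]
    return (state.n_wt + hyper.beta) / (state.topic_totals()[None, :] + W * hyper.beta)


def joint_log_likelihood(state: GibbsState, hyper: Hyperparameters) -> float:
    """Collapsed Dirichlet-multinomial joint log P(w, z, y | α, β).

    The uniform author-choice factor Π_d |A_d|^{-N_d} is constant in (z, y)
    and omitted. Invariant under permutation of topic labels.
    """
    from scipy.special import gammaln

    W, T = state.n_wt.shape
    A = state.n_ta.shape[1]
    alpha, beta = hyper.alpha, hyper.beta
    ll = T * gammaln(W * beta) - gammaln(state.topic_totals() + W * beta).sum()
    ll += gammaln(state.n_wt + beta).sum() - W * T * gammaln(beta)
    ll += A * gammaln(T * alpha) - gammaln(state.author_totals() + T * alpha).sum()
    ll += gammaln(state.n_ta + alpha).sum() - T * A * gammaln(alpha)
    return float(ll)


# ---------------------------------------------------------------------------
# exact posterior by exhaustive enumeration (validation utility for tiny
# corpora; shares no code with the sampler)
# ---------------------------------------------------------------------------

def enumerate_exact_posterior(corpus: Corpus, hyper: Hyperparameters) -> np.ndarray:
    """Exact per-token posterior P(z_i = t, y_i = a) for a tiny corpus.

    Enumerates every joint (z, y) configuration, scores it with the collapsed
    Dirichlet-multinomial joint and marginalizes. Returns [n_tokens, T, A].
    Cost is (T · |A_d|)^n configurations: only feasible for ~10 tokens.
    """
    from scipy.special import gammaln

    token_word, token_doc, _, auth_flat, auth_offsets = _flatten(corpus)
    n = token_word.shape[0]
    T, W, A = hyper.T, corpus.W, corpus.A
    alpha, beta = hyper.alpha, hyper.beta
    choices = []
    for i in range(n):
        d = token_doc[i]
        authors = auth_flat[auth_offsets[d]:auth_offsets[d + 1]]
        choices.append([(t, int(a)) for t in range(T) for a in authors])
    n_config = 1
    for c in choices:
        n_config *= len(c)
    if n_config > 2_000_000:
        raise ValueError(f"{n_config} configurations: corpus too large to enumerate")

    log_weights = np.empty(n_config)
    configs = list(itertools.product(*choices))
    for ci, cfg in enumerate(configs):
        n_wt = np.zeros((W, T))
        n_ta = np.zeros((T, A))
        for i, (t, a) in enumerate(cfg):
            n_wt[token_word[i], t] += 1
            n_ta[t, a] += 1
        ll = -gammaln(n_wt.sum(axis=0) + W * beta).sum() + gammaln(n_wt + beta).sum()
        ll += -gammaln(n_ta.sum(axis=0) + T * alpha).sum() + gammaln(n_ta + alpha).sum()
        log_weights[ci] = ll
    log_weights -= log_weights.max()
    weights = np.exp(log_weights)
    weights /= weights.sum()
    marginals = np.zeros((n, T, A))
    for ci, cfg in enumerate(configs):
        wgt = weights[ci]
        for i, (t, a) in enumerate(cfg):
            marginals[i, t, a] += wgt
    return marginals


# ---------------------------------------------------------------------------
# model bundle persistence
# ---------------------------------------------------------------------------

def save_model(model: FittedATM, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def write_matrix(path, matrix, col_labels, row_label):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(row_label + "\t" + "\t".join(col_labels) + "\n")
            for r in range(matrix.shape[0]):
                fh.write(str(r) + "\t" + "\t".join(f"{v:.17g}" for v in matrix[r]) + "\n")

    authors = model.author_names or [str(a) for a in range(model.A)]
    words = model.vocabulary or [str(w) for w in range(model.W)]
    write_matrix(out / "theta.tsv", model.theta, authors, "topic")
    write_matrix(out / "phi.tsv", model.phi, [f"T{t}" for t in range(model.T)], "word")
    with open(out / "model.json", "w", encoding="utf-8") as fh:
        json.dump({
            "T": model.hyper.T,
            "alpha": model.hyper.alpha,
            "beta": model.hyper.beta,
            "n_sweeps": model.n_sweeps,
            "seed": model.seed,
            "vocabulary": words,
            "author_names": authors,
            "log_likelihood": model.log_likelihood.tolist(),
        }, fh)


def load_model(in_dir: str | Path) -> FittedATM:
    src = Path(in_dir)
    with open(src / "model.json", encoding="utf-8") as fh:
        meta = json.load(fh)

    def read_matrix(path):
        with open(path, encoding="utf-8") as fh:
            next(fh)
            rows = [[float(v) for v in line.rstrip("\n").split("\t")[1:]] for line in fh]
        return np.array(rows)

    return FittedATM(
        theta=read_matrix(src / "theta.tsv"),
        phi=read_matrix(src / "phi.tsv"),
        hyper=Hyperparameters(T=meta["T"], alpha=meta["alpha"], beta=meta["beta"]),
        n_sweeps=meta["n_sweeps"],
        seed=meta["seed"],
        log_likelihood=np.asarray(meta["log_likelihood"]),
        vocabulary=meta["vocabulary"],
        author_names=meta["author_names"],
    )
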