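# Methods

## Model

The author-topic model (ATM) explains a corpus of bag-of-words documents
with observed author lists. Each token of document d is generated by (i)
choosing an author uniformly from the document's author set A_d, (ii)
drawing a topic from that author's distribution θ_{·a} ~ Dirichlet(α), and
(iii) drawing the word from the topic's distribution φ_{·t} ~ Dirichlet(β).
Unlike LDA, the mixing proportions live on authors, not documents, so the
model ties together everything an author writes across the corpus.

Inference is by collapsed Gibbs sampling: θ and φ are integrated out and
the chain moves over per-token (topic, author) pairs with the conditional

P(z=t, y=a | w, rest) ∝ (N_wt+β)/(N_·t+Wβ) · (N_ta+α)/(N_·a+Tα),

restricted to a ∈ A_d. The pair is drawn **jointly** as one categorical
draw over the T·|A_d| support — the conditional is a joint distribution and
a two-stage draw would sample from a different kernel. Tokens are visited
in document order, left to right, so a fit is a pure function of
(corpus, hyperparameters, seed); the inner loop is a numba kernel and the
per-token scan is O(T·|A_d|).

## Estimators and averaging

Point estimates are the posterior-predictive count ratios
θ_ta=(N_ta+α)/(N_·a+Tα) and φ_wt=(N_wt+β)/(N_·t+Wβ). Because single-sample
estimates are noisy and the literature convention for ATM leaves the
schedule open, we average the estimator over retained states: burn-in
defaults to half the sweep budget and every 5th subsequent sweep is kept.
Averaging raw θ/φ across sweeps is safe against label switching here
because a well-mixed chain on identified data stays in one labeling mode
over the retention window; comparisons against ground truth additionally
re-align topics with a Hungarian assignment on pairwise L1 distance.

Defaults α = 50/T and β = 0.01 follow the common ATM practice for
abstract-scale corpora. The per-sweep collapsed joint log-likelihood
(Dirichlet-multinomial, uniform author factor omitted as constant) is
recorded as a convergence diagnostic.

## Preprocessing

Abstracts are lower-cased, split on non-alphabetic characters (tokens of
length < 2 and pure digits vanish), filtered against a stop list
(scikit-learn's English list by default; any list can be supplied), then
Porter-stemmed with an in-package implementation of the classic 1980
algorithm, validated against the algorithm's published example behavior.
Stems with corpus-wide count below 2 are discarded, as are stems present in
more than a configurable fraction of documents (default 0.5 — no
principled universal cutoff exists, so the knob is explicit and logged); an
optional mean-TF-IDF quantile filter is available but disabled by default.
Documents left empty are dropped with a logged count, since the sampler
iterates per token.

The author universe is "principal investigators on the roster, plus each
record's last author", with names normalized to case-folded,
whitespace-collapsed `surname initials` form. No disambiguation beyond
string equality is attempted: homonym merging requires external identity
data and silently guessing is worse than being explicit.

## Evaluation

**Perplexity** is exp(−Σ_d log p(w_d) / Σ_d N_d) over held-out documents.
The per-token likelihood follows the generative process:
p(w|d) = (1/|A_d|) Σ_{a∈A_d} Σ_t θ_ta φ_wt. Authors unseen in training
carry the prior-mean uniform θ column automatically. A fold-in variant
(resampling held-out assignments with φ frozen) is available behind a flag.
A uniform single-topic model scores exactly W — the closed form used as a
sanity anchor.

**PMI coherence** of a topic is the mean pairwise pointwise mutual
information of its top-N words (default N = 20; ties on φ break to the
lower word id), with probabilities measured as document-level occurrence
frequencies over the reference corpus (the training corpus itself) and a
smoothing ε (default 1e-12) inside the logarithm only to avoid log 0.
Natural logarithms throughout; raw PMI values are reported without any
percentage normalization, since no defensible mapping of PMI onto a
percentage scale exists.

**Topic-number selection** fits each candidate T on a deterministic shuffle
split (default 80/20) and picks the T minimizing held-out perplexity, ties
to the smallest T.

## Analytics

The author-topic network links author a to topic t when θ_ta strictly
exceeds a threshold, default 0.01. θ is the model's per-author topic
*proportion*, so the threshold reads "more than 1 % of this author's
output sits in this topic". Dominant-topic counts take each author's
argmax over θ (ties to the lowest topic index); topic co-occurrence counts,
for each unordered topic pair, the authors linked to both — an author of
network degree k contributes C(k,2) pairs, an identity the tests enforce on
random networks; the involvement histogram tabulates authors by degree.
Journal and yearly tables are exact tallies; MeSH diversity is the
per-year count of distinct headings.

## Temporal trends

Records are partitioned by publication year, each year's slice is
preprocessed and fitted independently with a shared configuration, and a
keyword w is scored per year by Σ_k p(k)·φ_wk with p(k) the fraction of
tokens assigned to topic k in the final chain state (an alternative
p(k) = mean over authors of θ_ka is provided). Keywords pass through the
same case-folding and stemming as the corpus before lookup; an
out-of-vocabulary keyword scores 0 with a warning rather than erroring, so
sparse early years produce honest zeros. Multi-word keywords score as the
mean of their constituent stems (flagged in output) — the principled
alternative, phrase tokenization, would change the vocabulary itself.
Because vocabularies are rebuilt per year, absolute levels are not strictly
comparable across years with very different vocabularies; trends should be
read as within-keyword ordinal patterns, which is what the Kendall-based
validation checks.

## Synthetic data

The generator draws θ*, φ* from symmetric Dirichlets (low concentration →
near-sparse, well-separated topics), assigns 1–3 authors per document, and
samples tokens through the exact author→topic→word chain. The vocabulary
is a list of pronounceable CVCVC pseudo-stems verified to be fixed points
of the Porter stemmer, so fixture abstracts survive preprocessing with
their vocabulary intact. Synthetic corpora have no grammar, no correlated
author sociology, no journal-prestige structure and no vocabulary drift
over time; passing tests therefore validate the *inference and analytics
machinery*, not robustness to real-text phenomena such as tokenization
noise, rare-word tails or author-name ambiguity.

## Validation experiment sizes

Chosen to make each check sharp on one CPU in seconds:

* **Exact-posterior check**: 8 tokens, T=2, A=2, α=β=0.5 — small enough to
  enumerate all (z,y) configurations exactly; the chain runs 50 000 sweeps
  and per-token marginals must agree within ±0.02.
* **Parameter recovery**: W=25, T=3, A=8, D=300, 60 tokens/doc,
  concentration 0.05, 500 sweeps at α=0.5, β=0.1; aligned mean L1 errors
  must stay below 0.15 (φ) and 0.20 (θ) — observed ≈ 0.02 and 0.01.
* **Topic-number recovery**: truth T=5 at W=60, A=30, D=300, 40 tokens/doc;
  grid {2, 5, 20} with a 20 % holdout. α is held fixed at 0.1 across
  candidates so every model is compared under the same prior strength; a
  T-dependent α would confound the perplexity comparison with prior
  smoothing. Per-author data is deliberately scarce (~hundreds of tokens)
  so that a 4× over-parameterized model pays a visible generalization
  price; the margin between T=5 and T=20 remains small, so acceptance is
  stochastic (≥ 8 of 10 seeds).
* **Trend recovery**: base truth T=4, W=30, A=6, D=80/year, 40 tokens/doc
  over 5 years, with the target stem's φ mass grown by 0.02/year; the
  fitted series must correlate positively with year (Kendall) in ≥ 8 of 10
  seeds.

## Numerical notes and limitations

Counts are int64 and conserved exactly; conditionals are computed in plain
double precision (magnitudes are benign — no log-space needed). All
randomness flows from user seeds; distinct sub-streams for initialization
and chains are derived by a Knuth multiplicative hash kept below 2³¹.
Reproducibility is bit-exact on a given platform; across BLAS/compiler
variants, floating-point sums may differ in the last ulp.

Known limitations: one author per token (author correlations only appear
across documents), no author disambiguation, no hyperparameter
optimization, single holdout split rather than cross-validation, and
per-year vocabularies in the trend module as discussed above.
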