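# atmbiblio

Author-topic modeling and bibliometric analytics for citation corpora.

`atmbiblio` answers the questions a research-program administrator or
bibliometrician asks of a body of literature: *what topics does this
community work on, who works on which topic, how do topics co-occur within
investigators' portfolios, and how do key terms trend over time?* It does so
with the author-topic model (ATM) — a bag-of-words Bayesian model in which
each token of a document is attributed to one of the document's authors,
that author emits a topic from their personal topic distribution, and the
topic emits the word — fitted by collapsed Gibbs sampling to abstracts from
MEDLINE-style citation records.

## The model

For a corpus of D documents over W word stems, T topics and A authors, each
token i of document d carries latent variables (z_i, y_i): the author
y_i ∈ A_d (the document's author set, chosen uniformly) and the topic
z_i ~ θ_{·,y_i}. With symmetric Dirichlet priors α on the author-topic
distributions θ and β on the topic-word distributions φ, integrating out
θ and φ leaves a collapsed Gibbs sampler over the per-token assignments:

    P(z_i = t, y_i = a | w_i = w, rest) ∝
        (N_wt + β) / (N_·t + Wβ)  ·  (N_ta + α) / (N_·a + Tα)

where N^WT and N^TA are word-topic and topic-author count matrices with
token i removed. Point estimates are the smoothed count ratios

    θ_ta = (N_ta + α) / (N_·a + Tα),    φ_wt = (N_wt + β) / (N_·t + Wβ),

averaged over thinned post-burn-in samples.

Around the sampler the package provides:

* **corpus_io** — PubMed XML / JSONL / TSV ingestion, an author universe of
  principal investigators plus each record's last author, and preprocessing
  (stop words, Porter stemming, minimum-count and document-frequency
  filters) into an integer-encoded corpus.
* **evaluation** — held-out perplexity, PMI topic coherence from
  document-level co-occurrence, and grid search over the topic number T.
* **bibliometrics** — journal/year/MeSH-diversity tables and the
  author-topic network obtained by linking author a to topic t whenever
  θ_ta exceeds a threshold (default 0.01), with dominant-topic counts,
  topic co-occurrence and involvement histograms.
* **temporal_trends** — per-year ATM fits and the keyword statistic
  Σ_k p(k)·p(w|k) traced over years.
* **synthetic_data** — corpora drawn from the ATM generative process with
  known θ*, φ*, so the whole pipeline is testable without external data.

## Worked example

Fit a model to a synthetic corpus with known ground truth and read off the
standard analytics:

```python
import numpy as np
from atmbiblio import *

truth = make_recovery_scenario(T=3, W=25, A=8, D=300, doc_len=60,
                               concentration=0.05, seed=7)
corpus = sample_corpus(truth)
model = fit(corpus, Hyperparameters(T=3, alpha=0.5, beta=0.1),
            n_sweeps=500, seed=7)

perm = align_topics(model.phi, truth.phi)
print("mean L1(phi_hat, phi*): %.3f"
      % np.abs(model.phi[:, perm] - truth.phi).sum(0).mean())

train, test = holdout_split(corpus, 0.2, seed=0)
print("holdout perplexity: %.2f" % perplexity(model, test).value)

net = top_author_network(model.theta, 0.01)
print("author-topic edges at 0.01:", len(net.edges))
print("dominant-topic counts:", dominant_topic_counts(model.theta).tolist())
print("involvement histogram:", topic_involvement_histogram(net))
```

prints

```
mean L1(phi_hat, phi*): 0.021
holdout perplexity: 5.14
author-topic edges at 0.01: 12
dominant-topic counts: [3, 2, 3]
involvement histogram: {1: 4, 2: 4}
```

The aligned L1 error of 0.021 per topic (out of a maximum of 2) says the
sampler recovered the generating word distributions almost exactly; a
held-out perplexity of 5.14 against a 25-stem vocabulary reflects a highly
concentrated topic structure; the network summaries say each of the 8
authors is linked to one or two topics and every topic is some author's
dominant one.

The same pipeline runs from the shell: `atmbiblio simulate | ingest | fit |
evaluate | grid | network | tables | trends` (see `atmbiblio --help`).

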