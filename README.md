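# medtopic

Health-topic detection for online health-community messages.

Patients and caregivers discuss symptoms, examinations, drugs, procedures
and complications on disease discussion boards. `medtopic` clusters such
messages into health topics without supervision, combining two feature
families:

- **F1 — keyword features**: frequencies of uni/bi/trigrams over
  stop-word-filtered, Porter-stemmed content tokens;
- **F2 — medical domain features**: frequencies of matched medical terms
  from a typed lexicon (a dictionary stand-in for UMLS/MetaMap concept
  mapping) and of their semantic types (sosy, dsyn, diap, topp, phsu, …).

The pipeline is: read → preprocess (stop words, stemming, removal of
medically-empty "emotional" messages) → term matching → feature matrix →
PCA → EM clustering of a diagonal-Gaussian mixture with the number of
clusters `K` chosen by 10-fold cross-validated likelihood → per-cluster
key-phrase ranking → topic labeling from dominant semantic types →
external validation against gold labels.

## The model

Messages are rows `x_i` of the PCA-reduced feature matrix. A `K`-component
diagonal-Gaussian mixture is fitted by expectation–maximization:

- E step: responsibilities
  `r_ik ∝ w_k · Π_j N(x_ij; μ_kj, σ_kj)` (computed in log space),
- M step: `w_k, μ_k, σ_k` become responsibility-weighted moments, with a
  variance floor,

so the total log-likelihood rises each iteration until convergence. `K`
starts at 1 and grows while the mean held-out per-row log-likelihood keeps
improving appreciably.

Key phrases for cluster `C_i` are ranked by the TF-IDF-like score

```
score(w, C_i) = f(w, C_i) · ln(N / n_w)
```

with `f` the term's frequency in the cluster, `N` the number of clusters
and `n_w` the number of clusters whose frequency of `w` is ≥ `f(w, C_i)`.
Clusters are labeled by their dominant semantic type (sosy → Symptom,
dsyn/patf → Complication, diap/lbpr → Examination, topp → Procedure,
phsu → Drug, otherwise Other).

Clustering quality against gold labels uses pair counts SS/SD/DS/DD over
all message pairs (same/different cluster × same/different category):
Rand = (SS+DD)/total, Jaccard = SS/(SS+SD+DS),
Fowlkes–Mallows = SS/√((SS+SD)(SS+DS)); annotator agreement uses Cohen's
kappa.

Because the original forum scrape is not redistributable, the package
ships a synthetic corpus generator (`medtopic.synthetic`) producing
labeled corpora with the same structure — K latent topics emitting typed
medical terms plus background vocabulary, and medically-empty noise
messages — so every stage is testable end to end.

## Worked example

```
$ medtopic synth --topics 3 --messages 600 --seed 11 \
      --out corpus.jsonl --lexicon-out lexicon.tsv
wrote 600 messages to corpus.jsonl

$ medtopic stats corpus.jsonl
{
  "n_messages": 600,
  "n_members": 187,
  "messages_per_member": 3.21,
  ...
}

$ medtopic run --corpus corpus.jsonl --lexicon lexicon.tsv --seed 11 > report.json
```

The report for this run shows (values printed by the commands above):

- 600 messages read, 548 retained after noise filtering (the generator
  plants ~10% medically-empty messages);
- cross-validation curve `[0.745, 1.372, 1.835, 1.874]` — the mean
  held-out log-likelihood per message rises strongly up to `K = 3` and
  flattens, so `chosen_k = 3`, matching the three planted topics;
- cluster labels `Examination / Complication / Symptom`, exactly the
  categories of the three planted topics' semantic types (diap, dsyn,
  sosy);
- external validation `rand = 0.941, jaccard = 0.838, fm = 0.912` against
  the gold topic labels, and `kappa = 0.93` between predicted and gold
  categories;
- per-cluster key phrases: the Complication cluster's top terms are all
  planted topic-1 terms (e.g. `t1med12`, `t1med12 t1med12x`, `t1med14`);
  in clusters whose share of the corpus is largest, a few high-frequency
  background words also surface, since the score rewards any term whose
  frequency in that cluster strictly leads the others.

`medtopic evaluate labels.csv --pred-col pred --true-col true` computes
the same indices for any two label columns.

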