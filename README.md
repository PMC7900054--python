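# metafragility

Fragility analysis for meta-analyses of dichotomous outcomes.

A statistically significant 2×2-table result can hinge on the outcomes of
remarkably few participants.  The **fragility index (FI)** quantifies this:
it is the minimum number of single-participant event-status changes needed
to turn a significant result non-significant.  For a single trial the
classical construction adds events to the arm with the fewer events until
the two-sided Fisher exact P value reaches 0.05.  For a **meta-analysis**
the index generalises to the minimal number of event-status modifications,
spread over one or more included trials, after which the pooled 95%
confidence interval includes the null ratio of 1.  The **fragility
quotient (FQ)** expresses the index as a percentage of all participants in
the analysis, FQ = 100 · FI / N.

This package implements the whole pipeline for meta-research surveys of
such corpora:

* **`meta_model`** — 2×2 trial and meta-analysis domain types; two-sided
  Fisher's exact test (minimum-likelihood rule, exact integer
  enumeration); fixed-effect Mantel–Haenszel pooling with the
  Greenland–Robins variance; random-effects DerSimonian–Laird pooling
  (moment estimator of τ²); Wald confidence intervals and P values for
  relative risks and odds ratios.
* **`fragility`** — the single-trial (Walsh) index; the meta-analysis
  index by a minimal-perturbation search (greedy and single-rail upper
  bounds plus a branch-and-bound refinement that certifies minimality on
  small instances); an exhaustive breadth-first oracle for verification;
  the fragility quotient.
* **`corpus_stats`** — corpus summaries as surveys report them: medians
  with interquartile ranges, cumulative-count distribution curves, and
  Pearson correlations (Fisher-z confidence intervals) between fragility
  measures and pooled P values.
* **`synthetic_data`** — a seeded generator of significance-filtered
  meta-analysis corpora (binomial trials, lognormal arm sizes, Beta
  control rates, between-trial heterogeneity on the log relative risk), so
  the full pipeline runs without any external data, plus the constructed
  two-study contrast below.
* **`cli_io`** — trial-table CSV input/output, the JSON analysis report,
  and the `metafragility` command-line tool.

## Worked example

`demo.csv` holds one meta-analysis of two small trials:

```
meta_id,trial_id,events_t,size_t,events_c,size_c
appendectomy,t1,2,50,10,50
appendectomy,t2,3,60,12,60
```

```sh
$ metafragility compute demo.csv --model fixed
meta-analysis appendectomy: k=2, n=220
pooled RR = 0.227 (0.089-0.579), P = 0.001885, tau2 = 0
fragility index = 7
fragility quotient = 3.18%
```

The pooled Mantel–Haenszel relative risk is 0.23 with a confidence
interval well below 1 (P ≈ 0.002), yet changing the outcome of just
**7** of the 220 participants (3.18% of them) makes the pooled interval
include 1 — the finding is fragile.

The index also penalises small studies.  Two constructed trials with
near-identical Fisher P values but very different effect sizes:

```sh
$ metafragility contrast
small: 1/100 vs 9/100; RRR = 89%, Fisher P = 0.0185, fragility index = 1
large: 184/1300 vs 230/1300; RRR = 20%, Fisher P = 0.0158, fragility index = 9
```

The small trial's 89% relative risk reduction collapses after a single
added event; the large trial's modest 20% reduction withstands eight.
Equal P values, very unequal robustness — because the index is, at heart,
a re-expression of the P value and the sample size.

The same machinery runs at corpus scale (`metafragility simulate` to
generate a synthetic survey corpus, `metafragility corpus` to analyse any
trial CSV and emit a JSON report plus cumulative-curve CSV), or from
Python:

```python
import metafragility as mf

corpus = mf.simulate_corpus(mf.CorpusModel(seed=20210116))
report = mf.run_pipeline(corpus.specs)
print(report.summary.index_stats)   # FiveNumber(median=5.0, q25=2.0, q75=9.0, min=1.0, max=20.0)
```

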