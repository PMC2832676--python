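# expplan — experiment planning for genome-scale functional annotation

When a poorly studied organism is to be functionally annotated from
expression data, which experiments should be run first?  Large compendia
from model organisms show that experimental treatments differ enormously in
which biological processes they reveal, and that many treatments are
redundant with one another.  `expplan` turns an existing compendium into an
ordered experiment plan for a new (or resource-limited) setting:

1. **Informativeness.** For every (dataset, GO biological-process term)
   pair, a class-weighted linear SVM separates the term's genes (y = +1)
   from all others (y = −1) using the dataset's expression rows x_i as
   features, with the slack on positives weighted by the cost factor
   j = #negatives/#positives.  Scores are aggregated by 0.632-bootstrap
   cross-validation (n-out-of-n sampling with replacement; a sample holds
   ≈63.2% distinct genes) as the median of out-of-bag scores over 25
   rounds, and summarized by AUC and precision at 1/10/20/50/80% recall.
   A dataset's overall accuracy is its mean AUC across the GO functional
   slim terms.
2. **Redundancy.** For each dataset, the Fisher z-transform z = atanh(r) of
   the Pearson correlation is computed for every gene pair whose
   functional-relationship label FR is defined (fr = 1: the genes share a
   slim co-annotation; fr = 0: both are slim-annotated but share none).
   The overlap between datasets X and Y is the conditional mutual
   information I(X;Y | FR) (bits) of their binned z distributions.
3. **Minimum arrays.** Very large datasets are subsampled on an increasing
   grid of array counts (25 random draws per grid point); the smallest
   count whose mean slim AUC is within a tolerance of the full dataset is
   the minimum-array call.
4. **Recommendation.** Datasets are picked greedily to maximize
   S(X) = α·A(X) − (1−α)·(1/k)·Σ_{Y∈selected} C′(X,Y), with A the overall
   accuracy, C′ the (min-max normalized) CMI, k the number already selected
   (warm-start experiments count), and α = 0.9 by default.  Afterwards,
   slim terms with AUC < 0.65 and ≥ 30 annotated genes on the achieved data
   are flagged and a second round adds the best-covering datasets for them.

A seed-deterministic synthetic-compendium generator with planted signal,
duplicated experiments and noise datasets makes every stage testable
without any external download.

## Worked example

```python
import expplan as ep

comp, onto, _ = ep.simulate_compendium(ep.default_spec(seed=0))
norm = ep.Compendium(datasets=[ep.normalize(d) for d in comp])
ann = ep.propagate_annotations(onto.direct_annotations, onto)
terms = sorted(onto.slim_terms)

im = ep.informativeness_matrix(norm, ann, terms,
                               cfg=ep.BootstrapConfig(n_rounds=10, seed=0))
acc = ep.overall_accuracy(im, onto.slim_terms)
fr = ep.pair_fr_labels(ann, onto.slim_terms, sorted(norm.gene_universe))
cm = ep.cmi_matrix(norm, fr, seed=0)
plan = ep.greedy_select(acc, cm.values,
                        ep.TradeoffConfig(alpha=0.9, list_length=3))
print(plan.to_frame()[["rank", "dataset", "combined_score", "accuracy",
                       "redundancy"]].to_string(index=False))
```

prints

```
 rank dataset  combined_score  accuracy  redundancy
    1   exp03        0.605498  0.672775    0.000000
    2   exp01        0.570680  0.648462    0.129359
    3   exp02        0.558374  0.638564    0.163340
```

i.e. the plan recovers exactly the three planted informative datasets:
`accuracy` is each dataset's mean slim AUC (the noise and duplicated
datasets sit near 0.5 and are never picked), `redundancy` the mean
normalized CMI against the datasets already selected, and
`combined_score = 0.9·accuracy − 0.1·redundancy` the greedy objective.
Evaluating the plan's datasets jointly gives a mean slim AUC of 1.000
versus 0.595 for random selections with the same 60-array budget
(`examples/05_recommend_experiments.py`).

The `examples/` directory holds one short script per capability
(normalization, informativeness, CMI redundancy, minimum arrays, greedy
recommendation, second round), each printing the numbers it computes and a
note on what they mean.  A thin CLI mirrors the same stages
(`expplan simulate|normalize|informativeness|cmi|subsample|recommend|second-round`).

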