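# Methods

## Problem setting

Given a compendium of expression datasets (genes × arrays matrices on a
log-ratio scale), gene–GO annotations with the ontology DAG, and a list of
functional-slim terms, the package answers four questions: how informative
is each dataset for each biological process; how redundant is each pair of
datasets; how many arrays do very large datasets actually need; and in what
order should experiments be performed to cover the most biology for the
least effort.

## Normalization

Each dataset passes a fixed pipeline before any analysis: (1) genes
observed in fewer than half of the arrays are removed (exactly half is
retained — the boundary is read strictly); (2) remaining gaps are filled by
K-nearest-neighbour imputation with K = 10, where the distance between two
genes is the *mean* squared difference over mutually observed arrays
(per-array scaling keeps distances comparable across different overlap
sizes) and a neighbour must itself be observed at the target array; a cell
with no eligible neighbour falls back to the gene's row mean and is
counted in the log; (3) technical replicates are averaged.  Replicate
groups come from an optional sidecar mapping; without one, every array is a
singleton.  Imputation is strictly per-dataset — datasets are later treated
as independent feature blocks, so no information crosses dataset
boundaries.  No per-gene or per-array centering is applied after
imputation; an optional z-scoring switch exists but is off by default.

## Gold standard

Annotations are propagated over is_a and part_of edges (transitive
closure), so a gene annotated to a term is annotated to all its ancestors.
For a term, positives are the propagated annotated genes of the evaluated
universe and negatives are all remaining genes; the evaluated universe for
a dataset is that dataset's post-normalization gene list, which avoids
feature rows that are entirely absent.  Terms enter evaluation when their
propagated positive count lies in [10, 500] (inclusive; [10, 300] is the
conventional grid for targeted follow-up evaluation).  Functional
relationships over the slim: fr = 1 when a gene pair shares at least one
slim co-annotation, fr = 0 when both genes are slim-annotated but share
none, undefined otherwise (undefined pairs are excluded from redundancy
estimation).  NOT-qualified GAF rows are dropped; evidence codes are kept
by default (a filtering switch is the caller's choice).

## Informativeness

The per-term classifier is a soft-margin linear SVM whose slack on positive
examples is weighted by the cost factor j = #negatives/#positives of the
training sample, counteracting the heavy class imbalance of GO terms.  The
solver is liblinear's primal squared-hinge formulation
(`LinearSVC(loss="squared_hinge", dual=False)`) with C = 1.0; the libsvm
hinge variant is available via `ClassifierSpec(loss="hinge")`.  The
squared-hinge default was chosen because it is several-fold faster and
convergent at these problem sizes while producing score rankings that agree
with the hinge solver at Spearman ρ ≈ 0.997 — and only score *ranks* enter
the reported metrics.  C is configurable but immaterial here; the class
weight j is the parameter that matters.

Evaluation uses 0.632-bootstrap aggregation: each round draws n genes with
replacement from the n labeled genes (≈63.2% distinct), trains on the draw
and scores the out-of-bag genes; a gene's final score is the median of its
out-of-bag scores over 25 rounds (10 in the heavier simulation tests).
Single-class draws are redrawn (logged, capped at 50); genes never
out-of-bag get extra rounds, then the pooled mean score as a last resort
(logged — at 25 rounds this is vanishingly rare).  AUC is the midrank
Mann–Whitney statistic (ties count ½).  Precision-at-recall scans the
ranked list in tied-score blocks (a threshold cannot split a tie); for
level r the first block where the true-positive count reaches
ceil(r·#positives) defines the threshold, and precision is TP/retrieved
there.  Overall accuracy is the unweighted mean AUC over evaluable slim
terms; terms with fewer than 2 positives or 2 negatives in a dataset's
universe are skipped and recorded.

## Redundancy (conditional mutual information)

For each dataset, Pearson correlations over arrays are computed for every
FR-defined gene pair present in the dataset, clamped to ±0.999999 and
Fisher z-transformed.  The overlap between datasets X and Y is

I(X;Y|FR) = Σ_fr p(fr) Σ_{a,b} p(a,b|fr) log2 [ p(a,b|fr) / (p(a|fr)p(b|fr)) ]

estimated from joint histograms of the binned z values over the pairs
common to both datasets, with p(fr) the empirical mixture weight of that
common-pair set.  Conditioning on FR removes the component of the
dependence that only reflects how many related vs unrelated pairs the two
datasets share.  Numerical choices: equal-width bins over z clipped to
[−3, 3], 20 bins per axis (stable histograms at 10³–10⁵ pairs); log base 2
(bits); 0·log 0 = 0; negative estimates clipped at 0; estimates with fewer
than 500 common pairs in either FR stratum are reported as missing, never
as zero.  The shared pair universe is subsampled to at most 200,000 pairs
(seeded) to bound the quadratic cost; the estimate is symmetric bit-exactly
because arguments are canonicalized by dataset id before summation.  The
histogram estimator has a positive bias of roughly (B−1)²/(2N ln 2) bits
per stratum (≈0.01 bits at 25,000 pairs, B = 20), which sets the floor used
when asserting near-independence.

## Minimum arrays

For a large dataset, m arrays are drawn uniformly without replacement (a
random subset of real arrays is what an experimentalist would run) for each
m on an increasing grid, default {5, 10, 15, 20, 25, 30, 40, 50, 75, 100,
…} capped at the dataset size; the bootstrap evaluation is repeated for 25
rounds per grid point (the full-size point needs only one) and the mean,
median and SD of the slim-average (or single-term) AUC are recorded.  The
minimum-array call is the smallest grid point whose *mean* AUC is within a
tolerance (default 0.01, 0.02 in the saturation tests) of the full-dataset
AUC, or "not reached".  The call is monotone in the tolerance and the whole
curve is bit-reproducible under a fixed seed.

## Greedy recommendation

Candidates are picked iteratively to maximize
S(X) = α·A′(X) − (1−α)·(1/k)·Σ_{Y∈selected} C′(X,Y), where selected
includes warm-start datasets and k = |selected| (k = 0 drops the penalty).
The 1/k mean keeps the penalty's scale independent of how many datasets are
already selected.  α defaults to 0.9.  Normalization was a genuinely open
design point: CMI is unbounded (bits) and is min-max normalized across the
candidate matrix's off-diagonal; accuracy is *not* rescaled by default,
because AUC already lives on a fixed [0, 1] scale with a 0.5 baseline and
min-max rescaling across near-tied candidates divides estimation noise by
a small, noisy range, destabilizing the ranking.  Both behaviours are
switchable (`accuracy_norm`, `cmi_norm`).  Exact ties break
lexicographically by dataset id, making the procedure fully deterministic;
candidates with undefined CMI against the selected set are excluded with a
warning (optionally penalized as zero).  No global optimality is claimed —
the selection is greedy by construction.

Plans carry per-dataset array recommendations: datasets with ≥ 50 arrays
take their minimum-array call (full size, flagged, when saturation was not
reached); smaller datasets take their full size.  After the achieved data
are evaluated jointly — arrays of the selected datasets concatenated over
the intersection of their gene coverage — slim terms with AUC strictly
below 0.65 and at least 30 annotated genes are flagged weak, and the second
round appends, per weak term, the highest per-term-AUC dataset not yet
recommended (deduplicated across terms; terms whose best candidate does not
exceed 0.5 are reported uncoverable).

## Synthetic compendia

The generator plants exactly the structure the pipeline must detect.
Signal model: for a dataset informative for a term, the term's genes share
an additive latent per-array response profile (rank-one), scaled by
`signal_strength`, on top of unit Gaussian noise — a single model that both
the margin classifier (mean shift along the profile) and the
correlation-based CMI (shared co-variation) can see.  Gene–term assignment
is sampled independently per term, so overlaps occur and exercise
multi-membership; 10% of genes are kept annotation-free so FR-undefined
pairs exist; half of the first slim term's genes are annotated via a nested
child term to exercise propagation.

Default study conditions (chosen once): 400 genes; 6 slim terms of 35–45
genes; 8 datasets of 20 arrays — 3 informative datasets carrying disjoint
pairs of slim terms, 2 duplicated experiments, 3 pure-noise datasets;
signal strength 2.0 (calibrated so a planted (dataset, term) cell scores
AUC > 0.9); duplicates are a source dataset plus Gaussian perturbation of
SD 0.5 (a same-treatment repeat with fresh technical noise); 5% missing
values.  The default duplicates repeat the two first noise datasets;
a planted-redundancy variant (`redundancy_spec`) instead duplicates the two
strongest informative datasets, which is the regime where a pure accuracy
sort wastes picks and an interior α wins.  `saturation_spec` builds one
100-array dataset whose response is confined to 10 known arrays with
strength 5 — strong enough that performance saturates once a couple of
signal arrays are covered, the regime the minimum-array analysis targets.
`second_round_spec` adds a seventh slim term covered only by a dataset too
narrow to enter a length-3 first-round plan.

What the generator does *not* emulate: dye bias, spatial artifacts,
intensity-dependent noise, correlated gene backgrounds, or realistic GO DAG
depth.  Passing tests therefore demonstrate that the algorithms recover the
planted statistical structure under idealized Gaussian noise, not that any
particular biological compendium will behave identically.

## Problem sizes and determinism

Simulation-based checks run at deliberately modest sizes — 400-gene
compendia, 10 bootstrap rounds, 10 seeds/replicates, 5–10 random baselines,
CMI on ~17,000 labeled pairs — chosen so the whole suite and the
reproduction script each complete in minutes on a single CPU while leaving
the qualitative margins (duplicate detection, plan recovery, greedy-vs-
random, rescue rates) far from their thresholds.  Every stochastic
component takes an explicit seed; per-cell bootstrap seeds are derived from
the top-level seed via `numpy` seed sequences, so all results are exactly
reproducible.

## Known limitations

- Negatives are "all other genes", so unannotated true members of a process
  depress measured AUC; the gold standard inherits annotation
  incompleteness.
- The histogram CMI estimator is biased upward at small pair counts and
  downward by binning; values are comparable across dataset pairs computed
  on the same pair universe and bin specification, not across studies.
- The greedy objective's algebraic form (mean CMI penalty, min-max CMI
  normalization) is one reasonable reading of "linearly combining accuracy
  with redundancy"; alternatives (summed penalty, per-iteration
  renormalization) are not implemented.
- Joint evaluation restricts genes to the intersection of the selected
  datasets' coverage; a union-with-reimputation mode is not implemented and
  an empty intersection raises.
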