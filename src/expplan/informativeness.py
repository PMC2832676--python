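"""Dataset informativeness for biological processes.

For each (dataset, GO term) pair a class-weighted linear max-margin
classifier is trained to separate genes annotated to the term (positives,
y=+1) from all other genes (negatives, y=-1), using the dataset's expression
rows as feature vectors.  Training errors on positives are weighted by the
cost factor j = #negatives / #positives of the training sample, which
counteracts the strong class imbalance typical of GO terms.

Scores are aggregated by bootstrap cross-validation: in each round the n
labeled genes are resampled with replacement (the 0.632 bootstrap — a sample
contains on average ~63.2% distinct genes), a model is fit on the sample and
scores are recorded for the out-of-bag genes; each gene's final score is the
median of its out-of-bag scores across rounds.  Informativeness is then
summarized as the AUC (probability a random positive outranks a random
negative, ties counted 1/2) and precision at fixed recall levels, and a
dataset's overall accuracy is its mean AUC over the functional-slim terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ClassifierSpec",
    "BootstrapConfig",
    "InformativenessMatrix",
    "train_weighted_linear",
    "bootstrap_scores",
    "bootstrap_distinct_fraction",
    "auc",
    "precision_at_recall",
    "informativeness_matrix",
    "overall_accuracy",
]

DEFAULT_RECALL_LEVELS = (0.01, 0.10, 0.20, 0.50, 0.80)


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of the class-weighted linear classifier.

    ``cost_weight_j`` of ``None`` (the default) sets j to the ratio of
    negatives to positives in each training sample.  ``base_cost`` is the
    soft-margin regularization constant C.  ``loss`` selects the slack
    penalty: "squared_hinge" (liblinear primal, default) or "hinge"
    (libsvm); both produce near-identical score rankings.
    """

    cost_weight_j: float | None = None
    base_cost: float = 1.0
    loss: str = "squared_hinge"

    def __post_init__(self) -> None:
        if self.cost_weight_j is not None and self.cost_weight_j <= 0:
            raise ValueError("cost_weight_j must be positive")
        if self.base_cost <= 0:
            raise ValueError("base_cost must be positive")
        if self.loss not in {"hinge", "squared_hinge"}:
            raise ValueError("loss must be 'hinge' or 'squared_hinge'")


@dataclass(frozen=True)
class BootstrapConfig:
    """0.632-bootstrap aggregation settings (median over out-of-bag scores)."""

    n_rounds: int = 25
    seed: int = 0
    max_redraws: int = 50
    max_extra_rounds: int = 20

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


@dataclass
class InformativenessMatrix:
    """Datasets x GO terms table of AUC and precision-at-recall scores."""

    auc: pd.DataFrame
    precision_at: dict[float, pd.DataFrame]
    n_pos: pd.DataFrame
    n_neg: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.auc.index)

    @property
    def term_ids(self) -> list[str]:
        return list(self.auc.columns)


def train_weighted_linear(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec = ClassifierSpec()
):
    """Fit the class-weighted soft-margin linear classifier.

    Returns a callable mapping a feature matrix to real-valued decision
    scores.  j (the positive-class slack weight) defaults to
    #negatives/#positives of the training sample.  Raises on a single-class
    sample; the bootstrap loop handles that by redrawing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training sample must contain both classes")
    j = spec.cost_weight_j if spec.cost_weight_j is not None else n_neg / n_pos
    if spec.loss == "hinge":
        from sklearn.svm import SVC

        model = SVC(kernel="linear", C=spec.base_cost, class_weight={1: j, -1: 1.0})
    else:
        from sklearn.svm import LinearSVC

        model = LinearSVC(
            loss="squared_hinge",
            dual=False,
            C=spec.base_cost,
            class_weight={1: j, -1: 1.0},
            max_iter=5000,
        )
    model.fit(X, y)
    return model.decision_function


def bootstrap_distinct_fraction(n: int, rng: np.random.Generator) -> float:
    """Fraction of distinct items in one n-out-of-n draw with replacement.

    Uses the same sampling primitive as :func:`bootstrap_scores`; the
    expectation approaches 1 - 1/e ~ 63.2% for large n.
    """
    draw = rng.integers(0, n, size=n)
    return np.unique(draw).size / n


def bootstrap_scores(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    cfg: BootstrapConfig = BootstrapConfig(),
    log: dict | None = None,
) -> np.ndarray:
    """Median out-of-bag decision score per gene across bootstrap rounds.

    Each round draws n genes with replacement from the n labeled genes,
    trains on the drawn multiset and scores the out-of-bag genes.  Draws
    containing a single class are redrawn (counted in the log).  Genes never
    out-of-bag after the configured rounds are covered by extra rounds, or —
    should any remain — assigned the mean of all out-of-bag scores (logged).

    Requires at least 2 positives and 2 negatives.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if int((y == 1).sum()) < 2 or int((y == -1).sum()) < 2:
        raise ValueError("need >=2 positives and >=2 negatives")
    rng = np.random.default_rng(cfg.seed)
    oob_scores: list[list[float]] = [[] for _ in range(n)]
    redraws = 0

    def one_round() -> None:
        nonlocal redraws
        for _ in range(cfg.max_redraws):
            bag = rng.integers(0, n, size=n)
            if len(np.unique(y[bag])) == 2:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a two-class bootstrap sample")
        oob = np.setdiff1d(np.arange(n), bag)
        if oob.size == 0:
            return
        predict = train_weighted_linear(X[bag], y[bag], spec)
        for i, s in zip(oob, predict(X[oob])):
            oob_scores[i].append(float(s))

    for _ in range(cfg.n_rounds):
        one_round()
    extra = 0
    while any(len(s) == 0 for s in oob_scores) and extra < cfg.max_extra_rounds:
        one_round()
        extra += 1

    uncovered = [i for i, s in enumerate(oob_scores) if len(s) == 0]
    pooled_mean = float(np.mean([v for s in oob_scores for v in s])) if n else 0.0
    final = np.array(
        [np.median(s) if s else pooled_mean for s in oob_scores], dtype=float
    )
    if log is not None:
        log["redraws"] = log.get("redraws", 0) + redraws
        log["extra_rounds"] = log.get("extra_rounds", 0) + extra
        log["mean_fallbacks"] = log.get("mean_fallbacks", 0) + len(uncovered)
    return final


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 1/2.

    Computed with the midrank Mann-Whitney statistic.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y == 1
    neg = y == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with an empty class")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def precision_at_recall(
    scores: np.ndarray,
    y: np.ndarray,
    levels: tuple[float, ...] = DEFAULT_RECALL_LEVELS,
) -> dict[float, float]:
    """Precision at the first score threshold whose recall reaches each level.

    The ranked list is scanned in blocks of tied scores (a threshold cannot
    split a tie); for recall level r the required true-positive count is
    ceil(r * #positives), and precision is TP / retrieved at the first block
    boundary meeting it.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y == 1
    n_pos = int(pos.sum())
    if n_pos == 0 or int((y == -1).sum()) == 0:
        raise ValueError("precision-at-recall undefined with an empty class")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    p_sorted = pos[order].astype(int)
    # block boundaries: last index of each tied-score run
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.concatenate([boundary, [len(scores) - 1]])
    cum_tp = np.cumsum(p_sorted)[ends]
    retrieved = ends + 1
    out: dict[float, float] = {}
    for r in levels:
        need = max(1, int(np.ceil(r * n_pos - 1e-12)))
        hit = np.flatnonzero(cum_tp >= need)
        k = hit[0]
        out[r] = float(cum_tp[k] / retrieved[k])
    return out


def _term_seed(base_seed: int, ds_idx: int, term_idx: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, ds_idx, term_idx]).generate_state(1)[0]
        % (2**31)
    )


def informativeness_matrix(
    compendium,
    annotations: dict[str, set[str]],
    terms: list[str],
    spec: ClassifierSpec = ClassifierSpec(),
    cfg: BootstrapConfig = BootstrapConfig(),
    levels: tuple[float, ...] = DEFAULT_RECALL_LEVELS,
    min_pos: int = 2,
) -> InformativenessMatrix:
    """Evaluate every (dataset, term) pair of a compendium.

    For each dataset the evaluated universe is that dataset's genes; terms
    with fewer than ``min_pos`` positives (or negatives) in it are skipped
    and recorded as NaN with a reason in the metadata.  Per-cell bootstrap
    seeds are derived deterministically from ``cfg.seed``.
    """
    ds_ids = [d.dataset_id for d in compendium]
    auc_df = pd.DataFrame(np.nan, index=ds_ids, columns=terms)
    prec = {r: pd.DataFrame(np.nan, index=ds_ids, columns=terms) for r in levels}
    n_pos_df = pd.DataFrame(0, index=ds_ids, columns=terms)
    n_neg_df = pd.DataFrame(0, index=ds_ids, columns=terms)
    meta: dict = {"seed": cfg.seed, "skipped": [], "cell_seeds": {}, "log": {}}

    for di, ds in enumerate(compendium):
        genes = ds.gene_ids
        term_member = {
            t: np.array([t in annotations.get(g, ()) for g in genes]) for t in terms
        }
        for ti, t in enumerate(terms):
            y = np.where(term_member[t], 1, -1)
            n_pos = int((y == 1).sum())
            n_neg = int((y == -1).sum())
            n_pos_df.loc[ds.dataset_id, t] = n_pos
            n_neg_df.loc[ds.dataset_id, t] = n_neg
            if n_pos < min_pos or n_neg < min_pos:
                meta["skipped"].append(
                    {"dataset": ds.dataset_id, "term": t, "n_pos": n_pos, "n_neg": n_neg}
                )
                continue
            seed = _term_seed(cfg.seed, di, ti)
            meta["cell_seeds"][f"{ds.dataset_id}|{t}"] = seed
            cell_cfg = BootstrapConfig(
                n_rounds=cfg.n_rounds,
                seed=seed,
                max_redraws=cfg.max_redraws,
                max_extra_rounds=cfg.max_extra_rounds,
            )
            scores = bootstrap_scores(ds.values, y, spec, cell_cfg, log=meta["log"])
            auc_df.loc[ds.dataset_id, t] = auc(scores, y)
            for r, p in precision_at_recall(scores, y, levels).items():
                prec[r].loc[ds.dataset_id, t] = p
    return InformativenessMatrix(
        auc=auc_df, precision_at=prec, n_pos=n_pos_df, n_neg=n_neg_df, meta=meta
    )


def overall_accuracy(
    im: InformativenessMatrix, slim_terms: set[str] | list[str]
) -> pd.Series:
    """Per-dataset overall accuracy: unweighted mean AUC over evaluable slim terms.

    Slim terms skipped for a dataset are excluded from that dataset's mean;
    a dataset with no evaluable slim term raises.
    """
    cols = [t for t in im.term_ids if t in set(slim_terms)]
    if not cols:
        raise ValueError("no slim terms present in the informativeness matrix")
    sub = im.auc[cols]
    if sub.isna().all(axis=1).any():
        bad = sub.index[sub.isna().all(axis=1)].tolist()
        raise ValueError(f"no evaluable slim terms for dataset(s): {bad}")
    return sub.mean(axis=1, skipna=True)
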