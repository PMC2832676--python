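"""Greedy experiment recommendation under an accuracy/redundancy trade-off.

Datasets are picked iteratively to maximize

    S(X) = alpha * A'(X) - (1 - alpha) * (1/k) * sum_{Y in selected} C'(X, Y)

where A'(X) is the dataset's overall accuracy (mean slim AUC), C'(X, Y) the
conditional mutual information with an already-selected dataset, and
k = |selected| (warm-start datasets count as selected; with k = 0 the pick
maximizes accuracy alone).  alpha in [0, 1] weights accuracy against
redundancy.  By default the CMI matrix is min-max normalized across
candidates while AUC is used on its native [0, 1] scale.

The module also attaches minimum-array calls to large datasets, flags
weakly covered processes on the achieved data (AUC < 0.65 with >= 30
annotated genes), recommends second-round experiments targeting them, and
evaluates a selection by concatenating the chosen datasets into one joint
feature block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .informativeness import (
    BootstrapConfig,
    ClassifierSpec,
    InformativenessMatrix,
    auc,
    bootstrap_scores,
)
from .io_normalize import ExpressionDataset
from .saturation import NOT_REACHED

__all__ = [
    "TradeoffConfig",
    "PlanEntry",
    "RecommendationPlan",
    "greedy_select",
    "attach_min_arrays",
    "weak_terms",
    "second_round",
    "evaluate_selection",
    "random_equal_array_selection",
]


@dataclass(frozen=True)
class TradeoffConfig:
    """Trade-off settings for greedy selection.

    ``accuracy_norm`` / ``cmi_norm`` in {"none", "minmax"} control min-max
    rescaling across candidates before combining.  AUC already lives on a
    fixed [0, 1] scale, so its default is "none"; CMI is in bits and
    unbounded, so its default is "minmax".  ``missing_cmi`` picks the policy
    for undefined CMI entries: "exclude" the candidate (default, warns) or
    treat as 0.
    """

    alpha: float = 0.9
    list_length: int | None = None
    accuracy_norm: str = "none"
    cmi_norm: str = "minmax"
    missing_cmi: str = "exclude"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        for v in (self.accuracy_norm, self.cmi_norm):
            if v not in {"none", "minmax"}:
                raise ValueError("normalization must be 'none' or 'minmax'")
        if self.missing_cmi not in {"exclude", "zero"}:
            raise ValueError("missing_cmi must be 'exclude' or 'zero'")


@dataclass
class PlanEntry:
    dataset_id: str
    rank: int
    combined_score: float
    accuracy_component: float
    redundancy_component: float
    recommended_array_count: int | None = None
    round: str = "first"
    target_terms: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass
class RecommendationPlan:
    """Ordered experiment recommendations plus warm-start context."""

    entries: list[PlanEntry]
    warm_start: list[str] = field(default_factory=list)

    @property
    def dataset_ids(self) -> list[str]:
        return [e.dataset_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": e.rank,
                    "dataset": e.dataset_id,
                    "arrays": e.recommended_array_count,
                    "combined_score": e.combined_score,
                    "accuracy": e.accuracy_component,
                    "redundancy": e.redundancy_component,
                    "round": e.round,
                    "target_terms": ";".join(e.target_terms),
                    "flags": ";".join(e.flags),
                }
                for e in self.entries
            ]
        )


def _minmax(s: pd.Series | pd.DataFrame):
    lo, hi = np.nanmin(s.values), np.nanmax(s.values)
    if hi <= lo:
        return s * 0.0
    return (s - lo) / (hi - lo)


def greedy_select(
    accuracy: pd.Series,
    cmi: pd.DataFrame,
    cfg: TradeoffConfig = TradeoffConfig(),
    warm_start: list[str] | None = None,
) -> RecommendationPlan:
    """Iteratively pick datasets maximizing the accuracy/redundancy score.

    Deterministic: exact score ties break by lexicographic dataset id.
    Warm-start datasets seed the selected set and are never re-recommended.
    Candidates with undefined CMI against a selected dataset are excluded
    (or penalized as 0) per ``cfg.missing_cmi``.
    """
    warm = list(warm_start or [])
    candidates = [d for d in accuracy.index if d not in warm]
    acc = _minmax(accuracy) if cfg.accuracy_norm == "minmax" else accuracy.astype(float)
    if cfg.cmi_norm == "minmax":
        off = cmi.values[~np.eye(len(cmi), dtype=bool)]
        off = off[~np.isnan(off)]
        lo, hi = (off.min(), off.max()) if off.size else (0.0, 1.0)
        cmi_n = (cmi - lo) / (hi - lo) if hi > lo else cmi * 0.0
    else:
        cmi_n = cmi.astype(float)

    selected = list(warm)
    entries: list[PlanEntry] = []
    length = cfg.list_length if cfg.list_length is not None else len(candidates)
    while candidates and len(entries) < length:
        k = len(selected)
        best = None
        for d in sorted(candidates):
            a = float(acc[d])
            if k == 0:
                red = 0.0
            else:
                vals = np.array([cmi_n.loc[d, y] for y in selected], dtype=float)
                if np.isnan(vals).any():
                    if cfg.missing_cmi == "exclude":
                        warnings.warn(
                            f"excluding {d}: undefined CMI vs selected set",
                            stacklevel=2,
                        )
                        continue
                    vals = np.nan_to_num(vals)
                red = float(vals.sum() / k)
            score = cfg.alpha * a - (1.0 - cfg.alpha) * red
            if best is None or score > best[0]:
                best = (score, d, a, red)
        if best is None:
            break
        score, d, a, red = best
        entries.append(
            PlanEntry(
                dataset_id=d,
                rank=len(entries) + 1,
                combined_score=score,
                accuracy_component=a,
                redundancy_component=red,
            )
        )
        selected.append(d)
        candidates.remove(d)
    return RecommendationPlan(entries=entries, warm_start=warm)


def attach_min_arrays(
    plan: RecommendationPlan,
    min_array_calls: dict[str, int | str],
    dataset_sizes: dict[str, int],
    large_threshold: int = 50,
) -> RecommendationPlan:
    """Attach recommended array counts to a plan.

    Datasets at or above ``large_threshold`` arrays carry their
    minimum-array call; smaller datasets (and "not reached" calls, flagged)
    carry the full array count.
    """
    for e in plan.entries:
        size = dataset_sizes[e.dataset_id]
        call = min_array_calls.get(e.dataset_id)
        if size >= large_threshold and call not in (None, NOT_REACHED):
            e.recommended_array_count = int(call)
        else:
            e.recommended_array_count = size
            if size >= large_threshold and call == NOT_REACHED:
                e.flags.append("saturation_not_reached")
    return plan


def weak_terms(
    per_term_auc: pd.Series,
    n_pos: pd.Series,
    auc_threshold: float = 0.65,
    min_genes: int = 30,
) -> list[str]:
    """Slim terms weakly covered by the achieved data.

    A term qualifies when its AUC is strictly below ``auc_threshold`` and it
    has at least ``min_genes`` annotated genes.
    """
    out = [
        t
        for t in per_term_auc.index
        if not np.isnan(per_term_auc[t])
        and per_term_auc[t] < auc_threshold
        and int(n_pos[t]) >= min_genes
    ]
    return sorted(out)


def second_round(
    weak: list[str],
    im: InformativenessMatrix,
    plan: RecommendationPlan,
    per_term_top: int = 1,
    min_auc: float = 0.5,
) -> RecommendationPlan:
    """Recommend targeted experiments for weakly covered processes.

    For each weak term the not-yet-recommended datasets are ranked by their
    per-term AUC; the top hits (above ``min_auc``) are appended as
    second-round entries, deduplicated across terms and annotated with the
    terms they target.  Terms with no qualifying candidate are flagged
    uncoverable on the returned plan.  The input plan is not modified.
    """
    import copy

    plan = copy.deepcopy(plan)
    if not weak:
        return plan
    used = set(plan.dataset_ids) | set(plan.warm_start)
    chosen: dict[str, list[str]] = {}
    uncoverable: list[str] = []
    for t in weak:
        col = im.auc[t].drop(labels=[d for d in used if d in im.auc.index])
        col = col.dropna().sort_values(ascending=False)
        hits = [d for d in col.index[:per_term_top] if col[d] > min_auc]
        if not hits:
            uncoverable.append(t)
            continue
        for d in hits:
            chosen.setdefault(d, []).append(t)
    rank = len(plan.entries)
    for d in sorted(chosen, key=lambda d: -max(im.auc.loc[d, t] for t in chosen[d])):
        rank += 1
        plan.entries.append(
            PlanEntry(
                dataset_id=d,
                rank=rank,
                combined_score=float(max(im.auc.loc[d, t] for t in chosen[d])),
                accuracy_component=float(max(im.auc.loc[d, t] for t in chosen[d])),
                redundancy_component=0.0,
                round="second",
                target_terms=sorted(chosen[d]),
            )
        )
    if uncoverable:
        warnings.warn(f"uncoverable weak terms: {uncoverable}", stacklevel=2)
        plan.uncoverable = uncoverable  # type: ignore[attr-defined]
    return plan


def _joint_block(chosen: list[ExpressionDataset]) -> ExpressionDataset:
    """Concatenate datasets' arrays over their common genes."""
    common: set[str] | None = None
    for ds in chosen:
        common = set(ds.gene_ids) if common is None else common & set(ds.gene_ids)
    if not common:
        raise ValueError(
            "empty gene intersection across the selection; consider a "
            "union-with-imputation strategy upstream"
        )
    genes = sorted(common)
    blocks = []
    array_ids = []
    for ds in chosen:
        idx = ds.gene_index()
        rows = np.array([idx[g] for g in genes])
        blocks.append(ds.values[rows])
        array_ids.extend(f"{ds.dataset_id}:{a}" for a in ds.array_ids)
    return ExpressionDataset(
        dataset_id="+".join(d.dataset_id for d in chosen),
        gene_ids=genes,
        array_ids=array_ids,
        values=np.hstack(blocks),
        missing_mask=np.zeros((len(genes), len(array_ids)), dtype=bool),
    )


def evaluate_selection(
    compendium,
    selection: list,
    annotations: dict[str, set[str]],
    terms: list[str],
    spec: ClassifierSpec = ClassifierSpec(),
    cfg: BootstrapConfig = BootstrapConfig(),
) -> pd.Series:
    """Per-term AUC of the joint feature block of a selection.

    ``selection`` is a list of dataset ids (looked up in the compendium) or
    of :class:`ExpressionDataset` objects (e.g. a column-subsampled random
    baseline).  The selected datasets' arrays are concatenated (genes
    restricted to the intersection of their coverage) and the bootstrap
    evaluation is run per term; terms with fewer than 2 positives or
    negatives are NaN.
    """
    if not selection:
        raise ValueError("selection is empty")
    chosen = [
        d if isinstance(d, ExpressionDataset) else compendium[d] for d in selection
    ]
    joint = _joint_block(chosen)
    out = {}
    for ti, t in enumerate(terms):
        y = np.where([t in annotations.get(g, ()) for g in joint.gene_ids], 1, -1)
        if (y == 1).sum() < 2 or (y == -1).sum() < 2:
            out[t] = np.nan
            continue
        seed = int(np.random.SeedSequence([cfg.seed, ti]).generate_state(1)[0] % 2**31)
        scores = bootstrap_scores(
            joint.values,
            y,
            spec,
            BootstrapConfig(n_rounds=cfg.n_rounds, seed=seed),
        )
        out[t] = auc(scores, y)
    return pd.Series(out)


def random_equal_array_selection(
    compendium,
    total_arrays: int,
    rng: np.random.Generator,
    exclude: list[str] | None = None,
) -> list[ExpressionDataset]:
    """Random datasets matched to a total array budget.

    Datasets are drawn in random order; the last one is column-subsampled so
    the total array count equals ``total_arrays`` exactly.  Used as the
    random-selection baseline when judging a recommended plan.
    """
    pool = [d for d in compendium if d.dataset_id not in (exclude or [])]
    order = rng.permutation(len(pool))
    picked: list[ExpressionDataset] = []
    remaining = total_arrays
    for k in order:
        ds = pool[k]
        if remaining <= 0:
            break
        if ds.n_arrays <= remaining:
            picked.append(ds)
            remaining -= ds.n_arrays
        else:
            cols = rng.choice(ds.n_arrays, size=remaining, replace=False)
            picked.append(ds.subset_arrays(np.sort(cols)))
            remaining = 0
    return picked
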