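"""Array-saturation analysis: how many arrays does a large dataset need?

Very large expression datasets often reach their full function-prediction
performance with a fraction of their arrays.  Starting from a small number
of randomly selected arrays and progressively increasing it, the bootstrap
informativeness evaluation is repeated over resampling rounds; the mean,
median and standard deviation of AUC per grid point form a saturation
curve, from which the minimum array count within a tolerance of the
full-dataset performance is read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .informativeness import BootstrapConfig, ClassifierSpec, auc, bootstrap_scores

__all__ = [
    "SaturationCurve",
    "NOT_REACHED",
    "default_grid",
    "saturation_curve",
    "minimum_arrays",
]

#: sentinel returned when no grid point reaches the tolerance band
NOT_REACHED = "not reached"

SLIM_AVERAGE = "slim_average"

_DEFAULT_STEPS = (5, 10, 15, 20, 25, 30, 40, 50, 75, 100, 150, 200, 300, 500)


def default_grid(n_arrays: int) -> list[int]:
    """Default increasing grid capped at the dataset size (size included)."""
    grid = [m for m in _DEFAULT_STEPS if m < n_arrays]
    grid.append(n_arrays)
    return grid


@dataclass
class SaturationCurve:
    """Per-grid-point AUC summaries plus the full-dataset reference AUC.

    ``summary`` is indexed by array count m with columns mean/median/sd;
    ``per_round`` holds the raw (m, round, term, auc) records.  ``scope`` is
    a single term id or "slim_average".
    """

    dataset_id: str
    scope: str
    grid: list[int]
    summary: pd.DataFrame
    per_round: pd.DataFrame
    full_auc: float
    n_rounds: int
    skipped: list[int] = field(default_factory=list)


def _evaluate_terms(
    values: np.ndarray,
    labels: dict[str, np.ndarray],
    spec: ClassifierSpec,
    cfg: BootstrapConfig,
) -> dict[str, float]:
    out = {}
    for t, y in labels.items():
        scores = bootstrap_scores(values, y, spec, cfg)
        out[t] = auc(scores, y)
    return out


def saturation_curve(
    ds,
    annotations: dict[str, set[str]],
    terms: list[str],
    grid: list[int] | None = None,
    n_rounds: int = 25,
    seed: int = 0,
    spec: ClassifierSpec = ClassifierSpec(),
    bootstrap_rounds: int = 25,
    scope: str = SLIM_AVERAGE,
) -> SaturationCurve:
    """Subsample arrays on a grid and evaluate function prediction.

    For each grid point m and each of ``n_rounds`` rounds, m arrays are
    drawn uniformly without replacement, the bootstrap evaluation is run on
    the column-restricted dataset for every term, and the slim-average (or
    single-term) AUC is recorded.  Grid points below 2 arrays are skipped
    with a warning entry; the full-dataset AUC is computed once as the
    reference.  Fully seed-deterministic.
    """
    if grid is None:
        grid = default_grid(ds.n_arrays)
    if sorted(grid) != list(grid) or len(set(grid)) != len(grid):
        raise ValueError("grid must be strictly increasing")
    if grid[-1] > ds.n_arrays:
        raise ValueError("grid exceeds the number of arrays")
    if scope != SLIM_AVERAGE:
        terms = [scope]

    genes = ds.gene_ids
    labels = {
        t: np.where([t in annotations.get(g, ()) for g in genes], 1, -1)
        for t in terms
    }
    root = np.random.SeedSequence(seed)
    boot_seed = int(root.generate_state(1)[0] % (2**31))

    full = _evaluate_terms(
        ds.values, labels, spec, BootstrapConfig(n_rounds=bootstrap_rounds, seed=boot_seed)
    )
    full_auc = float(np.mean(list(full.values())))

    rng = np.random.default_rng(root.spawn(1)[0])
    records = []
    skipped = []
    for m in grid:
        if m < 2:
            skipped.append(m)
            continue
        for rnd in range(n_rounds if m < ds.n_arrays else 1):
            cols = rng.choice(ds.n_arrays, size=m, replace=False)
            sub = ds.values[:, np.sort(cols)]
            cfg = BootstrapConfig(
                n_rounds=bootstrap_rounds,
                seed=int(rng.integers(0, 2**31)),
            )
            per_term = _evaluate_terms(sub, labels, spec, cfg)
            for t, a in per_term.items():
                records.append({"m": m, "round": rnd, "term": t, "auc": a})
            records.append(
                {
                    "m": m,
                    "round": rnd,
                    "term": SLIM_AVERAGE,
                    "auc": float(np.mean(list(per_term.values()))),
                }
            )
    per_round = pd.DataFrame.from_records(records)
    scope_term = SLIM_AVERAGE if scope == SLIM_AVERAGE else scope
    sub = per_round[per_round["term"] == scope_term]
    summary = (
        sub.groupby("m")["auc"]
        .agg(mean="mean", median="median", sd=lambda s: float(np.std(s, ddof=0)))
        .sort_index()
    )
    return SaturationCurve(
        dataset_id=ds.dataset_id,
        scope=scope,
        grid=[m for m in grid if m >= 2],
        summary=summary,
        per_round=per_round,
        full_auc=full_auc,
        n_rounds=n_rounds,
        skipped=skipped,
    )


def minimum_arrays(curve: SaturationCurve, tolerance: float = 0.01):
    """Smallest grid point whose mean AUC is within ``tolerance`` of the
    full-dataset AUC, or :data:`NOT_REACHED`.

    Monotone in tolerance: a larger tolerance never yields a larger answer.
    """
    target = curve.full_auc - tolerance
    for m in curve.summary.index:
        if curve.summary.loc[m, "mean"] >= target:
            return int(m)
    return NOT_REACHED
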