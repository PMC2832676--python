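"""Synthetic expression compendia with known ground truth.

The generator plants the statistical structure the planning pipeline is
meant to detect: *informative* datasets in which the genes of a term share
an additive latent per-array response profile (a rank-one signal scaled by
``signal_strength`` on top of unit Gaussian noise), *duplicate* datasets
that repeat another dataset's experiment (source values plus Gaussian
perturbation), and pure *noise* datasets.  Annotations come with a minimal
ontology (a root process term, the slim terms, and one nested child term to
exercise annotation propagation).  Missing values, technical replicates and
signal restricted to a known subset of arrays are all supported, and
generation is fully seed-deterministic.

The default specification builds the study compendium used throughout the
test-bed: 8 datasets of 20 arrays over 400 genes — 3 informative datasets
carrying disjoint pairs of the 6 slim terms, 2 duplicated experiments and 3
noise datasets — with signal strength 2.0 and 5% missing values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gold_standard import OntologyAnnotation
from .io_normalize import Compendium, ExpressionDataset, write_expression

__all__ = [
    "SimulationSpec",
    "default_spec",
    "redundancy_spec",
    "second_round_spec",
    "saturation_spec",
    "simulate_compendium",
    "write_fixture",
]

ROOT_TERM = "GO:0008150"  # biological_process
CHILD_TERM = "GO:CHILD01"  # nested under the first slim term


@dataclass
class SimulationSpec:
    """Declarative description of a synthetic compendium.

    ``terms`` maps term id -> (min size, max size); ``dataset_arrays`` maps
    dataset id -> array count; ``informative_map`` lists the terms each
    dataset carries signal for; ``duplicate_of`` maps a duplicate dataset to
    (source id, perturbation sd); ``signal_arrays`` optionally restricts a
    dataset's signal to given array indices.  ``replicate_copies`` > 1
    emits that many technical-replicate copies per array.
    """

    n_genes: int = 400
    terms: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {f"GO:SLIM{i:02d}": (35, 45) for i in range(1, 7)}
    )
    dataset_arrays: dict[str, int] = field(
        default_factory=lambda: {
            **{f"exp{i:02d}": 20 for i in (1, 2, 3)},
            **{f"noise{i:02d}": 20 for i in (1, 2, 3)},
            "dup01": 20,
            "dup02": 20,
        }
    )
    informative_map: dict[str, set[str]] = field(
        default_factory=lambda: {
            "exp01": {"GO:SLIM01", "GO:SLIM02"},
            "exp02": {"GO:SLIM03", "GO:SLIM04"},
            "exp03": {"GO:SLIM05", "GO:SLIM06"},
        }
    )
    signal_strength: float = 2.0
    duplicate_of: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {"dup01": ("noise01", 0.5), "dup02": ("noise02", 0.5)}
    )
    signal_arrays: dict[str, list[int]] = field(default_factory=dict)
    missing_rate: float = 0.05
    replicate_copies: int = 1
    annotatable_fraction: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        ids = set(self.dataset_arrays)
        if not set(self.informative_map) <= ids:
            raise ValueError("informative_map keys must be dataset ids")
        for dup, (src, sd) in self.duplicate_of.items():
            if dup not in ids or src not in ids:
                raise ValueError(f"duplicate pair ({dup}, {src}) not in dataset ids")
            if src in self.duplicate_of:
                raise ValueError("chained duplicates are not supported")
            if sd < 0:
                raise ValueError("perturbation sd must be >= 0")
            if self.dataset_arrays[dup] != self.dataset_arrays[src]:
                raise ValueError("a duplicate must match its source's array count")
        for t, (lo, hi) in self.terms.items():
            if not 1 <= lo <= hi <= self.n_genes:
                raise ValueError(f"term {t}: invalid size range ({lo}, {hi})")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.replicate_copies < 1:
            raise ValueError("replicate_copies must be >= 1")


def default_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """The default 8-dataset study compendium (see module docstring)."""
    return SimulationSpec(seed=seed, **overrides)


def redundancy_spec(seed: int = 0, perturbation_sd: float = 0.3) -> SimulationSpec:
    """Planted-redundancy variant: duplicates copy the informative datasets.

    Used to study redundancy-aware selection — with duplicates of the best
    datasets in the pool, a pure accuracy sort wastes picks on repeats.
    """
    return SimulationSpec(
        seed=seed,
        duplicate_of={
            "dup01": ("exp01", perturbation_sd),
            "dup02": ("exp02", perturbation_sd),
        },
    )


def second_round_spec(seed: int = 0) -> SimulationSpec:
    """Adds a 7th slim term covered only by a low-overall-accuracy dataset.

    ``special01`` carries signal for GO:SLIM07 alone, so its overall (slim
    average) accuracy trails the three broad informative datasets and a
    short first-round plan leaves GO:SLIM07 weakly covered.
    """
    spec = SimulationSpec(seed=seed)
    spec.terms["GO:SLIM07"] = (35, 45)
    spec.dataset_arrays["special01"] = 20
    spec.informative_map["special01"] = {"GO:SLIM07"}
    return spec


def saturation_spec(
    seed: int = 0,
    n_arrays: int = 100,
    n_signal_arrays: int = 10,
    signal_strength: float = 5.0,
) -> SimulationSpec:
    """One large dataset whose signal lives in a known subset of arrays.

    The informative response is restricted to the first ``n_signal_arrays``
    columns; subsampling fewer arrays than needed to hit them degrades
    prediction, which is what the saturation analysis must detect.  The
    response is strong (default 5 noise SD) so that performance saturates
    once a couple of signal-bearing arrays are covered — the regime the
    minimum-array analysis targets.
    """
    return SimulationSpec(
        seed=seed,
        n_genes=200,
        terms={"GO:SLIM01": (35, 45), "GO:SLIM02": (35, 45)},
        dataset_arrays={"big01": n_arrays},
        informative_map={"big01": {"GO:SLIM01", "GO:SLIM02"}},
        signal_strength=signal_strength,
        signal_arrays={"big01": list(range(n_signal_arrays))},
        duplicate_of={},
        missing_rate=0.0,
    )


def _assign_terms(
    spec: SimulationSpec, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Sample each term's member genes (overlaps allowed)."""
    genes = [f"gene{i:04d}" for i in range(spec.n_genes)]
    annotatable = max(2, int(spec.n_genes * spec.annotatable_fraction))
    members: dict[str, list[str]] = {}
    for t in sorted(spec.terms):
        lo, hi = spec.terms[t]
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(annotatable, size=size, replace=False)
        members[t] = [genes[i] for i in sorted(idx)]
    return members


def simulate_compendium(
    spec: SimulationSpec,
) -> tuple[Compendium, OntologyAnnotation, dict]:
    """Generate (compendium, annotations, truth) from a specification.

    Masked cells are NaN in ``values`` with ``missing_mask`` set.  The truth
    dict records term members, the informative map, duplicate structure,
    signal arrays and the seed, for assertions against recovered structure.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i:04d}" for i in range(spec.n_genes)]
    members = _assign_terms(spec, rng)
    slim_terms = set(spec.terms)

    # minimal DAG: slim terms under the root, one child under the first slim
    term_list = sorted(slim_terms)
    dag_parents = {t: {ROOT_TERM} for t in term_list}
    dag_parents[ROOT_TERM] = set()
    dag_parents[CHILD_TERM] = {term_list[0]}
    direct: dict[str, set[str]] = {}
    child_members = set(members[term_list[0]][: len(members[term_list[0]]) // 2])
    for t, mem in members.items():
        for g in mem:
            if t == term_list[0] and g in child_members:
                direct.setdefault(g, set()).add(CHILD_TERM)
            else:
                direct.setdefault(g, set()).add(t)

    gene_row = {g: i for i, g in enumerate(genes)}
    raw_values: dict[str, np.ndarray] = {}
    datasets: list[ExpressionDataset] = []
    order = [d for d in sorted(spec.dataset_arrays) if d not in spec.duplicate_of]
    order += sorted(spec.duplicate_of)
    for ds_id in order:
        n_arr = spec.dataset_arrays[ds_id]
        if ds_id in spec.duplicate_of:
            src, sd = spec.duplicate_of[ds_id]
            X = raw_values[src] + rng.normal(0.0, sd, size=raw_values[src].shape)
        else:
            X = rng.normal(size=(spec.n_genes, n_arr))
            for t in sorted(spec.informative_map.get(ds_id, ())):
                profile = rng.normal(size=n_arr)
                allowed = spec.signal_arrays.get(ds_id)
                if allowed is not None:
                    mask = np.zeros(n_arr)
                    mask[list(allowed)] = 1.0
                    profile = profile * mask
                rows = [gene_row[g] for g in members[t]]
                X[rows] += spec.signal_strength * profile
        raw_values[ds_id] = X

        if spec.replicate_copies > 1:
            copies = [
                X + rng.normal(0.0, 0.05, size=X.shape)
                for _ in range(spec.replicate_copies)
            ]
            full = np.empty((spec.n_genes, n_arr * spec.replicate_copies))
            array_ids = []
            groups = []
            for a in range(n_arr):
                grp = []
                for c in range(spec.replicate_copies):
                    j = a * spec.replicate_copies + c
                    full[:, j] = copies[c][:, a]
                    aid = f"{ds_id}_a{a:03d}r{c}"
                    array_ids.append(aid)
                    grp.append(aid)
                groups.append(grp)
            X_out, ids_out, groups_out = full, array_ids, groups
        else:
            X_out = X.copy()
            ids_out = [f"{ds_id}_a{a:03d}" for a in range(n_arr)]
            groups_out = [[a] for a in ids_out]

        if spec.missing_rate > 0:
            mask = rng.random(X_out.shape) < spec.missing_rate
            X_out = np.where(mask, np.nan, X_out)
        else:
            mask = np.zeros(X_out.shape, dtype=bool)
        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                gene_ids=list(genes),
                array_ids=ids_out,
                values=X_out,
                missing_mask=mask,
                replicate_groups=groups_out,
            )
        )

    datasets.sort(key=lambda d: list(spec.dataset_arrays).index(d.dataset_id))
    ontology = OntologyAnnotation(
        term_ids={ROOT_TERM, CHILD_TERM} | slim_terms,
        dag_parents=dag_parents,
        direct_annotations=direct,
        slim_terms=slim_terms,
    )
    truth = {
        "seed": spec.seed,
        "term_members": {t: list(m) for t, m in members.items()},
        "informative_map": {d: sorted(ts) for d, ts in spec.informative_map.items()},
        "duplicate_of": {d: [s, sd] for d, (s, sd) in spec.duplicate_of.items()},
        "signal_arrays": {d: list(a) for d, a in spec.signal_arrays.items()},
        "signal_strength": spec.signal_strength,
        "missing_rate": spec.missing_rate,
    }
    return Compendium(datasets=datasets), ontology, truth


def write_fixture(
    compendium: Compendium,
    ontology: OntologyAnnotation,
    truth: dict,
    out_dir: str | Path,
) -> None:
    """Write a simulated fixture as plain-text files.

    Emits one TSV per dataset (under ``datasets/``), a two-column propagated
    gene->term table, the slim list and a truth JSON; everything needed to
    re-run the pipeline from disk.
    """
    from .gold_standard import propagate_annotations

    out = Path(out_dir)
    (out / "datasets").mkdir(parents=True, exist_ok=True)
    for ds in compendium:
        write_expression(ds, out / "datasets" / f"{ds.dataset_id}.tsv")
    propagated = propagate_annotations(ontology.direct_annotations, ontology)
    with open(out / "annotations.tsv", "w") as fh:
        for g in sorted(propagated):
            for t in sorted(propagated[g]):
                fh.write(f"{g}\t{t}\n")
    with open(out / "slim.txt", "w") as fh:
        for t in sorted(ontology.slim_terms):
            fh.write(t + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
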