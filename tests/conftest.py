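import numpy as np
import pytest

import expplan as ep


@pytest.fixture(scope="session")
def default_runs():
    """Full pipeline products for 10 seeds of the default synthetic compendium.

    Shared by the redundancy-detection, plan-recovery and greedy-vs-random
    checks; bootstrap rounds are reduced to 10 to keep runs quick.
    """
    runs = []
    for seed in range(10):
        comp, onto, truth = ep.simulate_compendium(ep.default_spec(seed=seed))
        norm = ep.Compendium(datasets=[ep.normalize(d) for d in comp])
        ann = ep.propagate_annotations(onto.direct_annotations, onto)
        terms = sorted(onto.slim_terms)
        im = ep.informativeness_matrix(
            norm, ann, terms, cfg=ep.BootstrapConfig(n_rounds=10, seed=seed)
        )
        acc = ep.overall_accuracy(im, onto.slim_terms)
        fr = ep.pair_fr_labels(ann, onto.slim_terms, sorted(norm.gene_universe))
        cm = ep.cmi_matrix(norm, fr, seed=seed)
        plan = ep.greedy_select(
            acc, cm.values, ep.TradeoffConfig(alpha=0.9, list_length=3)
        )
        runs.append(
            {
                "seed": seed,
                "compendium": norm,
                "ontology": onto,
                "truth": truth,
                "annotations": ann,
                "terms": terms,
                "im": im,
                "accuracy": acc,
                "cmi": cm,
                "plan": plan,
            }
        )
    return runs


@pytest.fixture
def toy_dataset():
    """6 genes x 4 arrays, complete, for small-scale exercises."""
    rng = np.random.default_rng(42)
    values = rng.normal(size=(6, 4))
    return ep.ExpressionDataset(
        dataset_id="toy",
        gene_ids=[f"g{i}" for i in range(6)],
        array_ids=[f"a{j}" for j in range(4)],
        values=values,
        missing_mask=np.zeros((6, 4), dtype=bool),
    )
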