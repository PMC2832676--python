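import numpy as np
import pandas as pd
import pytest

import expplan as ep
from expplan.recommend import PlanEntry, RecommendationPlan
from expplan.saturation import NOT_REACHED


def random_tables(rng, n=6):
    ids = [f"d{i}" for i in range(n)]
    acc = pd.Series(rng.random(n) * 0.4 + 0.5, index=ids)
    m = rng.random((n, n)) * 2
    m = (m + m.T) / 2
    np.fill_diagonal(m, 3.0)
    cmi = pd.DataFrame(m, index=ids, columns=ids)
    return acc, cmi


def greedy_trace_oracle(acc, cmi, alpha, warm=()):
    """Independent step-by-step enumeration of the greedy rule."""
    acc_n = acc.astype(float)
    off = cmi.values[~np.eye(len(cmi), dtype=bool)]
    lo, hi = off.min(), off.max()
    cmi_n = (cmi - lo) / (hi - lo) if hi > lo else cmi * 0.0
    selected = list(warm)
    order = []
    candidates = [d for d in acc.index if d not in selected]
    while candidates:
        scores = {}
        for d in candidates:
            k = len(selected)
            red = sum(cmi_n.loc[d, y] for y in selected) / k if k else 0.0
            scores[d] = alpha * acc_n[d] - (1 - alpha) * red
        best = max(sorted(scores), key=lambda d: scores[d])
        order.append(best)
        selected.append(best)
        candidates.remove(best)
    return order


class TestGreedySelect:
    @pytest.mark.parametrize("seed", range(10))
    def test_alpha_one_equals_accuracy_sort(self, seed):
        acc, cmi = random_tables(np.random.default_rng(seed))
        plan = ep.greedy_select(acc, cmi, ep.TradeoffConfig(alpha=1.0))
        assert plan.dataset_ids == list(acc.sort_values(ascending=False).index)

    @pytest.mark.parametrize("seed", range(10))
    def test_alpha_zero_minimizes_mean_cmi(self, seed):
        rng = np.random.default_rng(100 + seed)
        acc, cmi = random_tables(rng)
        warm = [acc.index[0]]
        plan = ep.greedy_select(acc, cmi, ep.TradeoffConfig(alpha=0.0), warm_start=warm)
        # re-derive each pick: it must minimize mean CMI to the selected set
        off = cmi.values[~np.eye(len(cmi), dtype=bool)]
        cmi_n = (cmi - off.min()) / (off.max() - off.min())
        selected = list(warm)
        for d in plan.dataset_ids:
            others = [c for c in acc.index if c not in selected]
            mean_cmi = {c: np.mean([cmi_n.loc[c, y] for y in selected]) for c in others}
            assert mean_cmi[d] == min(mean_cmi.values())
            selected.append(d)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.9])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_trace_oracle(self, alpha, seed):
        acc, cmi = random_tables(np.random.default_rng(1000 + seed))
        plan = ep.greedy_select(acc, cmi, ep.TradeoffConfig(alpha=alpha))
        assert plan.dataset_ids == greedy_trace_oracle(acc, cmi, alpha)

    def test_duplicate_deferred_below_orthogonal_dataset(self):
        # d_b duplicates d_a (high CMI); at alpha=0.5 the orthogonal d_c is
        # picked second despite lower accuracy
        ids = ["d_a", "d_b", "d_c", "d_d"]
        acc = pd.Series([0.80, 0.79, 0.70, 0.55], index=ids)
        m = np.full((4, 4), 0.1)
        m[0, 1] = m[1, 0] = 2.0
        np.fill_diagonal(m, 3.0)
        cmi = pd.DataFrame(m, index=ids, columns=ids)
        plan = ep.greedy_select(acc, cmi, ep.TradeoffConfig(alpha=0.5))
        assert plan.dataset_ids[0] == "d_a"
        assert plan.dataset_ids[1] == "d_c"
        assert plan.dataset_ids.index("d_b") > plan.dataset_ids.index("d_c")

    def test_warm_start_first_pick_and_no_rerecommendation(self):
        rng = np.random.default_rng(5)
        acc, cmi = random_tables(rng)
        warm = ["d1"]
        plan = ep.greedy_select(acc, cmi, ep.TradeoffConfig(alpha=0.7), warm_start=warm)
        assert "d1" not in plan.dataset_ids
        assert plan.dataset_ids == greedy_trace_oracle(acc, cmi, 0.7, warm=("d1",))

    def test_deterministic_tie_break_lexicographic(self):
        ids = ["b", "a", "c"]
        acc = pd.Series([0.7, 0.7, 0.7], index=ids)
        cmi = pd.DataFrame(0.0, index=ids, columns=ids)
        plan = ep.greedy_select(acc, cmi, ep.TradeoffConfig(alpha=1.0, cmi_norm="none"))
        assert plan.dataset_ids == ["a", "b", "c"]

    def test_missing_cmi_excludes_candidate(self):
        ids = ["a", "b", "c"]
        acc = pd.Series([0.9, 0.8, 0.7], index=ids)
        m = pd.DataFrame(0.1, index=ids, columns=ids)
        m.loc["b", "a"] = m.loc["a", "b"] = np.nan
        with pytest.warns(UserWarning, match="undefined CMI"):
            plan = ep.greedy_select(acc, m, ep.TradeoffConfig(alpha=0.5, cmi_norm="none"))
        assert plan.dataset_ids == ["a", "c", "b"] or plan.dataset_ids == ["a", "c"]


class TestAttachMinArrays:
    def make_plan(self, ids):
        return RecommendationPlan(
            entries=[PlanEntry(d, i + 1, 0.0, 0.0, 0.0) for i, d in enumerate(ids)]
        )

    def test_large_dataset_carries_min_call(self):
        plan = ep.attach_min_arrays(
            self.make_plan(["big"]), {"big": 30}, {"big": 300}, large_threshold=50
        )
        assert plan.entries[0].recommended_array_count == 30

    def test_small_dataset_carries_full_size(self):
        plan = ep.attach_min_arrays(self.make_plan(["small"]), {}, {"small": 12})
        assert plan.entries[0].recommended_array_count == 12

    def test_not_reached_flagged_full_size(self):
        plan = ep.attach_min_arrays(
            self.make_plan(["big"]), {"big": NOT_REACHED}, {"big": 200}
        )
        assert plan.entries[0].recommended_array_count == 200
        assert "saturation_not_reached" in plan.entries[0].flags


class TestWeakTerms:
    def test_threshold_and_gene_floor(self):
        auc = pd.Series({"t1": 0.64, "t2": 0.64, "t3": 0.65, "t4": 0.9})
        npos = pd.Series({"t1": 40, "t2": 20, "t3": 40, "t4": 40})
        assert ep.weak_terms(auc, npos) == ["t1"]  # t2 too few genes,
        # t3 exactly at threshold (strictly below required), t4 accurate


def hand_im(auc_dict):
    auc_df = pd.DataFrame(auc_dict)
    return ep.InformativenessMatrix(
        auc=auc_df, precision_at={}, n_pos=auc_df * 0, n_neg=auc_df * 0
    )


class TestSecondRound:
    def test_best_covering_dataset_added_with_annotation(self):
        im = hand_im({"T": {"d1": 0.6, "d2": 0.9, "d3": 0.8}})
        plan = RecommendationPlan(entries=[PlanEntry("d1", 1, 0, 0, 0)])
        out = ep.second_round(["T"], im, plan)
        added = [e for e in out.entries if e.round == "second"]
        assert [e.dataset_id for e in added] == ["d2"]
        assert added[0].target_terms == ["T"]
        assert plan.dataset_ids == ["d1"]  # input untouched

    def test_all_coverers_already_selected(self):
        im = hand_im({"T": {"d1": 0.9, "d2": 0.45}})
        plan = RecommendationPlan(entries=[PlanEntry("d1", 1, 0, 0, 0)])
        with pytest.warns(UserWarning, match="uncoverable"):
            out = ep.second_round(["T"], im, plan)
        assert out.dataset_ids == ["d1"]
        assert out.uncoverable == ["T"]

    def test_shared_dataset_deduplicated_across_terms(self):
        im = hand_im(
            {"T1": {"d1": 0.5, "d2": 0.9}, "T2": {"d1": 0.5, "d2": 0.8}}
        )
        plan = RecommendationPlan(entries=[PlanEntry("d1", 1, 0, 0, 0)])
        out = ep.second_round(["T1", "T2"], im, plan)
        added = [e for e in out.entries if e.round == "second"]
        assert len(added) == 1
        assert added[0].target_terms == ["T1", "T2"]


class TestEvaluateSelection:
    def test_single_dataset_equals_direct_bootstrap(self, default_runs):
        run = default_runs[0]
        comp, ann, terms = run["compendium"], run["annotations"], run["terms"]
        cfg = ep.BootstrapConfig(n_rounds=6, seed=77)
        ev = ep.evaluate_selection(comp, ["exp01"], ann, terms[:2], cfg=cfg)
        ds = comp["exp01"]
        for ti, t in enumerate(terms[:2]):
            y = np.where([t in ann.get(g, ()) for g in ds.gene_ids], 1, -1)
            seed = int(np.random.SeedSequence([77, ti]).generate_state(1)[0] % 2**31)
            scores = ep.bootstrap_scores(
                ds.values, y, cfg=ep.BootstrapConfig(n_rounds=6, seed=seed)
            )
            assert ev[t] == pytest.approx(ep.auc(scores, y))

    def test_empty_selection_rejected(self, default_runs):
        run = default_runs[0]
        with pytest.raises(ValueError):
            ep.evaluate_selection(run["compendium"], [], run["annotations"], run["terms"])

    def test_random_selection_matches_array_budget(self, default_runs):
        comp = default_runs[0]["compendium"]
        rng = np.random.default_rng(0)
        sel = ep.random_equal_array_selection(comp, 45, rng)
        assert sum(d.n_arrays for d in sel) == 45


class TestAlphaSweep:
    def test_interior_alpha_best_with_redundant_duplicates(self):
        """When duplicates of the best datasets are in the pool, a pure
        accuracy sort (alpha=1) wastes picks on repeats and a pure
        redundancy objective (alpha=0) ignores accuracy; an interior alpha
        maximizes the evaluated mean slim AUC."""
        alphas = [0.0, 0.25, 0.5, 0.75, 0.9, 1.0]
        means = {a: [] for a in alphas}
        for seed in range(3):
            comp, onto, _ = ep.simulate_compendium(ep.redundancy_spec(seed=seed))
            norm = ep.Compendium(datasets=[ep.normalize(d) for d in comp])
            ann = ep.propagate_annotations(onto.direct_annotations, onto)
            terms = sorted(onto.slim_terms)
            im = ep.informativeness_matrix(
                norm, ann, terms, cfg=ep.BootstrapConfig(n_rounds=10, seed=seed)
            )
            acc = ep.overall_accuracy(im, onto.slim_terms)
            fr = ep.pair_fr_labels(ann, onto.slim_terms, sorted(norm.gene_universe))
            cm = ep.cmi_matrix(norm, fr, seed=seed)
            for a in alphas:
                plan = ep.greedy_select(
                    acc, cm.values, ep.TradeoffConfig(alpha=a, list_length=3)
                )
                ev = ep.evaluate_selection(
                    norm, plan.dataset_ids, ann, terms,
                    cfg=ep.BootstrapConfig(n_rounds=10, seed=seed + 900),
                )
                means[a].append(ev.mean())
        avg = {a: np.mean(v) for a, v in means.items()}
        best_interior = max(avg[a] for a in (0.5, 0.75, 0.9))
        assert best_interior > avg[0.0]
        assert best_interior > avg[1.0]


class TestPlanRecovery:
    def test_top3_are_the_informative_datasets(self, default_runs):
        """End-to-end: with the default planted compendium, the alpha=0.9
        greedy plan's top 3 recover the 3 informative datasets in >=9/10 seeds."""
        hits = sum(
            set(run["plan"].dataset_ids) == {"exp01", "exp02", "exp03"}
            for run in default_runs
        )
        assert hits >= 9
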