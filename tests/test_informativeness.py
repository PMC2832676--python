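import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import expplan as ep
from expplan.informativeness import bootstrap_distinct_fraction


def brute_force_auc(scores, y):
    """Exhaustive pos x neg pair counting, ties worth 1/2."""
    pos = [s for s, l in zip(scores, y) if l == 1]
    neg = [s for s, l in zip(scores, y) if l == -1]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_ranking(self):
        assert ep.auc([3, 2, 1], [1, 1, -1]) == 1.0

    def test_all_ties_half(self):
        assert ep.auc([5.0] * 6, [1, 1, 1, -1, -1, -1]) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            scores = rng.integers(0, 6, size=n).astype(float)  # forces ties
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if (y == 1).sum() == 0 or (y == -1).sum() == 0:
                continue
            assert ep.auc(scores, y) == pytest.approx(
                brute_force_auc(scores, y), abs=0
            )

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            ep.auc([1.0, 2.0], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_antisymmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        scores = rng.normal(size=n)  # tie-free almost surely
        y = np.where(rng.random(n) < 0.4, 1, -1)
        if (y == 1).sum() == 0 or (y == -1).sum() == 0:
            return
        a = ep.auc(scores, y)
        assert ep.auc(-scores, y) == pytest.approx(1.0 - a)
        assert ep.auc(np.exp(3 * scores), y) == pytest.approx(a)


class TestPrecisionAtRecall:
    def test_perfect_ranking_all_levels(self):
        scores = [5, 4, 3, 2, 1]
        y = [1, 1, -1, -1, -1]
        out = ep.precision_at_recall(scores, y, (0.01, 0.5, 1.0))
        assert all(v == 1.0 for v in out.values())

    def test_hand_enumerated_interleaved_list(self):
        # ranked P, N, P, N: recall 0.5 at the first item (precision 1),
        # recall 1.0 first reached at the third item (precision 2/3)
        scores = [4, 3, 2, 1]
        y = [1, -1, 1, -1]
        out = ep.precision_at_recall(scores, y, (0.5, 1.0))
        assert out[0.5] == 1.0
        assert out[1.0] == pytest.approx(2 / 3)

    def test_low_level_ceil_semantics(self):
        # 1% of 10 positives still requires >= 1 true positive
        scores = np.arange(20, 0, -1).astype(float)
        y = [-1] + [1] * 10 + [-1] * 9
        out = ep.precision_at_recall(scores, y, (0.01,))
        assert out[0.01] == pytest.approx(1 / 2)  # first positive is ranked 2nd

    def test_tied_block_included_whole(self):
        scores = [2.0, 1.0, 1.0, 1.0]
        y = [-1, 1, 1, -1]
        out = ep.precision_at_recall(scores, y, (0.5,))
        # threshold cannot split the tie: block of three enters together
        assert out[0.5] == pytest.approx(2 / 4)


class TestWeightedLinear:
    def separable(self):
        rng = np.random.default_rng(0)
        Xp = rng.normal(loc=+2, size=(10, 2))
        Xn = rng.normal(loc=-2, size=(30, 2))
        X = np.vstack([Xp, Xn])
        y = np.array([1] * 10 + [-1] * 30)
        return X, y

    def test_separable_scores_rank_perfectly(self):
        X, y = self.separable()
        predict = ep.train_weighted_linear(X, y)
        assert ep.auc(predict(X), y) == 1.0

    def test_single_class_raises(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            ep.train_weighted_linear(X, np.array([1, 1, 1, 1]))

    def test_larger_cost_weight_raises_positive_recall(self):
        # imbalanced, overlapping fixture: heavier j pushes the boundary
        # toward the negatives, so more positives clear threshold 0
        rng = np.random.default_rng(7)
        Xp = rng.normal(loc=0.6, size=(5, 2))
        Xn = rng.normal(loc=-0.6, size=(15, 2))
        X = np.vstack([Xp, Xn])
        y = np.array([1] * 5 + [-1] * 15)
        spec_lo = ep.ClassifierSpec(cost_weight_j=1.0)
        spec_hi = ep.ClassifierSpec(cost_weight_j=16.0)
        rec_lo = (ep.train_weighted_linear(X, y, spec_lo)(Xp) > 0).mean()
        rec_hi = (ep.train_weighted_linear(X, y, spec_hi)(Xp) > 0).mean()
        assert rec_hi >= rec_lo
        assert rec_hi > 0.5

    def test_hinge_and_squared_hinge_rank_alike(self):
        X, y = self.separable()
        s1 = ep.train_weighted_linear(X, y, ep.ClassifierSpec(loss="hinge"))(X)
        s2 = ep.train_weighted_linear(X, y, ep.ClassifierSpec(loss="squared_hinge"))(X)
        assert ep.auc(s1, y) == ep.auc(s2, y) == 1.0


class TestBootstrapScores:
    def test_distinct_fraction_near_632(self):
        rng = np.random.default_rng(1)
        fracs = [bootstrap_distinct_fraction(500, rng) for _ in range(200)]
        assert np.mean(fracs) == pytest.approx(0.632, abs=0.01)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = np.where(rng.random(40) < 0.3, 1, -1)
        cfg = ep.BootstrapConfig(n_rounds=8, seed=123)
        s1 = ep.bootstrap_scores(X, y, cfg=cfg)
        s2 = ep.bootstrap_scores(X, y, cfg=cfg)
        np.testing.assert_array_equal(s1, s2)

    def test_permuted_labels_give_null_auc(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 6))
        y = np.where(rng.random(120) < 0.25, 1, -1)  # labels independent of X
        aucs = []
        for seed in range(5):
            s = ep.bootstrap_scores(X, y, cfg=ep.BootstrapConfig(n_rounds=10, seed=seed))
            aucs.append(ep.auc(s, y))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_requires_two_per_class(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            ep.bootstrap_scores(X, np.array([1, -1, -1, -1, -1]))


class TestPlantedSignalRecovery:
    def test_planted_dataset_beats_noise_dataset(self):
        """A dataset whose positives share a response profile must score a
        higher AUC than an equal-shape pure-noise dataset on the same labels,
        in at least 19 of 20 simulation replicates."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, m = 200, 12
            y = np.full(n, -1)
            y[rng.choice(n, size=30, replace=False)] = 1
            noise = rng.normal(size=(n, m))
            planted = rng.normal(size=(n, m))
            planted[y == 1] += 2.0 * rng.normal(size=m)
            cfg = ep.BootstrapConfig(n_rounds=10, seed=seed)
            a_planted = ep.auc(ep.bootstrap_scores(planted, y, cfg=cfg), y)
            a_noise = ep.auc(ep.bootstrap_scores(noise, y, cfg=cfg), y)
            wins += a_planted > a_noise
        assert wins >= 19


class TestOverallAccuracy:
    def make_im(self, aucs):
        import pandas as pd

        auc_df = pd.DataFrame(aucs)
        return ep.InformativenessMatrix(
            auc=auc_df,
            precision_at={},
            n_pos=auc_df * 0,
            n_neg=auc_df * 0,
        )

    def test_mean_over_slim_terms(self):
        im = self.make_im({"S1": [0.6], "S2": [0.8], "other": [0.99]})
        acc = ep.overall_accuracy(im, {"S1", "S2"})
        assert acc.iloc[0] == pytest.approx(0.7)

    def test_skipped_terms_excluded_from_mean(self):
        im = self.make_im({"S1": [0.9], "S2": [np.nan]})
        assert ep.overall_accuracy(im, {"S1", "S2"}).iloc[0] == pytest.approx(0.9)

    def test_no_slim_terms_raises(self):
        im = self.make_im({"S1": [np.nan]})
        with pytest.raises(ValueError):
            ep.overall_accuracy(im, {"S1"})
        with pytest.raises(ValueError):
            ep.overall_accuracy(im, {"absent"})
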