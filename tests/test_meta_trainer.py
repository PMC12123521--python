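"""Episode sampling, inner adaptation, the Reptile update, ROC-AUC."""

import numpy as np
import pytest

from molfuse import meta_trainer as mt
from molfuse.fusion_model import MolPropertyModel
from molfuse.meta_trainer import (
    inner_adapt,
    reptile_outer_update,
    roc_auc,
    sample_episode,
)


@pytest.fixture(scope="module")
def model():
    return MolPropertyModel(n_tasks=1, seed=21)


class TestRocAuc:
    def test_perfect_and_inverted_ranking(self):
        y = [0, 0, 1, 1]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], y) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], y) == 0.0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=8)
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert abs(roc_auc(scores, labels) - wins / (len(pos) * len(neg))) < 1e-12

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestSampleEpisode:
    def test_two_way_three_shot_sizes(self, tasks, cache_plain):
        ep = sample_episode(tasks["halo"], cache_plain, way=2, shot=3, ratio=5,
                            rng=np.random.default_rng(0))
        assert len(ep.support) == 6
        assert len(ep.query) == 30
        labels = [t[2] for t in ep.support]
        assert labels.count(1.0) == 3 and labels.count(0.0) == 3

    def test_table_ratio_support_12_query_60(self, tasks, cache_plain):
        ep = sample_episode(tasks["amide"], cache_plain, way=2, shot=6, ratio=5,
                            rng=np.random.default_rng(1))
        assert (len(ep.support), len(ep.query)) == (12, 60)

    def test_support_query_disjoint_many_draws(self, tasks, cache_plain):
        rng = np.random.default_rng(2)
        for _ in range(200):
            task = tasks[list(tasks)[rng.integers(5)]]
            ep = sample_episode(task, cache_plain, rng=rng)
            if ep is None:
                continue
            sup = {id(t[0]) for t in ep.support}
            qry = {id(t[0]) for t in ep.query}
            sup_s = {t[0].smiles for t in ep.support}
            qry_s = {t[0].smiles for t in ep.query}
            assert not sup_s & qry_s, (sup, qry)

    def test_deterministic_under_seed(self, tasks, cache_plain):
        e1 = sample_episode(tasks["halo"], cache_plain, rng=np.random.default_rng(7))
        e2 = sample_episode(tasks["halo"], cache_plain, rng=np.random.default_rng(7))
        assert [t[0].smiles for t in e1.support] == [t[0].smiles for t in e2.support]
        assert [t[0].smiles for t in e1.query] == [t[0].smiles for t in e2.query]

    def test_insufficient_data_returns_none(self, cache_plain, molecules_300):
        from molfuse.data_io import MoleculeRecord, SplitAssignment

        recs = [MoleculeRecord(s, np.array([float(i % 2)]), ["t"])
                for i, s in enumerate(molecules_300[:10])]
        task = mt.TaskData("t", recs, np.array([r.labels[0] for r in recs]),
                           SplitAssignment(list(range(10)), [], []))
        assert sample_episode(task, cache_plain, rng=np.random.default_rng(0)) is None


class TestInnerAdapt:
    def test_noop_adaptation_returns_theta(self, model, tasks, cache_plain):
        theta = model.get_flat()
        ep = sample_episode(tasks["halo"], cache_plain, rng=np.random.default_rng(3))
        theta_pp = inner_adapt(model, theta, ep, inner_steps=0, alpha=0.01, beta=0.0)
        assert np.array_equal(theta_pp, theta)

    def test_three_steps_match_scalar_gd_oracle(self):
        """Plain GD on the BCE of a single logistic parameter matches a
        hand-iterated scalar recursion."""
        from molfuse.autodiff import Parameter, Tensor

        w = Parameter(np.array([0.3]))
        x, y = 2.0, 1.0
        lr = 0.1
        # engine: 3 GD steps on BCE(sigmoid(w*x), y)
        for _ in range(3):
            w.zero_grad()
            p = (Tensor(np.array([x])) * w).sigmoid()
            loss = -(p.log() * y).sum()
            loss.backward()
            w.data = w.data - lr * w.grad
        # oracle: d/dw BCE = (sigmoid(wx) - y) * x
        w_o = 0.3
        for _ in range(3):
            s = 1 / (1 + np.exp(-w_o * x))
            w_o -= lr * (s - y) * x
        assert abs(w.data[0] - w_o) < 1e-12

    def test_meta_theta_untouched_and_deterministic(self, model, tasks, cache_plain):
        theta = model.get_flat()
        theta_copy = theta.copy()
        ep = sample_episode(tasks["halo"], cache_plain, rng=np.random.default_rng(4))
        t1 = inner_adapt(model, theta, ep, inner_steps=2, alpha=0.01, beta=0.01)
        t2 = inner_adapt(model, theta, ep, inner_steps=2, alpha=0.01, beta=0.01)
        assert np.array_equal(theta, theta_copy)
        assert np.array_equal(t1, t2)
        assert not np.array_equal(t1, theta)


class TestReptileOuterUpdate:
    def test_fixed_point(self):
        theta = np.arange(5.0)
        assert np.array_equal(reptile_outer_update(theta, [theta.copy()] * 3, 0.7), theta)

    def test_full_interpolation_single_task(self):
        theta = np.zeros(4)
        tpp = np.array([1.0, -2.0, 3.0, 0.5])
        assert np.array_equal(reptile_outer_update(theta, [tpp], 1.0), tpp)

    def test_three_tasks_mean_interpolation(self):
        theta = np.array([1.0, 1.0])
        adapted = [np.array([2.0, 0.0]), np.array([4.0, 1.0]), np.array([0.0, 2.0])]
        out = reptile_outer_update(theta, adapted, 0.5)
        assert np.allclose(out, theta + 0.5 * (np.mean(adapted, axis=0) - theta))

    def test_interpolation_stays_in_convex_hull(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(size=10)
        adapted = [rng.normal(size=10) for _ in range(3)]
        mean = np.mean(adapted, axis=0)
        for eps in (0.0, 0.3, 1.0):
            out = reptile_outer_update(theta, adapted, eps)
            lo = np.minimum(theta, mean) - 1e-12
            hi = np.maximum(theta, mean) + 1e-12
            assert ((out >= lo) & (out <= hi)).all()

    def test_empty_task_list_raises(self):
        with pytest.raises(ValueError):
            reptile_outer_update(np.zeros(3), [], 0.1)


class TestFinetune:
    def test_zero_epochs_identity(self, model, tasks, cache_plain):
        theta = model.get_flat()
        out, hist = mt.finetune(model, theta, tasks["halo"], cache_plain, epochs=0)
        assert np.array_equal(out, theta)
        assert hist == []

    def test_best_so_far_selection(self, model, tasks, cache_plain):
        theta = model.get_flat()
        out, hist = mt.finetune(model, theta, tasks["halo"], cache_plain,
                                epochs=2, lr=0.01, seed=0, max_train=24)
        best = max(h["valid_auc"] for h in hist)
        got = mt.evaluate(model, out, tasks["halo"], cache_plain, "valid")
        assert abs(got - best) < 1e-9


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        scores=arrays(np.float64, 10, elements=st.floats(-3, 3)),
        labels=arrays(np.int64, 10, elements=st.integers(0, 1)),
    )
    def test_roc_auc_property_matches_pair_counting(scores, labels):
        """For any scores and any two-class labelling, ROC-AUC equals the
        Mann–Whitney pair statistic."""
        if len(np.unique(labels)) < 2:
            labels = labels.copy()
            labels[0], labels[1] = 0, 1
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert abs(roc_auc(scores, labels) - wins / (len(pos) * len(neg))) < 1e-12

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        theta=arrays(np.float64, 8, elements=st.floats(-5, 5)),
        deltas=arrays(np.float64, (3, 8), elements=st.floats(-5, 5)),
        eps=st.floats(0.0, 1.0),
    )
    def test_reptile_update_property_convex_hull(theta, deltas, eps):
        """The outer update always lands between θ and the mean adapted
        vector, coordinatewise, for ε in [0,1]."""
        adapted = [theta + d for d in deltas]
        out = reptile_outer_update(theta, adapted, eps)
        mean = np.mean(adapted, axis=0)
        lo, hi = np.minimum(theta, mean) - 1e-9, np.maximum(theta, mean) + 1e-9
        assert ((out >= lo) & (out <= hi)).all()
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass
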