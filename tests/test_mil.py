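"""MIL algebra, focal loss, Fisher vectors, splitting and training."""

import numpy as np
import pandas as pd
import pytest
from sklearn.mixture import GaussianMixture

from milscore.features import EmbeddingBag
from milscore.mil import (
    ModelConfig,
    RNNAggregator,
    SAAbMILP,
    _focal_grad,
    fisher_vector_encode,
    focal_loss,
    predict,
    split_dataset,
    train,
)


def _model(d=16, n_classes=2, sa=True, gated=True, seed=0, L=8):
    cfg = ModelConfig(
        n_classes=n_classes, attention_hidden=L, self_attention=sa, gated=gated
    )
    m = SAAbMILP(d, cfg, seed=seed)
    if sa:
        m.params["g"] = np.array(0.4)  # exercise the self-attention path
    return m


class TestAttentionAlgebra:
    def test_single_instance_weight_is_exactly_one(self, rng):
        m = _model()
        out = m.forward(rng.standard_normal((1, 16)))
        assert out.a.tolist() == [1.0]

    def test_two_identical_instances_split_evenly(self, rng):
        m = _model()
        h = rng.standard_normal(16)
        out = m.forward(np.stack([h, h]))
        assert np.allclose(out.a, [0.5, 0.5], atol=1e-6)

    def test_fuzzed_bags_sum_to_one_and_permutation_invariance(self, rng):
        """1000 fuzzed bags: weights form a distribution; permuting the bag
        permutes the weights and leaves z unchanged."""
        models = [
            _model(sa=sa, gated=g, seed=s)
            for sa in (True, False)
            for g in (True, False)
            for s in (0, 1)
        ]
        for i in range(1000):
            m = models[i % len(models)]
            n = int(rng.integers(1, 12))
            H = rng.standard_normal((n, 16)) * rng.uniform(0.3, 3.0)
            out = m.forward(H)
            assert (out.a >= 0).all()
            assert abs(out.a.sum() - 1.0) <= 1e-6
            perm = rng.permutation(n)
            out_p = m.forward(H[perm])
            assert np.allclose(out_p.a, out.a[perm], atol=1e-9)
            assert np.allclose(out_p.z, out.z, atol=1e-5)

    def test_replication_invariance(self, rng):
        """Replicating every instance m times leaves z unchanged."""
        for m_rep in (2, 3, 5):
            model = _model(seed=3)
            H = rng.standard_normal((6, 16))
            base = model.forward(H)
            rep = model.forward(np.repeat(H, m_rep, axis=0))
            assert np.allclose(rep.z, base.z, atol=1e-5)
            assert np.allclose(rep.a, np.repeat(base.a / m_rep, m_rep), atol=1e-9)

    def test_matches_brute_force_oracle_with_hand_set_weights(self):
        """Hidden width 1, self-attention off: pooling reproduced by a
        few-line direct calculation."""
        cfg = ModelConfig(
            n_classes=2, attention_hidden=1, self_attention=False, gated=True
        )
        m = SAAbMILP(3, cfg, seed=0)
        m.params["V"] = np.array([[0.5, -1.0, 2.0]])
        m.params["U"] = np.array([[1.0, 0.0, -0.5]])
        m.params["w"] = np.array([2.0])
        m.params["Wc"] = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        m.params["bc"] = np.array([0.1, -0.1])
        H = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0], [0.5, 0.5, -1.0]])
        # independent brute-force recomputation
        e = []
        for h in H:
            t = np.tanh(m.params["V"][0] @ h)
            s = 1.0 / (1.0 + np.exp(-(m.params["U"][0] @ h)))
            e.append(2.0 * t * s)
        e = np.array(e)
        a = np.exp(e - e.max())
        a /= a.sum()
        z = (a[:, None] * H).sum(axis=0)
        scores = m.params["Wc"] @ z + m.params["bc"]
        out = m.forward(H)
        assert np.allclose(out.a, a, atol=1e-9)
        assert np.allclose(out.z, z, atol=1e-9)
        assert np.allclose(out.scores, scores, atol=1e-9)

    def test_rbf_kernel_variant_runs(self, rng):
        cfg = ModelConfig(n_classes=2, self_attention=True, sa_kernel="rbf")
        m = SAAbMILP(8, cfg, seed=1)
        m.params["g"] = np.array(0.5)
        out = m.forward(rng.standard_normal((5, 8)))
        assert abs(out.a.sum() - 1.0) <= 1e-6

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError):
            _model().forward(np.zeros((0, 16)))


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self, rng):
        for _ in range(1000):
            c = int(rng.integers(2, 6))
            logits = rng.standard_normal(c) * 3
            y = int(rng.integers(c))
            p = np.exp(logits - logits.max())
            p /= p.sum()
            assert focal_loss(logits, y, gamma=0.0) == pytest.approx(
                -np.log(p[y]), abs=1e-9
            )

    def test_perfect_prediction_has_zero_loss(self):
        assert focal_loss(np.array([0.0, 1.0]), 1, gamma=2.0, scores_are_probs=True) == 0.0

    def test_hand_worked_value(self):
        """gamma=2, p_t=0.9: 0.01 * (-ln 0.9) ~ 0.0010536."""
        val = focal_loss(np.array([0.1, 0.9]), 1, gamma=2.0, scores_are_probs=True)
        assert val == pytest.approx(0.0010536, abs=1e-6)

    def test_monotone_decreasing_in_pt(self):
        pts = np.linspace(0.05, 0.999, 50)
        losses = [
            focal_loss(np.array([1 - pt, pt]), 1, gamma=2.0, scores_are_probs=True)
            for pt in pts
        ]
        assert all(b < a for a, b in zip(losses, losses[1:]))
        assert all(lo >= 0 for lo in losses)

    def test_class_weight_scales_loss(self):
        logits = np.array([0.3, -0.2, 0.1])
        base = focal_loss(logits, 2, gamma=1.5)
        weighted = focal_loss(logits, 2, gamma=1.5, class_weights=np.array([1, 1, 2.5]))
        assert weighted == pytest.approx(2.5 * base)

    def test_gradient_matches_finite_differences(self, rng):
        for gamma in (0.0, 0.5, 2.0):
            logits = rng.standard_normal(4)
            y = 2
            cw = np.array([1.0, 0.5, 2.0, 1.5])
            _, grad = _focal_grad(logits, y, gamma, cw)
            eps = 1e-6
            for j in range(4):
                up, dn = logits.copy(), logits.copy()
                up[j] += eps
                dn[j] -= eps
                num = (focal_loss(up, y, gamma, cw) - focal_loss(dn, y, gamma, cw)) / (
                    2 * eps
                )
                assert grad[j] == pytest.approx(num, abs=1e-6)

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([np.inf, 0.0]), 0)


@pytest.fixture(scope="module")
def gmm():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((400, 16))
    return GaussianMixture(4, covariance_type="diag", random_state=0).fit(X)


class TestFisherVector:
    def test_length_is_2kd(self, gmm, rng):
        v = fisher_vector_encode(rng.standard_normal((10, 16)), gmm)
        assert v.shape == (2 * 4 * 16,)

    def test_unit_l2_norm(self, gmm, rng):
        for _ in range(20):
            v = fisher_vector_encode(rng.standard_normal((rng.integers(1, 30), 16)), gmm)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-6)

    def test_mean_gradient_vanishes_at_component_mean(self):
        rng = np.random.default_rng(1)
        gmm1 = GaussianMixture(1, covariance_type="diag", random_state=0).fit(
            rng.standard_normal((200, 8))
        )
        bag = np.tile(gmm1.means_[0], (5, 1))
        # raw (pre-normalisation) mean block must vanish: recompute directly
        u = (bag - gmm1.means_[0]) / np.sqrt(gmm1.covariances_[0])
        assert np.allclose(u, 0.0)
        v = fisher_vector_encode(bag, gmm1)
        assert np.allclose(v[:8], 0.0, atol=1e-12)

    def test_empty_bag_rejected(self, gmm):
        with pytest.raises(ValueError):
            fisher_vector_encode(np.zeros((0, 16)), gmm)


class TestRNNAggregator:
    def _fitted(self, rng, d=8, S=4):
        cfg = ModelConfig(aggregator="rnn", n_classes=2, rnn_hidden=6, rnn_seq_len=S)
        m = RNNAggregator(d, cfg, seed=0)
        bags = [rng.standard_normal((10, d)) + (i % 2) for i in range(8)]
        m.fit_scorer(bags, [i % 2 for i in range(8)])
        return m

    def test_deterministic_output(self, rng):
        m = self._fitted(rng)
        H = rng.standard_normal((9, 8))
        assert np.array_equal(m.forward_scores(H), m.forward_scores(H))

    def test_short_bags_processed_whole(self, rng):
        m = self._fitted(rng, S=32)
        H = rng.standard_normal((3, 8))
        assert m.rank_instances(H).shape[0] == 3

    def test_appending_low_relevance_instance_beyond_rank_s_is_a_no_op(self, rng):
        """An instance ranked below the top-S cannot change the output."""
        m = self._fitted(rng, S=4)
        H = rng.standard_normal((8, 8)) + 1.0  # high-relevance cloud
        rel = m.relevance(H)
        low = H[np.argmin(rel)] - 5.0  # push far into the low-relevance class
        H2 = np.vstack([H, low])
        assert m.relevance(H2[-1:])[0] < np.sort(m.relevance(H))[-4]
        assert np.allclose(m.forward_scores(H), m.forward_scores(H2), atol=1e-12)

    def test_empty_bag_rejected(self, rng):
        with pytest.raises(ValueError):
            self._fitted(rng).forward_scores(np.zeros((0, 8)))


class TestSplitDataset:
    def _manifest(self, n=100, levels=(0, 1), seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat(levels, n // len(levels))
        return pd.DataFrame(
            {
                "biopsy_id": [f"B{i:04d}" for i in range(n)],
                "compartment": "colon",
                "path": "x.png",
                "PolysEP": labels,
                "patient_id": [f"P{i:04d}" for i in range(n)],
            }
        )

    def test_balanced_binary_gives_exact_80_20(self):
        plan = split_dataset(self._manifest(), "PolysEP", seed=0)
        assert len(plan.working_ids) == 80 and len(plan.testing_ids) == 20
        test_labels = [plan.labels[b] for b in plan.testing_ids]
        assert test_labels.count(0) == 10 and test_labels.count(1) == 10

    def test_folds_partition_working_set_with_8_per_class(self):
        plan = split_dataset(self._manifest(), "PolysEP", seed=0)
        assert len(plan.folds) == 5
        seen = set()
        for train_ids, val_ids in plan.folds:
            assert not set(train_ids) & set(val_ids)
            val_labels = [plan.labels[b] for b in val_ids]
            assert val_labels.count(0) == 8 and val_labels.count(1) == 8
            seen |= set(val_ids)
        assert seen == set(plan.working_ids)

    def test_deterministic_under_seed(self):
        a = split_dataset(self._manifest(), "PolysEP", seed=7)
        b = split_dataset(self._manifest(), "PolysEP", seed=7)
        assert a == b
        c = split_dataset(self._manifest(), "PolysEP", seed=8)
        assert a.testing_ids != c.testing_ids

    def test_singleton_class_goes_to_working_with_warning(self):
        manifest = self._manifest(n=21, levels=(0,))
        manifest.loc[20, "PolysEP"] = 3
        with pytest.warns(UserWarning, match="single patient"):
            plan = split_dataset(manifest, "PolysEP", seed=0)
        assert manifest.loc[20, "biopsy_id"] in plan.working_ids

    def test_patients_never_straddle_the_split(self):
        manifest = self._manifest(n=100)
        manifest["patient_id"] = [f"P{i // 4:04d}" for i in range(100)]
        plan = split_dataset(manifest, "PolysEP", seed=3)
        pat = dict(zip(manifest.biopsy_id, manifest.patient_id))
        working_p = {pat[b] for b in plan.working_ids}
        testing_p = {pat[b] for b in plan.testing_ids}
        assert not working_p & testing_p

    def test_stratification_property_over_seeds(self):
        """Fold class proportions stay within 10 points of the working
        proportions, for classes with at least 10 members, over 20 seeds."""
        manifest = self._manifest(n=120, levels=(0, 1, 2))
        for seed in range(20):
            plan = split_dataset(manifest, "PolysEP", seed=seed)
            work_labels = np.array([plan.labels[b] for b in plan.working_ids])
            for _, val_ids in plan.folds:
                val_labels = np.array([plan.labels[b] for b in val_ids])
                for level in (0, 1, 2):
                    p_work = (work_labels == level).mean()
                    p_val = (val_labels == level).mean()
                    assert abs(p_val - p_work) <= 0.10


@pytest.fixture(scope="module")
def toy_problem():
    """Separable synthetic bags: positives contain a shifted cluster."""
    rng = np.random.default_rng(5)
    n = 60
    bags, labels, rows = {}, {}, []
    for i in range(n):
        bid = f"B{i:04d}"
        y = i % 2
        H = rng.standard_normal((rng.integers(4, 9), 12))
        if y:
            H[: 2] += 2.5
        bags[bid] = EmbeddingBag(biopsy_id=bid, H=H)
        labels[bid] = y * 2  # severities 0 vs 2
        rows.append(
            {"biopsy_id": bid, "compartment": "colon", "path": "",
             "PolysEP": y * 2, "patient_id": bid}
        )
    manifest = pd.DataFrame(rows)
    plan = split_dataset(manifest, "PolysEP", seed=1)
    return bags, labels, plan


class TestTrainPredict:
    @pytest.mark.parametrize("aggregator", ["sa_abmilp", "rnn", "fv_rf"])
    def test_all_aggregators_learn_separable_task(self, toy_problem, aggregator):
        bags, labels, plan = toy_problem
        cfg = ModelConfig(aggregator=aggregator, epochs=30, patience=10)
        model = train(bags, labels, plan, cfg, "colon", "PolysEP", seed=2)
        hits = sum(
            predict(model, bags[b])[0] == labels[b] for b in plan.testing_ids
        )
        assert hits / len(plan.testing_ids) >= 0.9
        assert model.classes == (0, 2)

    def test_training_is_deterministic(self, toy_problem):
        bags, labels, plan = toy_problem
        cfg = ModelConfig(epochs=10, patience=5)
        a = train(bags, labels, plan, cfg, "colon", "PolysEP", seed=9)
        b = train(bags, labels, plan, cfg, "colon", "PolysEP", seed=9)
        assert a.fold_metrics == b.fold_metrics
        bid = plan.testing_ids[0]
        assert np.array_equal(predict(a, bags[bid])[1], predict(b, bags[bid])[1])

    def test_refit_final_mode(self, toy_problem):
        bags, labels, plan = toy_problem
        cfg = ModelConfig(epochs=10, patience=5, final="refit")
        model = train(bags, labels, plan, cfg, "colon", "PolysEP", seed=2)
        assert len(model.fold_models) == 1

    def test_prediction_contracts(self, toy_problem, rng):
        bags, labels, plan = toy_problem
        cfg = ModelConfig(epochs=5, patience=3)
        model = train(bags, labels, plan, cfg, "colon", "PolysEP", seed=0)
        for bid in plan.testing_ids[:20]:
            severity, probs, attention = predict(model, bags[bid])
            assert severity in model.classes
            assert probs.sum() == pytest.approx(1.0, abs=1e-6)
            assert abs(attention.a.sum() - 1.0) <= 1e-6
        with pytest.raises(ValueError, match="compartment mismatch"):
            predict(model, bags[plan.testing_ids[0]], compartment="ileum")

    def test_probability_tie_breaks_to_lower_severity(self):
        from milscore.mil import TrainedModel

        class Constant:
            def predict_proba(self, H):
                return np.array([0.5, 0.5])

        model = TrainedModel(
            compartment="colon", subgrade="PolysEP",
            config=ModelConfig(), fold_models=[Constant()], fold_metrics=[],
            classes=(0, 2), scaler_mean=np.zeros(4), scaler_std=np.ones(4), seed=0,
        )
        bag = EmbeddingBag(biopsy_id="b", H=np.zeros((3, 4)))
        severity, probs, _ = predict(model, bag)
        assert severity == 0

    def test_single_class_fold_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        bags = {
            f"B{i}": EmbeddingBag(biopsy_id=f"B{i}", H=rng.standard_normal((3, 4)))
            for i in range(12)
        }
        labels = {b: (0 if i < 10 else 1) for i, b in enumerate(sorted(bags))}
        ids = sorted(bags)
        plan_args = dict(stratify_on="y", labels=labels)
        from milscore.mil import SplitPlan

        plan = SplitPlan(
            working_ids=tuple(ids),
            testing_ids=(),
            folds=(
                (tuple(ids[:2]), tuple(ids[2:])),  # train side single class
                (tuple(ids[2:]), tuple(ids[:2])),  # train side has both classes
            ),
            **plan_args,
        )
        cfg = ModelConfig(epochs=2, patience=1)
        with pytest.warns(UserWarning, match="single class"):
            model = train(bags, labels, plan, cfg, "colon", "y", seed=0)
        assert len(model.fold_models) == 1
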