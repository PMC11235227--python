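"""Attention mechanism contracts, training protocol, cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tissuemil as tm
from tissuemil.containers import Bag, BagSet
from tissuemil.evaluation import weighted_roc
from tissuemil.mil import (
    ModelConfig,
    _init_params,
    class_balanced_sampling_probs,
    donor_folds,
    gated_attention,
    train,
    tune_hyperparameters,
)


def _params(n_features=4, embed=8, attn=4, n_classes=2, seed=0):
    cfg = ModelConfig(
        n_features=n_features, embed_width=embed, attn_width=attn, n_classes=n_classes
    )
    return cfg, _init_params(cfg, np.random.default_rng(seed))


class TestAttend:
    def test_single_instance_gets_weight_one(self):
        cfg, p = _params()
        h = np.random.default_rng(1).standard_normal((1, 8))
        a, _ = gated_attention(h, p["V"], p["U"], p["w"])
        np.testing.assert_allclose(a, [1.0])

    def test_identical_embeddings_split_evenly(self):
        cfg, p = _params()
        h = np.tile(np.random.default_rng(2).standard_normal(8), (2, 1))
        a, _ = gated_attention(h, p["V"], p["U"], p["w"])
        np.testing.assert_allclose(a, [0.5, 0.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 12), st.integers(0, 10_000), st.booleans())
    def test_weights_sum_to_one_and_positive(self, k, seed, gated):
        cfg, p = _params()
        h = np.random.default_rng(seed).standard_normal((k, 8)) * 3
        a, _ = gated_attention(h, p["V"], p["U"], p["w"], gated=gated)
        assert a.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(a > 0)

    def test_ungated_drops_sigmoid_branch(self):
        cfg, p = _params()
        h = np.random.default_rng(3).standard_normal((3, 8))
        a_g, s_g = gated_attention(h, p["V"], p["U"], p["w"], gated=True)
        a_u, s_u = gated_attention(h, p["V"], None, p["w"], gated=False)
        assert not np.allclose(s_g, s_u)
        np.testing.assert_allclose(s_u, np.tanh(h @ p["V"].T) @ p["w"])


class TestAttendWeighted:
    def test_g_all_ones_is_bitwise_identical(self):
        cfg, p = _params()
        h = np.random.default_rng(4).standard_normal((5, 8))
        a_plain, _ = gated_attention(h, p["V"], p["U"], p["w"])
        a_g, _ = gated_attention(h, p["V"], p["U"], p["w"], g=np.ones(5))
        assert np.array_equal(a_plain, a_g)

    def test_two_identical_instances_closed_form(self):
        cfg, p = _params()
        h = np.tile(np.random.default_rng(5).standard_normal(8), (2, 1))
        a, s = gated_attention(h, p["V"], p["U"], p["w"], g=np.array([1.0, 0.0]))
        expected = np.exp([s[0], 0.0])
        expected /= expected.sum()
        np.testing.assert_allclose(a, expected, atol=1e-12)
        if s[0] > 0:
            assert a[0] > a[1]
        elif s[0] < 0:
            assert a[0] < a[1]

    def test_all_g_zero_uniform(self):
        cfg, p = _params()
        h = np.random.default_rng(6).standard_normal((3, 8))
        a, _ = gated_attention(h, p["V"], p["U"], p["w"], g=np.zeros(3))
        np.testing.assert_allclose(a, 1 / 3)

    def test_invalid_g_rejected(self):
        cfg, p = _params()
        h = np.zeros((2, 8))
        with pytest.raises(ValueError):
            gated_attention(h, p["V"], p["U"], p["w"], g=np.array([0.5, 1.5]))

    def test_paper_literal_variant_unnormalised(self):
        """The printed form re-uses the instance's own g in the denominator;
        with g = 1 it coincides with the shared-denominator softmax."""
        cfg, p = _params()
        h = np.random.default_rng(7).standard_normal((4, 8))
        g = np.array([0.9, 0.2, 0.6, 1.0])
        a_lit, _ = gated_attention(h, p["V"], p["U"], p["w"], g=g, paper_literal=True)
        assert a_lit.sum() != pytest.approx(1.0, abs=1e-9)
        a_one, _ = gated_attention(
            h, p["V"], p["U"], p["w"], g=np.ones(4), paper_literal=True
        )
        a_ref, _ = gated_attention(h, p["V"], p["U"], p["w"])
        np.testing.assert_allclose(a_one, a_ref, atol=1e-15)


@pytest.fixture(scope="module")
def fitted(clean_bags):
    folds = donor_folds(clean_bags.bags, 5, seed=0)
    tr, va, _ = folds[0]
    return train(clean_bags, ModelConfig(n_features=10, max_epochs=40, patience=15),
                 split=(tr, va), seed=0)


class TestPredictBag:
    def test_single_instance_bag_pools_to_its_embedding(self, fitted, clean_bags):
        b = clean_bags[0]
        one = Bag("x", "D", b.label, b.features[:1])
        probs, a = fitted.predict(one)
        np.testing.assert_allclose(a, [1.0])
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_bag_same_probabilities(self, fitted, clean_bags):
        b = clean_bags[1]
        dup = Bag("x", "D", b.label, np.vstack([b.features, b.features]))
        p1, _ = fitted.predict(b)
        p2, a2 = fitted.predict(dup)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        assert a2.sum() == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance_bit_exact(self, fitted, clean_bags):
        rng = np.random.default_rng(8)
        for i in (0, 5, 10):
            b = clean_bags[i]
            perm = rng.permutation(b.n_instances)
            shuffled = Bag("x", "D", b.label, b.features[perm])
            p1, a1 = fitted.predict(b)
            p2, a2 = fitted.predict(shuffled)
            assert np.array_equal(p1, p2)
            np.testing.assert_array_equal(a1[perm], a2)


class TestMilMax:
    def test_bag_score_is_max_instance_probability(self, clean_bags):
        cfg = ModelConfig(n_features=10, mode="milmax", max_epochs=20, patience=10)
        folds = donor_folds(clean_bags.bags, 5, seed=0)
        tr, va, _ = folds[0]
        res = train(clean_bags, cfg, split=(tr, va), seed=0)
        b = clean_bags[0]
        probs, a = res.predict(b)
        assert a.sum() == pytest.approx(1.0)
        assert np.count_nonzero(a) == 1  # the argmax instance
        # adding instances can only raise the bag's positive score
        base, _ = res.predict(Bag("x", "D", 1, b.features[:3]))
        more, _ = res.predict(Bag("x", "D", 1, b.features))
        assert more[1] >= base[1] - 1e-12

    def test_multiclass_milmax_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_features=4, n_classes=3, mode="milmax")


class TestTraining:
    def test_weighted_sampling_balances_classes(self):
        labels = np.array([0] * 90 + [1] * 10)
        p = class_balanced_sampling_probs(labels, 2)
        minority_mass = p[labels == 1].sum()
        assert minority_mass == pytest.approx(0.5, abs=1e-12)
        rng = np.random.default_rng(0)
        draws = rng.choice(labels, size=2000, p=p)
        frac = (draws == 1).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_separable_bags_reach_high_auc(self, clean_bags):
        folds = donor_folds(clean_bags.bags, 5, seed=0)
        tr, va, te = folds[0]
        res = train(clean_bags, ModelConfig(n_features=10, max_epochs=120),
                    split=(tr, va), seed=0)
        y = np.array([clean_bags[i].label for i in te])
        s = np.array([res.predict(clean_bags[i])[0][1] for i in te])
        assert weighted_roc(y, s).auc >= 0.95

    def test_validation_missing_class_raises(self, clean_bags):
        tr = [i for i in range(100)]
        va = [i for i in range(100, 140) if clean_bags[i].label == 0]
        model = tm.AttentionMIL(clean_bags, ModelConfig(n_features=10))
        with pytest.raises(ValueError):
            model.fit(tr, va, seed=0)

    def test_history_and_early_stopping_bookkeeping(self, clean_bags):
        folds = donor_folds(clean_bags.bags, 5, seed=0)
        tr, va, _ = folds[0]
        cfg = ModelConfig(n_features=10, max_epochs=60, patience=10)
        res = train(clean_bags, cfg, split=(tr, va), seed=0)
        assert {"epoch", "train_loss", "val_auc"} <= set(res.history.columns)
        assert res.best_epoch == res.history["val_auc"].idxmax()
        assert len(res.history) <= 60
        assert "Attention-MIL" in res.summary()

    def test_same_seed_reproduces_training(self, clean_bags):
        folds = donor_folds(clean_bags.bags, 5, seed=0)
        tr, va, _ = folds[0]
        cfg = ModelConfig(n_features=10, max_epochs=15, patience=10)
        r1 = train(clean_bags, cfg, split=(tr, va), seed=3)
        r2 = train(clean_bags, cfg, split=(tr, va), seed=3)
        assert r1.history.equals(r2.history)
        for k in r1.params:
            np.testing.assert_array_equal(r1.params[k], r2.params[k])


class TestCrossValidation:
    def test_folds_partition_donors_and_bags(self, clean_bags):
        folds = donor_folds(clean_bags.bags, 5, seed=1)
        all_test = []
        for tr, va, te in folds:
            assert not (set(tr) & set(va)) and not (set(tr) & set(te))
            tr_d = {clean_bags[i].donor_id for i in tr}
            va_d = {clean_bags[i].donor_id for i in va}
            te_d = {clean_bags[i].donor_id for i in te}
            assert not (tr_d & va_d) and not (tr_d & te_d) and not (va_d & te_d)
            all_test += te
        assert sorted(all_test) == list(range(len(clean_bags.bags)))

    def test_five_by_five_gives_25_models(self):
        bs = tm.make_bags(tm.BagSetConfig(n_bags=60, effect_size=3.0,
                                          n_donors=15, seed=5))
        cfg = ModelConfig(n_features=10, max_epochs=6, patience=3)
        cv = tm.cross_validate(bs, cfg, n_folds=5, n_seeds=5, seed=0)
        assert len(cv.models) == 25
        per_fold = cv.predictions.groupby("fold")["bag_id"].nunique()
        assert per_fold.sum() == 60  # every bag tested in exactly one fold
        assert "25 models" in cv.summary()

    def test_deterministic_given_seed(self):
        bs = tm.make_bags(tm.BagSetConfig(n_bags=40, effect_size=3.0,
                                          n_donors=10, seed=6))
        cfg = ModelConfig(n_features=10, max_epochs=4, patience=2)
        cv1 = tm.cross_validate(bs, cfg, n_folds=5, n_seeds=1, seed=2)
        cv2 = tm.cross_validate(bs, cfg, n_folds=5, n_seeds=1, seed=2)
        assert cv1.predictions.equals(cv2.predictions)

    def test_too_few_donors_per_class_raises(self):
        bs = tm.make_bags(tm.BagSetConfig(n_bags=8, effect_size=3.0,
                                          n_donors=4, seed=0))
        with pytest.raises(ValueError):
            tm.cross_validate(bs, ModelConfig(n_features=10), n_folds=5)


class TestTune:
    def test_one_point_space_returned_directly(self, clean_bags):
        base = ModelConfig(n_features=10, max_epochs=4, patience=2)
        cfg = tune_hyperparameters(clean_bags, {"embed_width": [16]}, budget=3,
                                   base_config=base, seed=0)
        assert cfg.embed_width == 16

    def test_budget_one_samples_single_config(self, clean_bags):
        base = ModelConfig(n_features=10, max_epochs=4, patience=2)
        cfg = tune_hyperparameters(
            clean_bags, {"embed_width": [8, 16], "gated": [True, False]},
            budget=1, base_config=base, seed=0,
        )
        assert cfg.embed_width in (8, 16)

    def test_empty_space_rejected(self, clean_bags):
        base = ModelConfig(n_features=10)
        with pytest.raises(ValueError):
            tune_hyperparameters(clean_bags, {}, budget=2, base_config=base)
        with pytest.raises(ValueError):
            tune_hyperparameters(clean_bags, {"gated": []}, budget=2, base_config=base)
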