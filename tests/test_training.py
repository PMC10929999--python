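"""Loss oracles and identities, fold construction, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selfseg import (
    ContractError,
    LossConfig,
    NetworkConfig,
    TrainConfig,
    bernoulli_cross_entropy,
    composite_loss,
    cross_entropy,
    dsc,
    make_folds,
    one_hot,
    soft_dice,
    train_model,
)
from selfseg.training import composite_loss_and_logit_grad


def _random_probs(rng, shape=(5, 4, 4)):
    p = rng.random(shape)
    return p / p.sum(axis=0, keepdims=True)


class TestSoftDice:
    def test_perfect_prediction_scores_one(self, rng):
        y = one_hot(rng.integers(0, 5, size=(6, 6)))
        assert soft_dice(y, y, smooth=1e-8) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_prediction_scores_zero(self):
        # target uses classes 1 and 2, the prediction puts all its mass on
        # classes 3 and 4: every foreground class has zero overlap
        labels = np.ones((4, 4), dtype=int)
        labels[2:] = 2
        y = one_hot(labels)
        p = one_hot(labels + 2).astype(float)
        assert soft_dice(p, y, smooth=1e-8) < 1e-5

    def test_uniform_probability_closed_form(self):
        """Uniform p=0.2: per-class dice is 2*0.2*|G| / (0.2*N + |G|)."""
        labels = np.zeros((5, 5), dtype=int)
        labels[:2, :] = 1  # |G1| = 10 of N = 25
        y = one_hot(labels)
        p = np.full((5, 5, 5), 0.2)
        smooth = 1e-9
        expected_per_class = []
        for c in (1, 2, 3, 4):
            G = (labels == c).sum()
            expected_per_class.append((2 * 0.2 * G + smooth) /
                                      (0.2 * 25 + G + smooth))
        assert soft_dice(p, y, smooth) == pytest.approx(
            np.mean(expected_per_class), rel=1e-9)

    def test_matches_hard_dsc(self, rng):
        """Cross-module consistency: soft Dice on 0/1 masks equals the
        evaluation DSC as smooth -> 0."""
        labels = rng.integers(0, 5, size=(6, 6, 6))
        pred = rng.integers(0, 5, size=(6, 6, 6))
        sd = soft_dice(one_hot(pred).astype(float), one_hot(labels), 1e-12)
        hard = np.mean([dsc(pred == c, labels == c) for c in (1, 2, 3, 4)])
        assert sd == pytest.approx(hard, abs=1e-6)


class TestCrossEntropy:
    def test_uniform_prediction_is_log5(self, rng):
        y = one_hot(rng.integers(0, 5, size=(8, 8)))
        p = np.full((5, 8, 8), 0.2)
        assert cross_entropy(p, y) == pytest.approx(np.log(5), rel=1e-9)

    def test_perfect_prediction_near_zero(self, rng):
        y = one_hot(rng.integers(0, 5, size=(8, 8)))
        assert cross_entropy(y.astype(float), y) < 1e-6

    def test_matches_per_voxel_loop(self, rng):
        p = _random_probs(rng)
        y = one_hot(rng.integers(0, 5, size=(4, 4)))
        total = 0.0
        for i in range(4):
            for j in range(4):
                c = int(np.argmax(y[:, i, j]))
                total -= np.log(p[c, i, j])
        assert cross_entropy(p, y) == pytest.approx(total / 16, rel=1e-9)

    def test_bernoulli_form_two_class_relation(self, rng):
        """On 2 effective classes the Bernoulli sum counts every voxel from
        both channels: twice the categorical value."""
        labels = rng.integers(0, 2, size=(6, 6))
        y = one_hot(labels)
        p = np.zeros((5, 6, 6))
        q = rng.uniform(0.05, 0.95, size=(6, 6))
        p[0], p[1] = q, 1 - q
        assert bernoulli_cross_entropy(p[:2], y[:2]) == pytest.approx(
            2 * cross_entropy(p, y), rel=1e-6)


class TestCompositeLoss:
    def test_reduces_to_dice_at_a1(self, rng):
        p = _random_probs(rng)
        y = one_hot(rng.integers(0, 5, size=(4, 4)))
        cfg = LossConfig(a=1.0)
        assert composite_loss(p, y, cfg) == pytest.approx(
            1.0 - soft_dice(p, y, cfg.smooth), rel=1e-12)

    def test_reduces_to_ce_at_a0(self, rng):
        p = _random_probs(rng)
        y = one_hot(rng.integers(0, 5, size=(4, 4)))
        assert composite_loss(p, y, LossConfig(a=0.0)) == pytest.approx(
            cross_entropy(p, y), rel=1e-12)

    def test_perfect_prediction_near_zero(self, rng):
        y = one_hot(rng.integers(0, 5, size=(6, 6)))
        for a in (0.0, 0.5, 1.0):
            assert composite_loss(y.astype(float), y, LossConfig(a=a)) < 1e-3

    @given(a=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_convex_combination_bounds(self, a):
        rng = np.random.default_rng(0)
        p = _random_probs(rng)
        y = one_hot(rng.integers(0, 5, size=(4, 4)))
        cfg = LossConfig(a=a)
        ldice = 1.0 - soft_dice(p, y, cfg.smooth)
        lce = cross_entropy(p, y)
        loss = composite_loss(p, y, cfg)
        assert min(ldice, lce) - 1e-9 <= loss <= max(ldice, lce) + 1e-9

    def test_logit_gradient_matches_numeric(self, rng):
        logits = rng.normal(size=(5, 3, 3))
        y = one_hot(rng.integers(0, 5, size=(3, 3))).astype(np.float64)
        cfg = LossConfig(a=0.5)

        def sm(z):
            e = np.exp(z - z.max(axis=0, keepdims=True))
            return e / e.sum(axis=0, keepdims=True)

        _, dz = composite_loss_and_logit_grad(logits, y, cfg)
        eps = 1e-6
        for idx in [(0, 0, 0), (2, 1, 2), (4, 2, 1)]:
            lp, lm = logits.copy(), logits.copy()
            lp[idx] += eps
            lm[idx] -= eps
            num = (composite_loss(sm(lp), y, cfg) -
                   composite_loss(sm(lm), y, cfg)) / (2 * eps)
            assert dz[idx] == pytest.approx(num, abs=1e-6)


class TestFolds:
    def test_fifty_cases_five_folds_of_ten(self):
        split = make_folds([f"c{i}" for i in range(50)], k=5, seed=1)
        sizes = sorted(len(split.fold_cases(f)) for f in range(5))
        assert sizes == [10] * 5

    def test_eleven_cases_pigeonhole(self):
        split = make_folds([f"c{i}" for i in range(11)], k=5, seed=0)
        sizes = sorted((len(split.fold_cases(f)) for f in range(5)), reverse=True)
        assert sizes == [3, 2, 2, 2, 2]

    def test_each_case_validates_exactly_once(self):
        ids = [f"c{i}" for i in range(23)]
        split = make_folds(ids, k=5, seed=3)
        seen = [c for f in range(5) for c in split.fold_cases(f)]
        assert sorted(seen) == sorted(ids)

    def test_deterministic_under_seed(self):
        ids = [f"c{i}" for i in range(20)]
        assert make_folds(ids, 5, seed=7).assignment == \
            make_folds(ids, 5, seed=7).assignment

    def test_too_few_cases_raises(self):
        with pytest.raises(ContractError):
            make_folds(["a", "b"], k=5, seed=0)


@pytest.fixture(scope="module")
def tiny_cases():
    from dataclasses import replace
    from selfseg import PhantomConfig, generate_phantom, zscore_normalize
    from selfseg.phantom import _derived_seed
    cfg = PhantomConfig(grid_shape=(8, 32, 32), seed=21)
    cases = []
    for i in range(4):
        v, l = generate_phantom(replace(cfg, seed=_derived_seed(21, i)),
                                f"t{i}")
        cases.append((zscore_normalize(v), l))
    return cases


class TestTrainModel:
    def _config(self, epochs=4, seed=0):
        return TrainConfig(epochs=epochs, batch_size=4, steps_per_epoch=8,
                           patch_size=(1, 32, 32), seed=seed,
                           foreground_fraction=0.5)

    def test_loss_decreases_on_learnable_task(self, tiny_cases):
        net = NetworkConfig(dims=2, n_stages_xy=2, base_channels=6,
                            max_channels=12)
        res = train_model(tiny_cases[:3], tiny_cases[3:], net,
                          self._config(epochs=6))
        hist = res.history
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
        assert not hist["val_dsc"].isna().any()

    def test_single_case_single_epoch_writes_checkpoint(self, tiny_cases,
                                                        tmp_path):
        net = NetworkConfig(dims=2, n_stages_xy=1, base_channels=4,
                            max_channels=8)
        res = train_model(tiny_cases[:1], [], net, self._config(epochs=1),
                          checkpoint_path=tmp_path / "m.npz")
        assert (tmp_path / "m.npz").exists()
        assert len(res.history) == 1

    def test_same_seed_same_first_epoch_loss(self, tiny_cases):
        net = NetworkConfig(dims=2, n_stages_xy=1, base_channels=4,
                            max_channels=8)
        h1 = train_model(tiny_cases[:2], [], net,
                         self._config(epochs=1, seed=9)).history
        h2 = train_model(tiny_cases[:2], [], net,
                         self._config(epochs=1, seed=9)).history
        assert h1["train_loss"].iloc[0] == h2["train_loss"].iloc[0]
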