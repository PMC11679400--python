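"""Architecture contracts, training behavior, and inference invariants."""

import numpy as np
import pytest

from dasleep import (
    ModelConfig,
    SleepWakeFit,
    SleepWakeNet,
    TrainConfig,
    extract_windows,
    generate_cohort,
    pooled_lengths,
    stack_windows,
    windows_for_cohort,
)
from dasleep.model import _Network

SMALL = ModelConfig(channels=(4, 8, 16), fc_units=16, dropout_rate=0.2)


@pytest.fixture(scope="module")
def tiny_fit():
    """A briefly trained small network on a 4-subject cohort."""
    src, tgt = generate_cohort(4, seed=31)
    ws = windows_for_cohort(src, 10, 2, 0)
    wt = windows_for_cohort(tgt, 10, 2, 1)
    model = SleepWakeNet(ws, target=wt, config=SMALL)
    fit = model.fit(TrainConfig(max_epochs=3, batch_size=128, seed=0))
    return src, tgt, fit


class TestArchitecture:
    @pytest.mark.parametrize(
        "L,expected", [(101, [50, 25, 12]), (53, [26, 13, 6])]
    )
    def test_pooled_temporal_lengths(self, L, expected):
        assert pooled_lengths(L, ModelConfig()) == expected

    def test_single_block_halves_length(self):
        cfg = ModelConfig(n_blocks=1, channels=(4,), fc_units=8)
        assert pooled_lengths(10, cfg) == [5]

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            _Network(SMALL, input_length=7, seed=0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(channels=(8, 16)).validate()  # wrong per-block count
        with pytest.raises(ValueError):
            ModelConfig(kernel_size=4).validate()
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0).validate()


class TestForward:
    def test_probabilities_normalized_and_bounded(self):
        net = _Network(SMALL, input_length=53, seed=1)
        x = np.random.default_rng(0).lognormal(3, 1, size=(16, 53))
        p_sleep, p_dom = net.forward(x, train=False)
        assert ((0 <= p_sleep) & (p_sleep <= 1)).all()
        assert ((0 <= p_dom) & (p_dom <= 1)).all()

    def test_fresh_model_is_roughly_symmetric(self):
        net = _Network(SMALL, input_length=53, seed=2)
        x = np.random.default_rng(1).lognormal(3, 1, size=(64, 53))
        p, _ = net.forward(x, train=False)
        assert 0.2 < p.mean() < 0.8

    def test_identical_windows_get_identical_outputs(self):
        net = _Network(SMALL, input_length=53, seed=3)
        x = np.tile(np.random.default_rng(2).lognormal(3, 1, 53), (8, 1))
        p, _ = net.forward(x, train=False)
        assert np.allclose(p, p[0])

    def test_length_mismatch_rejected(self):
        net = _Network(SMALL, input_length=53, seed=4)
        with pytest.raises(ValueError, match="input length"):
            net.forward(np.zeros((2, 40)), train=False)


class TestGradientReversalOracle:
    def test_total_gradient_equals_label_minus_lambda_domain(self):
        """Finite-difference check on a toy two-layer extractor: the
        gradient of the combined loss w.r.t. extractor parameters equals
        grad(label loss) - lambda * grad(domain loss)."""
        from dasleep import nn

        rng = np.random.default_rng(7)
        lam = 0.7
        ext = nn.Sequential([nn.Dense(5, 4, rng), nn.ReLU()])
        label_head = nn.Dense(4, 2, rng)
        domain_head = nn.Sequential([nn.GradientReversal(lam), nn.Dense(4, 2, rng)])
        x = rng.normal(size=(12, 5))
        y = rng.integers(0, 2, 12)
        dom = rng.integers(0, 2, 12)

        def losses():
            f = ext.forward(x)
            l_loss, _ = nn.cross_entropy(label_head.forward(f), y)
            d_loss, _ = nn.cross_entropy(domain_head.forward(f), dom)
            return l_loss, d_loss

        # analytic: backprop label + reversed domain gradients into extractor
        f = ext.forward(x)
        _, dlab = nn.cross_entropy(label_head.forward(f), y)
        _, ddom = nn.cross_entropy(domain_head.forward(f), dom)
        ext.backward(label_head.backward(dlab) + domain_head.backward(ddom))
        analytic = [g.copy() for _, g in ext.params()]

        eps = 1e-6
        for (p, _), ana in zip(ext.params(), analytic):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                l_hi, d_hi = losses()
                p[idx] = orig - eps
                l_lo, d_lo = losses()
                p[idx] = orig
                num = ((l_hi - l_lo) - lam * (d_hi - d_lo)) / (2 * eps)
                assert num == pytest.approx(ana[idx], rel=1e-4, abs=1e-9)


class TestTraining:
    def test_training_reduces_validation_loss(self, tiny_fit):
        _, _, fit = tiny_fit
        assert fit.history["val_loss"].iloc[-1] <= fit.history["val_loss"].iloc[0]

    def test_no_adversary_reduces_to_plain_path(self):
        """With the adversary off, attaching target data changes nothing."""
        src, tgt = generate_cohort(3, seed=33)
        ws = windows_for_cohort(src, 10, 2, 0)
        wt = windows_for_cohort(tgt, 10, 2, 1)
        cfg = TrainConfig(max_epochs=2, batch_size=128, seed=5,
                          use_domain_adversary=False)
        f1 = SleepWakeNet(ws, target=wt, config=SMALL).fit(cfg)
        f2 = SleepWakeNet(ws, target=None, config=SMALL).fit(cfg)
        for a, b in zip(f1.network.get_state(), f2.network.get_state()):
            assert np.array_equal(a, b)
        assert (f1.history["domain_loss"] == 0).all()

    def test_target_labels_never_read(self):
        """Deleting target labels changes nothing (leakage guard)."""
        src, tgt = generate_cohort(3, seed=34)
        ws = windows_for_cohort(src, 10, 2, 0)
        wt = windows_for_cohort(tgt, 10, 2, 1)
        cfg = TrainConfig(max_epochs=2, batch_size=128, seed=6)
        f1 = SleepWakeNet(ws, target=wt, config=SMALL).fit(cfg)
        f2 = SleepWakeNet(ws, target=wt.without_labels(), config=SMALL).fit(cfg)
        for a, b in zip(f1.network.get_state(), f2.network.get_state()):
            assert np.array_equal(a, b)

    def test_unlabeled_source_rejected(self):
        src, _ = generate_cohort(3, seed=35)
        ws = windows_for_cohort(src, 10, 2, 0).without_labels()
        with pytest.raises(ValueError, match="labeled"):
            SleepWakeNet(ws, config=SMALL)

    def test_fit_is_reproducible_per_seed(self):
        src, _ = generate_cohort(3, seed=36)
        ws = windows_for_cohort(src, 10, 2, 0)
        cfg = TrainConfig(max_epochs=2, batch_size=128, seed=9,
                          use_domain_adversary=False)
        f1 = SleepWakeNet(ws, config=SMALL).fit(cfg)
        f2 = SleepWakeNet(ws, config=SMALL).fit(cfg)
        for a, b in zip(f1.network.get_state(), f2.network.get_state()):
            assert np.array_equal(a, b)


class TestInference:
    def test_prediction_covers_every_epoch(self, tiny_fit):
        src, _, fit = tiny_fit
        probs, hyp = fit.predict_series(src[0])
        assert len(probs) == len(hyp) == len(src[0])

    def test_threshold_extremes(self, tiny_fit):
        src, _, fit = tiny_fit
        _, all_sleep = fit.predict_series(src[0], threshold=0.0)
        _, all_wake = fit.predict_series(src[0], threshold=1.0 + 1e-9)
        assert (all_sleep == 1).all()
        assert (all_wake == 0).all()

    def test_probabilities_invariant_to_batch_partition(self, tiny_fit):
        src, _, fit = tiny_fit
        ws = extract_windows(src[0], 10, 2)
        a = fit.predict_proba(ws.windows, batch_size=64)
        b = fit.predict_proba(ws.windows, batch_size=1024)
        assert np.allclose(a, b)

    def test_domain_probe_separates_less_after_adaptation(self):
        """A linear probe on frozen features distinguishes source from
        target worse for the adversarially trained network than for the
        plain one."""
        from sklearn.linear_model import LogisticRegression

        src, tgt = generate_cohort(6, seed=37)
        ws = windows_for_cohort(src, 50, 2, 0)
        wt = windows_for_cohort(tgt, 50, 2, 1)
        cfg_da = TrainConfig(max_epochs=12, batch_size=256, seed=3,
                             use_domain_adversary=True,
                             early_stop_patience=12)
        cfg_no = TrainConfig(max_epochs=12, batch_size=256, seed=3,
                             use_domain_adversary=False,
                             early_stop_patience=12)
        fit_da = SleepWakeNet(ws, target=wt, config=SMALL).fit(cfg_da)
        fit_no = SleepWakeNet(ws, config=SMALL).fit(cfg_no)

        rng = np.random.default_rng(0)
        idx_s = rng.choice(len(ws.windows), 1500, replace=False)
        idx_t = rng.choice(len(wt.windows), 1500, replace=False)
        X = np.concatenate([ws.windows[idx_s], wt.windows[idx_t]])
        y = np.repeat([0, 1], 1500)

        def probe_acc(fit, domains):
            # features as each model would compute them at inference:
            # the adapted model normalises each row with its own domain's
            # frozen statistics, the plain model only has source stats
            F = fit.network.features(X, domains=domains)
            F = (F - F.mean(0)) / (F.std(0) + 1e-9)
            clf = LogisticRegression(max_iter=300)
            half = len(F) // 2
            order = rng.permutation(len(F))
            clf.fit(F[order[:half]], y[order[:half]])
            return clf.score(F[order[half:]], y[order[half:]])

        assert probe_acc(fit_da, y) < probe_acc(fit_no, np.zeros(len(X), int))


class TestPersistence:
    def test_checkpoint_round_trip(self, tiny_fit, tmp_path):
        src, _, fit = tiny_fit
        path = tmp_path / "ckpt.npz"
        fit.save(path)
        back = SleepWakeFit.load(path)
        p1, _ = fit.predict_series(src[0])
        p2, _ = back.predict_series(src[0])
        assert np.allclose(p1, p2)

    def test_summary_mentions_architecture(self, tiny_fit):
        _, _, fit = tiny_fit
        text = fit.summary()
        assert "conv blocks" in text and "domain adversary" in text
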