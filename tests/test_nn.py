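"""Network building blocks: architecture contracts, SE module, Cox loss oracle."""

import itertools

import numpy as np
import pytest

from perisurv.nn import Adam, ArchitectureConfig, SEResNet3D
from perisurv.nn.layers import BatchNorm, Conv3d, Dense, MaxPool3d, SEBlock
from perisurv.survival_net import cox_ph_loss


def brute_force_cox_loss(h, t, d):
    """Independent oracle: naive double loop, Breslow ties, event-normalized."""
    h, t, d = map(np.asarray, (h, t, d))
    terms = []
    for i in range(len(h)):
        if d[i] != 1:
            continue
        risk = [np.exp(h[j]) for j in range(len(h)) if t[j] >= t[i]]
        terms.append(h[i] - np.log(np.sum(risk)))
    return -np.mean(terms) if terms else 0.0


class TestCoxLoss:
    def test_single_event_risk_set_self(self):
        assert cox_ph_loss([2.3], [5.0], [1]) == pytest.approx(0.0)

    def test_two_subjects_symmetric(self):
        # events at t=1,2 with equal scores: -(1/2)[(0 - log 2) + (0 - log 1)]
        assert cox_ph_loss([0.0, 0.0], [1.0, 2.0], [1, 1]) == pytest.approx(np.log(2) / 2)

    def test_matches_brute_force_on_all_permutations(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 4, 5, 6):
            h = rng.normal(size=n)
            t = rng.choice([1.0, 2.0, 3.0], size=n)  # induces ties
            d = rng.integers(0, 2, size=n)
            if d.sum() == 0:
                d[0] = 1
            for perm in itertools.permutations(range(n)):
                p = list(perm)
                assert cox_ph_loss(h[p], t[p], d[p]) == pytest.approx(
                    brute_force_cox_loss(h[p], t[p], d[p]), abs=1e-12
                )

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=8)
        t = rng.exponential(size=8) + 0.1
        d = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        _, grad = cox_ph_loss(h, t, d, return_grad=True)
        eps = 1e-6
        for j in range(8):
            hp, hm = h.copy(), h.copy()
            hp[j] += eps
            hm[j] -= eps
            fd = (brute_force_cox_loss(hp, t, d) - brute_force_cox_loss(hm, t, d)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, abs=1e-4)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        h = rng.normal(size=10)
        t = rng.exponential(size=10) + 0.1
        d = rng.integers(0, 2, size=10)
        d[0] = 1
        assert cox_ph_loss(h, t, d) == pytest.approx(cox_ph_loss(h + 7.5, t, d), abs=1e-10)

    def test_event_free_batch_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert cox_ph_loss([1.0, 2.0], [1.0, 2.0], [0, 0]) == 0.0

    def test_nan_scores_rejected(self):
        with pytest.raises(ValueError):
            cox_ph_loss([np.nan, 1.0], [1.0, 2.0], [1, 1])

    def test_stabilized_for_large_scores(self):
        loss = cox_ph_loss([500.0, -500.0, 100.0], [1.0, 2.0, 3.0], [1, 1, 1])
        assert np.isfinite(loss)


class TestSEBlock:
    def test_zero_weights_halve_the_input(self):
        se = SEBlock(4, ratio=2)
        for p in se.params():
            p.value[...] = 0.0
        x = np.random.default_rng(0).normal(size=(2, 4, 3, 3, 3)).astype(np.float32)
        y = se.forward(x)
        assert np.allclose(y, x / 2.0, atol=1e-6)

    def test_constant_channel_squeeze_exact(self):
        se = SEBlock(3, ratio=1)
        x = np.zeros((1, 3, 2, 2, 2), dtype=np.float32)
        x[0, 1] = 7.0
        se.forward(x)
        squeeze = x.mean(axis=(2, 3, 4))
        assert squeeze[0, 1] == 7.0

    def test_bottleneck_width(self):
        se = SEBlock(512, ratio=64)
        assert se.fc1.w.value.shape == (512, 8)
        tiny = SEBlock(8, ratio=64)  # bottleneck floors at 1
        assert tiny.fc1.w.value.shape == (8, 1)


class TestArchitecture:
    def test_gap_width_512_full_preset(self):
        net = SEResNet3D(ArchitectureConfig())
        assert net.config.gap_width == 512
        assert net.out.w.value.shape == (128, 1)

    def test_stride_arithmetic_on_desk_input(self):
        cfg = ArchitectureConfig.desk()
        net = SEResNet3D(cfg)
        x = np.random.default_rng(0).normal(size=(1, 32, 32, 32)).astype(np.float32)
        h = net.pool.forward(net.stem.forward(x[:, None]))
        assert h.shape[2:] == (8, 8, 8)  # ceil(32/2) -> ceil(16/2)
        scores, feats = net.forward(x)
        assert scores.shape == (1,) and feats.shape == (1, 64)
        assert -1 < scores[0] < 1  # tanh-bounded

    def test_se_ablation_reduces_parameter_count(self):
        cfg = ArchitectureConfig.desk()
        with_se = SEResNet3D(cfg).n_parameters
        without = SEResNet3D(ArchitectureConfig.desk(se_enabled=False)).n_parameters
        assert without < with_se
        # forward still defined without SE
        x = np.zeros((1, 32, 32, 32), dtype=np.float32)
        SEResNet3D(ArchitectureConfig.desk(se_enabled=False)).forward(x)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(filters=(64, 64, 128, 256))
        with pytest.raises(ValueError):
            ArchitectureConfig(filters=(64, 128, 256))

    def test_gap_features_deterministic_inference(self):
        net = SEResNet3D(ArchitectureConfig.desk())
        x = np.random.default_rng(1).normal(size=(2, 32, 32, 32)).astype(np.float32)
        f1 = net.extract_gap_features(x)
        f2 = net.extract_gap_features(x)
        assert np.array_equal(f1, f2)
        z = np.zeros((3, 32, 32, 32), dtype=np.float32)
        fz = net.extract_gap_features(z)
        assert np.allclose(fz[0], fz[1]) and np.allclose(fz[1], fz[2])


class TestBackprop:
    def test_network_gradient_matches_finite_differences(self):
        """End-to-end gradient check of the full layer graph on a tiny net."""
        cfg = ArchitectureConfig(
            input_size=8, filters=(2, 3, 4, 5), fc_widths=(4, 3, 2),
            se_ratio=2, dropout=0.0, l2=0.0, seed=3,
        )
        net = SEResNet3D(cfg)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 8, 8, 8)).astype(np.float32)
        t = np.array([3.0, 1.0, 4.0, 2.0])
        d = np.array([1, 1, 0, 1])

        def loss_at():
            s, _ = net.forward(x, training=True)
            return cox_ph_loss(s.astype(np.float64), t, d)

        s, _ = net.forward(x, training=True)
        _, gscore = cox_ph_loss(s.astype(np.float64), t, d, return_grad=True)
        net.zero_grad()
        net.backward(gscore.astype(np.float32))

        checked = 0
        for p in net.params()[::3]:
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for j in (0, flat.size // 2):
                eps = 1e-3
                orig = flat[j]
                flat[j] = orig + eps
                lp = loss_at()
                flat[j] = orig - eps
                lm = loss_at()
                flat[j] = orig
                fd = (lp - lm) / (2 * eps)
                if abs(fd) > 1e-4 or abs(gflat[j]) > 1e-4:
                    assert gflat[j] == pytest.approx(fd, rel=0.15, abs=2e-3)
                    checked += 1
        assert checked >= 5

    def test_lr_schedule(self):
        p = [Dense(2, 2).params()[0]]
        opt = Adam(p, lr=1e-4, decay=0.96, decay_steps=1000)
        for k in (0, 999, 1000, 2500):
            opt.step_count = k
            assert opt.current_lr == pytest.approx(1e-4 * 0.96 ** (k // 1000))
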