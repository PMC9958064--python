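import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import softmax as scipy_softmax

import cenkd as ck
from cenkd.distill import KDConfig, hard_loss, soft_loss, tempered_softmax, total_loss


class TestTemperedSoftmax:
    def test_symmetric_logits(self):
        assert np.allclose(tempered_softmax([0.0, 0.0], 2.0), [0.5, 0.5])

    def test_two_class_value(self):
        # e^0.5 / (e^0.5 + 1)
        expected = np.exp(0.5) / (np.exp(0.5) + 1)
        out = tempered_softmax([1.0, 0.0], 2.0)
        assert out[0] == pytest.approx(expected, abs=1e-12)
        assert out[0] == pytest.approx(0.6225, abs=1e-4)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_tau_one_is_standard_softmax(self, logits):
        assert np.allclose(tempered_softmax(logits, 1.0), scipy_softmax(logits), atol=1e-12)

    @given(st.lists(st.floats(-20, 20), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_sums_to_one(self, logits):
        assert abs(tempered_softmax(logits, 2.0).sum() - 1.0) < 1e-6

    def test_raising_temperature_softens(self):
        logits = np.array([3.0, 1.0, -2.0])
        gaps = []
        for tau in (1.0, 2.0, 4.0, 8.0):
            p = tempered_softmax(logits, tau)
            gaps.append(p.max() - p.min())
        assert gaps == sorted(gaps, reverse=True)
        assert all(g1 > g2 for g1, g2 in zip(gaps, gaps[1:]))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            tempered_softmax([1.0, 2.0], 0.0)

    def test_extreme_logits_are_stable(self):
        p = tempered_softmax([1000.0, 0.0], 1.0)
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)


class TestLosses:
    def test_kl_of_identical_distributions_is_zero(self):
        p = [0.2, 0.3, 0.5]
        assert soft_loss(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_kl_hand_value(self):
        # 0.5·ln2 + 0.5·ln(2/3)
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert soft_loss([0.5, 0.5], [0.25, 0.75]) == pytest.approx(expected, abs=1e-12)
        assert soft_loss([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.1438, abs=1e-4)

    @given(st.lists(st.floats(0.01, 1), min_size=3, max_size=6),
           st.lists(st.floats(0.01, 1), min_size=3, max_size=6))
    @settings(max_examples=150, deadline=None)
    def test_kl_nonnegative(self, a, b):
        n = min(len(a), len(b))
        p = np.array(a[:n]) / np.sum(a[:n])
        q = np.array(b[:n]) / np.sum(b[:n])
        assert soft_loss(p, q) >= -1e-12

    def test_kl_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_loss([0.5, 0.5], [0.2, 0.3, 0.5])

    def test_cce_one_hot_correct_is_zero(self):
        assert hard_loss([0.0, 1.0, 0.0], 1) == pytest.approx(0.0, abs=1e-9)

    def test_cce_uniform_six_classes(self):
        assert hard_loss(np.full(6, 1 / 6), 3) == pytest.approx(np.log(6), abs=1e-12)

    def test_cce_decreasing_in_true_class_probability(self):
        losses = [hard_loss([p, 1 - p], 0) for p in (0.2, 0.5, 0.9)]
        assert losses == sorted(losses, reverse=True)

    def test_cce_bad_index_rejected(self):
        with pytest.raises(IndexError):
            hard_loss([0.5, 0.5], 2)

    def test_total_loss_arithmetic(self):
        assert total_loss(2.0, 1.0, 0.3) == pytest.approx(1.7)
        assert total_loss(5.0, 3.0, 1.0) == 3.0
        assert total_loss(5.0, 3.0, 0.0) == 5.0

    def test_total_loss_symmetry(self):
        # exchanging (soft, hard) while mapping α ↦ 1−α leaves the value fixed
        assert total_loss(2.0, 7.0, 0.3) == pytest.approx(total_loss(7.0, 2.0, 0.7))

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, 1.5)


class TestKDConfig:
    def test_defaults_match_protocol(self):
        cfg = KDConfig()
        assert cfg.temperature == 2.0
        assert cfg.alpha == 0.3
        assert cfg.batch_size == 16
        assert cfg.epochs == 30
        assert cfg.optimizer == "adam"

    @pytest.mark.parametrize("kw", [{"temperature": 0}, {"alpha": -0.1}, {"alpha": 1.1}])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            KDConfig(**kw)


class TestTraining:
    def test_separable_set_reaches_perfect_training_accuracy(self, tiny_dataset, tiny_arrays):
        """On an easy synthetic set the teacher fits as well as a linear probe."""
        from sklearn.linear_model import LogisticRegression

        (xtr, ytr), _ = tiny_arrays
        probe = LogisticRegression(max_iter=2000).fit(xtr.reshape(len(xtr), -1), ytr)
        assert probe.score(xtr.reshape(len(xtr), -1), ytr) == 1.0

        cfg = KDConfig(seed=0, epochs=30, learning_rate=1e-3)
        graph = ck.build_teacher(32, 6, seed=0)
        model, hist = ck.train_classifier(graph, tiny_dataset, cfg, arrays=(xtr, ytr))
        assert len(hist["loss"]) == cfg.epochs
        assert hist["accuracy"][-1] == 1.0

    def test_same_seed_identical_first_epoch_loss(self, tiny_dataset, tiny_arrays):
        (xtr, ytr), _ = tiny_arrays
        cfg = KDConfig(seed=3, epochs=1)
        g = ck.build_teacher(32, 6, seed=3)
        _, h1 = ck.train_classifier(g, tiny_dataset, cfg, arrays=(xtr, ytr))
        _, h2 = ck.train_classifier(g, tiny_dataset, cfg, arrays=(xtr, ytr))
        assert h1["loss"][0] == h2["loss"][0]

    def test_empty_class_rejected(self, tiny_dataset, tiny_arrays):
        import copy

        (xtr, ytr), _ = tiny_arrays
        broken = copy.deepcopy(tiny_dataset)
        for s in broken.samples:
            if s.label == 0 and s.split == "train":
                s.split = "validation"
        with pytest.raises(ValueError, match="empty"):
            ck.train_classifier(ck.build_teacher(32, 6), broken, KDConfig(epochs=1))

    def test_head_width_mismatch_rejected(self, tiny_dataset, tiny_arrays):
        (xtr, ytr), _ = tiny_arrays
        with pytest.raises(ValueError, match="head width"):
            ck.train_classifier(ck.build_teacher(32, 4), tiny_dataset,
                                KDConfig(epochs=1), arrays=(xtr, ytr))


class TestDistill:
    def test_identical_teacher_student_soft_loss_zero_at_start(self, tiny_dataset, tiny_arrays):
        """τ=1, α=0, teacher == student weights → first-batch soft loss ≈ 0."""
        (xtr, ytr), _ = tiny_arrays
        g = ck.build_teacher(32, 6, seed=5)
        teacher = ck.Model(g, seed=5)
        cfg = KDConfig(temperature=1.0, alpha=0.0, epochs=1, seed=5)
        _, hist = ck.distill(teacher, g, tiny_dataset, cfg, arrays=(xtr, ytr))
        # the student drifts within the epoch, so the epoch-mean soft loss is
        # tiny but not exactly zero
        assert hist["soft_loss"][0] < 0.05

    def test_alpha_one_matches_plain_training_trajectory(self, tiny_dataset, tiny_arrays):
        (xtr, ytr), _ = tiny_arrays
        teacher = ck.Model(ck.build_teacher(32, 6, seed=1), seed=1)
        sg = ck.build_teacher(32, 6, seed=2)
        cfg_kd = KDConfig(alpha=1.0, learning_rate=1e-3, epochs=2, seed=2)
        cfg_plain = KDConfig(learning_rate=1e-3, epochs=2, seed=2)
        _, h_kd = ck.distill(teacher, sg, tiny_dataset, cfg_kd, arrays=(xtr, ytr))
        _, h_plain = ck.train_classifier(sg, tiny_dataset, cfg_plain, arrays=(xtr, ytr))
        assert h_kd["hard_loss"] == pytest.approx(h_plain["loss"], rel=1e-5)

    def test_class_width_mismatch_rejected(self, tiny_dataset, tiny_arrays):
        (xtr, ytr), _ = tiny_arrays
        teacher = ck.Model(ck.build_teacher(32, 4, seed=1), seed=1)
        with pytest.raises(ValueError, match="width"):
            ck.distill(teacher, ck.build_teacher(32, 6), tiny_dataset,
                       KDConfig(epochs=1), arrays=(xtr, ytr))
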