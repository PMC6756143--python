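import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apneascan import model as m
from apneascan.ecg_io import APNEA, NORMAL


def brute_force_placements(l_in, kernel, stride):
    """Count valid kernel placements by direct enumeration."""
    return sum(1 for start in range(0, l_in - kernel + 1) if start % stride == 0)


class TestArchitectureArithmetic:
    @pytest.mark.parametrize(
        "l_in,kernel,stride,expected",
        [(900, 5, 2, 448), (448, 3, 3, 149), (149, 5, 2, 73), (73, 3, 3, 24)],
    )
    def test_published_shape_column(self, l_in, kernel, stride, expected):
        assert m.layer_output_length(l_in, kernel, stride, 0) == expected

    def test_single_position(self):
        for k in (1, 3, 7):
            assert m.layer_output_length(k, k, 1, 0) == 1

    def test_matches_brute_force_enumeration(self):
        for l_in, kernel, stride in [(10, 3, 1), (10, 3, 2), (97, 5, 2), (50, 3, 3)]:
            assert m.layer_output_length(l_in, kernel, stride) == brute_force_placements(
                l_in, kernel, stride
            )

    def test_input_too_small_rejected(self):
        with pytest.raises(ValueError):
            m.layer_output_length(3, 5, 1, 0)

    def test_full_shape_trace(self):
        trace = m.shape_trace(m.modified_lenet5())
        lengths = [shape[0] for _, shape in trace if len(shape) == 2]
        assert lengths == [900, 448, 149, 73, 24, 24]
        assert trace[-2][1] == (32,)
        assert trace[-1][1] == (2,)

    def test_parameter_counts_per_layer(self):
        counts, total = m.count_parameters(m.modified_lenet5())
        assert counts == [352, 0, 10304, 0, 0, 49184, 66]
        assert total == 59906

    def test_minimal_conv_has_two_parameters(self):
        spec = m.ModelSpec(
            input_length=4, input_channels=1,
            layers=(m.LayerSpec(kind="conv1d", filters=1, kernel=1),),
        )
        assert m.count_parameters(spec) == ([2], 2)


class TestSoftmaxAndLoss:
    def test_symmetry(self):
        np.testing.assert_allclose(m.softmax(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_closed_form(self):
        out = m.softmax(np.array([1.0, 0.0]))
        np.testing.assert_allclose(out, [0.7311, 0.2689], atol=1e-4)

    @given(
        z=st.lists(st.floats(-50, 50), min_size=2, max_size=5),
        c=st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, z, c):
        z = np.asarray(z)
        np.testing.assert_allclose(m.softmax(z + c), m.softmax(z), atol=1e-12)
        assert m.softmax(z).sum() == pytest.approx(1.0)

    def test_perfect_prediction_zero_loss(self):
        assert m.cross_entropy_loss([[1, 0]], [[1, 0]]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_ln2(self):
        assert m.cross_entropy_loss([[1, 0]], [[0.5, 0.5]]) == pytest.approx(np.log(2))

    def test_mean_aggregation(self):
        a = m.cross_entropy_loss([[1, 0]], [[0.9, 0.1]])
        b = m.cross_entropy_loss([[0, 1]], [[0.3, 0.7]])
        both = m.cross_entropy_loss([[1, 0], [0, 1]], [[0.9, 0.1], [0.3, 0.7]])
        assert both == pytest.approx((a + b) / 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.cross_entropy_loss([[1, 0]], [[0.5, 0.5], [0.5, 0.5]])


class TestBuildAndForward:
    def test_zero_input_gives_valid_distribution(self):
        net = m.build_model(m.modified_lenet5(), seed=0)
        out = net.forward(np.zeros((4, 900, 2)))
        np.testing.assert_allclose(out.sum(axis=1), 1.0)
        assert np.all(out >= 0)

    def test_reported_parameters_match_arithmetic_oracle(self):
        spec = m.modified_lenet5()
        net = m.build_model(spec, seed=1)
        assert net.n_parameters == m.count_parameters(spec)[1]

    def test_same_seed_identical_outputs(self):
        x = np.random.default_rng(0).normal(size=(2, 900, 2))
        a = m.build_model(m.modified_lenet5(), seed=7).forward(x)
        b = m.build_model(m.modified_lenet5(), seed=7).forward(x)
        np.testing.assert_array_equal(a, b)

    def test_gradient_matches_finite_differences(self):
        # small network, numeric gradient oracle on every parameter tensor
        spec = m.ModelSpec(
            input_length=20, input_channels=2,
            layers=(
                m.LayerSpec(kind="conv1d", filters=3, kernel=5, stride=2, activation="relu"),
                m.LayerSpec(kind="maxpool1d", kernel=2, stride=2),
                m.LayerSpec(kind="dense", units=4, activation="relu"),
                m.LayerSpec(kind="softmax_output", units=2, activation="softmax"),
            ),
        )
        net = m.build_model(spec, seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 20, 2))
        y = np.zeros((5, 2))
        y[np.arange(5), rng.integers(0, 2, 5)] = 1.0

        def loss():
            return m.cross_entropy_loss(y, net.forward(x))

        proba = net.forward(x)
        net.backward((proba - y) / 5)
        eps = 1e-6
        for p, g in net.params():
            flat_p, flat_g = p.ravel(), g.ravel()
            for idx in rng.choice(flat_p.size, size=min(5, flat_p.size), replace=False):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up = loss()
                flat_p[idx] = orig - eps
                down = loss()
                flat_p[idx] = orig
                assert (up - down) / (2 * eps) == pytest.approx(flat_g[idx], rel=1e-3, abs=1e-6)


class TestTraining:
    def test_learns_separable_windows(self, separable_windows):
        cfg = m.TrainConfig(max_epochs=30, seed=0, val_fraction=0.0)
        net = m.build_model(m.modified_lenet5(), seed=0)
        net, history = m.train(net, separable_windows, cfg)
        preds = m.predict_proba(net, separable_windows)
        acc = np.mean(
            [p == w.label for p, w in zip(preds.labels, separable_windows)]
        )
        assert acc >= 0.95
        assert history[-1] < history[0]

    def test_initial_loss_near_ln2_for_balanced_classes(self, separable_windows):
        cfg = m.TrainConfig(max_epochs=1, seed=0, val_fraction=0.0)
        net = m.build_model(m.modified_lenet5(), seed=0)
        _, history = m.train(net, separable_windows, cfg)
        assert history[0] == pytest.approx(np.log(2), abs=0.05)

    def test_seeded_rerun_identical_history(self, separable_windows):
        histories = []
        for _ in range(2):
            net = m.build_model(m.modified_lenet5(), seed=3)
            _, h = m.train(net, separable_windows[:60], m.TrainConfig(max_epochs=3, seed=3))
            histories.append(h)
        assert histories[0] == histories[1]

    def test_single_class_rejected(self, separable_windows):
        only_apnea = [w for w in separable_windows if w.label == APNEA]
        with pytest.raises(ValueError, match="both classes"):
            m.train(m.build_model(m.modified_lenet5(), seed=0), only_apnea, m.TrainConfig())


@pytest.fixture(scope="module")
def trained(separable_windows):
    net = m.build_model(m.modified_lenet5(), seed=0)
    net, _ = m.train(net, separable_windows[:80], m.TrainConfig(max_epochs=5, seed=0))
    return net


class TestPredict:

    def test_probabilities_valid(self, trained, separable_windows):
        preds = m.predict_proba(trained, separable_windows[80:120])
        assert np.all((preds.proba_apnea >= 0) & (preds.proba_apnea <= 1))

    def test_inference_is_deterministic_dropout_off(self, trained, separable_windows):
        a = m.predict_proba(trained, separable_windows[:20]).proba_apnea
        b = m.predict_proba(trained, separable_windows[:20]).proba_apnea
        np.testing.assert_array_equal(a, b)

    def test_batch_order_equivariance(self, trained, separable_windows):
        subset = separable_windows[:30]
        fwd = m.predict_proba(trained, subset).proba_apnea
        rev = m.predict_proba(trained, subset[::-1]).proba_apnea
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-12)

    def test_empty_input_empty_output(self, trained):
        assert len(m.predict_proba(trained, []).proba_apnea) == 0

    def test_hard_labels_follow_threshold(self, trained, separable_windows):
        preds = m.predict_proba(trained, separable_windows[:20])
        for p, lbl in zip(preds.proba_apnea, preds.labels):
            assert lbl == (APNEA if p >= 0.5 else NORMAL)
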