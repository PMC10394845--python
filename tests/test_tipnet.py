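import math

import numpy as np
import pytest

from tasselseg.io_formats import PointCloud
from tasselseg.preprocess import estimate_normals, farthest_point_sample
from tasselseg.tipnet import (
    NetworkConfig,
    TipSegNet,
    TrainConfig,
    cross_entropy_loss,
    forward,
    interpolate_features,
    load_checkpoint,
    predict_tips,
    reduced_config,
    save_checkpoint,
    segmentation_metrics,
    train,
)
from tasselseg.tipnet.autograd import Parameter, Tensor


def metrics_oracle(pred, truth, positive):
    tp = fp = fn = tn = 0
    for p, t in zip(pred, truth):
        if p == positive and t == positive:
            tp += 1
        elif p == positive:
            fp += 1
        elif t == positive:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestAutograd:
    def test_linear_gradients_match_finite_differences(self, rng):
        x = rng.normal(size=(7, 4))
        w = Parameter(rng.normal(size=(4, 3)))
        b = Parameter(rng.normal(size=3))
        labels = rng.integers(0, 3, 7)

        def loss_value(wdata):
            return -np.mean(
                np.log(np.exp(x @ wdata + b.data)
                       / np.exp(x @ wdata + b.data).sum(1, keepdims=True)
                       )[np.arange(7), labels])

        loss = Tensor(x).linear(w, b).log_softmax().nll_loss(labels)
        loss.backward()
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (3, 2)]:
            w2 = w.data.copy()
            w2[idx] += eps
            numeric = (loss_value(w2) - loss_value(w.data)) / eps
            assert w.grad[idx] == pytest.approx(numeric, abs=1e-4)

    def test_max_routes_gradient_to_argmax(self):
        x = Tensor(np.array([[1.0, 5.0, 3.0]]), requires_grad=True)
        y = x.max(axis=1)
        out = y.mul_const(2.0).sum(axis=0)
        out.backward()
        assert np.allclose(x.grad, [[0.0, 2.0, 0.0]])

    def test_gather_scatter_adds(self):
        x = Tensor(np.arange(4.0)[:, None], requires_grad=True)
        y = x.gather(np.array([0, 0, 2]))
        y.sum(axis=0).sum(axis=0).backward()
        assert np.allclose(x.grad.ravel(), [2.0, 0.0, 1.0, 0.0])


class TestInterpolateFeatures:
    def test_equidistant_mean(self):
        supports = np.array([[1.0, 0, 0], [-0.5, math.sqrt(3) / 2, 0],
                             [-0.5, -math.sqrt(3) / 2, 0]])
        feats = np.array([[1.0], [2.0], [3.0]])
        got = interpolate_features(np.zeros((1, 3)), supports, feats, 3)
        assert got[0, 0] == pytest.approx(2.0)

    def test_inverse_square_weighting(self):
        supports = np.array([[1.0, 0, 0], [2.0, 0, 0]])
        feats = np.array([[0.0], [3.0]])
        got = interpolate_features(np.zeros((1, 3)), supports, feats, 2)
        # w = 1, 0.25 -> (1*0 + 0.25*3) / 1.25 = 0.6
        assert got[0, 0] == pytest.approx(0.6)

    def test_coincident_support_exact(self):
        supports = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        feats = np.array([[7.0], [1.0], [9.0]])
        got = interpolate_features(np.zeros((1, 3)), supports, feats, 3)
        assert got[0, 0] == pytest.approx(7.0)

    def test_convex_combination_bounds(self, rng):
        supports = rng.normal(size=(20, 3))
        feats = rng.normal(size=(20, 5))
        queries = rng.normal(size=(10, 3))
        got = interpolate_features(queries, supports, feats, 4)
        assert np.all(got <= feats.max(axis=0) + 1e-12)
        assert np.all(got >= feats.min(axis=0) - 1e-12)

    def test_empty_supports_errors(self):
        with pytest.raises(ValueError):
            interpolate_features(np.zeros((1, 3)), np.zeros((0, 3)),
                                 np.zeros((0, 1)), 1)


class TestCrossEntropy:
    def test_perfect_predictions(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(p, np.array([0, 1])) == pytest.approx(0.0)

    def test_uniform_binary(self):
        p = np.full((10, 2), 0.5)
        labels = np.zeros(10, dtype=int)
        assert cross_entropy_loss(p, labels) == pytest.approx(math.log(2))

    def test_point_nine(self):
        p = np.array([[0.9, 0.1]])
        assert cross_entropy_loss(p, np.array([0])) == pytest.approx(
            -math.log(0.9))

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.array([[0.5, 0.5]]), np.array([2]))


class TestSegmentationMetrics:
    def test_perfect_match(self, rng):
        labels = rng.integers(0, 2, 100)
        m = segmentation_metrics(labels, labels)
        for c in (0, 1):
            assert m[c].iou == m[c].accuracy == 1.0
            assert m[c].precision == m[c].recall == 1.0

    def test_forced_counts(self):
        # TP=3 FP=1 FN=1 TN=5 for class 1
        pred = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        truth = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        m = segmentation_metrics(pred, truth)[1]
        assert m.iou == pytest.approx(0.6)
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 2, 1000)
        truth = rng.integers(0, 2, 1000)
        m = segmentation_metrics(pred, truth)
        for c in (0, 1):
            tp, fp, fn, tn = metrics_oracle(pred, truth, c)
            assert m[c].iou == pytest.approx(tp / (tp + fp + fn))
            assert m[c].precision == pytest.approx(tp / (tp + fp))
            assert m[c].recall == pytest.approx(tp / (tp + fn))
            assert m[c].accuracy == pytest.approx((tp + tn) / 1000)

    def test_absent_class_reports_one(self):
        pred = np.zeros(10, dtype=int)
        truth = np.zeros(10, dtype=int)
        assert segmentation_metrics(pred, truth)[1].iou == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            segmentation_metrics(np.zeros(3), np.zeros(4))


@pytest.fixture(scope="module")
def train_clouds():
    from tasselseg.synthetic import TasselSpec, generate_tassel

    clouds = []
    for seed in range(2):
        cloud, _ = generate_tassel(TasselSpec(seed=seed))
        clouds.append(cloud.select(farthest_point_sample(cloud, 512)))
    return clouds


@pytest.fixture(scope="module")
def tiny_net_config():
    from tasselseg.tipnet import IpLayerConfig, SaLayerConfig

    return NetworkConfig(
        sa_layers=(
            SaLayerConfig(64, (2.0,), (16,), ((16, 32),)),
            SaLayerConfig(16, (4.0,), (16,), ((32, 48),)),
            SaLayerConfig(4, (12.0,), (16,), ((48, 64),)),
        ),
        ip_layers=(
            IpLayerConfig(3, (64,)),
            IpLayerConfig(3, (48,)),
            IpLayerConfig(3, (32,)),
        ),
        head_channels=(32,),
    )


class TestForward:
    def test_simplex_output(self, train_clouds, tiny_net_config):
        model = TipSegNet(tiny_net_config, seed=0)
        cloud = estimate_normals(train_clouds[0], 16)
        p = forward(model, cloud)
        assert p.shape == (len(cloud), 2)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_duplicate_point_same_row(self, tiny_net_config, rng):
        coords = rng.uniform(0, 10, (100, 3))
        coords[50] = coords[10]  # exact duplicate
        cloud = estimate_normals(PointCloud(coords), 8)
        cloud.normals[50] = cloud.normals[10]
        p = forward(TipSegNet(tiny_net_config, seed=1), cloud)
        assert np.allclose(p[10], p[50], atol=1e-12)

    def test_deterministic(self, train_clouds, tiny_net_config):
        cloud = estimate_normals(train_clouds[0], 16)
        p1 = forward(TipSegNet(tiny_net_config, seed=3), cloud)
        p2 = forward(TipSegNet(tiny_net_config, seed=3), cloud)
        assert np.array_equal(p1, p2)

    def test_missing_normals_errors(self, train_clouds, tiny_net_config):
        with pytest.raises(Exception):
            forward(TipSegNet(tiny_net_config, seed=0), train_clouds[0])


class TestTrain:
    def test_lr_schedule(self):
        cfg = TrainConfig()
        assert cfg.learning_rate(0) == pytest.approx(0.001)
        assert cfg.learning_rate(20) == pytest.approx(0.0005)
        assert cfg.learning_rate(40) == pytest.approx(0.00025)

    def test_loss_decreases_and_memorizes(self, train_clouds, tiny_net_config):
        model = TipSegNet(tiny_net_config, seed=0)
        cfg = TrainConfig(epochs=15, batch_size=2, seed=0)
        model, hist = train(model, train_clouds, config=cfg)
        assert len(hist.train_loss) == 15
        # best-so-far loss decreases over training
        assert min(hist.train_loss[-3:]) < hist.train_loss[0]
        assert hist.train_accuracy[-1] > 0.8

    def test_same_seed_identical_history(self, train_clouds, tiny_net_config):
        histories = []
        for _ in range(2):
            model = TipSegNet(tiny_net_config, seed=0)
            _, hist = train(model, train_clouds,
                            config=TrainConfig(epochs=3, batch_size=2, seed=0))
            histories.append(hist)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].train_accuracy == histories[1].train_accuracy

    def test_empty_train_set_errors(self):
        with pytest.raises(Exception):
            train(TipSegNet(reduced_config(), seed=0), [])

    def test_unlabeled_cloud_errors(self, train_clouds):
        unlabeled = train_clouds[0].with_(labels=None)
        with pytest.raises(Exception):
            train(TipSegNet(reduced_config(), seed=0), [unlabeled])


class TestPredictTips:
    def test_labels_binary(self, train_clouds, tiny_net_config):
        model = TipSegNet(tiny_net_config, seed=0)
        out = predict_tips(model, train_clouds[0])
        assert set(np.unique(out.labels)) <= {0, 1}

    def test_tie_breaks_to_zero(self):
        # argmax of an exactly tied row returns the first class
        assert int(np.argmax(np.array([0.5, 0.5]))) == 0


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, train_clouds, tiny_net_config):
        model = TipSegNet(tiny_net_config, seed=0)
        model, _ = train(model, train_clouds,
                         config=TrainConfig(epochs=2, batch_size=2, seed=0))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        cloud = estimate_normals(train_clouds[0], 16)
        assert np.array_equal(forward(model, cloud), forward(loaded, cloud))


class TestConfigValidation:
    def test_requires_three_layers(self):
        from tasselseg.tipnet import IpLayerConfig, SaLayerConfig

        sa = SaLayerConfig(8, (1.0,), (8,), ((8,),))
        ip = IpLayerConfig(3, (8,))
        with pytest.raises(ValueError):
            NetworkConfig(sa_layers=(sa, sa), ip_layers=(ip, ip, ip))

    def test_radii_must_increase(self):
        from tasselseg.tipnet import SaLayerConfig

        with pytest.raises(ValueError):
            SaLayerConfig(8, (2.0, 1.0), (8, 8), ((8,), (8,)))

    def test_config_dict_roundtrip(self, tiny_net_config):
        back = NetworkConfig.from_dict(tiny_net_config.to_dict())
        assert back == tiny_net_config
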