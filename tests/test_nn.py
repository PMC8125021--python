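"""Layer gradients, architecture shape contracts, training and fusion."""

import numpy as np
import pytest

from skeldag import (
    ModelConfig,
    SyntheticSpec,
    TwoTowerClassifier,
    fuse_scores,
    generate_dataset,
    make_layer_specs,
    shape_trace,
    train_stream,
)
from skeldag.nn.layers import (
    BatchNorm,
    DagExpand,
    Dense,
    GlobalAvgPool,
    LinearMap,
    ReLU,
    TemporalConv,
    cross_entropy,
    softmax,
)
from skeldag.nn.network import load_checkpoint, save_checkpoint
from skeldag.pipeline import encode_dataset

RNG = np.random.default_rng(20)

SMALL_CHANNELS = (8, 8, 8, 8, 16, 16, 16, 32, 32, 32)


def to_float64(model):
    for l in model.layers():
        for k in l.params:
            l.params[k] = l.params[k].astype(np.float64)
        l.grads = {k: np.zeros_like(v) for k, v in l.params.items()}
        if isinstance(l, BatchNorm):
            l.running_mean = l.running_mean.astype(np.float64)
            l.running_var = l.running_var.astype(np.float64)
    return model


def numeric_vs_analytic(layer, x, train=True, atol=1e-7):
    """Check layer.backward against central differences of a linear loss."""
    for k in layer.params:
        layer.params[k] = layer.params[k].astype(np.float64)
    layer.grads = {k: np.zeros_like(v) for k, v in layer.params.items()}
    if isinstance(layer, BatchNorm):
        layer.running_mean = layer.running_mean.astype(np.float64)
        layer.running_var = layer.running_var.astype(np.float64)
    gout = RNG.standard_normal(layer.forward(x, train).shape)

    def loss():
        return (gout * layer.forward(x, train)).sum()

    loss()
    layer.zero_grad()
    gx = layer.backward(gout)
    eps = 1e-6
    worst = 0.0
    for arr, grads in [(x, gx)] + [
        (layer.params[k], layer.grads[k]) for k in layer.params
    ]:
        for fi in RNG.choice(arr.size, min(6, arr.size), replace=False):
            pr = np.unravel_index(fi, arr.shape)
            orig = arr[pr]
            arr[pr] = orig + eps
            lp = loss()
            arr[pr] = orig - eps
            lm = loss()
            arr[pr] = orig
            num = (lp - lm) / (2 * eps)
            worst = max(worst, abs(num - grads[pr]))
    assert worst < atol, f"gradient mismatch {worst:.2e}"


class TestLayerGradients:
    x4 = RNG.standard_normal((3, 12, 18, 5))

    @pytest.mark.parametrize(
        "factory",
        [
            lambda rng: LinearMap(5, 7, rng),
            lambda rng: BatchNorm(5),
            lambda rng: TemporalConv(5, 6, rng, kernel=9, stride=1, pad=4),
            lambda rng: TemporalConv(5, 6, rng, kernel=9, stride=2, pad=4),
            lambda rng: TemporalConv(5, 6, rng, kernel=3, stride=1, pad=1),
            lambda rng: GlobalAvgPool(),
        ],
        ids=["linear_map", "batch_norm", "conv_s1", "conv_s2", "conv_k3", "gap"],
    )
    def test_backward_matches_finite_differences(self, factory):
        numeric_vs_analytic(factory(np.random.default_rng(0)), self.x4.copy())

    def test_batch_norm_eval_mode_gradient(self):
        bn = BatchNorm(5)
        bn.running_mean = RNG.standard_normal(5)
        bn.running_var = RNG.uniform(0.5, 2.0, 5)
        numeric_vs_analytic(bn, self.x4.copy(), train=False)

    @pytest.mark.parametrize("enabled", [True, False], ids=["dag", "identity"])
    def test_dag_expand_gradient(self, dag, enabled):
        layer = DagExpand(dag.source, dag.target, enabled=enabled)
        layer.S = layer.S.astype(np.float64)
        layer.T = layer.T.astype(np.float64)
        numeric_vs_analytic(layer, self.x4.copy())

    def test_dense_gradient(self):
        numeric_vs_analytic(
            Dense(5, 4, np.random.default_rng(0)), RNG.standard_normal((6, 5))
        )

    def test_end_to_end_gradient(self, dag):
        cfg = ModelConfig(
            n_classes=4, channels=(4, 5, 6), stride2_layers=(2,),
            kernel=3, pad=1, seed=0,
        )
        model = to_float64(TwoTowerClassifier(cfg, dag))
        x = np.random.default_rng(1).standard_normal((3, 16, 18, 3))
        y = np.array([0, 2, 3])

        def loss_fn():
            return cross_entropy(model.forward(x, train=True), y)

        model.zero_grad()
        _, gl = loss_fn()
        model.backward(gl)
        eps, worst = 1e-6, 0.0
        for l in model.layers():
            for k, p in l.params.items():
                g = l.grads[k]
                pr = np.unravel_index(np.argmax(np.abs(g)), g.shape)
                orig = p[pr]
                p[pr] = orig + eps
                lp, _ = loss_fn()
                p[pr] = orig - eps
                lm, _ = loss_fn()
                p[pr] = orig
                num = (lp - lm) / (2 * eps)
                if abs(num - g[pr]) < 1e-8:  # below finite-difference noise
                    continue
                worst = max(
                    worst, abs(num - g[pr]) / max(abs(num), abs(g[pr]))
                )
        assert worst < 1e-5


class TestArchitectureShapes:
    def test_layer_specs_follow_triple_expansion_rule(self):
        specs = make_layer_specs()
        assert [s.linear_out for s in specs] == [64] * 4 + [128] * 3 + [256] * 3
        assert specs[0].linear_in == 3
        for prev, cur in zip(specs, specs[1:]):
            assert cur.linear_in == 3 * prev.linear_out
        assert [s.stride for s in specs] == [1, 1, 1, 1, 2, 1, 1, 2, 1, 1]

    def test_printed_layer_shapes_reproduced(self, dag):
        model = TwoTowerClassifier(ModelConfig(), dag)
        trace = shape_trace(model, 1200)
        expected = [
            (1, (600, 18, 3), (600, 18, 64), (600, 18, 64)),
            (2, (600, 18, 192), (600, 18, 64), (600, 18, 64)),
            (3, (600, 18, 192), (600, 18, 64), (600, 18, 64)),
            (4, (600, 18, 192), (600, 18, 64), (600, 18, 64)),
            (5, (600, 18, 192), (600, 18, 128), (300, 18, 128)),
            (6, (300, 18, 384), (300, 18, 128), (300, 18, 128)),
            (7, (300, 18, 384), (300, 18, 128), (300, 18, 128)),
            (8, (300, 18, 384), (300, 18, 256), (150, 18, 256)),
            (9, (150, 18, 768), (150, 18, 256), (150, 18, 256)),
            (10, (150, 18, 768), (150, 18, 256), (150, 18, 256)),
        ]
        for tower in ("joint_tower", "skeleton_tower"):
            got = [
                (e["layer"], e["linear_in"], e["linear_out"], e["conv_out"])
                for e in trace[tower]
            ]
            assert got == expected
        assert trace["head_in"] == 512
        assert trace["head_out"] == 49

    def test_no_dag_ablation_preserves_shapes(self, dag):
        cfg = ModelConfig(channels=SMALL_CHANNELS, use_dag=False)
        trace = shape_trace(TwoTowerClassifier(cfg, dag), 240)
        ref = shape_trace(
            TwoTowerClassifier(ModelConfig(channels=SMALL_CHANNELS), dag), 240
        )
        for t in ("joint_tower", "skeleton_tower"):
            assert [e["linear_in"] for e in trace[t]] == [
                e["linear_in"] for e in ref[t]
            ]

    def test_softmax_output_is_probability_simplex(self, dag):
        cfg = ModelConfig(n_classes=49, channels=SMALL_CHANNELS, seed=3)
        model = TwoTowerClassifier(cfg, dag)
        x = RNG.standard_normal((2, 240, 18, 3)).astype(np.float32)
        p = model.predict_proba(x)
        assert p.shape == (2, 49)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_input_shape_rejected(self, dag):
        model = TwoTowerClassifier(ModelConfig(channels=SMALL_CHANNELS), dag)
        with pytest.raises(ValueError, match="stream batch"):
            model.forward(np.zeros((2, 240, 18, 5), dtype=np.float32))


@pytest.fixture(scope="module")
def trained(dag):
    """A 2-class training run shared by the training-behaviour tests."""
    spec = SyntheticSpec(
        n_classes=2, clips_per_class=20, frames_per_clip=40, seed=11
    )
    seqs, _ = generate_dataset(spec)
    ds = encode_dataset(seqs, frames=40)
    cfg = ModelConfig(
        n_classes=2, channels=SMALL_CHANNELS, learning_rate=0.05,
        epochs=10, lr_step=0, seed=5,
    )
    res = train_stream(ds.motion, ds.labels, dag, cfg)
    return ds, cfg, res


class TestTraining:
    def test_two_class_smoke_run_fits_the_training_set(self, trained):
        _, _, res = trained
        assert res.history[-1]["train_acc"] > 0.9

    def test_loss_decreases_on_average(self, trained):
        _, _, res = trained
        losses = [h["loss"] for h in res.history]
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_fixed_seed_reproduces_loss_trace(self, trained, dag):
        ds, cfg, res = trained
        res2 = train_stream(ds.motion, ds.labels, dag, cfg)
        assert [h["loss"] for h in res2.history] == [
            h["loss"] for h in res.history
        ]

    def test_single_class_dataset_rejected(self, trained, dag):
        ds, cfg, _ = trained
        with pytest.raises(ValueError, match="two classes"):
            train_stream(
                ds.motion[:5], np.zeros(5, dtype=int), dag, cfg
            )

    def test_checkpoint_round_trip(self, trained, dag, tmp_path):
        ds, cfg, res = trained
        path = tmp_path / "model.npz"
        save_checkpoint(res.model, path)
        back = load_checkpoint(path, dag)
        np.testing.assert_array_equal(
            back.predict_proba(ds.motion[:4]),
            res.model.predict_proba(ds.motion[:4]),
        )


class TestFuseScores:
    def test_identical_inputs_are_a_fixed_point(self):
        p = softmax(RNG.standard_normal((3, 49)))
        fused, _ = fuse_scores(p, p)
        np.testing.assert_allclose(fused, p)

    def test_one_hot_beats_uniform(self):
        spatial = np.zeros(49)
        spatial[3] = 1.0
        motion = np.full(49, 1 / 49)
        _, pred = fuse_scores(spatial, motion)
        assert pred == 3

    def test_elementwise_mean(self):
        fused, pred = fuse_scores(
            np.array([0.6, 0.4]), np.array([0.2, 0.8])
        )
        np.testing.assert_allclose(fused, [0.4, 0.6])
        assert pred == 1

    def test_tie_breaks_toward_lower_class(self):
        _, pred = fuse_scores(np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        assert pred == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_scores(np.zeros(49), np.zeros(48))
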