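import numpy as np
import pytest

from rdpnet import (EntropySpec, LayerSpec, ModelConfig, build_model,
                    count_parameters, load_checkpoint, predict_proba,
                    receptive_field, save_checkpoint, softmax)
from rdpnet import nn
from rdpnet.model import ConfigurationError, ResBlock, ablation_configs

DCPM_PARAMS = 410_880  # 5 x (128*128*5 conv + 2*128 BN)


def gradient_support(layers, input_length):
    """Empirical receptive field: span of input positions (first to last,
    inclusive) with nonzero gradient for one central output position of a
    linear conv stack.  Dilated kernels touch isolated positions, so the
    field is the extent, not the count."""
    rng = np.random.default_rng(0)
    convs = []
    for spec in layers:
        conv = nn.Conv1d(1, 1, spec.kernel, stride=spec.stride,
                         dilation=spec.dilation,
                         padding=spec.dilation * (spec.kernel // 2), rng=rng)
        conv.weight.data[:] = 1.0  # positive taps: no cancellation
        convs.append(conv)
    x = np.zeros((1, 1, input_length), dtype=np.float32)
    y = x
    for conv in convs:
        y = conv.forward(y)
    dy = np.zeros_like(y)
    dy[0, 0, y.shape[2] // 2] = 1.0
    for conv in reversed(convs):
        dy = conv.backward(dy)
    support = np.nonzero(dy[0, 0])[0]
    return int(support[-1] - support[0] + 1)


class TestReceptiveField:
    def test_single_layer(self):
        assert receptive_field([LayerSpec(5)]) == 5

    def test_dcpm_stack(self):
        layers = [LayerSpec(5, d) for d in (1, 2, 4, 8, 16)]
        assert receptive_field(layers) == 125

    def test_two_small_kernels_compose(self):
        assert receptive_field([LayerSpec(3), LayerSpec(3)]) == 5

    def test_agrees_with_gradient_support_oracle(self):
        rng = np.random.default_rng(10)
        stacks = [[LayerSpec(5, d) for d in (1, 2, 4, 8, 16)]]
        for _ in range(5):
            n_layers = rng.integers(1, 4)
            stacks.append([
                LayerSpec(kernel=int(rng.choice([3, 5, 7])),
                          dilation=int(rng.choice([1, 2, 3, 4])))
                for _ in range(n_layers)])
        for layers in stacks:
            rf = receptive_field(layers)
            if rf > 201:
                continue
            assert gradient_support(layers, 2 * rf + 9) == rf


class TestShapes:
    @pytest.mark.parametrize("T", [512, 256, 1024])
    @pytest.mark.parametrize("batch", [1, 3])
    def test_stage_shapes_follow_configuration(self, T, batch, default_cfg):
        model = build_model(default_cfg, seed=0).eval()
        x = np.zeros((batch, 1, T), dtype=np.float32)
        logits = model.forward(x)
        assert model._stage["rcm"].shape == (batch, 128, T // 4)
        assert model._stage["dcpm"].shape == (batch, 128, T // 4)
        assert model._stage["fused"].shape == (batch, 512)
        assert logits.shape == (batch, 5)

    def test_minimum_length_runs_without_entropy(self):
        # T=4 collapses every stage to length-1 maps; a single time
        # sample has no variance, so only the pooled pathways remain
        model = build_model(ModelConfig(use_entropy=False)).eval()
        logits = model.forward(np.zeros((2, 1, 4), dtype=np.float32))
        assert model._stage["dcpm"].shape == (2, 128, 1)
        assert logits.shape == (2, 5)

    def test_minimum_length_with_entropy_is_explicit_error(self,
                                                           default_cfg):
        model = build_model(default_cfg).eval()
        with pytest.raises(ValueError, match="2 time samples"):
            model.forward(np.zeros((2, 1, 4), dtype=np.float32))

    def test_resblock_halves_length(self):
        rng = np.random.default_rng(0)
        block = ResBlock(1, 64, 5, rng)
        block.eval()
        y = block.forward(np.zeros((2, 1, 512), dtype=np.float32))
        assert y.shape == (2, 64, 256)

    def test_resblock_zero_input_zero_output(self):
        rng = np.random.default_rng(0)
        block = ResBlock(4, 8, 5, rng).eval()
        y = block.forward(np.zeros((1, 4, 64), dtype=np.float32))
        assert np.all(y == 0)

    def test_resblock_reduces_to_shortcut_when_main_is_zero(self):
        rng = np.random.default_rng(1)
        block = ResBlock(4, 8, 5, rng).eval()
        block.conv2.weight.data[:] = 0.0  # kill the residual function
        x = np.random.default_rng(2).standard_normal((2, 4, 32)) \
            .astype(np.float32)
        y = block.forward(x)
        short = block.sc_bn.forward(block.sc_conv.forward(x))
        assert y == pytest.approx(np.maximum(short, 0.0), abs=1e-6)

    def test_dcpm_preserves_length(self, default_cfg):
        model = build_model(default_cfg).eval()
        for layer in model.pyramid:
            x = np.random.default_rng(0).standard_normal((1, 128, 37)) \
                .astype(np.float32)
            assert layer.forward(x).shape == x.shape

    def test_fused_width_without_entropy(self):
        cfg = ModelConfig(use_entropy=False)
        model = build_model(cfg).eval()
        model.forward(np.zeros((2, 1, 64), dtype=np.float32))
        assert model._stage["fused"].shape == (2, 256)

    def test_ffem_temporal_permutation_invariant(self, default_cfg, rng):
        model = build_model(default_cfg, seed=3).eval()
        x = rng.standard_normal((2, 1, 512)).astype(np.float32)
        model.forward(x)
        branch = model._stage["rcm"]
        main = model._stage["dcpm"]
        fused = model.ffem.forward(branch, main)
        perm = rng.permutation(branch.shape[2])
        fused_p = model.ffem.forward(branch[:, :, perm], main[:, :, perm])
        assert fused_p == pytest.approx(fused, abs=1e-5)

    def test_constant_feature_maps_degenerate_entropy(self, default_cfg):
        model = build_model(default_cfg).eval()
        c = np.full((2, 128, 16), 1.5, dtype=np.float32)
        model.ffem.forward(c, c)
        bundle = model.ffem.bundle
        # pooled features equal the constant before normalization;
        # entropy features hit the eps floor
        pooled = model.ffem.pool_branch.forward(c)
        assert np.all(pooled == 1.5)
        eps = default_cfg.entropy_spec.eps
        raw_h = model.ffem.ent_branch.forward(c)
        assert raw_h == pytest.approx(
            0.5 * np.log(2 * np.pi * np.e * eps), abs=1e-4)
        assert bundle.fused.shape == (2, 512)


class TestParameterAccounting:
    def test_default_model_total(self, default_cfg):
        model = build_model(default_cfg)
        assert count_parameters(model) == 568_581

    def test_linear_head_count(self):
        lin = nn.Linear(512, 5)
        assert sum(p.data.size for p in lin.parameters()) == 2_565

    def test_extra_class_adds_head_row(self):
        base = count_parameters(build_model(ModelConfig(n_classes=5)))
        more = count_parameters(build_model(ModelConfig(n_classes=6)))
        assert more - base == 512 + 1

    def test_wo_dcpm_removes_exactly_the_pyramid(self, default_cfg):
        full = count_parameters(build_model(default_cfg))
        wo = count_parameters(build_model(ModelConfig(use_dcpm=False)))
        assert full - wo == DCPM_PARAMS

    def test_all_ablations_have_fewer_parameters(self, default_cfg):
        full = count_parameters(build_model(default_cfg))
        for name, cfg in ablation_configs(default_cfg).items():
            if name == "full":
                continue
            assert count_parameters(build_model(cfg)) < full


class TestAblationWiring:
    def test_wo_rcm_projects_input_to_pyramid(self):
        cfg = ModelConfig(use_rcm=False)
        model = build_model(cfg).eval()
        logits = model.forward(np.zeros((2, 1, 512), dtype=np.float32))
        assert model._stage["rcm"].shape == (2, 128, 128)  # adapter output
        assert logits.shape == (2, 5)

    def test_wo_dcpm_fuses_rcm_with_itself(self):
        cfg = ModelConfig(use_dcpm=False)
        model = build_model(cfg).eval()
        model.forward(np.zeros((2, 1, 512), dtype=np.float32))
        assert model._stage["fused"].shape == (2, 512)

    def test_disabling_both_modules_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(use_rcm=False, use_dcpm=False)

    @pytest.mark.parametrize("bad", [
        dict(rcm_kernel=4), dict(dcpm_kernel=1),
        dict(dcpm_dilations=(1, 2, 2)), dict(dcpm_dilations=(2, 1)),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ModelConfig(**bad)


class TestSoftmaxHead:
    def test_equal_logits_uniform(self):
        p = softmax(np.zeros((3, 5)))
        assert p == pytest.approx(np.full((3, 5), 0.2))

    def test_closed_form_binary(self):
        p = predict_proba(np.array([[0.0, np.log(3.0)]]))
        assert p[0] == pytest.approx([0.25, 0.75])

    def test_rows_sum_to_one(self, rng):
        p = softmax(rng.standard_normal((50, 7)) * 10)
        assert p.sum(axis=1) == pytest.approx(np.ones(50), abs=1e-6)


class TestDeterminismAndCheckpoints:
    def test_eval_forward_deterministic(self, default_cfg, rng):
        model = build_model(default_cfg, seed=5).eval()
        x = rng.standard_normal((2, 1, 512)).astype(np.float32)
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_checkpoint_roundtrip(self, default_cfg, rng, tmp_path):
        cfg = ModelConfig(entropy_spec=EntropySpec(eps=1e-5))
        model = build_model(cfg, seed=6).eval()
        x = rng.standard_normal((2, 1, 512)).astype(np.float32)
        before = model.forward(x)
        save_checkpoint(model, tmp_path / "ck")
        restored = load_checkpoint(tmp_path / "ck")
        assert restored.cfg == cfg
        assert np.array_equal(restored.eval().forward(x), before)
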