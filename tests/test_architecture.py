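"""Architecture contracts: patch ops, SD-SSM block residual identity, MUNet shapes."""

import numpy as np
import pytest

from munet.architecture import (
    ModelConfig,
    MUNet,
    PatchEmbed,
    PatchExpand,
    PatchMerge,
    SDSSMBlock,
    SkipFusion,
    build_munet,
    load_checkpoint,
    save_checkpoint,
)
from munet.autodiff import Tensor


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(embed_dim=16, num_stages=2)


class TestPatchOps:
    def test_embed_shape(self, rng):
        cfg = ModelConfig()
        pe = PatchEmbed(cfg, rng)
        out = pe(Tensor(rng.normal(size=(1, 4, 64, 64))))
        assert out.shape == (1, 32, 16, 16)

    def test_embed_constant_input_constant_output(self, rng):
        cfg = ModelConfig()
        pe = PatchEmbed(cfg, rng)
        out = pe(Tensor(np.ones((1, 4, 16, 16)))).data
        assert np.allclose(out, out[:, :, :1, :1], atol=1e-10)

    def test_embed_equals_unfold_matmul(self, rng):
        """Patch projection is exactly an unfold + linear map."""
        cfg = ModelConfig(patch_size=2, embed_dim=6)
        pe = PatchEmbed(cfg, rng)
        x = rng.normal(size=(1, 4, 8, 8))
        out = pe(Tensor(x)).data
        w = pe.proj.weight.data.reshape(6, -1)
        b = pe.proj.bias.data
        for i in range(4):
            for j in range(4):
                patch = x[0, :, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2].ravel()
                assert np.allclose(out[0, :, i, j], w @ patch + b, atol=1e-10)

    def test_embed_indivisible_raises(self, rng):
        pe = PatchEmbed(ModelConfig(), rng)
        with pytest.raises(ValueError, match="patch_size"):
            pe(Tensor(np.zeros((1, 4, 30, 32))))

    def test_merge_shape_and_rearrangement(self, rng):
        pm = PatchMerge(32, rng)
        x = rng.normal(size=(1, 32, 16, 16))
        assert pm(Tensor(x)).shape == (1, 64, 8, 8)
        pre = PatchMerge.rearrange(Tensor(x)).data
        # each 2x2 cell's entries are rearranged, not mixed
        cell = pre[0, :, 3, 5].reshape(4, 32)
        orig = x[0, :, 6:8, 10:12]
        assert np.array_equal(np.sort(cell.T.ravel()), np.sort(orig.ravel()))

    def test_merge_degenerate_raises(self, rng):
        pm = PatchMerge(4, rng)
        with pytest.raises(ValueError):
            pm(Tensor(np.zeros((1, 4, 1, 1))))

    def test_expand_inverse_shape(self, rng):
        px = PatchExpand(64, rng)
        assert px(Tensor(rng.normal(size=(1, 64, 8, 8)))).shape == (1, 32, 16, 16)
        pm = PatchMerge(32, rng)
        x = Tensor(rng.normal(size=(1, 32, 16, 16)))
        assert px(pm(x)).shape == x.shape

    def test_expand_odd_channels_raises(self, rng):
        with pytest.raises(ValueError):
            PatchExpand(5, rng)


class TestSDSSMBlock:
    def test_residual_identity_at_zero_scales(self, rng, tiny_cfg):
        block = SDSSMBlock(16, tiny_cfg, rng)
        x = Tensor(rng.normal(size=(2, 16, 8, 8)))
        assert np.array_equal(block(x).data, x.data)

    def test_nonzero_scales_change_output(self, rng, tiny_cfg):
        block = SDSSMBlock(16, tiny_cfg, rng)
        block.scale1.data[:] = 0.3
        block.scale2.data[:] = 0.3
        x = Tensor(rng.normal(size=(1, 16, 8, 8)))
        assert not np.allclose(block(x).data, x.data)

    def test_gradient_smoke(self, rng, tiny_cfg):
        block = SDSSMBlock(16, tiny_cfg, rng)
        block.scale1.data[:] = 0.1
        block.scale2.data[:] = 0.1
        x = Tensor(np.random.default_rng(0).normal(size=(1, 16, 8, 8)), requires_grad=True)
        block(x).sum().backward()
        assert np.all(np.isfinite(x.grad))
        assert np.any(x.grad != 0)


class TestSkipFusion:
    def test_zero_skip_is_projection_of_decoder(self, rng):
        fuse = SkipFusion(8, rng)
        d = Tensor(rng.normal(size=(1, 8, 4, 4)))
        z = Tensor(np.zeros((1, 8, 4, 4)))
        assert np.allclose(fuse(d, z).data, fuse.proj(d).data)

    def test_symmetry(self, rng):
        fuse = SkipFusion(8, rng)
        a = Tensor(rng.normal(size=(1, 8, 4, 4)))
        b = Tensor(rng.normal(size=(1, 8, 4, 4)))
        assert np.allclose(fuse(a, b).data, fuse(b, a).data, atol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        fuse = SkipFusion(8, rng)
        with pytest.raises(ValueError):
            fuse(Tensor(np.zeros((1, 8, 4, 4))), Tensor(np.zeros((1, 8, 2, 2))))


class TestMUNet:
    def test_end_to_end_shape_law(self, tiny_cfg):
        model = build_munet(tiny_cfg, seed=0)
        for hw in (32, 64, 96):
            logits = model(Tensor(np.zeros((1, 4, hw, hw))))
            assert logits.shape == (1, tiny_cfg.num_classes, hw, hw)

    def test_indivisible_input_raises(self, tiny_cfg):
        model = build_munet(tiny_cfg, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model(Tensor(np.zeros((1, 4, 36, 36))))

    def test_seeded_construction_identical(self, tiny_cfg):
        m1 = build_munet(tiny_cfg, seed=11)
        m2 = build_munet(tiny_cfg, seed=11)
        for (n1, p1), (n2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
            assert n1 == n2
            assert np.array_equal(p1.data, p2.data)

    def test_forward_deterministic(self, tiny_cfg, rng):
        model = build_munet(tiny_cfg, seed=3).eval()
        x = rng.normal(size=(1, 4, 32, 32))
        assert np.array_equal(model.predict_logits(x), model.predict_logits(x))

    def test_parameter_count_matches_closed_form_tally(self, tiny_cfg):
        model = build_munet(tiny_cfg, seed=0)
        assert model.num_parameters() == expected_munet_params(tiny_cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=15)
        with pytest.raises(ValueError):
            ModelConfig(depths=0)
        with pytest.raises(ValueError):
            ModelConfig(dilation_rates=())

    def test_checkpoint_round_trip(self, tiny_cfg, tmp_path, rng):
        model = build_munet(tiny_cfg, seed=5)
        x = rng.normal(size=(1, 4, 32, 32))
        ref = model.eval().predict_logits(x)
        save_checkpoint(model, tmp_path / "ckpt.npz", step=42)
        loaded, sidecar = load_checkpoint(tmp_path / "ckpt.npz")
        assert sidecar["step"] == 42
        assert sidecar["config"] == tiny_cfg.to_dict()
        assert np.array_equal(loaded.predict_logits(x), ref)


# ---------------------------------------------------------------------------
# Independent closed-form parameter tally (counts layers from the config
# arithmetic, not by walking the module tree).
# ---------------------------------------------------------------------------


def _sdconv_params(C: int) -> int:
    # SRU: group-norm affine
    n = 2 * C
    c_up = C // 2
    c_low = C - c_up
    sq_up = max(1, c_up // 2)
    sq_low = max(1, c_low // 2)
    import math

    g = math.gcd(2, math.gcd(sq_up, C))
    # CRU: squeeze convs, group-wise conv, two pointwise convs (bias-free)
    n += c_up * sq_up + c_low * sq_low
    n += (sq_up // g) * C * 9
    n += sq_up * C
    n += sq_low * (C - sq_low)
    # depthwise separable (bias-free)
    n += C * 9 + C * C
    return n


def _block_params(C: int, cfg: ModelConfig) -> int:
    n = 2 * C  # batch norm
    n += len(cfg.dilation_rates) * _sdconv_params(C)  # X1 branch
    n += 2 * C  # layer norm
    n += C * C + C  # linear 1x1 (with bias)
    n += _sdconv_params(C)  # X2 SD-Conv
    # S6: A, W_dt, b_dt, W_B, b_B, W_C, b_C
    N = cfg.n_state
    n += C * N + C * C + C + C * N + N + C * N + N
    n += C * C  # SS2D output projection
    n += 2  # branch scales
    return n


def expected_munet_params(cfg: ModelConfig) -> int:
    S = cfg.num_stages
    widths = [cfg.embed_dim * 2**s for s in range(S)]
    E = cfg.embed_dim
    n = cfg.in_channels * E * cfg.patch_size**2 + E  # patch embed
    for s in range(S - 1):
        n += cfg.depths * _block_params(widths[s], cfg)  # encoder blocks
        n += 4 * widths[s] * 2 * widths[s]  # patch merge (bias-free)
    n += cfg.depths * _block_params(widths[-1], cfg)  # bottleneck
    for s in range(S - 2, -1, -1):
        n += widths[s + 1] * 2 * widths[s + 1]  # patch expand (bias-free)
        n += widths[s] * widths[s] + widths[s]  # skip fusion projection
        n += cfg.depths * _block_params(widths[s], cfg)  # decoder blocks
    n += E * E * cfg.patch_size**2  # final expand (bias-free)
    n += E * cfg.num_classes + cfg.num_classes  # head
    return n
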