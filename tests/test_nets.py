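import numpy as np
import pytest

from bcseg import nets
from bcseg.ndnn.autograd import Tensor
from bcseg.nets import (ArchitectureCfg, GhostBottleneck, GhostBottleneckCfg,
                        GhostModule, GhostModuleCfg, ResidualBlock,
                        ResidualBlockCfg, binarize, build_model,
                        count_trainable_parameters)

SMALL = dict(widths=(8, 16, 32), input_size=(32, 32))


def _rng():
    return np.random.default_rng(0)


# ---------------------------------------------------------------------------
# ghost module
# ---------------------------------------------------------------------------

def test_ghost_module_channel_split():
    cfg = GhostModuleCfg(16, 32, ratio=2)
    assert cfg.intrinsic_channels == 16 and cfg.ghost_channels == 16
    gm = GhostModule(cfg, _rng())
    out = gm(Tensor(np.random.default_rng(1).normal(0, 1, (1, 16, 8, 8)).astype(np.float32)))
    assert out.data.shape == (1, 32, 8, 8)


def test_ghost_module_s1_reduces_to_plain_conv_layout():
    cfg = GhostModuleCfg(8, 8, ratio=1)
    assert cfg.ghost_channels == 0
    gm = GhostModule(cfg, _rng())
    assert gm.cheap is None
    out = gm(Tensor(np.zeros((1, 8, 4, 4), np.float32)))
    assert out.data.shape == (1, 8, 4, 4)


def test_ghost_module_parameter_count_symbolic():
    # (in=16, out=32, s=2, primary 1x1, cheap depthwise 3x3):
    # primary conv 16*16*1*1 + 16 bias, BN 2*16; cheap dw 16*9 + 16, BN 2*16
    expected = (16 * 16 + 16) + 2 * 16 + (16 * 9 + 16) + 2 * 16
    gm = GhostModule(GhostModuleCfg(16, 32, ratio=2), _rng())
    assert gm.num_parameters() == expected


def test_ghost_module_fewer_params_than_plain_conv():
    for cin, cout in [(16, 16), (16, 32), (32, 64)]:
        gm = GhostModule(GhostModuleCfg(cin, cout, ratio=2), _rng())
        plain = 3 * 3 * cin * cout + cout + 2 * cout  # conv3x3 + bias + BN
        assert gm.num_parameters() < plain


def test_ghost_bottleneck_shape_and_channel_mismatch():
    gb = GhostBottleneck(GhostBottleneckCfg(8, 16), _rng())
    out = gb(Tensor(np.zeros((2, 8, 8, 8), np.float32)))
    assert out.data.shape == (2, 16, 8, 8)
    with pytest.raises(ValueError):
        gb(Tensor(np.zeros((2, 4, 8, 8), np.float32)))


# ---------------------------------------------------------------------------
# residual block
# ---------------------------------------------------------------------------

def test_residual_block_identity_when_f_path_zeroed():
    rb = ResidualBlock(ResidualBlockCfg(4, 4), _rng())
    for name, p in rb.named_parameters():
        if not name.startswith("shortcut"):
            if name.endswith("bn1.weight") or name.endswith("bn2.weight"):
                p.data = np.zeros_like(p.data)  # BN scale 0 kills the F path
            elif "conv" in name:
                p.data = np.zeros_like(p.data)
    rb.eval()
    x = np.random.default_rng(2).normal(0, 1, (1, 4, 6, 6)).astype(np.float32)
    out = rb(Tensor(x))
    assert np.allclose(out.data, np.maximum(x, 0), atol=1e-6)


def test_residual_block_equals_two_branch_sum():
    rb = ResidualBlock(ResidualBlockCfg(3, 5, n_convs=1), _rng())
    rb.eval()
    x = np.random.default_rng(3).normal(0, 1, (1, 3, 6, 6)).astype(np.float32)
    out = rb(Tensor(x))
    f_path = rb.bn1(rb.conv1(Tensor(x))).data
    shortcut = rb.shortcut(Tensor(x)).data
    assert out.data.shape == (1, 5, 6, 6)
    assert np.allclose(out.data, np.maximum(f_path + shortcut, 0), atol=1e-6)


# ---------------------------------------------------------------------------
# whole nets
# ---------------------------------------------------------------------------

def test_reference_parameter_budgets():
    counts = {}
    for name in ("resunet", "unetpp", "ghost_unetpp"):
        model = build_model(ArchitectureCfg(name), seed=0)
        counts[name] = count_trainable_parameters(model)
    assert round(counts["resunet"] / 1e6, 2) == 0.81
    assert round(counts["unetpp"] / 1e6, 2) == 2.29
    assert round(counts["ghost_unetpp"] / 1e6, 2) == 0.35
    assert counts["ghost_unetpp"] < counts["resunet"] < counts["unetpp"]


def test_ghost_unetpp_has_15_bottlenecks_at_5_levels():
    model = build_model(ArchitectureCfg("ghost_unetpp"), seed=0)
    assert model.num_bottlenecks == 15  # 5+4+3+2+1


@pytest.mark.parametrize("name", nets.ARCH_NAMES)
def test_forward_shape_and_range(name):
    model = build_model(ArchitectureCfg(name, **SMALL), seed=0)
    out = model.predict(np.zeros((32, 32), np.float32))
    assert out.shape == (32, 32)
    assert np.all((out > 0) & (out < 1))


def test_forward_shape_at_other_sizes():
    model = build_model(ArchitectureCfg("ghost_unetpp", **SMALL), seed=0)
    out = model.predict(np.zeros((64, 64), np.float32))  # any multiple of 4
    assert out.shape == (64, 64)
    with pytest.raises(ValueError, match="divisible"):
        model.predict(np.zeros((30, 30), np.float32))


def test_seeded_build_bitwise_reproducible_and_eval_deterministic():
    cfg = ArchitectureCfg("ghost_unetpp", **SMALL)
    a = build_model(cfg, seed=5)
    b = build_model(cfg, seed=5)
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb and np.array_equal(pa.data, pb.data)
    c = build_model(cfg, seed=6)
    assert any(not np.array_equal(pa.data, pc.data)
               for pa, pc in zip(a.parameters(), c.parameters()))
    x = np.random.default_rng(0).normal(0, 1, (32, 32)).astype(np.float32)
    assert np.array_equal(a.predict(x), a.predict(x))


@pytest.mark.parametrize("name", nets.ARCH_NAMES)
def test_gradient_reaches_every_parameter(name):
    from bcseg.losses import dice_loss
    model = build_model(ArchitectureCfg(name, widths=(4, 8), input_size=(16, 16)), seed=3)
    model.train()
    rng = np.random.default_rng(4)
    x = Tensor(rng.normal(0, 1, (2, 1, 16, 16)).astype(np.float32))
    target = (rng.random((2, 1, 16, 16)) > 0.5).astype(np.float32)
    loss = dice_loss(model.forward(x), target)
    model.zero_grad()
    loss.backward()
    for pname, p in model.named_parameters():
        assert p.grad is not None, f"{pname} got no gradient"
        assert np.any(p.grad != 0), f"{pname} gradient identically zero"


def test_unknown_architecture_and_bad_size_rejected():
    with pytest.raises(ValueError, match="unknown architecture"):
        ArchitectureCfg("vnet")
    with pytest.raises(ValueError, match="divisible"):
        ArchitectureCfg("unetpp", widths=(8, 16, 32), input_size=(30, 30))


def test_binarize_thresholds():
    assert binarize(np.full((2, 2), 0.9)).pixels.all()
    assert not binarize(np.full((2, 2), 0.1)).pixels.any()
    assert binarize(np.full((2, 2), 0.5)).pixels.all()  # >= convention
    with pytest.raises(ValueError):
        binarize(np.zeros((2, 2)), threshold=1.5)


def test_checkpoint_round_trip(tmp_path):
    cfg = ArchitectureCfg("ghost_unet", widths=(4, 8), input_size=(16, 16))
    model = build_model(cfg, seed=9)
    x = np.random.default_rng(1).normal(0, 1, (16, 16)).astype(np.float32)
    ref = model.predict(x)
    nets.save_model(model, tmp_path / "m.npz")
    back = nets.load_model(tmp_path / "m.npz")
    assert back.cfg == cfg
    assert np.array_equal(back.predict(x), ref)
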