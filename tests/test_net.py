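"""Architecture contracts: shapes, ablation ladder, residual and AI blocks."""

import numpy as np
import pytest

import daunet.autodiff as ad
from daunet import LADDER, NetworkConfig, build_model
from daunet.net import AIModule, ResBlock


def tiny_cfg(**kw):
    base = dict(base_channels=2, patch_shape=(16, 32, 32))
    base.update(kw)
    return NetworkConfig(**base)


def test_forward_output_shapes_and_probability_range():
    model = build_model(tiny_cfg(), seed=0)
    out = model.forward(np.random.default_rng(0).random((16, 32, 32), dtype=np.float32))
    assert out.main_prob.shape == (1, 16, 32, 32)
    assert len(out.aux_probs) == 3
    for p in [out.main_prob] + out.aux_probs:
        assert p.shape == (1, 16, 32, 32)
        assert 0.0 <= p.data.min() and p.data.max() <= 1.0


def test_ds_flag_controls_auxiliary_heads():
    model = build_model(tiny_cfg(use_ds=False), seed=0)
    out = model.forward(np.zeros((16, 32, 32), dtype=np.float32))
    assert out.aux_probs == []


def test_parameter_count_deterministic_and_strictly_increasing_along_ladder():
    counts = []
    for _name, flags in LADDER:
        cfg = tiny_cfg(base_channels=4, **flags)
        counts.append(build_model(cfg, seed=0).n_parameters())
        assert build_model(cfg, seed=1).n_parameters() == counts[-1]
    # baseline -> +Res -> +AI strictly increases; +DS adds the auxiliary heads
    assert counts[0] < counts[1] < counts[2] < counts[3]


def test_invalid_patch_shape_rejected():
    with pytest.raises(ValueError, match="divisible"):
        NetworkConfig(patch_shape=(12, 32, 32))
    model = build_model(tiny_cfg(), seed=0)
    with pytest.raises(ValueError, match="patch"):
        model.forward(np.zeros((8, 32, 32), dtype=np.float32))


def test_residual_block_zero_branch_reduces_to_prelu_identity():
    rng = np.random.default_rng(0)
    blk = ResBlock(rng, 3, 3, "instance", dtype=np.float64)
    for conv in (blk.c1, blk.c2):
        conv.w.data[:] = 0.0
        conv.b.data[:] = 0.0
    x = rng.standard_normal((3, 4, 4, 4))
    out = blk(ad.Tensor(x)).data
    slope = blk.a2.a.data.reshape(3, 1, 1, 1)
    expected = np.maximum(x, 0) + slope * np.minimum(x, 0)
    assert np.allclose(out, expected)


def test_residual_block_gradient_matches_finite_differences():
    rng = np.random.default_rng(1)
    blk = ResBlock(rng, 2, 2, "instance", dtype=np.float64)
    x = ad.Tensor(rng.standard_normal((2, 4, 4, 4)), requires_grad=True)
    loss = ad.sum_all(blk(x) * blk(x))
    loss.backward()
    eps = 1e-6
    for idx in [(0, 1, 2, 3), (1, 3, 0, 2), (0, 0, 0, 0)]:
        xp, xm = x.data.copy(), x.data.copy()
        xp[idx] += eps
        xm[idx] -= eps
        lp = ad.sum_all(blk(ad.Tensor(xp)) * blk(ad.Tensor(xp))).item()
        lm = ad.sum_all(blk(ad.Tensor(xm)) * blk(ad.Tensor(xm))).item()
        assert x.grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


@pytest.mark.parametrize("dilation", [2, 4, 8])
def test_dilated_branch_preserves_spatial_shape(dilation):
    rng = np.random.default_rng(0)
    w = ad.Tensor(rng.standard_normal((2, 2, 3, 3, 3)))
    b = ad.Tensor(np.zeros(2))
    x = ad.Tensor(rng.standard_normal((2, 4, 9, 9)))
    assert ad.conv3d(x, w, b, dilation).shape == x.shape


def test_ai_module_zero_parameters_give_zero_output():
    rng = np.random.default_rng(0)
    ai = AIModule(rng, 8, dtype=np.float64)
    for layer in [ai.reduce, ai.fuse] + ai.branches:
        layer.w.data[:] = 0.0
        layer.b.data[:] = 0.0
    out = ai(ad.Tensor(rng.standard_normal((8, 2, 6, 6))))
    assert np.allclose(out.data, 0.0)
    assert out.shape == (8, 2, 6, 6)


def test_dilation8_impulse_response_spans_17_voxels_per_axis():
    w = ad.Tensor(np.ones((1, 1, 3, 3, 3)))
    b = ad.Tensor(np.zeros(1))
    imp = np.zeros((1, 33, 33, 33))
    imp[0, 16, 16, 16] = 1.0
    resp = ad.conv3d(ad.Tensor(imp), w, b, dilation=8).data[0]
    nz = np.argwhere(resp != 0)
    assert ((nz.max(axis=0) - nz.min(axis=0)) + 1 == 17).all()


def test_trunk_is_shift_covariant_on_interior_voxels():
    """Shifting the input by one full downsampling stride shifts the main
    logits identically, away from the patch borders."""
    cfg = NetworkConfig(base_channels=2, n_levels=2, use_ai=False, use_ds=False,
                        norm="none", patch_shape=(8, 96, 96))
    model = build_model(cfg, seed=0)
    rng = np.random.default_rng(1)
    x = np.zeros((8, 96, 96), dtype=np.float32)
    x[:, 30:62, 30:62] = rng.random((8, 32, 32), dtype=np.float32)
    shift = 4  # = 2**n_levels, the trunk's total stride
    y0 = model.forward(x).main_logits.data[0]
    y1 = model.forward(np.roll(x, shift, axis=1)).main_logits.data[0]
    margin = 24
    interior0 = np.roll(y0, shift, axis=1)[:, margin:-margin, :]
    interior1 = y1[:, margin:-margin, :]
    assert np.allclose(interior0, interior1, atol=1e-5)


def test_checkpoint_round_trip_reproduces_forward(tmp_path):
    from daunet.train import load_checkpoint, save_checkpoint

    model = build_model(tiny_cfg(), seed=3)
    x = np.random.default_rng(0).random((16, 32, 32), dtype=np.float32)
    ref = model.forward(x).main_prob.data
    save_checkpoint(model, tmp_path / "ck.npz")
    back = load_checkpoint(tmp_path / "ck.npz")
    assert np.array_equal(back.forward(x).main_prob.data, ref)
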