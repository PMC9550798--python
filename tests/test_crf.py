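"""Dense-CRF mean-field inference against brute-force oracles."""

import numpy as np
import pytest

from daunet import CRFParams, DenseCRF, Mask, Volume, dice, mean_field_step, refine
from daunet.crf import EXACT_VOXEL_CAP, unary_from_prob


def brute_force_message(intensity, spacing, params, v):
    """O(N^2) double loop over voxel pairs evaluating both kernels."""
    shape = intensity.shape
    coords = np.argwhere(np.ones(shape)).astype(float)
    I = intensity.ravel()
    n = I.size
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d2 = ((coords[i] - coords[j]) ** 2).sum()
            k = params.w_app * np.exp(
                -d2 / (2 * params.theta_pos_app ** 2)
                - (I[i] - I[j]) ** 2 / (2 * params.theta_int ** 2)
            ) + params.w_smooth * np.exp(-d2 / (2 * params.theta_pos_smooth ** 2))
            out[i] += k * v[j]
    return out


def test_exact_message_equals_bruteforce_double_loop():
    rng = np.random.default_rng(0)
    intensity = rng.random((5, 5, 5))
    params = CRFParams(theta_pos_app=2.0, theta_int=0.2, theta_pos_smooth=1.5, mode="exact")
    crf = DenseCRF(intensity, (1, 1, 1), params)
    v = rng.random(125)
    want = brute_force_message(intensity, (1, 1, 1), params, v)
    assert np.allclose(crf.kernel_apply(v), want, atol=1e-10)


def test_zero_pairwise_weights_reduce_to_unary_argmax():
    rng = np.random.default_rng(1)
    prob = rng.random((6, 6, 6))
    intensity = rng.random((6, 6, 6))
    params = CRFParams(w_app=0.0, w_smooth=0.0, n_iters=3, mode="exact")
    out = refine(Volume(prob, (1, 1, 1)), Volume(intensity, (1, 1, 1)), params)
    assert np.array_equal(out.data.astype(bool), prob > 0.5)


def test_zero_weight_step_is_unary_softmax_independent_of_q():
    rng = np.random.default_rng(2)
    params = CRFParams(w_app=0.0, w_smooth=0.0, mode="exact")
    crf = DenseCRF(rng.random((4, 4, 4)), (1, 1, 1), params)
    unary = rng.random((64, 2))
    expected = np.exp(-unary) / np.exp(-unary).sum(axis=1, keepdims=True)
    for q_seed in (0, 1):
        q = np.random.default_rng(q_seed).dirichlet((1, 1), size=64)
        out = mean_field_step(q, unary, crf)
        assert np.allclose(out, expected, atol=1e-12)


def test_step_rows_stay_normalized_and_reject_unnormalized_input():
    rng = np.random.default_rng(3)
    crf = DenseCRF(rng.random((4, 4, 4)), (1, 1, 1), CRFParams(mode="exact"))
    unary = rng.random((64, 2))
    q = np.random.default_rng(0).dirichlet((1, 1), size=64)
    out = mean_field_step(q, unary, crf)
    assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
    with pytest.raises(ValueError, match="normalized"):
        mean_field_step(q * 1.5, unary, crf)


def test_flipped_voxel_in_homogeneous_region_is_restored():
    """A single wrong-label voxel inside a uniform 6^3 block must snap back
    to the majority label under the smoothness kernel."""
    prob = np.full((6, 6, 6), 0.9)
    prob[3, 3, 3] = 0.1  # the flipped voxel
    intensity = np.full((6, 6, 6), 0.5)
    params = CRFParams(w_app=0.0, w_smooth=1.0, theta_pos_smooth=1.5, n_iters=3, mode="exact")
    out = refine(Volume(prob, (1, 1, 1)), Volume(intensity, (1, 1, 1)), params)
    assert out.data.all()


def test_uniform_half_probability_ties_break_to_background():
    prob = np.full((5, 5, 5), 0.5)
    intensity = np.full((5, 5, 5), 0.3)
    out = refine(Volume(prob, (1, 1, 1)), Volume(intensity, (1, 1, 1)),
                 CRFParams(n_iters=2, mode="exact"))
    assert not out.data.any()


@pytest.mark.parametrize("seed", range(20))
def test_exact_and_approximate_modes_agree_on_small_rois(seed):
    """Label agreement at ROI-proportionate bandwidths, phantom-like
    instances (structured intensity, informative unaries)."""
    from daunet import PhantomSpec, clip_hu, generate_phantom, normalize01

    rng = np.random.default_rng(seed)
    spec = PhantomSpec(grid_shape=(12, 12, 12), spacing_mm=(1, 1, 1),
                       organ_center=(5.5, 5.5, 5.5), organ_radii=(4.0, 4.0, 4.0),
                       n_lobes=1, neighbor_offset=None, noise_sd=10.0, seed=seed)
    vol, mask = generate_phantom(spec)
    intensity = normalize01(clip_hu(vol)).data
    gt = mask.data.astype(float)
    prob = gt * 0.9 + 0.05
    flip = rng.random(gt.shape) < 0.05
    prob = np.where(flip, 1.0 - prob, prob)
    unary = unary_from_prob(prob)
    kw = dict(theta_pos_app=3.0, theta_pos_smooth=1.5, n_iters=5)
    q_exact = DenseCRF(intensity, (1, 1, 1), CRFParams(mode="exact", **kw)).run(unary)
    q_approx = DenseCRF(intensity, (1, 1, 1), CRFParams(mode="approximate", **kw)).run(unary)
    labels_exact = q_exact[:, 1] > q_exact[:, 0]
    labels_approx = q_approx[:, 1] > q_approx[:, 0]
    assert (labels_exact == labels_approx).all()


def test_exact_mode_refuses_large_rois():
    side = int(np.ceil(EXACT_VOXEL_CAP ** (1 / 3))) + 1
    with pytest.raises(ValueError, match="cap"):
        DenseCRF(np.zeros((side, side, side)), (1, 1, 1), CRFParams(mode="exact"))


def test_refine_validates_grids_and_probability_range():
    prob = Volume(np.full((4, 4, 4), 0.5), (1, 1, 1))
    with pytest.raises(ValueError, match="mismatch"):
        refine(prob, Volume(np.zeros((4, 4, 5)), (1, 1, 1)))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        refine(Volume(np.full((4, 4, 4), 1.2), (1, 1, 1)),
               Volume(np.zeros((4, 4, 4)), (1, 1, 1)))
    out = refine(prob, Volume(np.random.default_rng(0).random((4, 4, 4)), (1, 1, 1)),
                 CRFParams(n_iters=1, mode="exact"))
    assert out.shape == prob.shape and out.spacing_mm == prob.spacing_mm
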