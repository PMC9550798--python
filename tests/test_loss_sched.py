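"""Tversky loss algebra, deep-supervision combination, and schedules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import daunet.autodiff as ad
from daunet import DSState, TverskyParams, dice_loss, ds_loss, lr_at_epoch, tversky_loss, update_ds_alpha


def test_hand_evaluated_example():
    # p=(1,1,0,0), g=(1,0,1,0): TP=1, FP=1, FN=1 -> 1 - 1/(1 + 0.4 + 0.6)
    p = np.array([1.0, 1.0, 0.0, 0.0]).reshape(1, 2, 2)
    g = np.array([1.0, 0.0, 1.0, 0.0]).reshape(1, 2, 2)
    params = TverskyParams(alpha=0.4, beta=0.6, squared_penalties=False, smooth=0.0)
    assert tversky_loss(p, g, params) == pytest.approx(0.5)


def test_perfect_and_disjoint_predictions():
    rng = np.random.default_rng(0)
    g = (rng.random((4, 4, 4)) > 0.5).astype(float)
    assert tversky_loss(g, g) == pytest.approx(0.0, abs=1e-5)
    assert tversky_loss(1.0 - g, g) == pytest.approx(1.0, abs=1e-5)


@pytest.mark.parametrize("squared", [False, True])
def test_binary_predictions_make_squared_and_linear_forms_agree(squared):
    rng = np.random.default_rng(1)
    p = (rng.random((5, 5, 5)) > 0.4).astype(float)
    g = (rng.random((5, 5, 5)) > 0.6).astype(float)
    half = TverskyParams(alpha=0.5, beta=0.5, squared_penalties=squared)
    assert tversky_loss(p, g, half) == pytest.approx(dice_loss(p, g), abs=1e-6)


def test_soft_predictions_dice_equivalence_holds_for_linear_form_only():
    rng = np.random.default_rng(2)
    p = rng.random((6, 6, 6))
    g = (rng.random((6, 6, 6)) > 0.5).astype(float)
    half_lin = TverskyParams(alpha=0.5, beta=0.5, squared_penalties=False)
    assert tversky_loss(p, g, half_lin) == pytest.approx(dice_loss(p, g), abs=1e-6)
    half_sq = TverskyParams(alpha=0.5, beta=0.5, squared_penalties=True)
    assert abs(tversky_loss(p, g, half_sq) - dice_loss(p, g)) > 1e-3


def test_empty_target_patch_is_well_defined():
    p = np.full((3, 3, 3), 0.2)
    g = np.zeros((3, 3, 3))
    loss = tversky_loss(p, g)
    assert 0.0 <= loss <= 1.0


def _unconstrained_params(alpha, beta):
    """Build params without the alpha+beta=1 guard, to vary one weight
    while the other is held fixed."""
    p = object.__new__(TverskyParams)
    p.alpha, p.beta = alpha, beta
    p.squared_penalties = True
    p.smooth = 1e-6
    return p


def test_alpha_monotonicity_with_false_positive_mass():
    """With beta and the prediction fixed, a larger FP weight strictly
    increases the loss whenever FP mass is nonzero."""
    rng = np.random.default_rng(3)
    p = rng.random((4, 4, 4))
    g = (rng.random((4, 4, 4)) > 0.5).astype(float)
    assert ((p * (1 - g)) > 0).any()  # nonzero FP mass
    losses = [
        tversky_loss(p, g, _unconstrained_params(a, 0.6)) for a in (0.2, 0.4, 0.6, 0.8)
    ]
    assert all(l1 < l2 for l1, l2 in zip(losses, losses[1:]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), alpha=st.floats(0.05, 0.95), squared=st.booleans())
def test_loss_always_within_unit_interval(seed, alpha, squared):
    rng = np.random.default_rng(seed)
    p = rng.random((3, 4, 5))
    g = (rng.random((3, 4, 5)) > rng.random()).astype(float)
    params = TverskyParams(alpha=alpha, beta=1 - alpha, squared_penalties=squared)
    assert 0.0 <= tversky_loss(p, g, params) <= 1.0


@pytest.mark.parametrize("squared", [False, True])
def test_gradient_matches_central_finite_differences(squared):
    rng = np.random.default_rng(4)
    params = TverskyParams(squared_penalties=squared)
    p = ad.Tensor(rng.random((4, 4, 4)), requires_grad=True)
    g = (rng.random((4, 4, 4)) > 0.5).astype(float)
    tversky_loss(p, g, params).backward()
    eps = 1e-6
    for idx in [(0, 1, 2), (3, 3, 3), (2, 0, 1)]:
        pp, pm = p.data.copy(), p.data.copy()
        pp[idx] += eps
        pm[idx] -= eps
        num = (tversky_loss(pp, g, params) - tversky_loss(pm, g, params)) / (2 * eps)
        assert p.grad[idx] == pytest.approx(num, abs=1e-4)


def test_invalid_params_and_inputs_rejected():
    with pytest.raises(ValueError):
        TverskyParams(alpha=0.3, beta=0.6)
    with pytest.raises(ValueError):
        TverskyParams(alpha=0.0, beta=1.0)
    with pytest.raises(ValueError, match="shape"):
        tversky_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        tversky_loss(np.full((2, 2, 2), 1.5), np.ones((2, 2, 2)))


def test_ds_loss_arithmetic_and_count_contract():
    assert ds_loss(0.2, (0.3, 0.3, 0.4), 1.0) == pytest.approx(1.2)
    assert ds_loss(0.1, (0.1, 0.1, 0.1), 0.8) == pytest.approx(0.34)
    assert ds_loss(0.7, (0.3, 0.3, 0.4), 0.0) == pytest.approx(0.7)
    assert ds_loss(0.5, [], 1.0, use_ds=False) == 0.5
    with pytest.raises(ValueError, match="3 auxiliary"):
        ds_loss(0.5, (0.1, 0.2), 1.0)
    with pytest.raises(ValueError):
        ds_loss(0.5, (0.1,), 1.0, use_ds=False)


@pytest.mark.parametrize(
    "epoch,expected", [(0, 1.0), (39, 1.0), (40, 0.8), (79, 0.8), (80, 0.64), (120, 0.512)]
)
def test_ds_alpha_decay_schedule(epoch, expected):
    state = update_ds_alpha(DSState(), epoch)
    assert state.ds_alpha == pytest.approx(expected)
    # stateless: re-applying at the same epoch changes nothing
    assert update_ds_alpha(state, epoch).ds_alpha == pytest.approx(expected)


@pytest.mark.parametrize(
    "epoch,expected", [(0, 1e-3), (349, 1e-3), (350, 1e-4), (649, 1e-4), (650, 1e-5), (700, 1e-5)]
)
def test_learning_rate_milestones(epoch, expected):
    assert lr_at_epoch(epoch) == pytest.approx(expected)
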