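"""Recursive activation filter and nonlinear shaping function."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anklemech.activation import (ActivationParams, activation_from_excitation,
                                  activation_nonlinearity, neural_activation)

RATE = 100.0


def test_identity_when_recursion_constants_zero():
    p = ActivationParams(c1=0.0, c2=0.0, shape_factor=-1.0, delay_s=0.0)
    e = np.linspace(0, 1, 50)
    assert np.allclose(neural_activation(e, p, RATE), e)


def test_hand_recursion_unit_step():
    # C1 = C2 = -0.5: beta1 = -1, beta2 = 0.25, alpha = 0.25
    p = ActivationParams(c1=-0.5, c2=-0.5, shape_factor=-1.0, delay_s=0.0)
    assert p.beta1 == -1.0 and p.beta2 == 0.25 and p.alpha == 0.25
    u = neural_activation(np.ones(10), p, RATE)
    assert u[0] == pytest.approx(0.25)
    assert u[1] == pytest.approx(0.5)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(c1=st.floats(-0.9, 0.9), c2=st.floats(-0.9, 0.9))
def test_unit_dc_gain_for_all_admissible_constants(c1, c2):
    """A sustained unit excitation drives u to 1: alpha/(1+b1+b2) = 1."""
    p = ActivationParams(c1=c1, c2=c2, shape_factor=-1.0, delay_s=0.0)
    u = neural_activation(np.ones(2000), p, RATE)
    assert u[-1] == pytest.approx(1.0, abs=1e-6)


def test_delay_is_whole_sample_shift_with_zero_fill():
    p = ActivationParams(c1=0.0, c2=0.0, shape_factor=-1.0, delay_s=0.040)
    e = np.zeros(20)
    e[0] = 1.0
    u = neural_activation(e, p, RATE)
    assert np.all(u[:4] == 0.0)
    assert u[4] == pytest.approx(1.0)


def test_impulse_response_decays_geometrically():
    p = ActivationParams(c1=0.6, c2=0.3, shape_factor=-1.0, delay_s=0.0)
    e = np.zeros(80)
    e[0] = 1.0
    u = neural_activation(e, p, RATE)
    rho = max(abs(p.c1), abs(p.c2))
    assert abs(u[60]) < 10 * rho**60


def test_unstable_constants_rejected():
    with pytest.raises(ValueError, match="unstable"):
        ActivationParams(c1=0.2, c2=1.2, shape_factor=-1.0)


@pytest.mark.parametrize("shape", [-3.0, -1.5, -0.2])
def test_nonlinearity_endpoints(shape):
    a = activation_nonlinearity(np.array([0.0, 1.0]), shape)
    assert a[0] == pytest.approx(0.0)
    assert a[1] == pytest.approx(1.0)


def test_nonlinearity_reference_value():
    # (e^{-1.5} - 1)/(e^{-3} - 1), direct evaluation
    a = activation_nonlinearity(np.array([0.5]), -3.0)
    assert a[0] == pytest.approx(0.8176, abs=1e-4)


def test_nonlinearity_linear_limit():
    u = np.linspace(0, 1, 11)
    assert np.allclose(activation_nonlinearity(u, -1e-9), u)


def test_nonlinearity_monotone_and_bounded():
    u = np.linspace(0, 1, 101)
    a = activation_nonlinearity(u, -2.5)
    assert np.all(np.diff(a) > 0)
    assert a.min() >= 0.0 and a.max() <= 1.0


@pytest.mark.parametrize("shape", [0.5, -3.5])
def test_nonlinearity_out_of_range_shape_rejected(shape):
    with pytest.raises(ValueError):
        activation_nonlinearity(np.array([0.5]), shape)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(c1=st.floats(-0.8, 0.8), c2=st.floats(-0.8, 0.8),
      shape=st.floats(-3.0, -0.01))
def test_composition_preserves_unit_interval(c1, c2, shape):
    p = ActivationParams(c1=c1, c2=c2, shape_factor=shape, delay_s=0.0)
    rng = np.random.default_rng(0)
    e = rng.random(300)
    a = activation_from_excitation(e, p, RATE)
    assert np.all(a >= 0.0) and np.all(a <= 1.0)


def test_excitation_outside_unit_interval_rejected():
    p = ActivationParams(c1=0.1, c2=0.1, shape_factor=-1.0)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        neural_activation(np.array([0.5, 1.5]), p, RATE)
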