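"""Synthetic gait generator: determinism, self-consistency, surface effects."""

import numpy as np
import pytest

import anklemech as am
from anklemech.synth import Burst, excitation_curve


def _trials_equal(a, b):
    assert a.condition == b.condition
    np.testing.assert_array_equal(a.theta, b.theta)
    np.testing.assert_array_equal(a.tau_id, b.tau_id)
    for m in am.MUSCLES:
        np.testing.assert_array_equal(a.emg[m], b.emg[m])


def test_trial_determinism_bit_identical():
    truth = am.default_truth(seed=42)
    _trials_equal(am.generate_trial(truth, "eva", 2),
                  am.generate_trial(truth, "eva", 2))


def test_zero_noise_trial_is_self_consistent(truth0, trial0):
    """tau_ID of a zero-noise trial equals the forward chain at truth params."""
    fwd = am.forward_simulate(trial0.emg, trial0.theta, trial0.rate,
                              truth0.model, truth0.geometry,
                              with_stiffness=False)
    assert am.nrmse(fwd.moment, trial0.tau_id) < 1e-6


def test_excitations_bounded(truth0):
    for cond in truth0.conditions:
        t = am.generate_trial(truth0, cond, 0)
        for m, e in t.emg.items():
            assert e.min() >= 0.0 and e.max() <= 1.0, m


def test_surface_effect_raises_midstance_plantarflexion(truth0, stance_pct):
    """+10% plantar-flexor drive strengthens the (negative) mid-stance moment
    at every node; excitation -> activation -> force -> moment is monotone."""
    base = am.generate_trial(truth0, "rigid", 0)
    soft = am.generate_trial(truth0, "epe", 0)
    mid = (stance_pct >= 40) & (stance_pct <= 60)
    assert np.all(-soft.tau_id[mid] > -base.tau_id[mid])


def test_unknown_condition_rejected(truth0):
    with pytest.raises(ValueError, match="unknown surface condition"):
        am.generate_trial(truth0, "ice", 0)


def test_truth_outside_calibration_bounds_rejected():
    base = am.default_truth(seed=0)
    with pytest.raises(ValueError, match="bounds"):
        am.SyntheticTruth(
            model=base.model.replace(gamma_pf=1.6),
            geometry=base.geometry, bursts=base.bursts,
            surface_effects=base.surface_effects, seed=0)


def test_dataset_shape_and_labels():
    truth = am.default_truth(seed=5)
    trials = am.generate_dataset(truth, n_subjects=10, trials_per_condition=4)
    assert len(trials) == 160
    labels = {(t.subject, t.condition, t.trial) for t in trials}
    assert len(labels) == 160
    subjects = {t.subject for t in trials}
    for s in subjects:
        for c in truth.conditions:
            assert sum(1 for t in trials
                       if t.subject == s and t.condition == c) == 4


def test_dataset_determinism():
    truth = am.default_truth(seed=9)
    d1 = am.generate_dataset(truth, 2, 2)
    d2 = am.generate_dataset(truth, 2, 2)
    for a, b in zip(d1, d2):
        _trials_equal(a, b)


def test_zero_jitter_makes_subjects_identical():
    truth = am.default_truth(seed=3, noise_sd=0.0)
    trials = am.generate_dataset(truth, n_subjects=3, trials_per_condition=1,
                                 subject_jitter=0.0)
    ref = [t for t in trials if t.subject == 0]
    for s in (1, 2):
        for t, r in zip([t for t in trials if t.subject == s], ref):
            np.testing.assert_array_equal(t.tau_id, r.tau_id)


def test_nonpositive_counts_rejected(truth0):
    with pytest.raises(ValueError):
        am.generate_dataset(truth0, 0, 4)
    with pytest.raises(ValueError):
        am.generate_dataset(truth0, 2, 0)


def test_burst_validation():
    with pytest.raises(ValueError):
        Burst(50.0, -1.0, 0.5)
    with pytest.raises(ValueError):
        Burst(50.0, 10.0, 1.5)


def test_excitation_curve_clipped():
    pct = np.linspace(0, 100, 101)
    e = excitation_curve(pct, [Burst(50.0, 10.0, 0.9), Burst(52.0, 10.0, 0.9)])
    assert e.max() <= 1.0 and e.min() >= 0.0


def test_angle_within_geometry_validity(truth0):
    t = am.generate_trial(truth0, "rigid", 0)
    lo, hi = truth0.geometry.theta_range
    assert t.theta.min() >= lo and t.theta.max() <= hi
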