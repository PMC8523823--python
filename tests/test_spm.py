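"""1D repeated-measures ANOVA F-fields and permutation inference."""

import numpy as np
import pytest

from anklemech.spm import (CurveDataset, effect_size_f, f_field,
                           permutation_inference)


def _dataset(rng, s=8, c=4, n=20, cond_effect=None, subject_sd=1.0,
             noise_sd=0.5):
    y = rng.standard_normal((s, c, n)) * noise_sd
    y += subject_sd * rng.standard_normal((s, 1, 1))
    if cond_effect is not None:
        y += np.asarray(cond_effect)[None, :, None]
    return CurveDataset(y, list(range(s)), [f"c{i}" for i in range(c)])


def test_identical_conditions_give_zero_field(rng):
    base = rng.standard_normal((6, 1, 15))
    y = np.repeat(base, 4, axis=1)
    ds = CurveDataset(y, list(range(6)), list("abcd"))
    assert np.allclose(f_field(ds), 0.0)


def test_f_matches_textbook_rm_anova_per_node(rng):
    """Pointwise oracle: statsmodels AnovaRM on each node's table."""
    import pandas as pd
    from statsmodels.stats.anova import AnovaRM

    ds = _dataset(rng, s=7, c=3, n=4, cond_effect=[0.0, 0.3, 0.6])
    f = f_field(ds)
    for node in range(4):
        rows = [{"subject": s, "cond": c, "y": ds.curves[s, c, node]}
                for s in range(7) for c in range(3)]
        res = AnovaRM(pd.DataFrame(rows), "y", "subject", within=["cond"]).fit()
        expected = float(res.anova_table["F Value"].iloc[0])
        assert f[node] == pytest.approx(expected, rel=1e-8)


def test_f_invariant_to_subject_offsets_and_relabeling(rng):
    ds = _dataset(rng, cond_effect=[0, 0.2, 0.4, 0.6])
    f0 = f_field(ds)
    shifted = CurveDataset(
        ds.curves + rng.standard_normal((8, 1, 1)) * 5.0,
        ds.subjects, ds.conditions)
    assert np.allclose(f_field(shifted), f0, atol=1e-8)
    perm = rng.permutation(8)
    relabeled = CurveDataset(ds.curves[perm], ds.subjects, ds.conditions)
    assert np.allclose(f_field(relabeled), f0, atol=1e-10)


def test_small_designs_rejected(rng):
    with pytest.raises(ValueError):
        f_field(_dataset(rng, s=1, c=4))
    with pytest.raises(ValueError):
        f_field(_dataset(rng, s=5, c=1))


def test_incomplete_design_rejected(rng):
    curves = [rng.standard_normal(10) for _ in range(3)]
    with pytest.raises(ValueError, match="incomplete"):
        CurveDataset.from_trials(curves, [0, 0, 1], ["a", "b", "a"])


def test_trial_averaging(rng):
    c1, c2 = rng.standard_normal((2, 5))
    ds = CurveDataset.from_trials([c1, c2, c1, c2], [0, 0, 1, 1],
                                  ["a", "a", "a", "a"])
    assert np.allclose(ds.curves[0, 0], (c1 + c2) / 2)


def test_inference_deterministic_given_seed(rng):
    ds = _dataset(rng, cond_effect=[0, 0.1, 0.2, 0.8])
    r1 = permutation_inference(ds, n_perm=300, seed=5)
    r2 = permutation_inference(ds, n_perm=300, seed=5)
    assert r1.threshold == r2.threshold
    assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]


def test_threshold_decreases_as_alpha_increases(rng):
    ds = _dataset(rng)
    thresholds = [permutation_inference(ds, alpha=a, n_perm=300, seed=1).threshold
                  for a in (0.01, 0.05, 0.20)]
    assert thresholds[0] >= thresholds[1] >= thresholds[2]


def test_exhaustive_enumeration_is_seed_independent(rng):
    ds = _dataset(rng, s=3, c=2, cond_effect=[0.0, 1.0])
    r1 = permutation_inference(ds, n_perm=1000, seed=1)
    r2 = permutation_inference(ds, n_perm=1000, seed=99)
    assert r1.exhaustive and r2.exhaustive
    assert r1.n_perm == 8  # (2!)^3
    assert r1.threshold == r2.threshold
    assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]


def test_whole_curve_offset_detected_as_wide_cluster(rng):
    """A strong constant offset in one condition -> one near-full-width
    significant cluster."""
    ds = _dataset(rng, s=10, c=4, n=101, cond_effect=[0, 0, 0, 3.0],
                  noise_sd=0.4)
    res = permutation_inference(ds, n_perm=300, seed=2)
    sig = res.significant_clusters()
    assert sig
    widest = max(sig, key=lambda c: c.extent)
    assert widest.extent >= 0.9 * 101
    assert widest.p_value < 0.05


def test_n_perm_floor():
    y = np.zeros((4, 3, 5))
    ds = CurveDataset(y, list(range(4)), list("abc"))
    with pytest.raises(ValueError):
        permutation_inference(ds, n_perm=50)


def test_effect_size_zero_for_identical_conditions(rng):
    base = rng.standard_normal((6, 1, 10))
    ds = CurveDataset(np.repeat(base, 3, axis=1), list(range(6)), list("abc"))
    assert effect_size_f(ds, (0.0, 100.0)) == 0.0


def test_effect_size_two_group_identity():
    """Means one within-cell SD apart -> f = 0.5, exactly, using +-1
    residual patterns with zero mean and unit mean square."""
    s = 8
    sigma, d = 0.7, 0.7
    u = np.tile([1.0, -1.0], s // 2)
    w = np.tile([-1.0, 1.0], s // 2)
    y = np.zeros((s, 2, 3))
    y[:, 0, :] = (sigma * u)[:, None]
    y[:, 1, :] = d + (sigma * w)[:, None]
    ds = CurveDataset(y, list(range(s)), list("ab"))
    assert effect_size_f(ds, (0.0, 100.0)) == pytest.approx(0.5, abs=1e-12)


def test_effect_size_invariant_to_global_constant(rng):
    ds = _dataset(rng, cond_effect=[0, 0.5, 1.0, 1.5])
    f1 = effect_size_f(ds, (10.0, 60.0))
    shifted = CurveDataset(ds.curves + 42.0, ds.subjects, ds.conditions)
    assert effect_size_f(shifted, (10.0, 60.0)) == pytest.approx(f1)


def test_effect_size_empty_window_rejected(rng):
    with pytest.raises(ValueError, match="empty"):
        effect_size_f(_dataset(rng), (200.0, 300.0))
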