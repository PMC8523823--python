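"""Curve-level statistics: 1D repeated-measures ANOVA with permutation
inference.

Stance-phase curves (moment, stiffness, GRF, excitation) are compared across
surface conditions with a one-way repeated-measures ANOVA F statistic
computed independently at every node of the 101-point stance grid, giving an
F-field over the curve.  Field-level inference uses a permutation null
rather than random-field theory: condition labels are permuted within each
subject, the (1 - alpha) quantile of the permuted field-maximum distribution
sets the critical threshold, and suprathreshold clusters receive p-values
from the permuted distribution of maximum cluster extent.  The permutation
null is exact under within-subject exchangeability and needs no sphericity
correction (none is applied; results are flagged accordingly).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CurveDataset",
    "Cluster",
    "SpmResult",
    "f_field",
    "permutation_inference",
    "effect_size_f",
]

log = logging.getLogger(__name__)


@dataclass
class CurveDataset:
    """Subject x condition curve array on a common stance grid.

    ``curves`` has shape (n_subjects, n_conditions, n_nodes): one mean curve
    per subject-condition (trials averaged beforehand — the subject is the
    repeated-measures unit of analysis).
    """

    curves: np.ndarray
    subjects: list
    conditions: list[str]
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim != 3:
            raise ValueError("curves must be (subjects, conditions, nodes)")
        s, c, n = self.curves.shape
        if s != len(self.subjects) or c != len(self.conditions):
            raise ValueError("label lengths do not match the curve array")
        if not np.all(np.isfinite(self.curves)):
            raise ValueError("incomplete design: curves contain non-finite values")
        if self.grid is None:
            self.grid = np.linspace(0.0, 100.0, n)

    @classmethod
    def from_trials(
        cls,
        curves: Sequence[np.ndarray],
        subjects: Sequence,
        conditions: Sequence[str],
    ) -> "CurveDataset":
        """Build a complete-design dataset from per-trial curves by averaging
        trials within each subject-condition cell."""
        curves = [np.asarray(c, float) for c in curves]
        subj_ids = sorted(set(subjects))
        cond_ids = list(dict.fromkeys(conditions))
        n_nodes = curves[0].size
        acc = np.zeros((len(subj_ids), len(cond_ids), n_nodes))
        cnt = np.zeros((len(subj_ids), len(cond_ids)))
        for curve, s, c in zip(curves, subjects, conditions):
            i, j = subj_ids.index(s), cond_ids.index(c)
            acc[i, j] += curve
            cnt[i, j] += 1
        if np.any(cnt == 0):
            raise ValueError("incomplete design: some subject lacks a condition")
        return cls(acc / cnt[:, :, None], subj_ids, cond_ids)


@dataclass
class Cluster:
    """A maximal contiguous suprathreshold run of the F-field.

    ``p_value`` is the familywise cluster p: the smaller of the
    field-maximum rank p (exactly calibrated) and the suprathreshold
    cluster-extent rank p (powerful for wide, flat effects); both
    components are kept for inspection.
    """

    start_pct: float
    end_pct: float
    extent: int          # nodes
    max_f: float
    p_value: float
    p_height: float = float("nan")
    p_extent: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class SpmResult:
    f: np.ndarray
    threshold: float
    clusters: list[Cluster]
    alpha: float
    n_perm: int
    seed: int
    exhaustive: bool = False
    sphericity_corrected: bool = False
    meta: dict = field(default_factory=dict)

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]


def _f_from_curves(y: np.ndarray) -> np.ndarray:
    """Node-wise one-way RM-ANOVA F for y of shape (S, C, N)."""
    s, c, _ = y.shape
    grand = y.mean(axis=(0, 1), keepdims=True)
    subj = y.mean(axis=1, keepdims=True)
    cond = y.mean(axis=0, keepdims=True)
    ss_cond = s * np.sum((cond - grand) ** 2, axis=(0, 1))
    resid = y - subj - cond + grand
    ss_err = np.sum(resid**2, axis=(0, 1))
    # sums of squares at round-off level are zero for inference purposes
    ss_tot = np.sum((y - grand) ** 2, axis=(0, 1))
    tol = 1e-12 * np.maximum(ss_tot, np.finfo(float).tiny)
    cond_zero = ss_cond <= tol
    err_zero = ss_err <= tol
    ms_cond = ss_cond / (c - 1)
    ms_err = ss_err / ((c - 1) * (s - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_cond / ms_err
    # zero interaction variance: F -> +inf (flagged by the caller via isinf)
    f = np.where(err_zero, np.where(cond_zero, 0.0, np.inf), f)
    return np.where(cond_zero & ~err_zero, 0.0, f)


def f_field(data: CurveDataset) -> np.ndarray:
    """One-way repeated-measures ANOVA F statistic at every grid node.

    The F at a node is condition mean square over condition-by-subject
    interaction mean square for that node's subject x condition table; the
    subject main effect is removed by design, so per-subject constant offsets
    leave the field unchanged.  Nodes with zero interaction variance report
    +inf (or 0 when the condition variance is also zero).
    """
    s, c, _ = data.curves.shape
    if s < 2 or c < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    return _f_from_curves(data.curves)


def _clusters_above(f: np.ndarray, threshold: float,
                    grid: np.ndarray) -> list[tuple[int, int]]:
    above = f > threshold
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    return runs


def _within_subject_permutations(
    s: int, c: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Index array (n_perm, S, C) permuting condition labels per subject.

    When the number of distinct within-subject label permutations
    (C!)**S does not exceed ``n_perm``, the full set is enumerated instead
    of sampled and inference becomes exact and seed-independent.
    """
    total = math.factorial(c) ** s
    if total <= n_perm:
        log.info("enumerating all %d within-subject permutations", total)
        perms = list(itertools.permutations(range(c)))
        combos = itertools.product(perms, repeat=s)
        idx = np.array([list(combo) for combo in combos])
        return idx, True
    idx = np.empty((n_perm, s, c), dtype=int)
    for i in range(n_perm):
        for j in range(s):
            idx[i, j] = rng.permutation(c)
    return idx, False


def permutation_inference(
    data: CurveDataset,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> SpmResult:
    """Suprathreshold-cluster inference on the F-field via permutation.

    The null distribution permutes condition labels independently within each
    subject.  The critical threshold is the (1 - alpha) quantile of the
    permuted field-maximum distribution; observed clusters are the maximal
    runs above it.  Each cluster's familywise p-value is the smaller of two
    rank tests against the permutation distributions (each with the +1
    finite-sample correction): the field-maximum height test, which is
    exactly calibrated under within-subject exchangeability, and the
    maximum-cluster-extent test, which adds power for wide flat effects but
    is conservative on its own.  Deterministic given ``seed``; switches to
    exhaustive enumeration when the permutation group is small enough.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for stable tail quantiles")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    y = data.curves
    s, c, n = y.shape
    f_obs = f_field(data)

    rng = np.random.default_rng(seed)
    idx, exhaustive = _within_subject_permutations(s, c, n_perm, rng)
    rows = np.arange(s)[:, None]

    max_f = np.empty(len(idx))
    fields = np.empty((len(idx), n))
    for i, perm in enumerate(idx):
        fields[i] = _f_from_curves(y[rows, perm, :])
        max_f[i] = fields[i].max()

    threshold = float(np.quantile(max_f, 1.0 - alpha))

    # permutation distribution of the maximum cluster extent above threshold
    max_extent = np.zeros(len(idx), dtype=int)
    for i in range(len(idx)):
        runs = _clusters_above(fields[i], threshold, data.grid)
        if runs:
            max_extent[i] = max(b - a + 1 for a, b in runs)

    clusters = []
    for a, b in _clusters_above(f_obs, threshold, data.grid):
        extent = b - a + 1
        height = float(np.max(f_obs[a: b + 1]))
        p_ext = (1.0 + np.sum(max_extent >= extent)) / (len(idx) + 1.0)
        p_hgt = (1.0 + np.sum(max_f >= height)) / (len(idx) + 1.0)
        clusters.append(Cluster(
            start_pct=float(data.grid[a]),
            end_pct=float(data.grid[b]),
            extent=extent,
            max_f=height,
            p_value=float(min(p_hgt, p_ext)),
            p_height=float(p_hgt),
            p_extent=float(p_ext),
        ))

    return SpmResult(
        f=f_obs, threshold=threshold, clusters=clusters, alpha=alpha,
        n_perm=len(idx), seed=seed, exhaustive=exhaustive,
    )


def effect_size_f(data: CurveDataset, window: tuple[float, float]) -> float:
    """Cohen's f over a stance-% window, from the ANOVA sums of squares.

    At each node f = sqrt(SS_condition / SS_error) with SS_error the total
    within-condition sum of squares (subject plus subject-by-condition
    variability), which reduces to the classical two-group identity
    f = d/2 for two conditions whose means differ by d within-cell standard
    deviations.  The windowed mean of the node values is reported (the
    conventional single-number summary over a significant region); invariant
    to adding a global constant to every curve.
    """
    lo, hi = window
    mask = (data.grid >= lo) & (data.grid <= hi)
    if not np.any(mask):
        raise ValueError(f"empty stance-% window {window}")
    y = data.curves[:, :, mask]
    s, c, _ = y.shape
    grand = y.mean(axis=(0, 1), keepdims=True)
    cond = y.mean(axis=0, keepdims=True)
    ss_cond = s * np.sum((cond - grand) ** 2, axis=(0, 1))
    ss_err = np.sum((y - cond) ** 2, axis=(0, 1))
    ss_tot = np.sum((y - grand) ** 2, axis=(0, 1))
    tol = 1e-12 * np.maximum(ss_tot, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_nodes = np.sqrt(np.where(ss_err > tol, ss_cond / ss_err, 0.0))
    f_nodes = np.where(ss_cond <= tol, 0.0, f_nodes)
    return float(np.mean(f_nodes))
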