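# Methods

This note records the modelling choices behind `anklemech`: the assumptions
of each pipeline stage, the defaults and why they were chosen, what the
synthetic data do and do not emulate, and the numerical details that matter
when reproducing results.

## Pipeline overview

Four superficial ankle muscles are modelled — tibialis anterior (TA, the
dorsiflexor) and the plantar flexors soleus (SOL), lateral (GAL) and medial
(GAM) gastrocnemius. Per trial the chain is: excitation → recursive
activation dynamics → angle-dependent MTU geometry → Hill-type fiber/tendon
equilibrium → joint moment and rotational stiffness → 101-node stance-
percent curves. Calibration wraps the chain in a bounded optimizer; curve
statistics compare conditions across subjects.

Sign conventions: ankle angle, moment and the TA moment arm are
dorsiflexion-positive; plantar-flexor arms are negative. All forces are
tensile (≥ 0).

## Activation dynamics

The recursive filter u(t) = α e(t−d) − β₁u(t−1) − β₂u(t−2) has poles −C₁,
−C₂; the constraint α = 1 + β₁ + β₂ pins its DC gain at exactly 1, so a
sustained excitation of 1 saturates neural activation at 1. Stability
requires both constants strictly inside (−1, 1); descriptions of this
filter sometimes print a looser bound on C₂, but any |C₂| ≥ 1 makes the
recursion diverge and also falls outside the calibration box, so the strict
bound is enforced. The delay d is applied as a whole-sample shift
(round(d·rate)); its default of 40 ms is the conventional electromechanical
delay for this model family. No published value or bound being available
for d, it is *not* a free calibration parameter.

The shaping function a = (e^{Au} − 1)/(e^A − 1) with A ∈ [−3, 0] is
evaluated after clipping u to [0, 1] (the filter can transiently overshoot);
|A| < 10⁻⁶ switches to the analytic linear limit a = u.

## EMG conditioning

Band-pass 30–450 Hz, full-wave rectification, low-pass 6 Hz, all as
zero-phase (forward–backward) second-order Butterworth filters — the
designed order is second; the effective order after bidirectional
application is four. Edges use reflective padding of three filter lengths,
and post-filter negative undershoot is clipped at zero because downstream
stages require e ∈ [0, 1]. Normalization divides all of a subject-muscle's
envelopes by their single across-trial maximum of the *fully processed*
envelope. Requires sampling above 900 Hz (twice the upper band edge).

## MTU geometry

MTU length lmt(θ) and moment arm r(θ) are independent least-squares
polynomials per muscle (degree 3 by default; ankle curves over stance-range
angles are smooth and low-order). The arm derivative used by the stiffness
sum is the exact polynomial derivative. Evaluation outside the fitted angle
interval raises instead of extrapolating: polynomial surrogates are
unreliable out of range and the ∂r/∂θ term would silently corrupt
stiffness. A tendon-excursion consistency ratio (r vs −dlmt/dθ) is reported
but never enforced, since the two fits are independent. Biarticular
knee-angle dependence of the gastrocnemii is not modelled (ankle-angle-only
surrogates) — a simplification to keep the geometry single-joint.

## Hill-type dynamics

Curve forms (standard in this model family; constants module-level):

* active force–length: f(l̃) = exp(−(l̃−1)²/0.45);
* force–velocity: Hill hyperbola for shortening, (1+ṽ)/(1−ṽ/0.25) on
  ṽ ∈ [−1, 0], and a smooth eccentric branch 1.4 − 0.4·e^{−12.5ṽ} chosen to
  be C¹-continuous at ṽ = 0 and plateau at 1.4× isometric; ṽ normalized by
  vmax = 10 optimal fiber lengths/s;
* passive: fP(l̃) = (e^{10(l̃−1)} − 1)/(e⁵ − 1) for l̃ > 1, else 0;
* tendon: quadratic toe region 1480.3·Fmax·ε² up to the transition strain
  0.0127, then linear (37.5ε − 0.2375)·Fmax; zero under slack. The printed
  coefficients make the two branches continuous to ~10⁻⁵ Fmax at the
  transition (they do not intersect exactly; their closest approach is at
  ε ≈ 0.01267).

Per step, the fiber/tendon split of the known lmt is found by a safeguarded
Newton iteration (bisection fallback, warm-started from the previous step)
on the force balance Ft(ε) = Fm cosΦ under the constant-thickness pennation
closure lm sinΦ = lm0 sinΦ₀; accepted roots satisfy |Ft − Fm cosΦ| ≤ 10⁻⁶ N.
Fiber velocity is a two-point backward difference of lm (zero at the first
step) — causal and stable at stance sampling rates. A small activation
floor (0.005) avoids the degenerate flat residual at a = 0 with an elastic
tendon. A rigid-tendon mode (lt ≡ lst, closed-form fiber length, Kt = ∞) is
available for oracles and comparisons.

Stiffness definitions: Km is the analytic ∂Fm/∂lm at *frozen activation and
velocity* (no short-range cross-bridge term), projected onto the tendon
line as Km cos²Φ + Fm sin²Φ/lm — the cos²Φ scaling plus the geometric
pennation-change term, keeping the series combination dimensionally
consistent along the MTU line of action. Kt is the branch-wise analytic
tendon slope. Kmt combines them in series and is zero when either component
is zero; steps with negative Km (deep descending-limb operation) flow
through the signed formula and are flagged.

## Joint aggregation

τ = Σ Fmtᵢ rᵢ with signed arms. The stiffness sum
K = Σ (Kmtᵢ ρᵢ² + (dρᵢ/dθ) Fmtᵢ) uses the arm in the tendon-excursion
convention ρ = d lmt/dθ = −r; written this way it equals −∂τ/∂θ at frozen
activation and velocity, which the test suite verifies against a
brute-force perturbation of the entire forward chain (agreement ~10⁻⁸
relative at mid-stance; the velocity must be frozen in the perturbed runs,
otherwise force–velocity coupling confounds the comparison at the percent
level). The quadratic term is convention-independent; only the slope term
changes sign, and the pipeline wires the conversion so callers never touch
it. Negative aggregate stiffness steps are clamped to zero and counted.

NRMSE = RMSE(τ_EMG − τ_ID)/RMS(τ_ID). The normalizer is the root mean
square of the experimental moment (not its range or the root of the plain
sum of squares, which differs by √N); outputs are labelled accordingly.

## Calibration

Free parameters: C₁, C₂ ∈ [−1, 1] and A ∈ [−3, 0] shared across muscles
(single-moment data cannot identify per-muscle activation dynamics);
strength coefficients γ_df (TA) and γ_pf (SOL/GAL/GAM) ∈ [0.5, 1.5] scaling
Fmax; per-muscle lm0 multipliers ∈ [0.975, 1.025] and lst multipliers ∈
[0.95, 1.05]. The objective J = (1/N) Σ (τ_EMG − τ_ID)² pools all samples
of all calibration trials of a subject; a forward-chain failure for an
extreme candidate returns a large finite penalty (10⁶) so the simplex
survives.

Nelder–Mead has no native bounds, so each coordinate is smoothly mapped
onto its interval by x = lo + (hi − lo) sin²(z); clipping would flatten the
simplex. The objective is multimodal, so 4 seeded Latin-hypercube interior
starts are used by default and the best restart returned; everything is
deterministic given the seed. Default budget: 1500 function evaluations
per restart (adaptive simplex). On clean synthetic data this recovers the
moment to NRMSE ~10⁻³ and the plantar-flexor strength coefficient to ±0.01.

## Curve statistics

One curve per subject-condition (trials averaged first — the subject is the
repeated-measures unit). At each stance node the one-way repeated-measures
ANOVA F is computed from condition and condition-by-subject sums of
squares; per-subject offsets cancel by construction. Sums of squares at
round-off level are treated as zero; zero interaction variance with a real
condition effect reports +inf.

Inference is permutation-based rather than random-field-theoretic: RFT
smoothness estimation is a large dependency surface, and the permutation
null is self-contained, assumption-light, and exact under within-subject
exchangeability (no sphericity correction needed or applied). Condition
labels are permuted within each subject; when the permutation group is
small enough the full set is enumerated and results become seed-
independent. The critical threshold is the (1−α) quantile of the permuted
field-maximum distribution. Cluster p-values take the smaller of two rank
tests (each with the +1 finite-sample correction): the field-maximum
*height* test, which is exactly calibrated (measured familywise type-I
error 0.045 over the 200-replicate null simulation in the acceptance suite,
α = 0.05), and the suprathreshold *extent* test, which adds power for wide
flat effects but is far too conservative alone (familywise rate ≈ 0 under
the null) — the reason extent is not used as the sole criterion.

Cohen's f over a stance window is √(SS_condition/SS_error) averaged across
the window's nodes, with SS_error the total within-condition sum of squares
(subject + interaction); this reduces exactly to the classical two-group
identity f = d/2 when two condition means differ by d within-cell standard
deviations. Windowed aggregation is the mean, and the output is labelled as
such.

## Synthetic data

The generator's defaults are the study conditions, chosen once for
physiological plausibility:

* **Excitations**: per-muscle sums of ≤ 2 Gaussian bursts over stance %,
  clipped to [0, 1] over a 0.02 baseline — TA bursting just after heel
  strike (peak 0.65) and again pre-swing, plantar flexors building through
  mid-stance to peaks of 0.14–0.20 at 66–72 % stance. Envelope-mode trials
  (default) supply these directly at 100 Hz; raw mode amplitude-modulates
  band-limited Gaussian noise at 1500 Hz for testing the EMG chain.
* **Angle**: a monotone spline through canonical stance waypoints (slight
  plantarflexion after heel strike, dorsiflexion to ~11° by 70 %, push-off
  plantarflexion to −18°), 0.65 s stance duration.
* **Geometry**: quadratic moment arms of adult-ankle magnitude with MTU
  length defined as the exact negative antiderivative, so the excursion
  identity holds by construction; muscle parameters are generic
  lower-limb-model values (e.g. SOL Fmax 3549 N, lm0 5.0 cm, lst 25 cm,
  pennation 25°). Resulting curves: peak plantarflexion moment ≈ 1.75
  N·m/kg for a 63-kg adult, joint stiffness up to ≈ 37 N·m/rad — on the low
  side of perturbation-based estimates, as expected when only four
  superficial muscles contribute.
* **Experimental moment**: the package's own forward model at the truth
  parameters plus i.i.d. Gaussian noise (default sd 2 N·m), the simplest
  stand-in for inverse-dynamics error. With zero noise the generator and
  estimator agree to machine precision by construction — that self-
  consistency validates plumbing, not the physics.
* **Surfaces**: four conditions; the two stiffest ("rigid", "rubber") are
  identical, the compliant ones scale plantar-flexor burst peaks by +5 %
  ("eva") and +10 % ("epe"), producing a known mid-stance moment effect.
  Setting all effects to zero yields exchangeable null cohorts.
* **Cohorts**: per-subject truths jitter burst peaks, strengths and angle
  amplitude (5 % default) within the calibration bounds; all randomness
  derives from one integer seed by counter-based splitting.
* **GRFs**: double-hump vertical and biphasic anterior–posterior shapes
  scaled to a 630 N bodyweight — plausible inputs for curve statistics, not
  contact-physics simulations.

What passing tests on these data do *not* show: robustness to real EMG
artifacts (motion, crosstalk, heartbeat), to inverse-dynamics bias (the
noise is unbiased and white), to geometry scaling errors, or to the
knee-angle dependence of the gastrocnemii. Synthetic truth values are
generic and make no claim to match any particular study population.

## Problem sizes and determinism

Default problem sizes were chosen as realistic-but-small: 100 Hz
envelope-mode trials (66 stance samples), 4 calibration trials per subject,
4 optimizer restarts, 200-permutation inference, and a 200-replicate null
simulation for the type-I-error check. Every stochastic component takes an
explicit integer seed; identical seeds reproduce results bit-for-bit
(permutation inference additionally becomes seed-independent in the
exhaustive regime).

## Known limitations

* Single-joint, four-muscle, sagittal-plane only; deep plantar flexors and
  co-contraction of unmeasured muscles are absent, biasing stiffness low.
* Tendon model has no hysteresis or damping; fibers have no
  history-dependent force enhancement or activation-dependent optimal
  length.
* The NRMSE normalizer (RMS of the experimental moment) is one reading of
  an ambiguous field convention; the alternative (root of the summed
  squares) differs by √N and would change reported magnitudes, not
  rankings.
* Electromechanical delay is fixed, not calibrated.
* Cluster-level p-values for secondary (non-maximal) clusters inherit the
  conservatism of rank tests on the global maximum.
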