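# Methods

## Model and procedure

`fillitup` implements a two-stage, frequentist "fill-it-up" procedure for
augmenting the control arm of a two-arm randomized superiority trial with
historical controls. Responses in the experimental group (E), the randomized
control group (C) and the historical control group (H) are modeled as
normally distributed with means μ_E, μ_C, μ_H and common variance fixed at 1;
all effect sizes and margins are therefore on the standardized scale, and all
tests are z-tests (known variance). The historical controls are treated as a
random sample of size n_H from an external control population.

The trial proceeds in two stages:

1. **Stage 1.** Randomize n_E = n_C = ⌈γN⌉ patients per arm (N is the
   per-arm size a conventional one-step trial would need). Run an
   equivalence pre-test (Ept) of H0: |μ_C − μ_H| ≥ Δ against
   H1: |μ_C − μ_H| < Δ on the stage-1 controls versus the historical
   controls, with statistic Z_Ept = (|ȳ_C − ȳ_H| − Δ)/√(1/n_C + 1/n_H) and
   rejection when Z_Ept < −z_{1−α_Ept/2} (equivalently, two one-sided
   shifted tests at level α_Ept/2 each; `z_ept_tost` verifies the identity).
2. **Branch S1 (pool).** If equivalence is established, test superiority of
   E against the ω-weighted hybrid control mean. The variance-optimal
   weight ω* = n_H/(n_H + n_C) makes this the ordinary two-sample z-test of
   E against the concatenated control sample.
3. **Branch S2 (fill it up).** Otherwise, discard the historical controls,
   randomize the remaining n′_E = n′_C = N − ⌈γN⌉ patients per arm, and run
   the plain two-sample z-test on all randomized patients.

The overall decision is ψ_FIU = max(φ_Ept·φ_S1, (1−φ_Ept)·φ_S2). Because
the two branches partition the sample space on the pre-test outcome and each
terminal test is a level-α test of its own null, the family-wise error rate
is bounded by max(α_S1, α_S2) whenever both superiority nulls hold.

## Planning

`one_step_sample_size` solves N_E·N_C/(N_E+N_C) = (z_{1−α}+z_{1−β})²/δ²
under balanced allocation with a per-group ceiling. `gamma_balanced` equates
the effective sample size of the pooled test (stage-1 patients plus
historical controls) with that of the final test, giving

    γ = (N − n_H + √(N² + n_H²)) / (2N),

the only positive root of the underlying quadratic; γ ∈ [1/2, 1], γ = 1 when
n_H = 0, and γ → 1/2 as n_H → ∞ — at least half of the maximum sample size
is always recruited in stage 1. `gamma_general` solves the same quadratic
for unequal test levels or unbalanced arms (the quotient of quantile sums
enters squared); designs whose admissible root leaves (0, 1] raise an
infeasibility error. Stage-1 sizes use a per-group ceiling ⌈γN⌉; this
convention reproduces every published planning row we checked (totals
100/40/620 for δ = 0.5/0.8/0.2; 328/192 for δ = 0.275 with n_H = 500; 102/54
and 138/74 for δ = 0.5 at powers 0.81 and 0.90).

The **average sample size** (AVN) accounts for stopping after stage 1 with
probability α_Ept (the pre-test level, i.e. its rejection probability at the
margin boundary): per group, AVN = ⌈n₁ + (1 − α_Ept)·n₂⌉, summed over arms.

The **equivalence margin** Δ is admissible in
[z_{1−α_Ept}·√(1/n_H + 1/n_C), δ): below the lower bound the pre-test's
rejection region is empty; at or above δ the control groups could differ by
more than the treatment effect the trial is powered for. Note an asymmetry
we deliberately preserve: the conventional lower bound uses the one-sided
quantile z_{1−α_Ept}, while the pre-test's own critical value uses
z_{1−α_Ept/2}. The one-sided bound reproduces the published margin columns
(0.4596, 0.2303, 0.1663 to four decimals); the `two_sided=True` flag gives
the bound that matches the test's actual never-reject threshold, and the
simulation engine confirms that borrowing probability is exactly zero below
the two-sided bound.

## Joint distribution of the statistics

With ω = ω*, Z_S1 has unit variance and is uncorrelated with the pre-test
difference. Z_S2 shares the stage-1 controls with the pre-test; for the
orientation (ȳ_C − ȳ_H, ȳ′_E − ȳ′_C),

    Cov = −(1/N_C) / (√(1/n_H + 1/n_C)·√(1/N_E + 1/N_C)),

reported as such (negative) by `joint_moments`. Its magnitude tends to 1/2
when n_C = n′_C and n_H is large, is at most 1/√2 (attained as n′_C → 0),
and vanishes as n′_C → ∞.

## Two evaluation schemes, and where they disagree

The folded statistic Z_Ept is not Gaussian: it is a folded-normal transform
of the control-group difference, and the fold matters exactly where the
design is most interesting — near |μ_C − μ_H| = Δ.

* `method="normal-approx"` (default) treats Z_Ept as Gaussian with mean
  (|μ_C − μ_H| − Δ)/se and unit variance and uses the positive covariance
  |Cov(Z_Ept, Z_S2)| above. This is the scheme in which the design's
  published operating characteristics are expressed, and the
  `mode="statistics"` Monte-Carlo draws from exactly this joint law. At the
  scenario-I boundary (|μ_C − μ_H| = Δ) it puts the pre-test rejection
  probability at α_Ept/2.
* `method="exact-folded"` integrates the pre-test event over both tails of
  the Gaussian difference ȳ_C − ȳ_H (bivariate-normal orthant
  probabilities against Z_S2 with the oriented covariance; S1 is exactly
  independent of the pre-test at ω*). At the same boundary the exact
  rejection probability is markedly smaller (e.g. 0.021 instead of 0.100
  at α_Ept = 0.2 for the δ = 0.275, n_H = 500 design).

The discrepancy propagates to boundary null scenarios: for the minimum-FWER
scenario (controls exactly Δ apart, weighted treatment difference zero) with
Δ = 0.15, α_Ept = 0.2, the approximation scheme gives ≈ 0.0077 while the
exact scheme (and patient-level simulation) gives ≈ 0.0036. Both numbers
are computed by this package and surfaced through their respective methods;
the acceptance suite compares the approximation scheme against the published
value and the exact scheme against its own Monte-Carlo. Away from the fold
(|μ_C − μ_H| more than ≈ 4 pre-test standard errors from zero) the two
schemes agree to a few 10⁻⁴, which the test suite asserts. Neither scheme
endangers the level of the procedure itself: FWER control holds by the
partitioning argument regardless of how the pre-test probability is
computed. The normal approximation can, however, overstate the FWER of a
boundary configuration by up to ≈ 6·10⁻⁴ beyond the nominal 5% (a pure
artifact of the positive-covariance approximation); the exact scheme
respects the 5% bound everywhere.

## The FWER surface

`fwer_surface` evaluates the error rate over a grid of control-group
differences μ_H − μ_C ∈ [−2.5, 0] and weighted treatment differences
μ_E − (ωμ_H + (1−ω)μ_C) ∈ [−0.2, 0], with μ_C = 0. A grid point pins the
pooled-test effect, which drives the raw S2 effect μ_E − μ_C far into its
null; taken literally, the S2 branch then never rejects and the surface
would tend to zero at large control-group differences. The surface
therefore evaluates the S2 component at the least-favorable point of its
own composite null (μ_E = μ_C, same control-group difference) — the same
configuration the maximum-case simulation scenario uses. Under this
convention the surface is maximal (→ α_S2) at large control-group
differences, minimal where the difference equals the margin, and bounded by
5% under the exact-folded scheme. `s2_at_boundary=False` recovers the
literal grid scenario.

## Simulation engine

`monte_carlo_oc` supports three modes. `means` (default) draws the group
sample means from their exact Gaussian sampling distribution — this is the
same probability law as patient-level simulation, not an approximation, and
is effectively instant at 50 000 replicates. `patients` loops the
individual-level `simulate_trial` (the engine that also powers the dataset
generator) and exists for end-to-end fidelity checks. `statistics` draws
from the joint normal approximation described above. One seeded
`numpy.random.Generator` drives each run; identical seeds give bit-identical
results, which is asserted in the suite.

Scenario presets mirror the design's simulation study for the small-effect
planning example (δ = 0.275, n_H = 500, plan 192/328): scenario I is the
boundary case (μ_C = 0, μ_H = −Δ, μ_E = −ωΔ with ω = ω* at stage-1 counts;
a flag switches to full-data counts), scenario II the maximum case
(μ_C = μ_E = 0, μ_H = 3Δ). The preset margins per pre-test level
(0.27, 0.22, 0.19, 0.15 for α_Ept = 0.01, 0.05, 0.1, 0.2) are taken as
given study constants; they do not follow a single quantile convention and
are not recomputed from the margin-bound formula.

## Synthetic data

`generate_synthetic_dataset` emulates exactly what the model assumes:
independent unit-variance normal responses at the scenario means, complete
follow-up, balanced arms, and historical controls drawn from a homogeneous
external population. It deliberately does not emulate covariates, baseline
imbalance, time trends, variance heterogeneity, dropout or measurement
floor/ceiling effects — the very features that make real historical
controls hazardous. Passing tests therefore validate the procedure's
operating characteristics under its stated assumptions, not robustness to
violations of them.

## Numerical choices and problem sizes

* Ceilings subtract 1e−9 before rounding up, so values that are integers up
  to floating-point noise are not inflated by one patient.
* Bivariate-normal probabilities use `scipy.stats.multivariate_normal.cdf`
  (absolute accuracy well below 1e−6 in the ranges used); rejection-region
  probabilities are assembled by inclusion–exclusion.
* Superiority tests reject on strict inequality; a statistic exactly at its
  critical value does not reject.
* Default grids step 0.05 on means; `max_fwer` refines ten-fold around the
  running maximum for two rounds.
* The test suite runs simulations at 20 000–100 000 replicates and the
  simulation-study checks at the study's 50 000 replicates; patient-level
  and mean-level engines are cross-checked at smaller sizes. The whole
  suite completes in well under a minute.

## Known limitations

* Known-variance z-tests only; no t-distribution or bootstrap variants.
* No sample-size reassessment or futility stopping at the interim.
* Normal endpoints only; no binary or time-to-event support.
* The pooled branch strictly establishes superiority of E over the hybrid
  control, which is a non-inferiority-flavored conclusion about E versus C
  whenever μ_H ≠ μ_C within the margin.
* No p-value is defined for ψ_FIU; only the binary decision is reported.
* Estimation properties (bias/MSE of the treatment-effect estimate) are out
  of scope.
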