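# fillitup

Planning, hypothesis testing and operating characteristics for the
**Fill-it-up design**: a two-stage, fully frequentist way to use historical
controls in a two-arm randomized superiority trial with a continuous,
normally distributed endpoint.

The package is aimed at trial statisticians — typically in rare-disease
settings, where a conventionally powered RCT is infeasible but registry
control data exist — who want to borrow external controls *only after*
demonstrating that they are comparable to the randomized controls, with
explicit control of the family-wise error rate.

## The design

Responses under the experimental treatment E, the randomized control C and
the historical control H are modeled as N(μ_E, 1), N(μ_C, 1), N(μ_H, 1).
The procedure:

1. **Stage 1** randomizes a fraction γ of the maximum sample size N_FIU and
   runs an equivalence pre-test of H₀: |μ_C − μ_H| ≥ Δ at level α_Ept using

       Z_Ept = (|ȳ_C − ȳ_H| − Δ) / √(1/n_C + 1/n_H)  <  −z₁₋α_Ept/₂

2. **If equivalence holds**, the n_H historical controls are pooled with the
   randomized controls and superiority is tested immediately (test S1) with
   the variance-optimal weight ω* = n_H/(n_H + n_C) — the ordinary z-test of
   E against the concatenated control sample. The trial stops after
   γN_FIU newly recruited patients.
3. **Otherwise**, the historical controls are discarded, randomization is
   "filled up" to N_FIU, and the plain two-sample z-test (S2) is run on all
   randomized patients.

The overall decision is ψ_FIU = max(φ_Ept·φ_S1, (1−φ_Ept)·φ_S2). The
stage-1 fraction that makes both terminal tests equally powered is

    γ = (N − n_H + √(N² + n_H²)) / (2N),   γ ∈ [1/2, 1],

and the admissible margins are z₁₋α_Ept·√(1/n_H + 1/n_C) ≤ Δ < δ.

Module map: `fillitup.design` (sample sizes, γ, margin bounds, ω*, average
sample size) · `fillitup.stats` (the three z-tests, TOST form, ψ_FIU) ·
`fillitup.oc` (analytic FWER/power from the joint distribution of the
statistics, FWER surfaces) · `fillitup.simulate` (seeded Monte-Carlo engine
and the two null-scenario presets) · `fillitup.data` (patient-level CSV
schema, synthetic datasets, stepwise analysis workflow) · `fillitup.cli`.

## Worked example

A fictive rare-disease trial (effect size δ = 0.275, power 0.8, one-sided
α = 0.05 for both superiority tests) with 500 registry controls:

```sh
$ fillitup plan --delta 0.275 --n-h 500 --power 0.8 --alpha-ept 0.05
Maximum total sample size N_FIU : 328
Stage-1 total (gamma N_FIU)     : 192  (96/96 per group)
Stage-2 additions               : 68/68 per group
Stage-1 fraction gamma          : 0.5799
Average sample size AVN         : 322
Equivalence margin range        : [0.1833, 0.2750)
```

A one-step trial without historical controls would need 328 patients
(`2 * one_step_sample_size(0.275, 0.05, 0.2)`); the Fill-it-up design
recruits 192 up front and only the remaining 136 when comparability fails,
for an average of 322 at α_Ept = 0.05. Simulating the worst-case null
(no treatment effect, controls three margins apart, so borrowing is
effectively impossible):

```sh
$ fillitup simulate --delta 0.275 --n-h 500 --alpha-ept 0.05 \
      --scenario scenario-II --replicates 50000 --seed 1
{
  "reject_rate": 0.04826,
  "borrow_rate": 0.0,
  "asn": 328.0,
  ...
}
```

The family-wise error rate stays at the nominal 5% (0.0483 ± 0.001 here).
Generating and analyzing a patient-level trial dataset at the planned
effect:

```sh
$ fillitup generate --delta 0.275 --n-h 500 --margin 0.22 \
      --mu-e 0.275 --mu-h 0.0 --stage 2 --seed 5 --out fiudata.csv
828 patient records written to fiudata.csv
$ fillitup analyze --delta 0.275 --n-h 500 --margin 0.22 --data fiudata.csv
Pre-test: Z = -0.0723 (reject=False) -> branch S2
Terminal test S2: Z = 4.1267 (reject=True)
Overall decision psi_FIU = 1
```

Here the pre-test could not establish equivalence (with Δ = 0.22 and
n_C = 96 the rejection region is almost empty), so the trial filled up to
164 patients per arm and S2 declared superiority. The same workflow is
available in the library:

```python
import fillitup as f

spec = f.DesignSpec(delta=0.275, alpha_ept=0.05, n_h=500, margin=0.22)
plan = f.stage_plan(spec)          # StagePlan(n_e=96, n_c=96, n_e2=68, ...)
res = f.fwer(f.ScenarioMeans(mu_e=0, mu_c=0, mu_h=3 * 0.22),
             plan, spec, method="exact-folded")
print(res.value)                   # 0.0500... = alpha_S2: S2 branch only
```

See `docs/methods.md` for the model, the two analytic evaluation schemes
(normal approximation of the folded pre-test statistic versus exact
folded-normal integration) and where they disagree, and the simulation
engine's sampling modes.

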