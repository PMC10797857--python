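# Methods

## Model and procedure

The package evaluates two-stage adaptive designs for two-arm trials with a
Bernoulli endpoint, X_I ~ B(p_I), X_C ~ B(p_C), equal per-group sizes at
both stages, testing H₀: p_I − p_C ≤ 0 one-sided.  The analysis statistic
is the normal-approximation (pooled-variance) Z test; its square is the
chi-square statistic, so everything carries over to that test.  The
asymptotic law of Z is parameterized by the single standardized effect
λ = (p_I − p_C)/√(p̄(1−p̄)), under which Z ~ N(λ√(n/2), 1 − λ²/4).  All
design calculus — conditional power, its inversion for the stage-2 size,
the fixed-design size formula

    n_fix(λ) = (√2·q_{1−α₁₊₂}/λ + q_{1−β}·√(2/λ² − 1/2))²

— is expressed in λ.  Trials where the treatment lowers a harmful endpoint
are handled by swapping the group roles before analysis so that benefit
means λ > 0.

A trial stops at the interim for efficacy (Z₁ ≥ q_{1−α₁}) or binding
futility (Z₁ < q_{1−α₀}); in between — the recalculation area — one of
five rules picks the per-group stage-2 size n₂ ∈ [1, n_max − n₁] from the
interim estimate λ̂ = Z₁/√(n₁/2):

* **classicGS** — constant n₂ = n_ini;
* **OCP** — smallest integer n₂ whose *observed* conditional power (the
  conditional power formula with λ̂ plugged in) reaches 1 − β, capped;
* **restrOCP** — as OCP, but stops the trial when even the cap cannot
  reach 1 − β₀^restr (strict inequality at the threshold);
* **promising** — OCP only when the observed conditional power at n_ini
  lies in [1 − β₀^prom, 1 − β]; otherwise n_ini;
* **optfunc** — argmax over integers of CP(n₂) − γ(n₂ − n_ini), found by
  exhaustive scan (ties to the smaller size; the constant CP(n_ini) offset
  sometimes written into this objective does not move the argmax and is
  omitted).

The final analysis uses the inverse normal combination
Z₁₊₂ = (w₁Z₁ + w₂Z₂)/√(w₁²+w₂²) with Pocock-type equal local levels
α₁ = α₁₊₂, solved from the bivariate-normal union probability with
correlation w₁/√(w₁²+w₂²).

## The conditional performance score

Conditionally on Z₁ in the recalculation area, four components in [0, 1]
score a rule at a true effect λ:

    l_CP = 1 − |E[CP] − CP_target| / (1 − α)        (location of conditional power)
    l_N  = 1 − |E[N] − N_target| / (n_max − n₁)     (location of total size)
    v_CP = 1 − √(Var(CP) / (1/2)²)                  (variation of conditional power)
    v_N  = 1 − √(Var(N) / ((n_max−n₁)/2)²)          (variation of total size)

combined as an equally weighted sum (weights configurable).  The CP
entering the score is the *observed* conditional power CP_λ̂ — the quantity
the rule itself acts on; a switch (`conditional_power_asymptotic`) exposes
the true-λ variant for sensitivity analysis.  Targets follow the powered /
underpowered dichotomy: (1 − β, n_fix(λ)) when λ > 0 and n_fix(λ) ≤ n_max,
else (α, n₁).  restrOCP stops inside the recalculation area stay in the
conditional evaluation set with N = n₁ and CP = 0 — the score conditions
on the interim zone, not on continuation.

## Simulation design

* **Outer loop.**  Z₁ is simulated *exactly*: per-group binomial draws of
  size n₁ pushed through the Z statistic, n_sim = 10,000 by default, so
  discreteness and small-sample effects propagate into zone frequencies
  and score components.  Population (divide-by-n) variances are used in
  the conditional summaries.
* **Global power.**  Estimated as the mean of the efficacy-stop indicator
  plus, for continuing trials, the true conditional power of the
  continuation, itself estimated by exact Bernoulli simulation of Z₂
  (default 1,000 replications per trial; the closed-form asymptotic
  version is available).  Stopped trials contribute 0.
* **Seeding.**  One master seed per run; the interim draws and the inner
  true-CP simulations use separately derived child streams, so changing
  the inner replication count never perturbs the interim draws.  Runs are
  bit-reproducible for a given seed.

## Numerical choices

* Degenerate data (all observations identical in both groups) make the
  pooled variance zero; Z and λ̂ are then defined as 0 — no evidence either
  way, and the simulation stays total.
* Sample sizes are integerized by ceiling (conservative); the stage-2
  floor is 1 patient when continuing.
* The bivariate-normal union probability behind the Pocock levels is
  computed by one-dimensional quadrature of the conditional normal CDF
  (tolerance 1e-10) and root-bracketed to 1e-8 in the level, avoiding any
  multivariate-normal library convention.
* The conditional-power inversion is closed-form; it round-trips through
  the CP formula to 1e-9, which the tests assert.
* `fixed_design_n` takes the rejection-quantile level explicitly: the
  score targets use the local final level α₁₊₂ exactly as the size formula
  is written, while conventional fixed-design benchmarks use the plain α.
  Near the cap the powered/underpowered branch can differ between the two
  conventions (at n₁ = 50, n_max = 200 this happens at λ ≈ 0.3, where
  n_fix is 201 under one convention and 174 under the other); both are
  exposed via the `level` argument of `score_targets`, the local-level
  form being the default.

## What the generator emulates — and what it does not

The Bernoulli generator reproduces the exact finite-sample law of the
test statistic under the stated model: independent responses, equal group
sizes, no dropout, no overdispersion, a single interim look at exactly n₁
per group.  Real trials violate these in known ways (staggered accrual,
missing data, covariate effects), so passing tests certify the design
calculus and the score machinery, not robustness of any rule to such
violations.  Two quantifications of the normal approximation's limits,
both visible in the test suite's exact-enumeration oracles:

* at n = 10 the exact variance of Z deviates from 1 − λ²/4 by up to
  ≈ 0.04–0.06 (worst under the null, where the degenerate-sample
  convention also bites); by n = 50 the deviation is below 0.01–0.02;
* the exact statistic has an atom at 0, so with α₀ = 0.5 the futility
  probability under H₀ is ≈ 0.457 at n₁ = 50, not 0.5, and zone
  probabilities sit a percent or two away from their asymptotic values.

Type I error control is asymptotic only: the empirical level at n₁ = 50
is ≈ 0.027 — the known inflation of efficacy-stopping designs with binary
endpoints at moderate sample sizes.

## Problem sizes

Default study sizes are the published ones: 10,000 outer interim
simulations per (rule, λ) cell and 1,000 inner replications per continuing
trial for true conditional power.  At these sizes a score value moves by
well under 0.01 between seeds (asserted in the tests), and a full
five-rule, 13-λ table with global power completes in a few minutes on one
CPU; examples use reduced sizes (2,000 / 300) for narrative speed.

## Known limitations

* Only two stages, equal allocation, binary endpoints; no exact
  conditional tests (Fisher, Barnard), continuity corrections, or
  error-spending boundaries.
* Futility is binding by construction; non-binding stops would change
  both the level calibration and the score's conditional set.
* The λ-parameterization caps |λ| at 2; effects are only meaningful where
  a valid proportion pair exists for the chosen control rate.
* Published score tables carry Monte-Carlo noise of their own; agreement
  is expected at the ±0.01–0.02 level at n_sim = 10,000, and one printed
  effect-table cell in ~20 sits on a 3-decimal rounding boundary.
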