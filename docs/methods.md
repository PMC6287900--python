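# Methods

## Model structure and assumptions

The package evaluates China's New Rural Cooperative Medical Scheme (NCMS)
with a deterministic three-state Markov cohort model (normotensive,
hypertensive, dead) run separately for two arms (insured vs. uninsured) and
two sexes, in one-year cycles from age 20 until age 100. Key structural
assumptions, inherited from the published analysis:

- Hypertension is irreversible: once hypertensive, a person keeps the lower
  utility (0.92 vs. 0.98) and incurs hypertension-related medical costs
  (Int$392/patient-year) until death.
- Hypertension does not raise mortality; the annual death probability is
  state-independent, so the scheme's mortality effect acts only through the
  background schedule.
- Survivors at age 100 exit the model with no terminal reward.
- All monetary flows are 2013 international dollars (PPP); the PPP rate
  (3.55 CNY/Int$) is carried for reporting only.

Within a cycle, death applies first, then onset among survivors. This
ordering is the one that keeps the death probability exactly
state-independent; because of it the occupancy recursion collapses to
running products (alive fraction = ∏(1−q), never-hypertensive fraction =
∏((1−q)(1−p))), which the engine uses directly. The generic
transition-matrix formulation is kept out of the implementation and serves
as an independent oracle in the tests (matrix powers vs. engine, 1e−12).

## Reward accounting conventions

The source analysis was built in a commercial decision-tree package whose
reward-timing conventions are not published. The engine's defaults are:

- rewards on start-of-cycle occupancies (no half-cycle correction), so a
  person contributes utility and costs for the cycle they enter alive;
- newly hypertensive individuals earn hypertensive utility/costs from the
  *next* cycle (onset at cycle end), consistent with the point above;
- discount factor (1+r)^−t with t = 0 at model entry (age 20).

Both conventions are isolated in `engine.Conventions` (`half_cycle`,
`discount_age_offset`) and swept by the acceptance test. The sweep is
informative: with `discount_age_offset=20` (discounting from birth rather
than from entry) the per-arm QALY totals and incremental cost move close to
the published table, suggesting that is what the original software did. The
ICER is invariant to the discount origin — the same factor multiplies costs
and QALYs — so this choice affects presentation, not conclusions.

The extra health expenditure HE₁ − HE₁/(1+g) applies to every alive member
of the insured arm (it is defined per rural resident, not per patient).
Hypertension medical costs accrue in both arms; the scheme's prevention
savings emerge endogenously from its lower hypertensive occupancy rather
than being entered as a separate credit. The labor-productivity benefit is
a negative cost component of the insured arm, zero below age 30 (no
published effect there); ages 45–49 fall in the 30–49 labor band and in the
45–59 mortality band — the bands are channel-specific.

## Parameters

All uncertain scalars carry (base, low, high) and live in one YAML file
mirroring the published input table (see `src/ncms_cea/fixtures/table1.yaml`
for values and units). The ones that matter most, per the one-way analyses:
total health expenditure per resident (Int$359; 243–977), its attributable
growth rate (0.61; 0.50–0.70), the hypertension risk ratio (0.98;
0.95–1.00), the six sex×band mortality effects (deaths/1,000/year, several
spanning zero), the annual wage (Int$1,029; 350–4,198), and the discount
rate (3%; 0–5%). The cohort is sex-weighted 0.5/0.5 by default
(configurable); the published analysis does not state its sex handling.

## Synthetic schedules

The analysis needs two external age/sex schedules — a national period life
table and an annual hypertension-onset schedule — that are not publicly
available. The bundled stand-ins are parametric:

- mortality: Gompertz–Makeham, q(age) = 1 − exp(−(λ + α·e^{β·age})) with
  λ = 1e−4, α = 6e−5, β = 0.092 and a female/male hazard ratio of 0.6.
  These values put remaining life expectancy at age 20 at 54.6 (men) /
  60.0 (women) years, matching the ~55/59 of the 2013 China life table;
- incidence: logistic in age, p(age) = 0.035 / (1 + e^{−0.07(age−55)}),
  i.e. rising from ~0.3%/year at 20 toward a 3.5%/year plateau, which
  yields ~50–60% lifetime hypertension prevalence at old age.

The life-table values are treated as annual death *probabilities* (qx), the
quantity a per-cycle Markov transition consumes, and the onset schedule as
annual *incidence* (the published wording, "likelihood of hypertension", is
ambiguous between incidence and prevalence; an irreversible-state model can
only use incidence).

What the stand-ins do not emulate: the fine age-structure of the real life
table (infant/accident humps are irrelevant above 20, but plateaus and
cohort effects are smoothed away), sex differences in hypertension onset,
and any correlation between regional mortality and expenditure levels.
Consequently, checks that pass on synthetic schedules validate the *method*
— transition arithmetic, accounting, sampling, ranking — not the published
point estimates: quantities that depend on the schedules (ΔQALY, hence the
ICER and the PSA quadrant shares) should be expected to differ from the
published table even when the pipeline is correct, while schedule-free
quantities (expenditure decomposition, WTP threshold, all invariants)
reproduce exactly.

`synthesize_parameter_set(seed, jitter)` additionally produces randomized
but always-valid parameter sets for property testing: each (base, low,
high) triple is multiplied by a common factor drawn from
[1−jitter, 1+jitter] (a common positive factor preserves the ordering for
any sign pattern), with utilities and the risk ratio re-capped at 1.

## Sensitivity machinery

One-way analyses rerun the full two-arm model with a single parameter at
its low/high bound. The tornado ranks parameters by ICER span; an endpoint
that leaves the north-east quadrant (cost-saving or dominated) makes the
span infinite, and such ties are broken by the always-finite net-monetary-
benefit span at the WTP threshold. Sorting is stable.

The PSA samples all 19 uncertain scalars independently (no correlation
structure is published) from triangular(low, base, high) via the
closed-form inverse CDF; mortality-effect intervals spanning zero are
sampled as-is — truncating them at zero would bias the ICER. Draw j uses
one uniform per parameter in the fixed enumeration order documented in
`params.iter_uncertain`, generated by numpy's PCG64 (`default_rng(seed)`),
so a (parameter set, n, seed) triple is reproducible bit-for-bit across
platforms. Summaries: means, equal-tailed 2.5/97.5 percentile intervals
(the published "95% plausible interval" is not otherwise specified),
quadrant probabilities at Int$37,059/QALY using the four-way classification
(QALY losses pooled regardless of cost sign), and the cost-effectiveness
acceptability curve, the fraction of draws with strictly positive net
monetary benefit per WTP value. Any PSA-level ICER is reported as
(mean Δcost)/(mean ΔQALY), never the mean of per-draw ratios, which is
unstable when ΔQALY ≈ 0. Note one deliberate asymmetry: the CEAC counts
QALY-losing draws with large cost savings as acceptable (NMB > 0) while the
quadrant table files them under "qaly_loss", so acceptability at the
threshold equals P(dominant) + P(cost-effective) only up to that set.

## Numerical choices and degenerate inputs

- Probabilities are clamped to [0, 1] after applying effects; clamping is
  part of the model definition, not an error path.
- The ICER is undefined when ΔQALY = 0 (`None`; classification then follows
  the cost sign via the QALY-loss rule). The WTP boundary is inclusive.
- Degenerate triangular specs (low = high) are point masses; a parameter
  whose three values coincide contributes nothing to the PSA spread.
- Occupancy conservation holds to 1e−12 by construction; cost components
  are checked to sum to the total within 1e−9 relative.
- Display rounding (costs to Int$1, QALYs to 0.01, ICER to Int$1) lives
  only in the CLI layer; library objects are never rounded.

## Problem sizes

Default runs use the full 80-cycle horizon, both sexes and both arms
(~0.7 ms per two-arm evaluation); the shipped PSA uses 10,000 draws (~10 s
single-core), the tornado 19 × 2 model reruns, and property tests use 100
synthetic parameter sets and 1e5 sampler draws.

## Known limitations

- No individual-level microsimulation, no hypertension-attributable
  mortality, no reversion, no tunnel states — structural exclusions of the
  source model, kept here.
- Only the national/Beijing/Guizhou expenditure variants; no broader
  regional parameter database and no CNY-denominated outputs.
- Indirect hypertension costs (transport, caregiving) are excluded.
- No value-of-information analysis and no correlated sampling; the
  triangular family is the only supported PSA distribution.
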