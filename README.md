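# ncms-cea

Lifetime cost-effectiveness analysis of China's **New Rural Cooperative
Medical Scheme (NCMS)** — the rural health-insurance program that by 2013
covered ~99% of China's rural residents — for health economists and policy
analysts who want the published decision model as a tested, scriptable
pipeline rather than a proprietary model file.

## The model

A deterministic two-arm Markov cohort model follows a hypothetical cohort of
20-year-old rural residents in annual cycles until death or age 100, through
three health states: *normotensive*, *hypertensive* (irreversible) and
*dead*. Per cycle, death applies first — with the same probability q(age,sex)
in both living states, since hypertension carries no excess mortality here —
then hypertension onset p(age,sex) among survivors.

The insured (NCMS) arm modifies the transitions and costs:

- mortality: q ← clamp(q + δ/1000, 0, 1), where δ is the marginal effect of
  the scheme on annual deaths per 1,000, by sex and age band (20–44, 45–59,
  60+);
- hypertension: p ← RR·p with RR = 0.98 (0.95–1.00);
- costs: an extra health expenditure of HE₁ − HE₁/(1+g) per alive
  person-year (Int$359 − Int$359/1.61 ≈ Int$136 nationally), offset by a
  monetized labor-productivity gain (off-farm participation × annual wage +
  extra farm hours × agricultural hourly income, ages 30+);
- both arms accrue hypertension-related medical costs (Int$392/patient-year)
  on hypertensive occupancy.

Rewards are utility-weighted life years (u = 0.98 normotensive, 0.92
hypertensive) and costs in 2013 international dollars, discounted at 3%/year.
The headline statistic is the incremental cost-effectiveness ratio

    ICER = Δcost / ΔQALY   (NCMS − no NCMS),

judged against a willingness-to-pay threshold of three times 2013 per-capita
GDP, 3 × Int$12,353 = **Int$37,059/QALY**. Uncertainty is handled by one-way
sensitivity analyses over each parameter's low/high bounds and by a Monte
Carlo probabilistic sensitivity analysis (PSA) sampling every uncertain
scalar independently from a triangular(low, base, high) distribution.

The background mortality and hypertension schedules consumed by the
published analysis are not publicly available; the bundled schedules are
**synthetic** stand-ins (Gompertz–Makeham mortality and logistic incidence,
calibrated to a plausible 2013 rural-China life expectancy) — see
`docs/methods.md` for what that does and does not preserve.

## Worked example

```sh
ncms-cea base --out out/
```

prints (bundled configuration):

```
Arm         Cost, Int$     QALYs
no-NCMS          1,528     26.61
NCMS             3,162     26.62
Incremental cost Int$1,633, incremental effectiveness 0.01 QALYs, ICER Int$131,534/QALY
Classification at WTP Int$37,059/QALY: not_cost_effective
```

Reading: over the cohort's lifetime the scheme adds Int$1,633 of discounted
cost per resident (extra expenditure net of labor gains and averted
hypertension costs) and buys ≈0.01 discounted QALYs, so each QALY costs
≈Int$131,534 — far above the Int$37,059 threshold, i.e. *not cost-effective*
under these inputs. Displayed QALYs are rounded to 0.01; the ICER always
uses the unrounded increments, which is why Δcost/0.01 does not reproduce it.

The same pipeline is available as a library:

```python
from ncms_cea import Arm, incremental, load_bundled_parameters, run_both_arms, run_psa, wtp_threshold

p = load_bundled_parameters()
outs = run_both_arms(p)
inc = incremental(outs[Arm.NCMS], outs[Arm.CONTROL], wtp_threshold(p.econ))
psa = run_psa(p, n=10_000, seed=20130101)
```

Other subcommands: `ncms-cea tornado` (ranked one-way analyses),
`ncms-cea psa --n 10000 --seed 20130101` (scatter, CEAC and quadrant
probabilities), `ncms-cea full` (everything plus a run manifest) and
`ncms-cea synthesize` (write a fresh synthetic configuration).

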