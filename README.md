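# caries-cea

A Markov cohort cost-effectiveness model for school-based dental-caries
prevention in a public-payer setting. A hypothetical cohort of 10,000
learners enters school caries-free at age 5 and is followed over 10
annual cycles to age 15 through four states — *no caries*, *caries*,
*treated* and *exited* (absorbing) — under six mutually exclusive
strategies: do nothing, APF (acidulated phosphate fluoride) gel, fissure
sealant, ART (atraumatic restorative treatment), supervised tooth
brushing, and population-level sugar reduction. The outcome is DMFT
(decayed, missing, filled teeth) averted; costs are ZAR per learner at
constant prices, discounted at 5%/year alongside health effects.

The package computes:

* **Deterministic CEA** — per-arm discounted total cost and DMFT averted,
  average lifetime cost per learner, ICERs versus do-nothing, ranked
  incremental ICERs along the effectiveness ordering
  (ICER = ΔC/ΔE), strict and extended dominance flags, and net monetary
  benefit NMB = λ·E − C at a willingness-to-pay λ = ZAR38,500 per DMFT
  averted.
* **Probabilistic sensitivity analysis** — gamma-distributed costs and
  beta-distributed effectiveness, moment-matched to published mean/SD
  (gamma: k = m²/s², θ = s²/m; beta: ν = m(1−m)/s² − 1, α = mν,
  β = (1−m)ν), propagated by Monte Carlo (default 1000 iterations)
  to produce cost-effectiveness planes and acceptability curves
  (CEAC: the probability an arm has the highest NMB across a WTP grid).
* **Synthetic age schedules** — the age-dependent caries-onset, cohort-exit
  and baseline-DMFT tables behind the original analysis are not public;
  a seeded generator produces plausible monotone schedules, and a
  bisection calibrator scales the exit column so the cohort's 10-year
  screening outlay matches the published ZAR43.78 million.

## Worked example

The CEA layer can be run directly on per-arm totals (fixture mode).
With the bundled published totals:

```bash
caries-cea deterministic \
    --fixture src/caries_cea/data/published_totals.csv --outdir out/
```

prints

```
           name  total_cost  dmft_averted  average_lifetime_cost icer_vs_donothing ranked_icer        nmb  dominated  extended_dominated
     do_nothing           0             0                      0               Ref         Ref          0      False               False
        apf_gel    54024439         42010                   5402            1286.0      1286.0 1563360561       True               False
sugar_reduction       91380         63762                      9              1.43     -2479.0 2454745620      False               False
 tooth_brushing    72779917         74018                   7278             983.0      7087.0 2776913083       True               False
fissure_sealant    44633687        100024                   4463             446.0     -1082.0 3806290313      False                True
            art    45057166        144035                   4506             313.0        10.0 5500290334      False               False
```

Reading the table: rows are sorted by effectiveness (DMFT averted,
ascending). APF gel costs ZAR1,286 per DMFT averted relative to doing
nothing; ART costs ZAR313. In the ranked column each arm is compared to
the previous row — the negative entries (sugar vs APF, fissure vs tooth
brushing) mean the more effective option is also cheaper, and ART buys
additional DMFT averted at only ZAR10 each relative to fissure sealant.
ART has the largest net monetary benefit (ZAR5.50 billion at
λ = ZAR38,500), making it the preferred strategy under the NMB rule;
APF gel and tooth brushing are strictly dominated, and fissure sealant
is extended-dominated (its incremental ICER exceeds ART's).

The same tables can be produced from the Markov engine with a generated,
calibrated schedule (`caries-cea deterministic --seed 1 --outdir out/`),
and `caries-cea psa --seed 1 -n 1000 --outdir out/` adds Monte Carlo
samples, the CEAC table/plot and a cost-effectiveness plane. Python
users can drive everything through `caries_cea.run_all_arms`,
`caries_cea.cea_table`, `caries_cea.run_psa` and `caries_cea.ceac`.

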