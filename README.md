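# her2cea

Cost-effectiveness analysis of neoadjuvant–adjuvant treatment strategies for
*ERBB2* (*HER2*)-positive breast cancer, for health-economics researchers and
modelers who want a reusable, tested implementation of the full analysis
pipeline: decision tree, lifetime Markov cohort model, ICER ladder with
dominance, probabilistic sensitivity analysis with acceptability curves, and
one-way/scenario/subgroup analyses.

## The problem and the model

In stage II–III HER2-positive breast cancer, the extent of residual disease
after preoperative (neoadjuvant) therapy can guide postoperative (adjuvant)
therapy: patients with a pathologic complete response (pCR) have an excellent
prognosis on adjuvant trastuzumab (H) alone, while patients with residual
disease benefit from escalation (e.g. trastuzumab emtansine, T-DM1). Five
strategies are compared, each a neoadjuvant regimen (HP, THP, DDAC/THP, or
TCHP) followed by a pCR-dependent adjuvant choice — for example, strategy 3 is
neoadjuvant THP, then adjuvant H after pCR or adjuvant DDAC + T-DM1 after
residual disease.

A decision tree splits each strategy's cohort by its pCR rate
(p<sub>pCR</sub>); each branch then enters a Markov cohort model over nine
health states — recurrence-free (RF), local recurrence (LR), distant
recurrence (DR), treatment-related AML and CHF, and four absorbing death
states — cycled annually from age 49 to age 100. Per-cycle transition
probabilities come from constant-hazard conversions, e.g.

- 3-year recurrence probability → annual: *p₁ = 1 − (1 − p₃)^(1/3)*, scaled by
  branch-specific relative risks on the probability scale;
- median survival m (months) → annual death probability *1 − 2^(−12/m)*;
- competing exits combined on the rate scale when they would overflow.

Expected discounted (3%/yr) costs (2020 USD) and quality-adjusted life-years
(QALYs, state utilities × occupancy, half-cycle corrected) accumulate over the
horizon. Strategies are ranked by cost; incremental cost-effectiveness ratios
(ICER = ΔC/ΔE) are computed along the efficient frontier after removing
strongly and extended-dominated strategies, and net monetary benefit
(NMB = λ·E − C) drives the acceptability curves over willingness-to-pay
λ ∈ [0, 200 000] $/QALY.

All input parameters (pCR rates, recurrence risks and relative risks, median
survivals, toxicity probabilities, costs, utilities) ship with their
probabilistic-sensitivity-analysis distributions in
`src/her2cea/data/default_config.yaml`; background mortality uses a
parametric Gompertz–Makeham life table (see `docs/methods.md`).

## Worked example

```sh
her2cea base-case --out out/
```

prints (and writes as CSV/JSON alongside a run manifest):

```
Strategy                                     Costs, $   QALYs  Inc. costs, $  Inc. QALYs  ICER ($/QALY)
THP -> DDAC+T-DM1 (residual) / H (pCR)        369,082   10.14             NA          NA  Optimal strategy
DDAC/THP -> T-DM1 (residual) / H (pCR)        395,864    9.68         26,782       -0.46  Dominated
DDAC/THP -> H (all)                           405,706    9.33         36,624       -0.81  Dominated
TCHP -> T-DM1 (residual) / H (pCR)            436,178   10.14         67,096       -0.00  Dominated
HP -> DDAC/THP+T-DM1 (residual) / H (pCR      492,045    9.92        122,962       -0.22  Dominated

Cost-effective at $50,000/QALY: strategy 3
Cost-effective at $100,000/QALY: strategy 3
Cost-effective at $150,000/QALY: strategy 3
```

Strategy 3 (neoadjuvant THP) yields the most QALYs (10.14) at the lowest cost
($369,082): it *dominates* every alternative, so all other strategies carry
negative incremental QALYs against it and no ICER is defined on the frontier.
Other entry points: `her2cea psa` (acceptability curves + frontier),
`her2cea owsa` (one-way sweeps), `her2cea scenario age64 | adjuvant_hp |
rr_ddac_tdm1`, `her2cea subgroup positive --pcr THP=0.30 ...`,
`her2cea make-lifetable`, and `her2cea oracle-check` (cohort engine vs an
independent patient-level microsimulation). The same operations are available
as library functions (`her2cea.evaluate_strategies`, `run_psa`, `run_owsa`,
...).

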