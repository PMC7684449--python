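# Methods

## Model structure

Each of the five treatment strategies is expanded by a decision tree into a
pCR branch (weight = the neoadjuvant regimen's pCR proportion) and a
residual-disease branch (complement). Each branch carries an upfront
treatment cost (neoadjuvant + branch-specific adjuvant regimen; the
TCHP-based strategy uses its own post-TCHP adjuvant prices) and branch-level
annual recurrence probabilities, and is run through a Markov cohort model
with states RF (recurrence-free), LR (local recurrence), DR (distant
recurrence), AML, CHF, and four absorbing death states (breast cancer, AML,
CHF, other causes). Strategy totals are the branch-weight averages.

Transitions per annual cycle:

| from | to | probability |
|---|---|---|
| RF | LR | annualized 3-y reference (4.6%) × branch RR (0.24; RR 1 for residual disease on H, the reference group) |
| RF | DR | annualized 3-y reference (15.9%) × branch RR (pCR 0.18; residual: 1.0 / 0.60 / 0.52 / 0.40 by adjuvant) |
| RF | AML, CHF | 1-y toxicity probability by exposure class (see below) |
| LR | DR | annualized 10-y probability 18.9% |
| DR | death (BC) | exponential median 38 mo → 0.1966/yr |
| AML | death (AML) | exponential median 8 mo → 0.6464/yr |
| CHF | death (CHF) | 12.7%/yr |
| any alive | death (other) | life-table q(age) |

Background mortality composes additively with state-specific exits; whenever
competing exit probabilities from a state would sum above 1 they are
converted to rates, and the combined exit probability 1 − exp(−Σ rates) is
allocated proportionally to the rates (ratio-preserving). Recurrence hazards
are held constant over the whole horizon (no cure window is modeled).

Toxicity exposure classes: anthracycline-containing chemotherapy (`ac`: CHF
3.7% × 1.26, AML 0.1% × 1.68 per year), non-anthracycline chemotherapy
(`non_ac`: CHF 3.7%, AML 0.1% × 0.88), and no chemotherapy (`no_chemo`: CHF
0, AML 0.1% baseline). Strategies 1 and 2 are `ac` in both branches;
strategy 3 is `non_ac` after pCR and `ac` with residual disease; strategy 4
is `no_chemo` after pCR (HP alone) and `ac` with residual disease; strategy 5
(TCHP) is `non_ac` in both branches.

### Toxicity window

The published state diagram draws AML and CHF as ongoing exits from the
recurrence-free state for chemotherapy-exposed patients, and the package's
default (`toxicity_mode: lifetime`) applies the 1-year AML/CHF probabilities
every cycle accordingly. We also implemented the alternative reading in which
the 1-year toxicity probabilities apply only in the treatment year
(`toxicity_mode: first_cycle`). The lifetime reading is the default because
it is the only one consistent with the published strategy ranking: under
first-cycle-only toxicity the cross-strategy QALY differences are driven
almost entirely by distant recurrence, which makes the
high-pCR/anthracycline-heavy strategies rank strictly better than the
published table reports, whereas the ongoing-risk reading reproduces the
published QALY ordering exactly and the published QALY magnitudes closely.

## Cycle conventions and rewards

- Annual cycles from start age 49 to horizon age 100 (51 cycles); both
  configurable, including sub-year cycle lengths.
- Half-cycle correction: state rewards (utilities; LR/DR/CHF annual costs)
  use the mean of beginning- and end-of-cycle occupancy, i.e. transitions at
  mid-cycle; rewards of cycle k are therefore discounted at
  (1 + r)^−(k + ½), r = 3%/yr.
- Upfront treatment costs are charged at time 0, undiscounted.
- One-off rewards ride on transition flows at the same mid-cycle discount
  point: the LR first-year premium ($21,005 − $2,335), initial CHF treatment
  ($36,748, on top of $7,035/yr of CHF care), and the lifetime AML cost
  ($21,345) at entry.
- Utilities: RF 0.79 in the first model year then 0.83, LR 0.72, DR 0.53,
  CHF 0.71, AML 0.26. The fraction leaving DR for death in a cycle is
  credited the terminal-year utility 0.16 for that full cycle in place of
  its half-cycle DR credit, and — for consistency with that "last full year
  with distant recurrence" reading — a full rather than half year of DR care
  cost ($144,865/yr).

## Parameter distributions

Every Table-style input carries a distribution for the PSA: beta for
probabilities and utilities, gamma (shape, scale; mean = shape × scale) for
costs, log-normal for relative risks, normal for median survivals, truncated
normal on [0.18, 0.60] for the two assumption-based distant-recurrence RRs
(location = base value, scale = 20% of location, mirroring the 20% SE
convention used where no summary statistics exist). Two idiosyncrasies are
preserved deliberately:

- the AML lifetime-cost gamma is parameterized with a rate printed as
  "1/8.44"; we store scale 8.44 so that mean = 2530.10 × 8.44 ≈ $21,354;
- the AML 1-year baseline beta(138.30, 197,505.60) has mean ≈ 0.0007 while
  the point estimate is 0.001; the base case uses the point value and the
  PSA samples the beta, and this row is exempt from the load-time check that
  a distribution's mean reproduces its base value within 10%.

PSA draws are mutually independent across parameters, consumed from a single
PCG64 stream in sorted-path order (seed-reproducible); draws violating a
field's range (e.g. a negative normal median) are rejected and redrawn.

## Synthetic life table

Background mortality uses a Gompertz–Makeham hazard λ + b·e^(θ·age) with
λ = 5×10⁻⁴/yr, b = 3.5×10⁻⁵/yr, θ = 0.094/yr of age, tabulated to annual
probabilities q(age) = 1 − exp(−hazard). This gives q(49) ≈ 0.0040 and an
undiscounted residual life expectancy at 49 of ≈ 30.5 years — a deliberately
download-free stand-in approximating recent US female mortality, somewhat
heavier at old ages than the current US life table. It does not emulate
cohort effects, period shocks, or cause-elimination; any real life table can
be substituted as a two-column CSV (`age,qx`). Passing tests therefore
demonstrate correctness of the engine and robustness of the strategy
ranking, not calibration to any particular national mortality experience.

## Verification

An independent patient-level microsimulation (`her2cea.synthetic
.microsim_oracle`) re-derives the transition probabilities and reward rules
from their definitions — without sharing the cohort engine's code — and must
agree with the cohort model within 3 Monte Carlo standard errors at 200,000
patients per branch for all five strategies (enforced in the test suite, and
runnable ad hoc via `her2cea oracle-check`). Degenerate settings have exact
closed forms (e.g. no events, no discounting over 51 years gives
0.79 + 50 × 0.83 = 42.29 QALYs) asserted to 10⁻⁹. The ICER-ladder labels are
cross-checked against exhaustive pairwise NMB comparison on synthetic
instances.

## Numerical choices

- NMB ties in the CEAC (measure-zero under continuous distributions) are
  split equally across tied strategies.
- ICERs are reported at full precision in machine outputs and rounded to the
  nearest dollar in presentation tables.
- One-way sensitivity sweeps use 13 evenly spaced points over ±30% of the
  base value (probabilities capped at 1) or over the published explicit
  ranges (THP pCR 0.32–0.59; residual DDAC + T-DM1 RR of DR 0.28–0.55; DR
  annual cost $97,434–$180,948).
- The adjuvant-HP scenario requires the pertuzumab cost increment as user
  input (no default is invented); it is charged to the pCR branch only, since
  the adjuvant-H price key is shared with strategy 1's residual branch.
- ER-subgroup runs require user-supplied ER-specific pCR rates; only the
  T-DM1 distant-recurrence RR defaults to the ER-specific estimates
  (0.48 ER-positive, 0.50 ER-negative).
- Problem sizes: the acceptance script runs the full 51-cycle model for all
  ten branches and a 1000-iteration PSA; the in-suite oracle comparison uses
  200,000 microsimulated patients per branch.

## Known limitations

- Base-case discounted costs land ~5–15% below the originally published
  totals while QALYs and all orderings match closely; the gap is consistent
  with the original analysis crediting full first/last cycles of
  distant-recurrence care (no half-cycle correction) and using a lighter
  real-world life table than the fixture. Conclusions (dominance of
  strategy 3, sensitivity robustness, acceptability probabilities) are
  unaffected.
- Constant lifetime recurrence hazards (no cure fraction or risk window);
  no tunnel states beyond the first-year/subsequent-year distinctions.
- Adjuvant endocrine therapy, treatment discontinuation, and adherence are
  out of scope; PSA parameters are sampled without correlation structure.
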