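# Methods

## Model structure and assumptions

The model is a deterministic Markov cohort simulation with a 1-month cycle,
a lifetime horizon, and four states: BRIDGE, POST_ICD, DEAD_CARDIAC,
DEAD_OTHER. The cohort starts 100% in BRIDGE at age 61. The bridge lasts
exactly one cycle; survivors are reimplanted and move to POST_ICD, from
which they can return to BRIDGE through a new device infection. Both
treatment arms (WCD vs low-intensity hospital stay) share identical clinical
dynamics — the equal-efficacy assumption that defines a cost-minimization
analysis — so a single cohort trace serves both arms and every cost
difference is attributable to unit costs alone.

Mortality is decomposed into (a) general-population mortality from an
annual life table, increasing with age, looked up at the floored age and
converted to a monthly probability on the hazard scale
(`1 − (1−q)^(1/12)`), and (b) a constant monthly excess cardiac death
probability representing the cardiac risk of an ICD population. The excess
is calibrated once at the cohort start age from trial summaries: trial
cumulative mortality → constant monthly hazard, minus the background hazard
at the start age (floored at zero), scaled by the SCD-attributable
fraction, and converted back to a probability. Holding it constant while
background mortality rises means the SCD share of total mortality falls
with age. The calibration arithmetic is one defensible scheme; the source
trials' figures are not part of the package's inputs, so the default excess
(0.0033/month) is a placeholder on that scheme's scale.

### Combination of competing monthly risks

Within the bridge month, SCA death (`p_sca × (1 − event_survival ×
vtvf_termination)`), excess cardiac death and background death are treated
as independent and combined on the complement scale; survivors then face
procedural death at reimplantation. SCA, excess and procedural deaths are
classed cardiac; background deaths non-cardiac. In POST_ICD the listed
monthly probabilities are marginal and mutually exclusive (cardiac `q_ex`,
other `q_bg`), with reinfection drawn among death survivors; heart-failure
hospitalization is drawn among death survivors (including those about to be
re-explanted), lead failure only among patients remaining in POST_ICD.
The source publication does not state its combination rule; these choices
are deliberate, documented, and mirrored exactly by the microsimulation.
At the life table's terminal age the background monthly probability is 1
and the POST_ICD row degenerates to certain death (cardiac share `q_ex`);
elsewhere, marginal death probabilities summing above 1 raise an error.

### Generator replacement

The generator is replaced at exact multiples of the battery life (60
months; no failures are possible before month 24, so a deterministic
60-month life satisfies that constraint trivially) after each
(re)implantation, as a pure cost event; replacement and reinfection both
reset the implant clock. Because exit from POST_ICD is memoryless given
the cycle, each reimplantation sub-cohort's survival in state is the ratio
of a single cumulative stay-probability product, so expected replacement
counts are computed exactly rather than through a cohort-mean
implant-time approximation; the microsimulation confirms the two engines
agree within Monte-Carlo error.

## Costs and discounting

Costs are in euro (Italian NHS perspective) and accrue at cycle start with
no half-cycle correction; cycle 0 is undiscounted and cycle t is weighted
by `(1.03)^(−t/12)` at the default 3%/year rate. The bridge is charged per
episode (per entry into BRIDGE): €3600 for the WCD, €250/day × 21 days =
€5250 for the stay. Reimplantation is charged per successful
BRIDGE→POST_ICD transition; heart-failure stays, lead revisions and
generator replacements per expected event; and a monthly management cost
per POST_ICD cycle. Reinfection re-entries re-incur the arm's episode cost
and a new reimplantation at the standard implant tariff (no separate
explant-procedure cost is modelled; the source is silent on one).

### Default parameter values

Main-text inputs carry their published values: WCD €3600/episode, stay
€250/day × 21 days, discount 3%/year, start age 61, event survival 0.855,
VT/VF termination 1.0, battery life 60 months (≥24 failure-free), bridge
SCA risk 5% (midpoint of the 4–6% band reported for explanted patients).
Inputs published only in supplementary material are config entries with
placeholder defaults on the scale of their cited sources: procedural death
0.005, excess cardiac mortality 0.0033/month, HF hospitalization
0.005/month, reinfection 0.0008/month (≈1%/year, registry scale), lead
failure 0.0008/month, implant tariff €16 000, generator replacement €9500,
HF stay €4000, lead revision €6500, post-ICD management €450/month. These
were fixed once from the cited literature families and are not fitted to
the published cost table; with them the base case lands at −€1863.92
(−€1811.21 discounted) against the published −€1822.58 (−€1782.40), and
the published rounded sensitivity figures (€2800, €810, €3500) are
reproduced within their rounding. Supplying the exact supplementary values
through a config reproduces the published table by construction.

## Analyses

- **Base case**: both arms on the shared trace; delta = WCD − standard
  (negative = WCD saves). The expected lifetime number of bridge episodes
  per patient (≥1; >1 with reinfection) is exposed because
  `delta = (episode-cost gap) × episodes`, which makes any gap between the
  delta and the single-episode cost difference diagnosable.
- **One-way sensitivity**: 13 evenly spaced points over ±30% of a
  parameter's base value (the grid always contains the baseline);
  probabilities are clipped to [0, 1]. Delta is exactly affine in each
  episode cost, with slopes of equal magnitude and opposite sign equal to
  the discounted episode count.
- **Threshold**: the standard-care episode cost at which the discounted
  delta is zero, solved from the affine relation by a two-point line solve
  (a bisection cross-check is in the tests). Structurally it equals the
  WCD episode price, independent of all other parameters.
- **Tornado**: delta at both ±30% extremes per parameter, ranked by spread.
  Parameters affecting both arms identically have spread exactly 0; the two
  episode costs dominate.

## Synthetic data and validation

The life-table generator uses a Gompertz–Makeham hazard
`q(age) = 1 − exp(−(a + b·e^{c·age}))` with defaults (a = 1e-4, b = 4e-5,
c = 0.09/yr) giving ≈1% annual mortality at 61 rising to ≈8% at 85 — the
shape of an adult high-income-country schedule — forced to 1 at the
terminal age 110 (the lifetime-horizon cap). The parameter-set generator
draws all probabilities and costs uniformly from documented plausible
ranges (SCA risk 4–6%, event survival 0.83–0.88, costs ±30% of defaults),
reproducibly by seed. Synthetic data emulate the statistical structure the
analysis assumes — monotone adult mortality and plausible parameter
magnitudes — not any real population's correlations between parameters, so
passing tests demonstrate internal correctness of the engine and analyses,
not the accuracy of any particular national input set.

The microsimulation oracle re-implements the transition, event and cost
rules by sequential per-path pseudo-random draws (vectorized over paths)
without reusing the engine's matrices. At the default validation budget of
100 000 paths (a few seconds on one CPU) the cohort engine's discounted
cost lies within 3 standard errors of the Monte-Carlo mean, occupancy
agrees at binomial-error scale, and the exact replacement accounting is
confirmed.

## Numerical choices and limitations

Row sums are enforced to 1e-12 when building matrices and 1e-9 along the
trace; the run stops when the alive fraction falls below 1e-9 or the
terminal age is reached. The threshold solver requires a nonzero bridge
occupancy (always true for a cohort starting in BRIDGE). Monetary outputs
are printed to cents; JSON keeps full precision.

Known limitations: no individual heterogeneity in the cohort engine (only
the oracle has it); no time-varying excess cardiac mortality; no
probabilistic sensitivity analysis, QALYs or ICERs (out of scope for a
cost-minimization design); the monthly bridge is a single cycle, so
bridging periods longer than one month are not represented.
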