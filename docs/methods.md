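# Methods

This note documents the modeling choices behind `safeward`: what each
stage assumes, where the numbers come from, which decisions were
genuinely open, and what the synthetic data can and cannot show.

## Surveillance data and underreporting

The descriptive stage works on two event streams from the same ward and
window: official accident reports (CAT forms) and questionnaire
self-reports. The two streams share no linkage keys, so underreporting
is measured by differencing totals — `max(self − official, 0)` — never
by record-level matching. With the study ward's totals (93 self-reports,
71 official reports over seven years) the gap is 22 events.

Percentages are rounded half-away-from-zero. This convention reproduces
every printed surveillance figure from the raw counts: the official
cause mix {33, 16, 11, 7, 4}/71 gives {46, 23, 15, 10, 6} % at zero
decimals, and the self-reported aggression and fall shares 58/93 and
23/93 give 62.37 % and 24.73 % at two decimals. Banker's rounding would
not (16/71 → 22.5 ≈ 23 only under half-away).

Annual rates use exact ratios: the baseline official rate is 71/7 =
10.142857… injuries/year and is never carried as a pre-rounded 10.14 —
at the two-decimal precision of the scenario outputs, rounding the
baseline would visibly corrupt the deltas.

## Safety indicators

The 23 indicators are ordinal 0–100 scores banded
very poor (0–20), poor (21–40), intermediate (41–60), good (61–80),
excellent (≥ 81). Integer band edges are inclusive of the band below —
a score of exactly 20 is *very poor* — which is the only convention
consistent with the ward's lowest-scoring indicators (e.g. "Protocols"
at 20) being reported among the critical red group. Non-integer scores
(none occur in the shipped table) follow the same closed-upper-bound
rule. Banding the 23 shipped results yields the tally
{excellent 3, good 5, intermediate 5, poor 5, very poor 5}; the
five-indicator intermediate group is the figure asserted in tests, as
it is the only whole-collection tally that is also stated narratively
in the source material's summary of the indicator results.

## Causal-loop structure

The causal diagram is encoded from the loop narratives, signing edges
on underlying quantities (SOP coverage, procedure-execution quality)
rather than on "absence of X" variables, which avoids double-negation.
Four feedback loops result:

* **R1, R2** (reinforcing) share the stress→performance→behavior tail:
  uncontrolled patient behaviors raise aggression risk and incidents
  (R1) and perceived injury risk, tension and alertness (R2); both
  paths raise staff stress, stress degrades performance, and degraded
  performance lets behaviors escalate. Sharing the tail is what keeps
  the enumeration at exactly two loops here instead of four
  cross-combinations.
* **R3** (reinforcing) is narrated as an open chain — safety resources
  → training → PPE use → fewer physical/chemical/biological hazards →
  fewer related injuries. It is closed with a single edge, injuries
  →(−) safety resources (the injury burden strains the safety budget),
  the minimal closure under which the loop exists and carries its
  stated reinforcing polarity.
* **B1** (balancing) is the incident-management control loop:
  aggression incidents →(+) incident reporting →(+) mitigation
  capacity →(+) behavior-management procedures →(−) aggression
  incidents. A literal "vicious circle" encoding of the underreporting
  narrative (more aggression → more underreporting → less capacity →
  fewer procedures → more aggression) necessarily has a positive sign
  product — flipping any variable's sense flips exactly two incident
  edge signs, so no re-encoding can make that cycle balancing. The
  loop's conventional *B* designation instead describes the stabilising
  reporting→response loop that underreporting attenuates; we encode
  that loop, and tag the incidents→reporting edge `underreporting` so
  the attenuation can be studied structurally (removing it disables
  exactly B1).

Loop enumeration delegates to networkx's bounded simple-cycle search;
cycles are canonicalized to start at their lexicographically smallest
variable and sorted, so output order is deterministic. Tests
cross-check against an exhaustive permutation search.

## The stock-and-flow engine

Explicit Euler at fixed step: auxiliaries are evaluated in topological
order from start-of-step state, all flow rates are read before any
stock is updated, and `stock(t+dt) = stock(t) + dt·(net flow)` holds
exactly at every step. The default grid is one year of monthly steps
(t₀ = 0, horizon 12, dt = 1). Algebraic loops among auxiliaries are an
error naming the cycle, not a fixed-point iteration — the ward model
has none, and failing fast surfaces specification bugs. Expressions use
a deliberately small grammar (`+ − * / **`, unary sign, `exp`, `min`,
`max`, parentheses, numbers, declared names) parsed through Python's
`ast` with a strict whitelist; anything else is rejected at model
construction. The unit checker enforces flow unit = stock unit / time
unit for every flow–stock pairing. No delay, smoothing, lookup-table or
stochastic primitives are provided: the ward model needs none.

Being first-order, Euler's global error is O(dt); the tests verify the
error against e^{−t} halves when dt halves. For the ward model this is
immaterial — at baseline the flows are constant in time, so Euler is
exact.

## The ward model and its calibration

The literal equation table of the original ward model is not available;
the model is reconstructed as the *minimal* set of response functions
exactly determined by the reported scenario anchors:

* behavior → injury rates: quadratic in (b−1). Two anchors per stream
  — official (+1.68 at b=1.10, +4.28 at b=1.25) and self-reported
  (+2.31, +5.78) — determine (a, c) and (a_s, c_s) exactly via a 2×2
  linear solve. A linear response cannot fit either pair, a quadratic
  fits both exactly; nothing in the anchors supports more structure.
* SOP coverage → injury reduction: saturating exponential
  D_max(1 − e^{−k·Δs}). The two anchors (−5.71 at Δs=0.20, −6.85 at
  Δs=0.40) give the closed form 1 + e^{−kΔs₁} = d₂/d₁ because the
  second abscissa doubles the first: k = 8.0560, D_max = 7.1344
  injuries/year. Saturation is the natural shape here — early SOPs
  cover the riskiest activities; marginal coverage buys less.
* PPE use → perception: linear, β = (89.35 − 76.48)/10 = 1.287
  perception points per percentage point of proper use, from the single
  reported anchor.
* SOP coverage → perception: same saturation constant k as the injury
  family, amplitude R_max = (89.35 − 72.68)/(1 − e^{−0.2k}) = 20.828
  points fitted from the 30 %-coverage anchor **only**. The
  50 %-coverage perception value (69.35) is held out of calibration
  entirely and recovered as an out-of-sample prediction (69.3518),
  which is the substantive validation of the shared-k assumption.
  Independently fitting k from the two perception anchors gives
  k′ = 8.0532, within 0.04 % of the injury-family k.

Remaining free choices, and why:

* The self-report stream has no SOP anchor of its own; its SOP
  reduction is the official reduction scaled by S₀/A₀ = 93/71. This is
  an assumption of proportional underreporting across the intervention,
  not a fitted quantity.
* Baseline overall perception R₀ = 89.35 % is **not** the unweighted
  mean (91.48) of the five per-hazard perception rates {100, 100, 93,
  93, 71.4}; the aggregation weights of the underlying instrument are
  unknown, so R₀ is carried as a measured constant and hazard
  components are reported descriptively, never summed. PPE shifts only
  the biological/chemical/noise components; perception of aggression
  and ergonomic load is untouched.
* The reinforcing stress loops are represented structurally in the
  causal diagram but not closed quantitatively: the behavior multiplier
  is an exogenous scenario input, because no anchor pins a stress →
  behavior response.
* Rates floor at zero and perception clamps to [0, 100]; no scenario in
  the standard suite reaches either bound.
* Combined overrides (changing PPE and SOP together) add their
  perception effects in percentage points. The standard suite never
  combines inputs, so this is an extrapolation and the CLI labels
  custom overrides as such.

In the stock-and-flow form, cumulative official injuries and cumulative
self-reports accumulate from constant monthly inflows (annual rate/12);
an auxiliary tracks the running underreported count (self − official),
which over a simulated seven years reproduces the observed gap of 22.
Annualized rates from the trajectory equal the closed-form responses to
1e-9, and the assembled model passes the unit checker with zero
violations.

## Scenario reporting

Each scenario is simulated against a baseline run under an identical
engine configuration; deltas are scenario − baseline (increases
positive). The whole-accident "equivalents" are reported under **both**
conventions found in surveillance write-ups — half-away-from-zero
rounding (1.68 → 2, 5.78 → 6) and ceiling (4.28 → 5, 2.31 → 3) —
because neither alone covers all the narrated integers; the unrounded
delta is always the primary output.

## Synthetic data: what it does and does not emulate

The generator draws true events as a Poisson stream (default 93/7
events/year over 7 years), assigns causes multinomially from the
observed mix (aggression 0.46, falls 0.23, sharp objects 0.15,
commuting 0.10, ergonomic 0.06), stamps a uniform month, and thins
events into the official register with reporting probability 71/93 —
making official records a subset of self-reports, the simplest
mechanism consistent with underreporting as reluctance to report.
Gender is Bernoulli (0.69 female, the observed share); occupation is a
70/30 technician/nurse mix (the ward's composition is not published;
this is a typical Brazilian ward staffing ratio). Questionnaires use
independent Bernoulli hazard answers at the observed rates
{1.0, 1.0, 0.93, 0.93, 0.714}, normal age/tenure around the observed
means (36 and 7 years, sd 8 and 4, clipped to plausible ranges), a 0.5
probability of any injury history, and shifted-Poisson self-report
counts scaled to the stream total.

Deliberately not modeled: within-month timing, shift/roster structure,
patient-level aggression dynamics, correlation between hazard answers,
and any cause-dependent reporting probability (in reality aggression
injuries are the *most* underreported category; the generator thins all
causes equally). Tests that recover generator parameters therefore
validate the estimators' arithmetic, not the realism of any of those
simplifications.

Monte-Carlo checks run at ~10,000 events / 10,000 respondents and
assert recovery within 3 standard deviations of the exact
binomial/multinomial sampling distributions; at the default desk-scale
sizes the same 3-sigma bands are used around the Poisson/thinned-Poisson
means. All generator randomness flows through one seeded
`numpy.random.Generator` (the questionnaire stream uses seed+1 so the
two outputs are independent but jointly reproducible).

## Problem sizes and determinism

Everything here is desk-scale: the scenario suite is five simulations
of a two-stock model over 12 monthly steps and completes in well under
a second; the largest test inputs are the 10,000-event recovery checks.
The calibration, the engine and the scenario suite are fully
deterministic; only the synthetic-data stage consumes a seed.
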