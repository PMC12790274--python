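# Methods

## Decision problem and strategies

The package evaluates one-off opportunistic osteoporosis screening: an AI
read of a chest radiograph already acquired for another clinical reason,
versus no screening, in South Korean adults aged 50 and over. The screening
arm's decision tree is: AI flag (Bernoulli with the tool's sensitivity for
diseased and 1 − specificity for non-diseased individuals) → confirmatory
DXA attendance (60%) → treatment initiation (50%). DXA is modelled as a
perfect reference: it is the diagnostic gold standard and no error rates are
modelled for it, so false-positive AI flags incur DXA cost but can never
lead to treatment. The AI read cost (KRW 15 000, 30% of a DXA) is charged to
every screened person whether flagged or not; the radiograph itself is free
because it exists anyway. Screening happens once, at model entry.

## Microsimulation

Individuals are simulated in annual cycles from entry age to death or age
105. Within a cycle, in order:

1. **Fractures.** Hip, vertebral and NHNV events are sampled independently
   (several sites may fracture in one year). The per-site rate is
   baseline incidence(sex, site, 10-year age band) × T-score relative risk
   (if osteoporotic) × subsequent-fracture multiplier (a function of years
   since the last fracture and the number of prior fractures) × residual
   treatment relative risk; rates convert to probabilities as
   `1 − exp(−rate)`.
2. **Death.** Background life-table probability qx plus attributed excess:
   in the cycle of a hip or vertebral fracture an additive first-year excess
   probability; in later cycles qx × (decaying hazard ratio − 1). Both are
   multiplied by the attribution fraction (0.25); NHNV fractures carry no
   excess.
3. **Costs.** First-year fracture costs per event (costs are charged per
   event even when several sites fracture; only utility is capped at the
   most severe). A hip fracture triggers permanent nursing-home admission
   with probability 0.10; nursing-home costs (365 × KRW 8 103) accrue from
   the admission year onward. While on treatment: annual drug cost,
   monitoring visits (alendronate 4 physician + 4 pharmacy + 1 DXA per year;
   denosumab 2 + 2), and alendronate adverse-event costs (0.041 extra GP
   visits in the first 6 months, 0.021 per later 6-month period, each with a
   PPI prescription).
4. **Utility.** Baseline age utility (linear interpolation between the
   5-year knots, held constant beyond the age-90 knot) times a post-fracture
   multiplier: in a fracture year the first-year multiplier of the most
   severe site fractured that year (severity order hip > vertebral > NHNV);
   in all later years the subsequent-year multiplier of the most severe site
   ever fractured. A re-fracture restarts the first-year multiplier. Death
   contributes half a cycle of utility and life-years (mid-cycle
   convention).
5. **Discounting.** Costs and QALYs are discounted at the cycle midpoint,
   `(1 + r)^-(t + 0.5)` with r = 0.045; upfront cascade costs are charged
   undiscounted at entry. Life-years are reported undiscounted.
6. **Clock advance.** Age, fracture-history clocks and treatment clocks
   advance; treatment discontinuation is evaluated at year boundaries with
   conditional probability `1 − S(k)/S(k−1)` from the drug's persistence
   table, and a forced stop at 5 treated years.

**Treatment effect and waning.** On treatment the drug's full per-site
relative risk applies. After discontinuation the risk reduction wanes:
linearly over the completed treatment duration for alendronate, linearly
over one year for denosumab (a step-at-one-year variant is selectable).
The waning clock is evaluated at the cycle midpoint, so the first year after
stopping retains on average half the effect under one-year waning. The
residual effect never rebounds above baseline.

**Persistence tables.** Alendronate: 73.2% at year 1, 33.6% at year 2,
constant thereafter. Denosumab: 67% at year 1, 35% from year 3 onward; the
unpublished year-2 value is linearly interpolated (51%).

**Drug efficacy.** The packaged relative risks follow the tabulated values
(alendronate 0.67/0.45/0.81 for hip/vertebral/NHNV; denosumab
0.60/0.32/0.80). An alternative source gives alendronate's vertebral
reduction as 44% (RR 0.56) rather than 55%; the tabulated 0.45 is the
default and the alternative is selectable through the config — the two are
deliberately not reconciled.

## Common random numbers

All uniforms (three fracture sites, death, nursing-home admission,
persistence per person-cycle, and four cascade draws per person) are
pre-drawn from labelled child streams of one master seed and shared between
the two strategy arms. Treatment changes event *thresholds*, never the
*draws*, so an individual's trajectory in the two arms diverges only where
treatment actually flips an event. With screening effects disabled the arms
are bit-identical, and paired incremental standard errors are an order of
magnitude smaller than the arm-mean errors. Cohorts above 125 000 are
simulated in blocks with independent child streams to bound memory; a scalar
per-person path consumes the same streams in the same order as the
vectorised cohort path and agrees with it bit-for-bit (tested).

## Synthetic stand-in inputs

Four model inputs come from national sources that publish no
machine-readable tables. The package generates flagged stand-ins
(`source: "synthetic stand-in"`, listed in every run manifest):

* **Life tables** — Gompertz–Makeham hazards
  (A + B·exp(c·(age − 50))), calibrated so that remaining life expectancy at
  50 is ≈ 36 years for women (A = 3·10⁻⁴, B = 1.474·10⁻³, c = 0.105) and
  ≈ 31 years for men (A = 6·10⁻⁴, B = 3.239·10⁻³, c = 0.095), in line with
  recent Korean period life tables. qx is forced to 1 at age 105.
* **Population structure** — 5-year age-band weights skewed toward 50–69
  with a thin 90+ tail (mass: 0.17/0.165/0.16/0.145/0.115/0.09/0.08/0.05/
  0.018/0.006/0.001 from 50–54 to 100–104), 53% female; ages uniform within
  a band.
* **Post-fracture excess mortality** — first-year additive excess death
  probability 0.10/0.15 (women/men) after hip and 0.04/0.06 after vertebral
  fracture; long-term hazard ratio declining linearly from 1.8 to 1.0 over
  10 years; attribution 0.25.
* **Subsequent-fracture multipliers** — RR 2.0 within 2 years of the last
  fracture, 1.5 in years 3–5, 1.2 beyond, +0.2 per prior fracture beyond the
  first, capped at 4.0.
* The **PPI unit cost** per adverse-event episode (KRW 10 000) is likewise a
  configurable stand-in.

These magnitudes are order-of-magnitude plausible for the setting, but they
are not the source values: absolute results (ICERs in KRW) carry their
uncertainty. The structural conclusions the tests assert — threshold
position of the base-case ICER, women < overall < men ordering, gains from
age-specific prevalence, monotone improvement with DXA uptake and treatment
initiation — are robust to reasonable variation in these stand-ins, which is
why the acceptance surface is phrased as bounds and orderings rather than
point reproduction.

## Sensitivity analyses

**One-way.** Scenarios edit the parameter bundle through dotted config paths
and re-run the paired cohort with the same roster and master seed, so
scenario differences are parameter-driven. The packaged set covers DXA
uptake 40–80%, treatment initiation 30–70%, AI cost ±50%, incidence ±20%,
fracture costs ±20%, fracture disutility ±20% (scaling the decrement
1 − multiplier, which keeps multipliers within bounds), excess mortality
±50%, drug cost ±20%, drug efficacy ±20% (scaling 1 − RR), single-drug
strategies, the ≥ 70 subgroup, and male prevalence 7.5/12.2/15%. Output is
ordered by each scenario family's ICER span (tornado convention).
Prevalence scenarios re-draw osteoporosis flags with the same seed, so
raising prevalence flips marginal individuals rather than resampling.

**Probabilistic.** Each outer draw perturbs: incidence rates and
post-fracture utility multipliers via beta distributions moment-matched to
(mean = base, SD = 10% of mean), except the utility multipliers, whose SDs
come from the packaged 95% confidence intervals ((hi − lo)/3.92); the
multiplier betas are scaled to [0, 1.1] so the NHNV subsequent-year interval
(upper limit above 1) remains reachable. Costs are normal with 10% CV,
truncated at zero; treatment RRs are log-normal with median at the base
value and 10% CV, capped at 1. Draws are independent across parameters;
cascade probabilities (DXA uptake, initiation) stay at base-case values —
they are decision variables explored in the one-way analysis. A single
dispersion scale multiplies every SD; at zero the PSA degenerates exactly to
the base case. The CEAC reports the fraction of draws with
wtp·ΔQ − ΔC ≥ 0 (ties count as cost-effective).

## Numerical conventions and edge cases

* Annual recurring costs (drug, monitoring, nursing home) are charged for
  the full cycle even when the person dies mid-cycle; fracture event costs
  are likewise charged in full. Only utility and life-years take the
  half-cycle death credit.
* Age bands are half-open ([50, 60) … [80, 105)); band lookup uses current
  integer age each cycle.
* Fracture-history clocks: the year of an event counts as year 0; the
  multiplier seen in the next cycle corresponds to one year since fracture.
* The dominance classification of (ΔC, ΔQ) is weak: zero ΔC with positive
  ΔQ counts as dominant, zero ΔQ with positive ΔC as dominated, and the
  degenerate (0, 0) is labelled indifferent.
* Config round-trip: YAML/JSON mappings merge onto packaged defaults with
  unknown keys rejected; dotted-path overrides apply last; the resulting
  bundle must pass `validate()` (which returns violations as data).

## Verification

A deterministic forward cohort recursion (`oracle.cohort_expected_value`)
computes exact expected outcomes under a history-independent restriction
(subsequent-fracture multipliers ≡ 1, excess mortality off, everyone
persisting to the forced stop); it tracks the utility-relevant
most-severe-site chain exactly and is implemented independently of the
simulation loop. The test suite checks the microsimulation against it at
3-Monte-Carlo-SE tolerance, the stochastic cascade against its closed form,
null-model identities (screening disabled ⇒ bit-identical arms; attribution
0 ⇒ life-table survival), scalar-vs-vector bit equality, determinism,
monotonicity properties, and the threshold/ordering claims. Problem sizes
used: 100 000 individuals for threshold and oracle checks, 500 000 (run in
blocks) for the strict monotonicity of the follow-up grids where adjacent
ICERs differ by well under 10%, 200 × 10 000 for the PSA.

## Limitations

* Life tables, population weights, post-fracture mortality and recurrence
  multipliers are synthetic stand-ins; absolute ICERs should be read as
  regime-level, not point estimates of the source setting.
* One screening event per lifetime; no repeat or interval screening.
* No treatment switching or re-initiation; drug assignment is fixed at
  initiation.
* DXA is error-free; untreated confirmed cases incur no follow-up costs.
* Only the most severe fracture affects utility in a given year (costs are
  additive), and fracture sites beyond hip/vertebral/NHNV are not modelled.
* Payer perspective, KRW 2025, no currency conversion or inflation
  machinery.
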