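# Methods

## Model structure

The analysis couples a decision tree (the screening cascade) to a Markov
cohort model. The decision tree converts cascade counts — screened,
suspected, radiographed, confirmed by severity, braced — into each
strategy arm's entry conditions: a per-person occupancy vector over six
health states (no AIS, mild, moderate braced, moderate unbraced, severe
awaiting surgery, post-operative stable) plus an up-front per-person cost.
The Markov model then propagates the cohort over 16 quarterly cycles
(4 years, the adolescent growth window to skeletal maturity). There is no
death state and no incidence after entry: the no-AIS and post-operative
rows of the transition matrix are identity, so the post-operative state is
absorbing and occupancy is conserved exactly.

Diagnosed and undiagnosed occupants of the same health state are tracked
as separate strata. Undiagnosed individuals progress under the same
natural-history probabilities but accrue no diagnosis-dependent costs (no
radiograph, no brace, no follow-up) and cannot be braced; when they reach
the severe state they are assumed to present clinically, transfer to the
diagnosed stratum, and enter the surgical pathway. This clinical-
presentation rule is a switch (`clinical_presentation_at_severe`, default
on); with it off, undiagnosed severe cases remain severe and never incur
surgery. The default is on because without it the no-screening arm could
never incur surgical costs, removing the cost-offset mechanism the
comparison is about.

## Entry conditions

True disease prevalence among the screened cohort is imputed as
`confirmed + (suspected − radiographed) × PPV_xray` over the cohort size:
suspected adolescents who never completed radiography are assumed diseased
at the radiographic positive-predictive rate (≈ 51%), giving ≈ 620 true
cases (1.18%) against 172 confirmed. The severity mix of undetected cases
follows the confirmed-case proportions (118:41:13).

* **Screening arm** — confirmed cases enter diagnosed (moderate split by
  the 0.902 brace-initiation probability); undetected cases enter
  undiagnosed; everyone else is disease-free. Up-front cost: screening
  organisation (9,269.07 US$ program-wide, 0.176 US$/person) + one
  radiograph (50.544 US$) per completed confirmation + one brace
  (772.20 US$) per initial initiation, averaged over the cohort.
* **No-screening arm** — the same true-disease mass enters; a fraction
  θ_miss = 0.30 is permanently undiagnosed (confirmed-case severity mix),
  the rest is diagnosed at entry with the first-presentation mix
  π = (0.235, 0.521, 0.244), moderate cases braced at 0.902. Up-front
  cost: one radiograph per diagnosed case plus entry brace initiations.
  Charging the entry braces here is this package's choice — the diagnosed
  moderate cases start in the braced state, and an uncharged brace would
  make the comparator's treatment free by construction.

Disease mass at entry is identical across arms to 1e-12 (property-tested);
only diagnosis status and severity mix differ. Opportunistic diagnoses all
occur at entry rather than spread over the horizon — a simplification, as
no diagnosis-timing distribution is available; it front-loads the
comparator's follow-up costs slightly.

## Transitions, hazards, and intervention effect

All published probabilities on other timescales are converted with exact
constant-hazard formulas (never the linear approximation): the 0.90/year
severe-to-surgery probability becomes 1 − 0.10^0.25 = 0.4377 per quarter,
and the bracing hazard ratio 0.45 maps the unbraced quarterly
moderate-to-severe probability 0.0877 to 1 − (1 − 0.0877)^0.45 = 0.0405.
Mild-to-moderate progression is 0.0164/quarter; diagnosed mild cases
progressing to moderate are braced with probability 0.902 (brace cost
charged at initiation), undiagnosed ones land unbraced. The per-cycle
surgery probability enforces a surgical wait of at least one cycle because
departure from the severe state is never instantaneous.

## Accounting conventions

Costs and utilities are discounted at 5%/year at **cycle start**: cycle k
carries (1.05)^(−k/4), cycle 0 undiscounted, with no half-cycle
correction. A full-health cohort therefore accrues
0.25 · Σ_{k=0..15} 1.05^(−k/4) = 3.656086 discounted QALYs, and the
published per-arm QALYs (≈ 3.6551) sit just below this value, which is the
evidence for the convention. Utilities (no AIS 1.0, mild 0.95, moderate
unbraced 0.95, moderate braced 0.87, severe 0.76, post-operative 0.82) are
constant within a cycle; undiagnosed occupants use the same utilities as
their diagnosed counterparts (the braced state is unreachable while
undiagnosed). Per-cycle follow-up costs (52.51 US$ screening arm,
26.25 US$ no-screening arm) accrue to diagnosed occupants of the mild,
moderate and severe states only — not no-AIS, not post-operative, whose
care is taken to be covered by the surgical episode. One-time costs
(surgery, in-model brace initiations) are charged on the transition mass
at the destination cycle's discount factor. Computation is in US dollars
throughout; renminbi reporting divides by the 0.1404 US$/CNY rate at the
presentation layer (by default after 2-dp rounding, matching how published
tables chain conversions; an unrounded path is available).

**Surgery cost.** The source tables print two irreconcilable values,
1,965.60 and 19,656 US$ per case. This package defaults to 1,965.60 US$:
with it the base case lands at 9.81 vs 15.34 US$/person, on the published
order of magnitude (18.03 vs 26.18) with the published sign structure
(screening dominant, ΔC < 0, ΔQ > 0); with 19,656 the arms cost 63 and
100 US$/person, several-fold above every published total. The higher value
remains one override away (`--param c_surgery=19656`).

## Parameter uncertainty

Each uncertain parameter carries a distribution spec (beta, gamma,
lognormal, or Dirichlet). "±20%"/"±50%" ranges resolve to
(b(1−r), b(1+r)); all ranges are interpreted as 95% intervals for moment
matching — beta/gamma match mean = base, sd = span/3.92; lognormal matches
median = base with the bounds a 95% interval on the ratio scale (the
source never states the interpretation; a 95% reading keeps the stated
bounds meaningful for skewed families). Dirichlet concentrations are
base × 172, the confirmed-case count, exposed as `dirichlet_ess`.
Infeasible beta moments collapse to a point mass with a warning.

The tornado analysis perturbs each scalar parameter to its bounds with
everything else at base, re-deriving dependent per-cycle probabilities
from the perturbed primitive (never perturbing a derived quantity
independently); bounds that violate the unit interval are clipped and
logged; entries sort by descending INMB span with alphabetical
tie-breaks. The PSA samples all parameters independently per iteration
(each severity triple as one Dirichlet draw), re-derives, and evaluates
the full model; 3,000 iterations by default; the acceptability curve is
computed from the same draw set on a 100-point grid from 0 to 3× the WTP
threshold. The default seed 20250512 is recorded in output manifests; any
seed is accepted.

## Calibration

The no-screening arm's (θ_miss, π) are fit by maximum likelihood against
anchors: a binomial log-likelihood for the anchored diagnosed fraction
(0.70) under 1 − θ_miss, plus a multinomial log-likelihood for anchor
severity counts under π, with effective sample sizes (default 172)
setting the weights. The published account names maximum likelihood but
not the likelihood; this binomial-plus-multinomial construction is this
package's own, documented choice. The search is a coarse grid (θ step
0.01 on [0.15, 0.50]; simplex lattice step 0.05) followed by Nelder-Mead
refinement in logit/log-ratio coordinates; the returned objective always
dominates every grid evaluation, and boundary maximizers are flagged.
Validation rebuilds the calibrated arm and reports the implied
opportunistically-diagnosed fraction (≈ 0.82% of the cohort) next to the
0.326% screening-detection anchor. That check fails its default 25%
tolerance by construction — the anchor was measured *under screening* —
and is reported as a soft diagnostic, not an error.

## Synthetic data and what it does (not) show

`generate_cascade` draws individual records with the cascade's assumed
statistical structure: Bernoulli suspicion (≈ 0.023), Bernoulli
radiography completion (0.2775), Bernoulli confirmation (≈ 0.512),
categorical severity (118:41:13), Bernoulli brace uptake (0.902).
`microsimulate` walks individuals through the quarterly transition
probabilities with the cohort engine's exact accounting conventions and
serves as its stochastic oracle: at 200,000 individuals the per-person
mean cost and QALY agree with the cohort model within Monte-Carlo error
(tested at 3 standard errors). Both use one seeded NumPy generator per
cohort with vectorized draws, so a fixed seed reproduces a cohort
bit-for-bit. The generator emulates only the cascade's *statistical*
structure — no covariates (age, sex, curve location), no measurement
error in the screening tests, no within-person correlation between
cascade stages beyond the modelled conditioning — so passing tests show
internal consistency of the pipeline, not fidelity to any real program's
individual-level data.

## Problem sizes

The default test suite runs the cohort model at its analytic size
(it is a 6-state matrix recursion, essentially free), the PSA at 3,000
iterations, the microsimulation oracle at 200,000 individuals, and the
synthetic-cascade recovery at the program's 52,678; the whole suite
completes in a few seconds.

## Known limitations

* Opportunistic diagnoses occur at model entry, not over time.
* No background mortality, no age/maturity heterogeneity, no
  time-varying brace adherence, no psychosocial harms of labelling.
* The true prevalence among radiography non-completers is imputed at the
  radiographic PPV — an assumption, not an observation.
* The published scenario claim that weaker routine diagnostic capacity
  (higher θ_miss) makes screening *more* favourable does not hold in this
  reconstruction: because undiagnosed cases accrue no diagnosis-dependent
  costs, raising θ_miss removes expensive managed cases from the
  comparator and lowers screening's INMB (scenario A INMB 25.96 vs B
  7.87 US$; both remain dominant). Reversing this would require the
  avoided-surgery term to dominate (e.g. the 19,656 US$ surgery cost),
  which is inconsistent with every published per-arm total. The tornado
  ranking itself — θ_miss the single most influential parameter — does
  reproduce.
* Under the base case the model's per-arm totals (9.81 / 15.34 US$;
  3.6526 / 3.6510 QALYs) reproduce the published comparison's sign
  structure, dominance and order of magnitude but not its exact figures
  (18.03 / 26.18; 3.655057 / 3.655052); the published cost accounting is
  under-specified (which states accrue follow-up costs, diagnosis timing)
  and internally inconsistent (an abstract increment of −2.32 vs a
  tabulated −8.15 US$).
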