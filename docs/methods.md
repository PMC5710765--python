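# Methods

## Model structure

The physician labour market is a deterministic Markov cohort model:
fractional head-counts move between mutually exclusive career states at
the end of each annual cycle. The system is closed and hierarchical —
doctors enter at the most junior level (intern) and never move to a more
junior state — and the three exits (left Malawi, left the public sector,
left the health labour market) are absorbing: re-entry after leaving is
rare enough in this labour market to be ignored, which is a strong
assumption over a 40-year horizon.

States and conventions:

- **Intern** (1 cycle). Internship in fact lasts 18 months; it is
  modelled as a single cycle. The complement of the intern's exit
  hazards moves to medical officer.
- **Medical officer.** Exposed to exit hazards, to the training offer
  (below), and to a forced transition: anyone still a medical officer at
  the end of career cycle 7 becomes a **generalist** with probability
  one (six years in post after internship). The forced move is applied
  to the stay-complement after the stochastic hazards of that cycle.
- **Pre-training medical officer** — a tunnel of length equal to the
  mandatory-service requirement (2–5 cycles), feeding the registrar
  tunnel of the scenario's training location.
- **Registrar tunnels** (Malawi / sandwich / South Africa), 4 cycles
  each, feeding the matching specialist state. The sandwich location
  mask defaults to Malawi, SA, SA, Malawi (configurable).
- **Specialists** by training location; **generalist**; three absorbing
  exits. Specialists never exit the public sector (they may exit Malawi
  or the labour market).

**Tunnel exposure.** The sources for this model family describe tunnels
both as unexitable and as subject to the health-labour-market exit; we
resolve the ambiguity by exposing all tunnel cycles (pre-training and
registrar) to the mortality/retirement-type exit hazard only — no
emigration or private-sector exit mid-training — which matches the
no-dropout assumption for registrars.

Occupancy rows record the state held *during* a cycle; the transition
closes the cycle. Career cycle `t` counts cycles since the cohort's
entry; the calendar cycle is `entry_cycle + t − 1`. No half-cycle
correction is applied. Internally each tunnel of length `d` expands to
`d` slots and each specialist state to two slots (first post-
qualification cycle, then established) so per-cycle locations and
one-off costs attach to single slots; public traces aggregate back to
the 13 named states.

## Hazards

Hazards are named by origin and destination (`EM_*` exit Malawi, `EPS_*`
exit public sector, `EHLM` exit health labour market, `T_*`/`ET` entry
to training or bonded service) and stored as tables over (career cycle,
cohort); stay probabilities are row complements, so a row is valid iff
its hazard sum is ≤ 1 everywhere. Structure imposed on generated sets:
`EHLM` rises geometrically with career age; junior-doctor and generalist
exits fall with career age; specialist emigration falls both within a
career and across cohorts (the magnet effect of a growing specialist
community) and is ordered SA-trained > sandwich > Malawi-trained.

## Scenarios and uptake

The baseline keeps the current training throughput: a probability
(default 0.07) that an eligible medical officer enters training, split
0.3/0.4/0.3 across Malawi/sandwich/SA registrars ("current training
patterns"; the split is configurable). Each of the 15 interventions
(3 locations × {0,2,3,4,5} service years) replaces this with uptake from
a stated-preference (discrete-choice-experiment) table: for immediate
training the uptake becomes the medical-officer → registrar hazard; with
mandatory service it becomes the hazard into the pre-training tunnel.
Doctors who decline remain medical officers under background hazards.

**Offer timing.** Training is entered from the medical-officer state
only, once per career. Whether the underlying decision is a single offer
or repeats each year is not observable from the published description;
we default to a single offer at the end of career cycle 2 (training is
not entered straight after internship) and expose a `repeated` mode
(offers each cycle 2–7) as a configuration switch. Uptake rates are
constant over the horizon.

## Population

40 cohorts enter one cycle apart, sized 100 + 5·(j−1) (final cohort
295, 7900 entrants). The existing stock (default 325 doctors across
intern, medical officer, generalist and the three specialist states) is
advanced from calendar cycle 1 with career ages consistent with each
starting state (e.g. specialists at career age 12); stock specialists
enter the established slot so they do not re-trigger one-off costs.
Everything is truncated at calendar cycle 40: later cohorts contribute
partial careers, and no effects or costs beyond the horizon are counted.
Since the recursion is linear in head-count, one unit trace per cohort
index is computed (cohort dependence enters only through the magnet
effect) and scaled; a compiled matrix-stack engine advances all cohorts
in one matrix product per cycle and is asserted to match the one-step
reference engine to machine precision.

## Costs and effects

Government perspective, MWK, discounted at 3% per cycle (cycle 1
undiscounted; `PV = x/(1+r)^(cycle−1)`). Per head-cycle:

- salary by state, +10% pension uplift;
- subsidised housing for all Malawi-located public-sector states;
- transport for interns, medical officers and bonded service;
- specialist perks: one-off vehicle allowance in the first
  post-qualification cycle, monthly fuel and communication allowances;
- training: tuition per registrar-cycle by location (College of
  Medicine fee in Malawi, mean South-African university fee abroad) plus
  registrar allowances in both locations.

Registrars located in South Africa draw tuition and allowances but no
Malawian salary, housing or transport (the published cost list does not
state the overlap; this is our resolution). Absorbing states cost
nothing. Effects count Malawi-located person-cycles only: doctor-years
for every Malawian public-sector state, specialist-years for specialist
states. Indirect costs (administration, induced service costs) are out
of scope.

**Valuation thresholds.** The current doctor-year valuation is the
baseline run's discounted cost divided by its discounted doctor-years.
The specialist-year valuation prices a representative career (intern,
2 medical-officer cycles, 4 Malawi registrar cycles, then specialist to
cycle 40) per discounted specialist-year. The published appendix formula
for these valuations is unavailable; this ratio-based construction is a
stand-in and is not expected to reproduce the published figures,
although it preserves specialist > doctor valuation. The MWK/intl-$
rate (158.5) is display-only.

## Probabilistic sensitivity analysis

Standard health-economics practice by method of moments around the
central values, default relative standard error 0.2 (overridable):
single probabilities (uptake, baseline training rate) → beta; competing
hazards sharing a row → dirichlet over (hazards, stay) with the
concentration set so the largest hazard has the target relative SE —
the simplex constraint then holds at the anchors by construction; costs
→ gamma. Trend factors are held fixed. One master seed spawns a child
generator per draw; a draw's parameter set evaluates every scenario
(common random numbers), so incremental comparisons are draw-wise
coherent. If a drawn row's trajectory leaves the simplex (the rising
labour-market exit, or a large uptake draw at the offer cycle), the row
— including the offer — is rescaled proportionally, preserving the
dirichlet shares; events are counted and logged, never silently
clipped. Zero dispersion collapses every draw to the deterministic
pipeline exactly.

## CEA

ICERs are pairwise versus baseline for both effect measures, with the
standard dominance classes; a zero incremental effect yields an
undefined-ICER marker, not ±inf. Extended dominance is not computed
(comparisons are pairwise). CEAFs are computed separately per effect on
the λ grid 0–50m MWK step 100k (501 points): optimal = highest mean net
monetary benefit; its probability = share of draws in which its NMB is
strictly highest, exact ties split equally (ties have probability zero
under continuous draws).

## Synthetic parameter generation

The original inputs (tracing-study hazard estimates, DCE uptake
predictions, MOH cost schedules) are not public. The generator produces
stand-ins that are deterministic in the seed: a small (2%) log-normal
jitter on shared base levels, applied so that every documented ordering
holds *exactly* for any seed (one jitter per uptake location, one scale
for the three specialist exit anchors, and so on). Defaults:

| group | anchors (t=1, c=1) | trend |
|---|---|---|
| intern exits | EM 0.08, EPS 0.07 | constant |
| medical officer / generalist exits | EM 0.05, EPS 0.04 | ×0.97 per cycle |
| labour-market exit (all states) | 0.02 | ×1.03 per cycle |
| specialist emigration | Malawi 0.04, sandwich 0.08, SA 0.25 | ×0.97 per cycle, ×0.98 per cohort (magnet) |
| uptake, no service | 0.55 / 0.65 / 0.75 (M / sandwich / SA) | service factors 0.32, 0.27, 0.23, 0.20 for 2–5 years |
| subgroups | pliant patriots ×1.15, money motivated ×1.03, stubborn specialists ×0.93, rich rejecters ×0.45 (×0.30 with service) | cap 0.86 |

Salary anchors (MWK 3.6m intern to 8.4m specialist), housing, transport,
perks and tuition start from plausible 2015 magnitudes; three scale
factors (training, perks, housing+transport) are then solved by least
squares — against one deterministic run of all scenarios, category
totals being linear in the scales — so that the *class means* of the
cost-category shares land at the reported values: salaries ≈74–80% of
spending under mandatory service and 62–65% without, training ≈1–2%
versus 7–8%, specialist perks inside the overall 7–19% band. The
published shares are reported "across most interventions"; per-scenario
enforcement of all bands simultaneously is arithmetically impossible for
any parameterisation consistent with the published effect spread, so the
calibration (and the corresponding acceptance check) uses class means.
The steep uptake drop from no-service to bonded offers is what makes the
two training-share regimes attainable at once.

What the generator does **not** emulate: real Malawian administrative
magnitudes (absolute costs and hazards are plausible, not estimated),
correlation between parameters beyond shared jitters, non-geometric
trend shapes, and any response of exit hazards to the policy itself
(cross-elasticities). Passing tests therefore demonstrate the pipeline's
arithmetic, invariances and the qualitative policy orderings — not the
published point estimates, whose appendix inputs are unavailable;
published magnitudes (ICER bands, exact Table-style proportions) serve
only as qualitative anchors.

## Numerical choices

- Row sums may exceed 1 by at most 1e-9 (validation tolerance);
  conservation holds to 1e-9 of the entry size, engine equivalence to
  1e-12 relative.
- Hazard tables clamp at their last tabulated cycle/cohort (stock
  members older than the table reuse the final value).
- The degenerate PSA (rse 0) bypasses sampling and returns central
  values bit-for-bit.
- CSVs are written in full double precision and read back with
  round-trip float parsing; identical configuration + seed gives
  byte-identical artifacts (manifests carry SHA-256 hashes).
- Default problem sizes: deterministic runs use the full study
  configuration; the test-suite's Monte-Carlo fixtures use 120 draws,
  and the robustness sweep uses 5 jitter seeds at a reduced population
  (12 cohorts, 25-cycle horizon) — chosen as the smallest sizes at which
  the checked properties are stable.

## Known limitations

- Absorbing exits and constant uptake over 40 years are strong
  assumptions inherited from the modelled study.
- The specialist-year valuation is a representative-career construction,
  not the published appendix formula.
- PSA renormalisation slightly shrinks the effective uptake in draws
  that overflow the offer-cycle simplex, biasing Monte-Carlo means a few
  per cent below the deterministic run for high-uptake scenarios.
- One scenario's state space is rebuilt per draw; a 2000-draw, 16-
  scenario PSA takes a few minutes on one CPU.
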