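# medretain

Cost-effectiveness analysis of specialty-training policies for retaining
doctors in the Malawian public sector.

Sub-Saharan health systems lose many of the doctors they train: few
specialty-training places exist at home, sending registrars abroad (most
often to South Africa) raises the risk they never return, and junior
doctors are reluctant to accept domestic training. `medretain` is a
deterministic multi-cohort Markov model of the physician labour market
built to compare policies that expand specialty training — by training
location (Malawi, "sandwich" split with South Africa, or South Africa)
and by mandatory public-sector service before training (0 or 2–5 years)
— against current conditions. It is written for health-economics and
health-workforce researchers who want a tested, scriptable version of
this class of analysis.

## The model

A doctor's career is a closed hierarchical Markov process with annual
cycles over a 40-year horizon: 10 temporary states — intern, medical
officer, a variable-length pre-training (bonded service) tunnel, three
4-cycle registrar tunnels, three specialist states distinguished by
training location, and generalist — plus 3 absorbing exits (left Malawi,
left the public sector, left the health labour market). Stay/progress
probabilities are complements of the competing exit hazards in each row,
e.g. for a medical officer

```
P(stay) = 1 − exitMalawi − exitPublicSector − exitHLM − uptake(training offer)
```

Tunnel states can be left only through the health-labour-market exit.
Medical officers still untrained at the end of cycle 7 become
generalists with probability one. Specialist emigration hazards fall
within a career and across successive cohorts (a "magnet effect" of a
growing domestic specialist community) and are highest for wholly
South-Africa-trained specialists.

The population stacks an existing stock of doctors onto 40 entering
cohorts (100 graduates growing by 5 per cohort, 7900 entrants in all).
Costs take the government perspective (salaries with a 10% pension
uplift, housing, transport, tuition, registrar allowances, specialist
perks); effects are discounted doctor-years and specialist-years worked
in the Malawian public sector — only time spent in Malawi counts. Both
are discounted at 3%. Policies are compared by ICER versus baseline and
by cost-effectiveness acceptability frontiers (CEAF): over a
willingness-to-pay grid λ = 0…50m MWK (step 100k), the option with the
highest mean net monetary benefit `λ·E − C` and the probability (over
2000 Monte-Carlo parameter draws) that it is cost-effective.

The study's appendix parameter tables are not public, so
`medretain.synthetic` generates internally consistent stand-ins with the
documented qualitative structure; see `docs/methods.md`.

## Worked example

```
python analysis/01_generate_params.py        # write synthetic parameter CSVs
python analysis/02_simulate_scenarios.py     # deterministic 16-scenario run
python analysis/03_valuation_thresholds.py
python analysis/04_psa_ceaf.py --draws 100   # PSA + frontiers (2000 by default)
```

The deterministic run prints effects as proportions of baseline
(seed 0):

```
                doctor_years_prop  specialist_years_prop
baseline                    1.000                  1.000
malawi_s0                   1.196                  7.288
malawi_s2                   1.067                  2.120
...
southafrica_s0              0.719                  5.278

Largest doctor-year gain: malawi_s0 (+19.6%)
Largest specialist-year gain: sandwich_s0 (7.49x baseline)
```

Expanding training in Malawi or as a sandwich raises both outcomes;
expanding it wholly in South Africa *reduces* total doctor-years (0.72×
baseline) because four training years abroad count nothing and
SA-trained specialists emigrate at much higher rates. Longer mandatory
service trades specialist-years (monotonically falling with service
length) for cheaper, better-retained cohorts. The thresholds script
prints the government's current implicit valuations
(`MWK 7.04m` per doctor-year, `MWK 17.04m` per specialist-year here),
and the frontier script shows where the optimal policy switches, e.g.

```
CEAF switch points (doctor_years, MWK):
  from MWK    0.0m: baseline
  from MWK    6.9m: malawi_s5
  from MWK   27.3m: malawi_s4
  from MWK   27.8m: malawi_s0
```

i.e. once the willingness to pay per doctor-year exceeds roughly
MWK 7m, expanded Malawian training with five years' mandatory service
has the highest net monetary benefit — the same qualitative conclusion
as the study this package re-implements, whose exact magnitudes depend
on its unpublished appendix tables.

The same pipeline is exposed as a CLI
(`medretain generate|simulate|psa|ceaf|report --config cfg.yaml`),
with `--subgroup` switching to the uptake rates of one of the four
stated-preference subgroups (rich rejecters, money motivated, stubborn
specialists, pliant patriots).

## Layout

- `src/medretain/` — the library: `states` (career graph + cohort
  engine), `engine` (vectorised batch engine), `scenarios`, `population`,
  `economics`, `uncertainty` (PSA), `cea`, `synthetic` (parameter
  generator), `params`/`config`/`pipeline`/`cli` (I/O and orchestration).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property (hypothesis) and acceptance suites.
- `docs/methods.md` — modelling assumptions, parameter defaults and
  limitations.
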