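"""Current-valuation thresholds: what the government implicitly pays per
discounted doctor-year (baseline workforce cost/effect ratio) and per
specialist-year (a representative 40-year specialist career)."""

import argparse

from medretain.economics import valuation_thresholds
from medretain.runmodel import evaluate_scenarios
from medretain.scenarios import BASELINE
from medretain.states import build_state_space
from medretain.synthetic import generate_default_params

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

bundle = generate_default_params(args.seed)
base = evaluate_scenarios(bundle, [BASELINE])["baseline"]
vt = valuation_thresholds(base.costs, base.effects, build_state_space(),
                          bundle.costs, intl_dollar_rate=bundle.intl_dollar_rate)
dollars = vt.in_dollars()
print(f"Doctor-year valuation:     MWK {vt.per_doctor_year/1e6:.2f}m "
      f"(intl $ {dollars['per_doctor_year']:,.0f})")
print(f"Specialist-year valuation: MWK {vt.per_specialist_year/1e6:.2f}m "
      f"(intl $ {dollars['per_specialist_year']:,.0f})")
print(f"Specialist/doctor ratio:   {vt.per_specialist_year/vt.per_doctor_year:.2f}")
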