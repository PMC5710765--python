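"""Generate the default synthetic parameter set and write it to CSV.

Emulates the study's input tables: tracing-study exit hazards with their
documented time/cohort trends, DCE-predicted uptake per subgroup, the MOH
cost schedule (calibrated so cost-category shares match the reported
ranges), the existing stock, and the enrolment plan.
"""

import argparse

from medretain.config import RunConfig
from medretain.pipeline import run_pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", default="results")
args = parser.parse_args()

config = RunConfig(seed=args.seed).validate()
artifacts = run_pipeline(config, "generate", args.out_dir)
print(f"Parameter set (seed {args.seed}) written:")
for name, path in artifacts.items():
    print(f"  {name}: {path}")
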