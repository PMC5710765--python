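"""The full parameter bundle driving a model run.

A bundle carries hazard anchors (the value of each named hazard at career
cycle 1, cohort 1) together with geometric time and cohort trends, the
baseline training rate and its allocation across locations, the
scenario/subgroup uptake table, the cost schedule, the existing-stock
distribution and the enrolment plan.  ``build_hazard_schedule`` expands
the anchors into tabulated hazards:

    value(t, c) = anchor * time_trend ** (t - 1) * cohort_trend ** (c - 1)

so exit-health-labour-market risk can rise with career age, exit-Malawi /
exit-public-sector risks fall with career age, and specialist emigration
falls across cohorts (the magnet effect).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import states
from .economics import CostSchedule
from .population import EntryPlan
from .states import HazardSchedule


@dataclass
class ParameterBundle:
    hazard_anchors: dict[str, dict[str, float]]   # origin -> hazard -> anchor
    time_trends: dict[str, float]                 # hazard -> factor per cycle
    cohort_trends: dict[str, float]               # hazard -> factor per cohort
    baseline_training_rate: float
    baseline_allocation: tuple[float, float, float]  # Malawi, sandwich, SA
    uptake: pd.DataFrame
    costs: CostSchedule
    stock: pd.DataFrame
    entry_plan: EntryPlan
    offer_cycle: int = 2
    uptake_mode: str = "single"                   # or "repeated" (cycles 2..7)
    intl_dollar_rate: float = 158.5
    meta: dict = field(default_factory=dict)

    def copy(self) -> "ParameterBundle":
        return ParameterBundle(
            hazard_anchors={o: dict(h) for o, h in self.hazard_anchors.items()},
            time_trends=dict(self.time_trends),
            cohort_trends=dict(self.cohort_trends),
            baseline_training_rate=self.baseline_training_rate,
            baseline_allocation=tuple(self.baseline_allocation),
            uptake=self.uptake.copy(),
            costs=dataclasses.replace(
                self.costs,
                salary=dict(self.costs.salary),
                transport=dict(self.costs.transport),
                monthly_allowances=dict(self.costs.monthly_allowances),
                tuition_per_training_year=dict(
                    self.costs.tuition_per_training_year),
            ),
            stock=self.stock.copy(),
            entry_plan=self.entry_plan,
            offer_cycle=self.offer_cycle,
            uptake_mode=self.uptake_mode,
            intl_dollar_rate=self.intl_dollar_rate,
            meta=dict(self.meta),
        )

    def offer_cycles(self) -> tuple[int, ...]:
        """Career cycles at which a training offer is open: a single offer
        by default, or every medical-officer cycle up to the forced
        generalist transition in 'repeated' mode."""
        if self.uptake_mode == "repeated":
            return tuple(range(self.offer_cycle, states.FORCE_GENERALIST_CYCLE + 1))
        return (self.offer_cycle,)

    def max_stock_age(self) -> int:
        return int(self.stock["career_age"].max()) if len(self.stock) else 1


def _trend_table(anchor: float, tt: float, ct: float,
                 n_cycles: int, n_cohorts: int) -> np.ndarray:
    t = anchor * tt ** np.arange(n_cycles)
    if ct == 1.0:
        return t[:, None]
    return t[:, None] * ct ** np.arange(n_cohorts)[None, :]


def build_hazard_schedule(
    bundle: ParameterBundle, n_cycles: int, n_cohorts: int
) -> HazardSchedule:
    """Tabulate the baseline hazard schedule from anchors and trends."""
    tables: dict[tuple[str, str], np.ndarray] = {}
    for origin, hazards in bundle.hazard_anchors.items():
        for name, anchor in hazards.items():
            tables[(origin, name)] = _trend_table(
                anchor,
                bundle.time_trends.get(name, 1.0),
                bundle.cohort_trends.get(name, 1.0),
                n_cycles, n_cohorts,
            )
    # baseline training places at the offer cycle(s), split across locations
    alloc = dict(zip(("T_M", "T_MSA", "T_SA"), bundle.baseline_allocation))
    for name, share in alloc.items():
        tab = np.zeros((n_cycles, 1))
        for t in bundle.offer_cycles():
            tab[t - 1, 0] = bundle.baseline_training_rate * share
        tables[(states.MEDICAL_OFFICER, name)] = tab
    schedule = HazardSchedule(tables, n_cycles=n_cycles, n_cohorts=n_cohorts)
    schedule.validate()
    return schedule


# ---------------------------------------------------------------------------
# On-disk interchange: tabular CSVs plus a YAML file of scalar parameters.

PARAM_FILES = {
    "hazards": "hazards.csv",
    "costs": "costs.csv",
    "uptake": "uptake.csv",
    "stock": "stock.csv",
    "scalars": "params.yaml",
}


def save_bundle(bundle: ParameterBundle, out_dir: str | Path,
                n_cycles: int = 52, n_cohorts: int = 40) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / v for k, v in PARAM_FILES.items()}
    schedule = build_hazard_schedule(bundle, n_cycles, n_cohorts)
    schedule.to_frame().to_csv(paths["hazards"], index=False)
    bundle.costs.to_frame().to_csv(paths["costs"], index=False)
    bundle.uptake.to_csv(paths["uptake"], index=False)
    bundle.stock.to_csv(paths["stock"], index=False)
    scalars = {
        "hazard_anchors": {o: {k: float(v) for k, v in h.items()}
                           for o, h in bundle.hazard_anchors.items()},
        "time_trends": {k: float(v) for k, v in bundle.time_trends.items()},
        "cohort_trends": {k: float(v) for k, v in bundle.cohort_trends.items()},
        "baseline_training_rate": float(bundle.baseline_training_rate),
        "baseline_allocation": [float(x) for x in bundle.baseline_allocation],
        "entry_plan": {
            "first_size": bundle.entry_plan.first_size,
            "growth_per_cohort": bundle.entry_plan.growth_per_cohort,
            "n_cohorts": bundle.entry_plan.n_cohorts,
        },
        "offer_cycle": bundle.offer_cycle,
        "uptake_mode": bundle.uptake_mode,
        "intl_dollar_rate": float(bundle.intl_dollar_rate),
        "meta": bundle.meta,
    }
    with open(paths["scalars"], "w") as fh:
        yaml.safe_dump(scalars, fh, sort_keys=True)
    return paths


def load_bundle(param_dir: str | Path) -> ParameterBundle:
    param_dir = Path(param_dir)
    with open(param_dir / PARAM_FILES["scalars"]) as fh:
        scalars = yaml.safe_load(fh)
    ep = scalars["entry_plan"]

    def read(key):
        return pd.read_csv(param_dir / PARAM_FILES[key],
                           float_precision="round_trip")

    return ParameterBundle(
        hazard_anchors=scalars["hazard_anchors"],
        time_trends=scalars["time_trends"],
        cohort_trends=scalars["cohort_trends"],
        baseline_training_rate=scalars["baseline_training_rate"],
        baseline_allocation=tuple(scalars["baseline_allocation"]),
        uptake=read("uptake"),
        costs=CostSchedule.from_frame(read("costs")),
        stock=read("stock"),
        entry_plan=EntryPlan(ep["first_size"], ep["growth_per_cohort"],
                             int(ep["n_cohorts"])),
        offer_cycle=int(scalars["offer_cycle"]),
        uptake_mode=scalars["uptake_mode"],
        intl_dollar_rate=scalars["intl_dollar_rate"],
        meta=scalars.get("meta", {}),
    )
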