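"""Policy scenarios: training location x mandatory service, with DCE uptake.

The baseline keeps the current trickle of government-funded training
places, split across the three training locations.  Each intervention
expands training in one location (Malawi, sandwich, South Africa) so
that every willing medical officer gets a place, optionally after a
mandatory service period of 2-5 years, giving 15 alternatives.  The
predicted uptake of an offer comes from a stated-preference (discrete
choice experiment) table and may differ by preference subgroup; it is
constant over the time horizon.  Doctors who decline remain medical
officers under the background exit hazards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidScenarioError, UnknownSubgroupError
from . import states
from .states import HazardSchedule, StateSpace

LOCATIONS = ("Malawi", "Sandwich", "SouthAfrica")
SERVICE_YEARS = (0, 2, 3, 4, 5)
SUBGROUPS = (
    "whole_population",
    "rich_rejecters",
    "money_motivated",
    "stubborn_specialists",
    "pliant_patriots",
)

#: Registrar tunnel entered from each training location.
LOCATION_TO_REGISTRAR = {
    "Malawi": states.REGISTRAR_MALAWI,
    "Sandwich": states.REGISTRAR_SANDWICH,
    "SouthAfrica": states.REGISTRAR_SA,
}
#: Immediate-entry training hazard per location.
LOCATION_TO_HAZARD = {
    "Malawi": "T_M",
    "Sandwich": "T_MSA",
    "SouthAfrica": "T_SA",
}
TRAINING_HAZARDS = ("T_M", "T_MSA", "T_SA", "ET")


@dataclass(frozen=True)
class Scenario:
    """A training-policy alternative.

    ``service_years == 0`` offers immediate training; otherwise the offer
    is bonded to a pre-training service tunnel of that length.  The
    baseline is the distinguished no-expansion scenario (no uptake
    override)."""

    name: str
    location: str | None
    service_years: int
    subgroup: str = "whole_population"
    uptake: float | None = None
    is_baseline: bool = False

    def __post_init__(self):
        if self.subgroup not in SUBGROUPS:
            raise UnknownSubgroupError(f"unknown subgroup {self.subgroup!r}")
        if self.is_baseline:
            if self.uptake is not None:
                raise InvalidScenarioError("baseline has no uptake override")
            return
        if self.location not in LOCATIONS:
            raise InvalidScenarioError(f"unknown location {self.location!r}")
        if self.service_years not in SERVICE_YEARS:
            raise InvalidScenarioError(
                f"service_years must be one of {SERVICE_YEARS}"
            )
        if self.uptake is not None and not 0 <= self.uptake <= 1:
            raise InvalidScenarioError("uptake must lie in [0, 1]")


BASELINE = Scenario("baseline", None, 0, is_baseline=True)


def scenario_name(location: str, service_years: int) -> str:
    return f"{location.lower()}_s{service_years}"


def enumerate_scenarios(
    locations: Sequence[str] = LOCATIONS,
    service_years: Sequence[int] = SERVICE_YEARS,
    subgroup: str = "whole_population",
    include_baseline: bool = False,
) -> list[Scenario]:
    """The full policy grid: 3 locations x {0,2,3,4,5} service years = 15
    interventions (plus the baseline when requested)."""
    out: list[Scenario] = []
    if include_baseline:
        out.append(replace(BASELINE, subgroup=subgroup))
    for loc in locations:
        for sy in service_years:
            out.append(Scenario(scenario_name(loc, sy), loc, int(sy),
                                subgroup=subgroup))
    return out


def validate_uptake_table(table: pd.DataFrame) -> None:
    required = {"subgroup", "location", "service_years", "uptake"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidScenarioError(f"uptake table missing columns {sorted(missing)}")
    if ((table["uptake"] < 0) | (table["uptake"] > 1)).any():
        raise InvalidScenarioError("uptake probabilities must lie in [0, 1]")


def subgroup_uptake(uptake_table: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    """Rows of one preference subgroup (``whole_population`` is the default
    analysis population)."""
    if subgroup not in SUBGROUPS:
        raise UnknownSubgroupError(
            f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}"
        )
    validate_uptake_table(uptake_table)
    rows = uptake_table[uptake_table["subgroup"] == subgroup]
    if rows.empty:
        raise UnknownSubgroupError(f"no uptake rows for subgroup {subgroup!r}")
    return rows.reset_index(drop=True)


def lookup_uptake(
    uptake_table: pd.DataFrame, subgroup: str, location: str, service_years: int
) -> float:
    rows = subgroup_uptake(uptake_table, subgroup)
    hit = rows[(rows["location"] == location)
               & (rows["service_years"] == service_years)]
    if hit.empty:
        raise InvalidScenarioError(
            f"no uptake row for ({subgroup}, {location}, {service_years})"
        )
    return float(hit["uptake"].iloc[0])


@dataclass
class ScenarioModel:
    """A scenario made concrete: the rewired state space (pre-training
    tunnel length/destination) plus its hazard schedule."""

    scenario: Scenario
    space: StateSpace
    schedule: HazardSchedule


def _offer_table(n_cycles: int, offer_cycles: Iterable[int], value: float) -> np.ndarray:
    tab = np.zeros((n_cycles, 1))
    for t in offer_cycles:
        tab[t - 1, 0] = value
    return tab


def apply_scenario(
    hazard_schedule: HazardSchedule,
    scenario: Scenario,
    uptake_table: pd.DataFrame | None,
    state_space: StateSpace,
    offer_cycles: Sequence[int] = (2,),
) -> ScenarioModel:
    """Rewire the medical-officer row for a policy scenario.

    Only the training hazards of the medical-officer row and the
    pre-training tunnel wiring are touched; all background hazards are
    left exactly as in the baseline schedule.  The baseline scenario is
    returned unchanged.
    """
    if scenario.is_baseline:
        return ScenarioModel(scenario, state_space, hazard_schedule.copy())

    if scenario.uptake is not None:
        uptake = scenario.uptake
    else:
        if uptake_table is None:
            raise InvalidScenarioError(
                f"scenario {scenario.name!r} needs an uptake table or override"
            )
        uptake = lookup_uptake(
            uptake_table, scenario.subgroup, scenario.location,
            scenario.service_years,
        )

    schedule = hazard_schedule.copy()
    for name in TRAINING_HAZARDS:
        schedule.drop_hazard(states.MEDICAL_OFFICER, name)

    registrar = LOCATION_TO_REGISTRAR[scenario.location]
    if scenario.service_years == 0:
        space = state_space
        if uptake > 0:
            schedule.set_hazard(
                states.MEDICAL_OFFICER, LOCATION_TO_HAZARD[scenario.location],
                _offer_table(schedule.n_cycles, offer_cycles, uptake),
            )
    else:
        space = state_space.with_pretraining(scenario.service_years, registrar)
        if uptake > 0:
            schedule.set_hazard(
                states.MEDICAL_OFFICER, "ET",
                _offer_table(schedule.n_cycles, offer_cycles, uptake),
            )

    total = schedule.row_sum_grid(states.MEDICAL_OFFICER)
    if np.any(total > 1 + 1e-9):
        raise InvalidScenarioError(
            f"scenario {scenario.name!r}: medical-officer hazards sum to "
            f"{total.max():.4f} > 1"
        )
    return ScenarioModel(scenario, space, schedule)
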