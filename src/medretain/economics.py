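"""Government-perspective costing and effect accounting.

Costs (MWK per head per cycle) attach to the internal slots of the state
space: salaries carry a 10% pension uplift, all public-sector doctors in
Malawi receive subsidised housing, interns and medical officers get
transport, specialists get monthly fuel/communication allowances plus a
one-off vehicle allowance in their first post-qualification cycle, and
registrars attract tuition (COM fees in Malawi, the mean of the South
African university fees for years spent there) plus training allowances.
Registrars located in South Africa draw no Malawian salary, housing or
transport.  Absorbing states cost nothing.

Effects are doctor-years and specialist-years worked in the Malawian
public sector: only Malawi-located cycles count.  Costs and effects are
both discounted by calendar cycle (cycle 1 undiscounted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import states
from .states import CohortTrace, StateSpace

COMPONENTS = (
    "salary", "pension", "housing", "transport",
    "vehicle", "fuel_comm", "tuition", "registrar_allowance",
)

#: Component groups used for cost-share reporting.
CATEGORIES = {
    "salary": ("salary", "pension"),
    "training": ("tuition", "registrar_allowance"),
    "perks": ("vehicle", "fuel_comm"),
    "other": ("housing", "transport"),
}


@dataclass
class CostSchedule:
    """Annual cost components per state, MWK."""

    salary: dict[str, float]
    annual_housing: float = 0.0
    pension_uplift_fraction: float = 0.10
    transport: dict[str, float] = field(default_factory=dict)
    monthly_allowances: dict[str, float] = field(default_factory=dict)
    one_off_vehicle: float = 0.0
    tuition_per_training_year: dict[str, float] = field(default_factory=dict)
    registrar_allowances: float = 0.0

    def __post_init__(self):
        for name, value in self._scalar_items():
            if value < 0:
                raise ValueError(f"cost component {name!r} must be non-negative")

    def _scalar_items(self):
        for d in (self.salary, self.transport, self.monthly_allowances,
                  self.tuition_per_training_year):
            yield from d.items()
        yield "annual_housing", self.annual_housing
        yield "one_off_vehicle", self.one_off_vehicle
        yield "registrar_allowances", self.registrar_allowances
        yield "pension_uplift_fraction", self.pension_uplift_fraction

    def scaled(self, factor: float) -> "CostSchedule":
        """Every monetary entry multiplied by ``factor`` (the pension
        fraction is dimensionless and untouched)."""
        return CostSchedule(
            salary={k: v * factor for k, v in self.salary.items()},
            annual_housing=self.annual_housing * factor,
            pension_uplift_fraction=self.pension_uplift_fraction,
            transport={k: v * factor for k, v in self.transport.items()},
            monthly_allowances={k: v * factor
                                for k, v in self.monthly_allowances.items()},
            one_off_vehicle=self.one_off_vehicle * factor,
            tuition_per_training_year={
                k: v * factor for k, v in self.tuition_per_training_year.items()},
            registrar_allowances=self.registrar_allowances * factor,
        )

    # CSV interchange: (state, component, value, periodicity)
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st, v in sorted(self.salary.items()):
            rows.append((st, "salary", v, "annual"))
        for st, v in sorted(self.transport.items()):
            rows.append((st, "transport", v, "annual"))
        for st, v in sorted(self.monthly_allowances.items()):
            rows.append((st, "monthly_allowance", v, "monthly"))
        rows.append(("*", "annual_housing", self.annual_housing, "annual"))
        rows.append(("*", "pension_uplift_fraction",
                     self.pension_uplift_fraction, "fraction"))
        rows.append(("*", "one_off_vehicle", self.one_off_vehicle, "one_off"))
        for loc, v in sorted(self.tuition_per_training_year.items()):
            rows.append((loc, "tuition", v, "per_training_year"))
        rows.append(("*", "registrar_allowances",
                     self.registrar_allowances, "annual"))
        return pd.DataFrame(rows, columns=["state", "component", "value",
                                           "periodicity"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CostSchedule":
        def rows(comp):
            return frame[frame["component"] == comp]
        return cls(
            salary=dict(zip(rows("salary")["state"], rows("salary")["value"])),
            transport=dict(zip(rows("transport")["state"],
                               rows("transport")["value"])),
            monthly_allowances=dict(zip(rows("monthly_allowance")["state"],
                                        rows("monthly_allowance")["value"])),
            annual_housing=float(rows("annual_housing")["value"].iloc[0]),
            pension_uplift_fraction=float(
                rows("pension_uplift_fraction")["value"].iloc[0]),
            one_off_vehicle=float(rows("one_off_vehicle")["value"].iloc[0]),
            tuition_per_training_year=dict(zip(rows("tuition")["state"],
                                               rows("tuition")["value"])),
            registrar_allowances=float(
                rows("registrar_allowances")["value"].iloc[0]),
        )


def _is_registrar(space: StateSpace, name: str) -> bool:
    """Registrar tunnels are the tunnels that feed a specialist state."""
    s = space[name]
    return (s.kind == "tunnel" and s.tunnel_destination is not None
            and space[s.tunnel_destination].counts_specialist_year)


def slot_cost_components(space: StateSpace, cs: CostSchedule) -> np.ndarray:
    """Cost component matrix (n_slots, len(COMPONENTS)), MWK per head-cycle."""
    K = np.zeros((space.n_slots, len(COMPONENTS)))
    col = {c: i for i, c in enumerate(COMPONENTS)}
    for i, slot in enumerate(space.slots):
        state = space[slot.state]
        if state.kind == "absorbing":
            continue
        registrar = _is_registrar(space, slot.state)
        if slot.location == states.MALAWI:
            sal = cs.salary.get(slot.state, 0.0)
            K[i, col["salary"]] = sal
            K[i, col["pension"]] = sal * cs.pension_uplift_fraction
            K[i, col["housing"]] = cs.annual_housing
            K[i, col["transport"]] = cs.transport.get(slot.state, 0.0)
            K[i, col["fuel_comm"]] = 12.0 * cs.monthly_allowances.get(slot.state, 0.0)
            if registrar:
                K[i, col["tuition"]] = cs.tuition_per_training_year.get(
                    states.MALAWI, 0.0)
        else:  # South-Africa-located training cycle
            if registrar:
                K[i, col["tuition"]] = cs.tuition_per_training_year.get(
                    states.SOUTH_AFRICA, 0.0)
        if registrar:
            K[i, col["registrar_allowance"]] = cs.registrar_allowances
        if slot.first_specialist:
            K[i, col["vehicle"]] = cs.one_off_vehicle
    return K


def annual_state_cost(
    state: str, career_cycle: int, cost_schedule: CostSchedule,
    state_space: StateSpace,
) -> float:
    """MWK cost of one head-cycle in ``state`` at its ``career_cycle``-th
    cycle *within the state* (tunnel position / first specialist cycle)."""
    if state not in state_space:
        raise KeyError(f"unknown state {state!r}")
    if career_cycle < 1:
        raise ValueError("career_cycle must be >= 1")
    if state_space[state].kind == "absorbing":
        return 0.0
    K = slot_cost_components(state_space, cost_schedule)
    r = state_space.slot_indices(state)
    i = r.start + min(career_cycle - 1, len(r) - 1)
    return float(K[i].sum())


def discount(amount, calendar_cycle, rate: float = 0.03):
    """Present value at cycle 1 of ``amount`` accruing in ``calendar_cycle``
    (cycle 1 is undiscounted)."""
    cycle = np.asarray(calendar_cycle)
    if np.any(cycle < 1):
        raise ValueError("calendar cycle must be >= 1")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return amount / (1.0 + rate) ** (cycle - 1)


@dataclass
class EffectTotals:
    """Discounted and undiscounted person-year effects."""

    doctor_years: float
    specialist_years: float
    doctor_years_undiscounted: float
    specialist_years_undiscounted: float

    def __post_init__(self):
        if self.specialist_years > self.doctor_years + 1e-9:
            raise ValueError("specialist-years cannot exceed doctor-years")


@dataclass
class CostTotals:
    """Discounted cost with a per-component breakdown (MWK)."""

    total: float
    by_component: dict[str, float]
    total_undiscounted: float

    def by_category(self) -> dict[str, float]:
        return {
            cat: sum(self.by_component[c] for c in comps)
            for cat, comps in CATEGORIES.items()
        }

    def category_shares(self) -> dict[str, float]:
        by_cat = self.by_category()
        return {k: v / self.total for k, v in by_cat.items()}


def _effect_weights(space: StateSpace) -> tuple[np.ndarray, np.ndarray]:
    w_dy = np.array([float(s.doctor_year) for s in space.slots])
    w_sy = np.array([float(s.specialist_year) for s in space.slots])
    return w_dy, w_sy


def accumulate(
    trace,
    cost_schedule: CostSchedule,
    state_space: StateSpace,
    rate: float = 0.03,
) -> tuple[CostTotals, EffectTotals]:
    """Discounted cost and effect totals of a cohort or population trace.

    Accepts a :class:`CohortTrace` or anything exposing ``member_traces()``
    (a :class:`~medretain.population.PopulationTrace`); discounting is by
    calendar cycle of each row.
    """
    members: Iterable[CohortTrace]
    if hasattr(trace, "member_traces"):
        members = trace.member_traces()
    else:
        members = [trace]
    K = slot_cost_components(state_space, cost_schedule)
    w_dy, w_sy = _effect_weights(state_space)
    comp = np.zeros(len(COMPONENTS))
    cost_undisc = 0.0
    dy = sy = dy_u = sy_u = 0.0
    for tr in members:
        d = discount(1.0, tr.calendar_cycles, rate)
        weighted = d @ tr.occupancy          # (n_slots,)
        unweighted = tr.occupancy.sum(axis=0)
        comp += weighted @ K
        cost_undisc += unweighted @ K.sum(axis=1)
        dy += weighted @ w_dy
        sy += weighted @ w_sy
        dy_u += unweighted @ w_dy
        sy_u += unweighted @ w_sy
    costs = CostTotals(
        total=float(comp.sum()),
        by_component=dict(zip(COMPONENTS, comp.tolist())),
        total_undiscounted=float(cost_undisc),
    )
    effects = EffectTotals(float(dy), float(sy), float(dy_u), float(sy_u))
    return costs, effects


@dataclass
class ValuationThresholds:
    """What the government currently pays per discounted doctor- and
    specialist-year, derived from the baseline run (MWK)."""

    per_doctor_year: float
    per_specialist_year: float
    intl_dollar_rate: float = 158.5  # MWK per international dollar, display only

    def __post_init__(self):
        if self.per_doctor_year <= 0 or self.per_specialist_year <= 0:
            raise ValueError("valuation thresholds must be positive")

    def in_dollars(self) -> dict[str, float]:
        return {
            "per_doctor_year": self.per_doctor_year / self.intl_dollar_rate,
            "per_specialist_year": self.per_specialist_year / self.intl_dollar_rate,
        }


def representative_specialist_trace(
    state_space: StateSpace, horizon: int = 40
) -> CohortTrace:
    """A representative specialist career: intern (1 cycle), medical officer
    (2), Malawi registrar tunnel (4), then Malawi specialist to the end of
    the horizon; no attrition."""
    occ = np.zeros((horizon, state_space.n_slots))
    occ[0, state_space.first_slot(states.INTERN)] = 1.0
    occ[1:3, state_space.first_slot(states.MEDICAL_OFFICER)] = 1.0
    reg = state_space.slot_indices(states.REGISTRAR_MALAWI)
    for k, i in enumerate(reg):
        occ[3 + k, i] = 1.0
    spec = state_space.slot_indices(states.SPECIALIST_MALAWI)
    occ[7, spec.start] = 1.0           # first post-qualification cycle
    occ[8:, spec.start + 1] = 1.0      # established specialist
    return CohortTrace(occupancy=occ, space=state_space, entry_cycle=1,
                       entry_size=1.0)


def valuation_thresholds(
    baseline_cost: CostTotals,
    baseline_effects: EffectTotals,
    state_space: StateSpace,
    cost_schedule: CostSchedule,
    rate: float = 0.03,
    horizon: int = 40,
    intl_dollar_rate: float = 158.5,
) -> ValuationThresholds:
    """Current-valuation thresholds: the doctor-year value is the baseline
    whole-workforce cost per discounted doctor-year; the specialist-year
    value prices a representative 40-year specialist career per discounted
    specialist-year."""
    if baseline_effects.doctor_years <= 0:
        raise ZeroDivisionError("baseline produced no discounted doctor-years")
    per_dy = baseline_cost.total / baseline_effects.doctor_years
    path = representative_specialist_trace(state_space, horizon)
    path_cost, path_eff = accumulate(path, cost_schedule, state_space, rate)
    if path_eff.specialist_years <= 0:
        raise ZeroDivisionError("representative career has no specialist-years")
    per_sy = path_cost.total / path_eff.specialist_years
    return ValuationThresholds(per_dy, per_sy, intl_dollar_rate)
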