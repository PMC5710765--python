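"""Calendar-time population: existing stock plus 40 staggered cohorts.

Cohort ``j`` (size ``first_size + (j-1) * growth``) enters the intern
state at calendar cycle ``j``; the existing stock is advanced from cycle
1 with career ages consistent with each starting state.  Everything is
truncated at the fixed calendar horizon, so late cohorts contribute only
partial careers.  The cohort recursion is deterministic and linear in
head-count, so unit traces are computed once per cohort index (hazards
may depend on the cohort through the magnet effect) and scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CompiledModel
from .states import CohortTrace, HazardSchedule, StateSpace


@dataclass(frozen=True)
class EntryPlan:
    """Linear enrolment expansion: cohort j has first_size + (j-1)*growth."""

    first_size: float = 100.0
    growth_per_cohort: float = 5.0
    n_cohorts: int = 40

    def sizes(self) -> np.ndarray:
        return self.first_size + self.growth_per_cohort * np.arange(self.n_cohorts)


def build_entry_plan(
    first_size: float = 100, growth: float = 5, n_cohorts: int = 40
) -> EntryPlan:
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    plan = EntryPlan(float(first_size), float(growth), int(n_cohorts))
    if np.any(plan.sizes() <= 0):
        raise ValueError("all cohort sizes must be positive")
    return plan


def validate_stock_table(stock: pd.DataFrame, space: StateSpace) -> None:
    required = {"state", "count", "career_age"}
    missing = required - set(stock.columns)
    if missing:
        raise ValueError(f"stock table missing columns {sorted(missing)}")
    for state in stock["state"]:
        if state not in space:
            raise ValueError(f"unknown stock state {state!r}")
        if space[state].kind == "absorbing":
            raise ValueError(f"stock cannot start in absorbing state {state!r}")
    if (stock["count"] < 0).any():
        raise ValueError("stock counts must be non-negative")
    if (stock["career_age"] < 1).any():
        raise ValueError("stock career ages must be >= 1")


@dataclass
class PopulationTrace:
    """Occupancy per calendar cycle and state, with per-cohort traces kept."""

    space: StateSpace
    horizon: int
    sizes: np.ndarray                 # (n_cohorts,)
    unit_traces: np.ndarray           # (n_cohorts, horizon, n_slots), unit entry
    stock_traces: list[CohortTrace] = field(default_factory=list)

    @property
    def n_cohorts(self) -> int:
        return len(self.sizes)

    def cohort_trace(self, j: int) -> CohortTrace:
        """Trace of cohort ``j`` (1-based), truncated at the horizon."""
        n = self.horizon - j + 1
        return CohortTrace(
            occupancy=self.sizes[j - 1] * self.unit_traces[j - 1, :n],
            space=self.space, entry_cycle=j,
            entry_size=float(self.sizes[j - 1]), cohort_index=j,
        )

    def member_traces(self) -> list[CohortTrace]:
        out = list(self.stock_traces)
        out.extend(self.cohort_trace(j) for j in range(1, self.n_cohorts + 1))
        return out

    def occupancy_calendar(self) -> np.ndarray:
        """Total slot occupancy (horizon, n_slots) across stock and cohorts."""
        total = np.zeros((self.horizon, self.space.n_slots))
        for trace in self.member_traces():
            rows = trace.calendar_cycles - 1
            total[rows] += trace.occupancy
        return total

    def by_state(self) -> pd.DataFrame:
        frame = self.space.aggregate(self.occupancy_calendar())
        frame.index = pd.RangeIndex(1, self.horizon + 1, name="calendar_cycle")
        return frame

    def specialist_retention_by_cohort(self, min_trained: float = 1e-6) -> pd.Series:
        """Share of each cohort's trained specialists still in Malawi at the
        end of the horizon.  Everyone qualifying passes through a
        first-specialist slot for exactly one cycle, so the number trained
        is the time-sum of those slots."""
        first = [i for i, s in enumerate(self.space.slots) if s.first_specialist]
        spec = [i for i, s in enumerate(self.space.slots) if s.specialist_year
                and self.space[s.state].kind != "tunnel"]
        out = {}
        for j in range(1, self.n_cohorts + 1):
            tr = self.cohort_trace(j)
            trained = tr.occupancy[:, first].sum()
            if trained > min_trained * tr.entry_size:
                out[j] = tr.occupancy[-1, spec].sum() / trained
        return pd.Series(out, name="retention")


def simulate_population(
    entry_plan: EntryPlan,
    stock_table: pd.DataFrame | None,
    state_space: StateSpace,
    scenario_schedule: HazardSchedule,
    horizon: int = 40,
) -> PopulationTrace:
    """Stack the existing stock and all entering cohorts under one schedule."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    model = CompiledModel(state_space, scenario_schedule)
    sizes = entry_plan.sizes()
    if len(sizes) > horizon:
        sizes = sizes[:horizon]  # cohorts past the horizon never enter
    unit = model.run_unit_cohorts(horizon)[: len(sizes)]

    stock_traces: list[CohortTrace] = []
    if stock_table is not None and len(stock_table):
        validate_stock_table(stock_table, state_space)
        live = stock_table[stock_table["count"] > 0]
        for age, group in live.groupby("career_age"):
            occ0 = np.zeros((len(group), state_space.n_slots))
            for r, row in enumerate(group.itertuples(index=False)):
                occ0[r, state_space.entry_slot(row.state, established=True)] = row.count
            traces = model.advance_rows(occ0, initial_career_cycle=int(age),
                                        n_cycles=horizon)
            for r, row in enumerate(group.itertuples(index=False)):
                stock_traces.append(CohortTrace(
                    occupancy=traces[r], space=state_space, entry_cycle=1,
                    entry_size=float(row.count), cohort_index=1,
                    initial_career_cycle=int(age),
                ))
    return PopulationTrace(
        space=state_space, horizon=horizon, sizes=sizes,
        unit_traces=unit, stock_traces=stock_traces,
    )
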