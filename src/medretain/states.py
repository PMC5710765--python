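"""Career state graph and single-cohort Markov engine.

The physician labour market is modelled as a closed hierarchical Markov
cohort process: doctors enter as interns, may move up through medical
officer, registrar (specialty training) and specialist states, and leave
through one of three absorbing exits (out of Malawi, out of the public
sector, out of the health labour market).  Cycles are annual.  Registrar
training and any mandatory pre-training service are tunnel states: fixed
dwell-time sequences that, per cycle, can only be left through the
exit-health-labour-market hazard.

Internally every tunnel state of length ``d`` is expanded into ``d``
slots and every specialist state into two slots (first cycle after
qualification, then established) so that one-off costs and per-training-
cycle locations attach to a single slot.  The public occupancy trace
aggregates slots back to the named states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidScheduleError, InvalidStateSpaceError

MALAWI = "Malawi"
SOUTH_AFRICA = "SouthAfrica"
LOCATIONS = (MALAWI, SOUTH_AFRICA)

KINDS = ("entry", "temporary", "tunnel", "absorbing")

# Baseline roster state names.
INTERN = "intern"
MEDICAL_OFFICER = "medical_officer"
PRETRAINING = "pretraining_medical_officer"
REGISTRAR_MALAWI = "registrar_malawi"
REGISTRAR_SANDWICH = "registrar_sandwich"
REGISTRAR_SA = "registrar_south_africa"
SPECIALIST_MALAWI = "specialist_malawi"
SPECIALIST_SANDWICH = "specialist_sandwich"
SPECIALIST_SA = "specialist_south_africa"
GENERALIST = "generalist"
EXIT_MALAWI = "exit_malawi"
EXIT_PUBLIC_SECTOR = "exit_public_sector"
EXIT_HLM = "exit_health_labour_market"

ABSORBING_STATES = (EXIT_MALAWI, EXIT_PUBLIC_SECTOR, EXIT_HLM)

#: Destination state of each named hazard.
DEFAULT_DESTINATIONS: dict[str, str] = {
    "EM_I": EXIT_MALAWI,
    "EPS_I": EXIT_PUBLIC_SECTOR,
    "EHLM": EXIT_HLM,
    "EM_MO": EXIT_MALAWI,
    "EPS_MO": EXIT_PUBLIC_SECTOR,
    "ET": PRETRAINING,
    "T_M": REGISTRAR_MALAWI,
    "T_MSA": REGISTRAR_SANDWICH,
    "T_SA": REGISTRAR_SA,
    "EM_G": EXIT_MALAWI,
    "EPS_G": EXIT_PUBLIC_SECTOR,
    "EM_M": EXIT_MALAWI,
    "EM_MSA": EXIT_MALAWI,
    "EM_SA": EXIT_MALAWI,
}

#: Career cycle at whose end any remaining medical officer becomes a
#: generalist (a transition probability of one).
FORCE_GENERALIST_CYCLE = 7

DEFAULT_SANDWICH_MASK = (MALAWI, SOUTH_AFRICA, SOUTH_AFRICA, MALAWI)

#: Seniority ranks used to assert that the system is hierarchical
#: (mass never flows from a senior state to a junior one).
SENIORITY = {
    INTERN: 0,
    MEDICAL_OFFICER: 1,
    PRETRAINING: 2,
    GENERALIST: 2,
    REGISTRAR_MALAWI: 3,
    REGISTRAR_SANDWICH: 3,
    REGISTRAR_SA: 3,
    SPECIALIST_MALAWI: 4,
    SPECIALIST_SANDWICH: 4,
    SPECIALIST_SA: 4,
    EXIT_MALAWI: 9,
    EXIT_PUBLIC_SECTOR: 9,
    EXIT_HLM: 9,
}


@dataclass(frozen=True)
class StateDef:
    """One state of the career graph.

    ``location_mask`` gives the country of each tunnel cycle; effects
    (doctor-years) accrue only in Malawi-located cycles.  ``progress_to``
    names the state that receives the stay/progress complement of an
    entry state (interns always move on after one cycle); for ordinary
    temporary states the complement stays put.
    """

    name: str
    kind: str
    tunnel_length: int | None = None
    location_mask: tuple[str, ...] | None = None
    counts_doctor_year: bool = False
    counts_specialist_year: bool = False
    tunnel_destination: str | None = None
    progress_to: str | None = None


@dataclass(frozen=True)
class Slot:
    """An expanded internal state (tunnel cycle or specialist phase)."""

    state: str
    index: int            # 0-based position within the named state
    location: str | None  # None for absorbing states
    doctor_year: bool
    specialist_year: bool
    first_specialist: bool = False


class StateSpace:
    """Validated career graph plus its expanded slot representation."""

    def __init__(
        self,
        states: Sequence[StateDef],
        force_generalist_cycle: int | None = None,
    ):
        self.states: tuple[StateDef, ...] = tuple(states)
        self._by_name = {s.name: s for s in self.states}
        self._validate()
        if force_generalist_cycle is None and MEDICAL_OFFICER in self._by_name \
                and GENERALIST in self._by_name:
            force_generalist_cycle = FORCE_GENERALIST_CYCLE
        self.force_generalist_cycle = force_generalist_cycle
        self._build_slots()

    # -- construction -------------------------------------------------

    def _validate(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvalidStateSpaceError(f"duplicate state names: {dupes}")
        entries = [s for s in self.states if s.kind == "entry"]
        if len(entries) != 1:
            raise InvalidStateSpaceError(
                f"exactly one entry state required, found {len(entries)}"
            )
        for s in self.states:
            if s.kind not in KINDS:
                raise InvalidStateSpaceError(f"unknown state kind {s.kind!r}")
            if s.kind == "tunnel":
                if not s.tunnel_length or s.tunnel_length < 1:
                    raise InvalidStateSpaceError(
                        f"tunnel state {s.name!r} needs an integer length >= 1"
                    )
                if s.tunnel_destination is None:
                    raise InvalidStateSpaceError(
                        f"tunnel state {s.name!r} needs a destination state"
                    )
                if s.tunnel_destination not in self._by_name:
                    raise InvalidStateSpaceError(
                        f"tunnel {s.name!r} destination {s.tunnel_destination!r} unknown"
                    )
                mask = s.location_mask or (MALAWI,) * s.tunnel_length
                if len(mask) != s.tunnel_length:
                    raise InvalidStateSpaceError(
                        f"location mask of {s.name!r} must have {s.tunnel_length} entries"
                    )
                for loc in mask:
                    if loc not in LOCATIONS:
                        raise InvalidStateSpaceError(f"unknown location {loc!r}")
            elif s.tunnel_length is not None:
                raise InvalidStateSpaceError(
                    f"non-tunnel state {s.name!r} must not carry a tunnel length"
                )
            if s.counts_specialist_year and not s.counts_doctor_year:
                raise InvalidStateSpaceError(
                    f"{s.name!r}: specialists are doctors; the specialist-year "
                    "flag requires the doctor-year flag"
                )
            if s.progress_to is not None and s.progress_to not in self._by_name:
                raise InvalidStateSpaceError(
                    f"{s.name!r} progresses to unknown state {s.progress_to!r}"
                )

    def _build_slots(self) -> None:
        slots: list[Slot] = []
        first: dict[str, int] = {}
        for s in self.states:
            first[s.name] = len(slots)
            if s.kind == "tunnel":
                mask = s.location_mask or (MALAWI,) * s.tunnel_length
                for i, loc in enumerate(mask):
                    slots.append(Slot(
                        state=s.name, index=i, location=loc,
                        doctor_year=s.counts_doctor_year and loc == MALAWI,
                        specialist_year=s.counts_specialist_year and loc == MALAWI,
                    ))
            elif s.counts_specialist_year:
                # first post-qualification cycle is its own slot so one-off
                # costs (vehicle allowance) can attach to it
                slots.append(Slot(s.name, 0, MALAWI, True, True, first_specialist=True))
                slots.append(Slot(s.name, 1, MALAWI, True, True))
            else:
                loc = None if s.kind == "absorbing" else MALAWI
                slots.append(Slot(
                    s.name, 0, loc, s.counts_doctor_year, s.counts_specialist_year,
                ))
        self.slots: tuple[Slot, ...] = tuple(slots)
        self._first_slot = first
        self._slot_range = {
            name: range(first[name], first[name] + self.n_slots_of(name))
            for name in self._by_name
        }

    # -- basic queries ------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    @property
    def entry_state(self) -> StateDef:
        return next(s for s in self.states if s.kind == "entry")

    @property
    def temporary_states(self) -> tuple[StateDef, ...]:
        return tuple(s for s in self.states if s.kind != "absorbing")

    @property
    def absorbing_states(self) -> tuple[StateDef, ...]:
        return tuple(s for s in self.states if s.kind == "absorbing")

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> StateDef:
        return self._by_name[name]

    def n_slots_of(self, name: str) -> int:
        s = self._by_name[name]
        if s.kind == "tunnel":
            return s.tunnel_length
        return 2 if s.counts_specialist_year else 1

    def first_slot(self, name: str) -> int:
        """Slot receiving inflow into ``name`` (tunnel entrance, first
        specialist cycle)."""
        return self._first_slot[name]

    def slot_indices(self, name: str) -> range:
        return self._slot_range[name]

    def entry_slot(self, name: str, established: bool = False) -> int:
        """Slot where existing stock in ``name`` is placed; established
        specialists skip the first-cycle slot (no fresh one-off costs)."""
        i = self._first_slot[name]
        if established and self._by_name[name].counts_specialist_year:
            i += 1
        return i

    def with_pretraining(self, length: int, destination: str) -> "StateSpace":
        """Return a copy with the pre-training tunnel rewired (mandatory
        service length and the registrar state it feeds)."""
        states = []
        for s in self.states:
            if s.name == PRETRAINING:
                s = replace(
                    s, tunnel_length=length,
                    location_mask=(MALAWI,) * length,
                    tunnel_destination=destination,
                )
            states.append(s)
        return StateSpace(states, force_generalist_cycle=self.force_generalist_cycle)

    # -- wiring used by the engines ------------------------------------

    def stay_slot(self, slot_idx: int, t: int) -> int:
        """Slot receiving the stay/progress complement of ``slot_idx``
        when the end-of-cycle-``t`` transition is applied."""
        slot = self.slots[slot_idx]
        state = self._by_name[slot.state]
        if state.kind == "absorbing":
            return slot_idx
        if state.kind == "tunnel":
            if slot.index + 1 < state.tunnel_length:
                return slot_idx + 1
            return self._first_slot[state.tunnel_destination]
        if state.kind == "entry" and state.progress_to is not None:
            return self._first_slot[state.progress_to]
        if (self.force_generalist_cycle is not None
                and slot.state == MEDICAL_OFFICER
                and t == self.force_generalist_cycle):
            return self._first_slot[GENERALIST]
        if slot.first_specialist:
            return slot_idx + 1
        return slot_idx

    def slot_frame(self) -> pd.DataFrame:
        """Slot metadata as a DataFrame (one row per internal slot)."""
        return pd.DataFrame([{
            "state": s.state, "slot": s.index, "location": s.location,
            "doctor_year": s.doctor_year, "specialist_year": s.specialist_year,
            "first_specialist": s.first_specialist,
        } for s in self.slots])

    def aggregate(self, occupancy: np.ndarray) -> pd.DataFrame:
        """Sum slot occupancy (..., n_slots) back to named states."""
        occupancy = np.asarray(occupancy)
        cols = {}
        for name in self.names:
            r = self._slot_range[name]
            cols[name] = occupancy[..., r.start:r.stop].sum(axis=-1)
        return pd.DataFrame(cols)


def default_roster(
    service_years: int = 2,
    pretraining_destination: str = REGISTRAR_MALAWI,
    sandwich_mask: tuple[str, ...] = DEFAULT_SANDWICH_MASK,
) -> list[StateDef]:
    """The baseline 13-state roster: 10 temporary (3 four-cycle registrar
    tunnels, a variable-length pre-training tunnel) and 3 absorbing exits."""
    dy = dict(counts_doctor_year=True)
    sy = dict(counts_doctor_year=True, counts_specialist_year=True)
    return [
        StateDef(INTERN, "entry", progress_to=MEDICAL_OFFICER, **dy),
        StateDef(MEDICAL_OFFICER, "temporary", **dy),
        StateDef(PRETRAINING, "tunnel", tunnel_length=service_years,
                 location_mask=(MALAWI,) * service_years,
                 tunnel_destination=pretraining_destination, **dy),
        StateDef(REGISTRAR_MALAWI, "tunnel", tunnel_length=4,
                 location_mask=(MALAWI,) * 4,
                 tunnel_destination=SPECIALIST_MALAWI, **dy),
        StateDef(REGISTRAR_SANDWICH, "tunnel", tunnel_length=4,
                 location_mask=tuple(sandwich_mask),
                 tunnel_destination=SPECIALIST_SANDWICH, **dy),
        StateDef(REGISTRAR_SA, "tunnel", tunnel_length=4,
                 location_mask=(SOUTH_AFRICA,) * 4,
                 tunnel_destination=SPECIALIST_SA, **dy),
        StateDef(SPECIALIST_MALAWI, "temporary", **sy),
        StateDef(SPECIALIST_SANDWICH, "temporary", **sy),
        StateDef(SPECIALIST_SA, "temporary", **sy),
        StateDef(GENERALIST, "temporary", **dy),
        StateDef(EXIT_MALAWI, "absorbing"),
        StateDef(EXIT_PUBLIC_SECTOR, "absorbing"),
        StateDef(EXIT_HLM, "absorbing"),
    ]


def build_state_space(
    roster_config: Sequence[StateDef | Mapping] | None = None, **kwargs
) -> StateSpace:
    """Build and validate a StateSpace from a roster (defaults to the
    baseline 13-state roster)."""
    if roster_config is None:
        roster_config = default_roster(**kwargs)
    states = [
        s if isinstance(s, StateDef) else StateDef(**dict(s))
        for s in roster_config
    ]
    return StateSpace(states)


class HazardSchedule:
    """Named exit/entry hazards per origin state, career cycle and cohort.

    Each hazard is stored as a 2-D table ``(n_cycles_or_1, n_cohorts_or_1)``;
    a 1-row or 1-column axis broadcasts (constant over that dimension) and
    lookups past the last tabulated cycle/cohort clamp to the final value.
    Stay/progress probabilities are never stored: they are the complement
    of the hazard row sum.
    """

    def __init__(
        self,
        tables: Mapping[tuple[str, str], "np.ndarray | float"],
        n_cycles: int,
        n_cohorts: int,
        destinations: Mapping[str, str] | None = None,
    ):
        self.n_cycles = int(n_cycles)
        self.n_cohorts = int(n_cohorts)
        self.destinations = dict(destinations or DEFAULT_DESTINATIONS)
        self.tables: dict[tuple[str, str], np.ndarray] = {}
        for key, value in tables.items():
            self.tables[key] = self._as_table(value)

    def _as_table(self, value) -> np.ndarray:
        arr = np.atleast_2d(np.asarray(value, dtype=float))
        if arr.ndim != 2:
            raise InvalidScheduleError("hazard tables must be scalar, 1-D or 2-D")
        return arr

    # -- access --------------------------------------------------------

    def origins(self) -> list[str]:
        return sorted({origin for origin, _ in self.tables})

    def hazards_for(self, origin: str) -> dict[str, np.ndarray]:
        return {n: tab for (o, n), tab in self.tables.items() if o == origin}

    def value(self, origin: str, name: str, t: int, c: int) -> float:
        tab = self.tables[(origin, name)]
        return float(tab[min(t - 1, tab.shape[0] - 1), min(c - 1, tab.shape[1] - 1)])

    def row(self, origin: str, t: int, c: int) -> dict[str, float]:
        return {
            name: self.value(origin, name, t, c)
            for (o, name) in self.tables if o == origin
        }

    def table_over_grid(self, origin: str, name: str) -> np.ndarray:
        """Hazard values broadcast/clamped to the full (n_cycles, n_cohorts) grid."""
        tab = self.tables[(origin, name)]
        rows = np.minimum(np.arange(self.n_cycles), tab.shape[0] - 1)
        cols = np.minimum(np.arange(self.n_cohorts), tab.shape[1] - 1)
        return tab[np.ix_(rows, cols)]

    # -- mutation ------------------------------------------------------

    def copy(self) -> "HazardSchedule":
        return HazardSchedule(
            {k: v.copy() for k, v in self.tables.items()},
            self.n_cycles, self.n_cohorts, self.destinations,
        )

    def set_hazard(self, origin: str, name: str, value) -> None:
        self.tables[(origin, name)] = self._as_table(value)

    def drop_hazard(self, origin: str, name: str) -> None:
        self.tables.pop((origin, name), None)

    def equals(self, other: "HazardSchedule") -> bool:
        if set(self.tables) != set(other.tables):
            return False
        return all(
            np.array_equal(
                self.table_over_grid(*k), other.table_over_grid(*k)
            ) for k in self.tables
        )

    # -- validation ----------------------------------------------------

    def row_sum_grid(self, origin: str) -> np.ndarray:
        """Sum of all hazards of ``origin`` over the full (t, c) grid."""
        total = np.zeros((self.n_cycles, self.n_cohorts))
        for (o, name) in self.tables:
            if o == origin:
                total += self.table_over_grid(o, name)
        return total

    def validate(self, space: StateSpace | None = None, atol: float = 1e-9) -> None:
        for (origin, name), tab in self.tables.items():
            if np.any(tab < -atol) or np.any(tab > 1 + atol):
                raise InvalidScheduleError(
                    f"hazard {name!r} of {origin!r} outside [0, 1]"
                )
            if name not in self.destinations:
                raise InvalidScheduleError(f"hazard {name!r} has no destination")
            if space is not None:
                if origin not in space:
                    raise InvalidScheduleError(f"unknown origin state {origin!r}")
                if space[origin].kind == "absorbing":
                    raise InvalidScheduleError(
                        f"absorbing state {origin!r} cannot have outgoing hazards"
                    )
                if self.destinations[name] not in space:
                    raise InvalidScheduleError(
                        f"hazard {name!r} points at unknown state "
                        f"{self.destinations[name]!r}"
                    )
        for origin in self.origins():
            total = self.row_sum_grid(origin)
            if np.any(total > 1 + atol):
                t, c = np.unravel_index(int(np.argmax(total)), total.shape)
                raise InvalidScheduleError(
                    f"hazard sum of {origin!r} exceeds 1 "
                    f"({total[t, c]:.6f} at cycle {t + 1}, cohort {c + 1})"
                )

    # -- CSV interchange ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (origin_state, hazard_name, cycle, cohort, value);
        a blank cycle/cohort marks a dimension over which the hazard is
        constant."""
        records = []
        for (origin, name), tab in sorted(self.tables.items()):
            nt, nc = tab.shape
            for i in range(nt):
                for j in range(nc):
                    records.append({
                        "origin_state": origin,
                        "hazard_name": name,
                        "cycle": i + 1 if nt > 1 else np.nan,
                        "cohort": j + 1 if nc > 1 else np.nan,
                        "value": tab[i, j],
                    })
        return pd.DataFrame.from_records(records)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, n_cycles: int, n_cohorts: int,
        destinations: Mapping[str, str] | None = None,
    ) -> "HazardSchedule":
        tables: dict[tuple[str, str], np.ndarray] = {}
        for (origin, name), grp in frame.groupby(["origin_state", "hazard_name"]):
            nt = int(grp["cycle"].max()) if grp["cycle"].notna().any() else 1
            nc = int(grp["cohort"].max()) if grp["cohort"].notna().any() else 1
            tab = np.zeros((nt, nc))
            rows = grp["cycle"].to_numpy(dtype=float)
            rows = np.where(np.isnan(rows), 1, rows).astype(int) - 1
            cols = grp["cohort"].to_numpy(dtype=float)
            cols = np.where(np.isnan(cols), 1, cols).astype(int) - 1
            tab[rows, cols] = grp["value"].to_numpy()
            tables[(origin, name)] = tab
        return cls(tables, n_cycles, n_cohorts, destinations)


def transition_matrix(
    space: StateSpace, schedule: HazardSchedule, t: int, c: int
) -> np.ndarray:
    """One-step slot-level transition matrix for the end of career cycle
    ``t`` of cohort ``c`` (reference implementation; rows sum to one)."""
    n = space.n_slots
    M = np.zeros((n, n))
    for state in space.states:
        slots = space.slot_indices(state.name)
        if state.kind == "absorbing":
            for i in slots:
                M[i, i] = 1.0
            continue
        hazards = schedule.row(state.name, t, c)
        total = sum(hazards.values())
        if total > 1 + 1e-9:
            raise InvalidScheduleError(
                f"hazard sum {total:.6f} > 1 for {state.name!r} at (t={t}, c={c})"
            )
        for i in slots:
            for name, v in hazards.items():
                M[i, space.first_slot(schedule.destinations[name])] += v
            M[i, space.stay_slot(i, t)] += 1.0 - total
    return M


@dataclass
class CohortTrace:
    """Occupancy of one cohort: rows are career cycles (state held during
    that cycle; end-of-cycle transitions produce the next row)."""

    occupancy: np.ndarray          # (n_cycles, n_slots)
    space: StateSpace
    entry_cycle: int               # calendar cycle of the first row
    entry_size: float
    cohort_index: int = 1
    initial_career_cycle: int = 1  # career age of the first row (stock > 1)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def career_cycles(self) -> np.ndarray:
        return self.initial_career_cycle + np.arange(self.n_cycles)

    @property
    def calendar_cycles(self) -> np.ndarray:
        return self.entry_cycle + np.arange(self.n_cycles)

    def by_state(self) -> pd.DataFrame:
        frame = self.space.aggregate(self.occupancy)
        frame.index = pd.Index(self.calendar_cycles, name="calendar_cycle")
        return frame


def step_cohort(
    occupancy_row: np.ndarray,
    state_space: StateSpace,
    hazard_schedule: HazardSchedule,
    t: int,
    c: int,
) -> np.ndarray:
    """Advance a slot-occupancy row across the end-of-cycle-``t`` transition."""
    occ = np.asarray(occupancy_row, dtype=float)
    if occ.shape != (state_space.n_slots,):
        raise ValueError(
            f"occupancy row must have {state_space.n_slots} slots, got {occ.shape}"
        )
    if np.any(occ < 0):
        raise ValueError("occupancy must be non-negative")
    M = transition_matrix(state_space, hazard_schedule, t, c)
    return occ @ M


def run_cohort(
    entry_size: float,
    entry_cycle: int,
    state_space: StateSpace,
    hazard_schedule: HazardSchedule,
    horizon: int = 40,
    cohort_index: int = 1,
    initial_occupancy: np.ndarray | None = None,
    initial_career_cycle: int = 1,
) -> CohortTrace:
    """Run one cohort from entry until the calendar horizon.

    The trace is truncated at the horizon, so a cohort entering at
    calendar cycle ``j`` contributes ``horizon - j + 1`` rows.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if entry_size <= 0:
        raise ValueError("entry_size must be positive")
    if not 1 <= entry_cycle <= horizon:
        raise ValueError("entry_cycle must lie within the horizon")
    n = horizon - entry_cycle + 1
    occ = np.zeros((n, state_space.n_slots))
    if initial_occupancy is None:
        occ[0, state_space.first_slot(state_space.entry_state.name)] = entry_size
    else:
        occ[0] = np.asarray(initial_occupancy, dtype=float)
    for k in range(1, n):
        t = initial_career_cycle + k - 1
        occ[k] = step_cohort(occ[k - 1], state_space, hazard_schedule, t, cohort_index)
    return CohortTrace(
        occupancy=occ, space=state_space, entry_cycle=entry_cycle,
        entry_size=float(entry_size), cohort_index=cohort_index,
        initial_career_cycle=initial_career_cycle,
    )
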