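"""Vectorised Markov engine.

The reference engine in :mod:`medretain.states` rebuilds a transition
matrix per step; this module precompiles the full stack of one-step
matrices for cohort 1 and applies cohort-dependent hazards (the magnet
effect on specialist emigration) as rank-one corrections, so that all
entering cohorts of a scenario advance simultaneously as one
matrix product per career cycle.  Results match the reference engine to
machine precision (asserted in the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidScheduleError
from .states import HazardSchedule, StateSpace


@dataclass
class _Correction:
    """Cohort-dependent hazard on a single slot: ``delta[t, c]`` mass is
    moved from the stay target to the hazard destination relative to the
    cohort-1 matrix."""

    slot: int
    dest: int
    stay: int
    delta: np.ndarray  # (n_cycles, n_cohorts)


class CompiledModel:
    """Pre-built transition-matrix stack for one (space, schedule) pair."""

    def __init__(self, space: StateSpace, schedule: HazardSchedule):
        self.space = space
        self.schedule = schedule
        self.n_cycles = schedule.n_cycles
        self.n_cohorts = schedule.n_cohorts
        self._compile()

    def _stay_slots(self, slot: int) -> np.ndarray:
        """Stay target of ``slot`` per career cycle 1..n_cycles.  Wiring is
        cycle-independent except the forced medical-officer -> generalist
        move, so one generic lookup plus a single override suffices."""
        space, T = self.space, self.n_cycles
        force = space.force_generalist_cycle
        probe = (force + 1) if force is not None else 1
        stays = np.full(T, space.stay_slot(slot, t=probe))
        if force is not None and force <= T:
            forced = space.stay_slot(slot, t=force)
            if forced != stays[0]:
                stays[force - 1] = forced
        return stays

    def _compile(self) -> None:
        space, schedule = self.space, self.schedule
        T, S = self.n_cycles, space.n_slots
        M = np.zeros((T, S, S))
        corrections: list[_Correction] = []
        for state in space.states:
            slots = space.slot_indices(state.name)
            if state.kind == "absorbing":
                M[:, slots, slots] = 1.0
                continue
            total = np.zeros(T)
            items = []  # (dest slot, values over t at cohort 1)
            for name, tab in schedule.hazards_for(state.name).items():
                grid = schedule.table_over_grid(state.name, name)  # (T, C)
                dest = space.first_slot(schedule.destinations[name])
                items.append((dest, grid[:, 0]))
                total += grid[:, 0]
                if grid.shape[1] > 1 and np.any(grid[:, 1:] != grid[:, [0]]):
                    # cohort-dependent hazard: only rows whose stay wiring is
                    # constant in t can be corrected after the matmul
                    for i in slots:
                        stays_i = self._stay_slots(i)
                        if np.any(stays_i != stays_i[0]):
                            raise InvalidScheduleError(
                                "cohort-dependent hazard on a state with "
                                "cycle-dependent stay wiring is not supported "
                                f"({state.name!r})"
                            )
                        corrections.append(_Correction(
                            slot=i, dest=dest, stay=int(stays_i[0]),
                            delta=grid - grid[:, [0]],
                        ))
            if np.any(total > 1 + 1e-9):
                raise InvalidScheduleError(
                    f"hazard sum exceeds 1 for {state.name!r}"
                )
            for i in slots:
                for dest, values in items:
                    M[:, i, dest] += values
                M[np.arange(T), i, self._stay_slots(i)] += 1.0 - total
        # cohort-dependent rows must also satisfy the simplex constraint
        for origin in schedule.origins():
            total = schedule.row_sum_grid(origin)
            if np.any(total > 1 + 1e-9):
                raise InvalidScheduleError(
                    f"hazard sum exceeds 1 for {origin!r} at some (t, c)"
                )
        self._M = M
        self._corrections = corrections

    def matrix(self, t: int, c: int) -> np.ndarray:
        """One-step matrix at career cycle ``t``, cohort ``c`` (clamped)."""
        ti = min(t, self.n_cycles) - 1
        M = self._M[ti].copy()
        ci = min(c, self.n_cohorts) - 1
        for corr in self._corrections:
            d = corr.delta[ti, ci]
            M[corr.slot, corr.dest] += d
            M[corr.slot, corr.stay] -= d
        return M

    def step(self, occupancy: np.ndarray, t: int) -> np.ndarray:
        """Advance occupancy ``(n_cohorts, n_slots)`` across the end of
        career cycle ``t``; row ``c-1`` uses cohort-``c`` hazards."""
        ti = min(t, self.n_cycles) - 1
        out = occupancy @ self._M[ti]
        for corr in self._corrections:
            move = occupancy[:, corr.slot] * corr.delta[ti, : occupancy.shape[0]]
            out[:, corr.dest] += move
            out[:, corr.stay] -= move
        return out

    def run_unit_cohorts(self, horizon: int) -> np.ndarray:
        """Unit-entry traces for all cohorts in career time.

        Returns ``(n_cohorts, horizon, n_slots)``: cohort ``c`` (0-based
        ``c-1``) entering with head-count one, advanced ``horizon - 1``
        steps.  Calendar truncation is applied by the caller.
        """
        C, S = self.n_cohorts, self.space.n_slots
        traces = np.zeros((C, horizon, S))
        occ = np.zeros((C, S))
        occ[:, self.space.first_slot(self.space.entry_state.name)] = 1.0
        traces[:, 0] = occ
        for k in range(1, horizon):
            occ = self.step(occ, t=k)
            traces[:, k] = occ
        return traces

    def advance_rows(
        self, occupancy_rows: np.ndarray, initial_career_cycle: int,
        n_cycles: int,
    ) -> np.ndarray:
        """Advance cohort-1 occupancy rows (existing stock) for ``n_cycles``
        rows, all starting at the same career age.  Cohort-dependent
        corrections vanish for cohort 1 by construction, so this is a plain
        matrix recursion.  Returns ``(n_rows, n_cycles, n_slots)``."""
        rows = np.atleast_2d(np.asarray(occupancy_rows, dtype=float))
        out = np.zeros((rows.shape[0], n_cycles, self.space.n_slots))
        out[:, 0] = rows
        for k in range(1, n_cycles):
            ti = min(initial_career_cycle + k - 1, self.n_cycles) - 1
            rows = rows @ self._M[ti]
            out[:, k] = rows
        return out

    def advance_row(
        self, occupancy_row: np.ndarray, initial_career_cycle: int,
        n_cycles: int, cohort_index: int = 1,
    ) -> np.ndarray:
        """Advance one occupancy row for ``n_cycles`` rows starting at the
        given career age."""
        if cohort_index == 1:
            return self.advance_rows(occupancy_row, initial_career_cycle,
                                     n_cycles)[0]
        out = np.zeros((n_cycles, self.space.n_slots))
        out[0] = occupancy_row
        # place the row in its cohort's column by padding
        row = np.zeros((cohort_index, self.space.n_slots))
        row[-1] = occupancy_row
        for k in range(1, n_cycles):
            row = self.step(row, t=initial_career_cycle + k - 1)
            out[k] = row[-1]
        return out
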