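"""Career graph construction and the single-cohort Markov engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medretain import states as stm
from medretain.engine import CompiledModel
from medretain.errors import InvalidScheduleError, InvalidStateSpaceError
from medretain.states import (
    HazardSchedule,
    SENIORITY,
    StateDef,
    StateSpace,
    build_state_space,
    default_roster,
    run_cohort,
    step_cohort,
    transition_matrix,
)


# ---------------------------------------------------------------------------
# state-space construction

def test_baseline_roster_counts():
    space = build_state_space()
    assert len(space.temporary_states) == 10
    assert len(space.absorbing_states) == 3
    for name in (stm.REGISTRAR_MALAWI, stm.REGISTRAR_SANDWICH, stm.REGISTRAR_SA):
        assert space[name].tunnel_length == 4


def test_roster_without_tunnels_is_valid():
    space = StateSpace([
        StateDef("work", "entry", counts_doctor_year=True),
        StateDef("done", "absorbing"),
    ])
    assert all(s.tunnel_length is None for s in space.states)


@pytest.mark.parametrize("roster, message", [
    ([StateDef("a", "entry"), StateDef("a", "absorbing")], "duplicate"),
    ([StateDef("a", "entry"),
      StateDef("t", "tunnel", tunnel_destination="a")], "length"),
    ([StateDef("a", "entry"),
      StateDef("s", "temporary", counts_specialist_year=True)], "doctor"),
    ([StateDef("a", "temporary")], "entry"),
    ([StateDef("a", "entry", tunnel_length=3)], "tunnel length"),
])
def test_invalid_rosters_rejected(roster, message):
    with pytest.raises(InvalidStateSpaceError, match=message):
        StateSpace(roster)


def test_pretraining_rewiring_changes_only_the_tunnel():
    space = build_state_space()
    rewired = space.with_pretraining(5, stm.REGISTRAR_SA)
    assert rewired[stm.PRETRAINING].tunnel_length == 5
    assert rewired[stm.PRETRAINING].tunnel_destination == stm.REGISTRAR_SA
    assert len(rewired.temporary_states) == 10
    assert rewired.n_slots == space.n_slots + 3


# ---------------------------------------------------------------------------
# hazard schedules

def test_schedule_validation_catches_row_sum_violation(space):
    sched = HazardSchedule(
        {(stm.INTERN, "EM_I"): 0.7, (stm.INTERN, "EPS_I"): 0.4},
        n_cycles=5, n_cohorts=1)
    with pytest.raises(InvalidScheduleError, match="exceeds 1"):
        sched.validate(space)


def test_schedule_rejects_hazards_on_absorbing_states(space):
    sched = HazardSchedule({(stm.EXIT_MALAWI, "EHLM"): 0.1},
                           n_cycles=5, n_cohorts=1)
    with pytest.raises(InvalidScheduleError, match="absorbing"):
        sched.validate(space)


def test_schedule_csv_round_trip(schedule):
    frame = schedule.to_frame()
    back = HazardSchedule.from_frame(frame, schedule.n_cycles,
                                     schedule.n_cohorts)
    assert back.equals(schedule)


def test_forced_generalist_transition_is_exactly_cycle_seven(space, schedule):
    """The stay mass of the medical-officer row moves to generalist with
    probability one at the end of cycle 7 and never otherwise."""
    mo = space.first_slot(stm.MEDICAL_OFFICER)
    gen = space.first_slot(stm.GENERALIST)
    for t in (2, 6, 7, 8):
        M = transition_matrix(space, schedule, t, c=1)
        hazard_sum = sum(schedule.row(stm.MEDICAL_OFFICER, t, 1).values())
        if t == 7:
            assert M[mo, gen] == pytest.approx(1.0 - hazard_sum)
            assert M[mo, mo] == 0.0
        else:
            assert M[mo, mo] == pytest.approx(1.0 - hazard_sum)
            assert M[mo, gen] == 0.0


# ---------------------------------------------------------------------------
# stepping

def _single_row_schedule(tables, n_cycles=10):
    return HazardSchedule(tables, n_cycles=n_cycles, n_cohorts=1)


def test_intern_complement_flows_to_medical_officer(space):
    sched = _single_row_schedule({
        (stm.INTERN, "EM_I"): 0.1, (stm.INTERN, "EPS_I"): 0.1,
        (stm.INTERN, "EHLM"): 0.01,
    })
    occ = np.zeros(space.n_slots)
    occ[space.first_slot(stm.INTERN)] = 1.0
    out = step_cohort(occ, space, sched, t=1, c=1)
    assert out[space.first_slot(stm.MEDICAL_OFFICER)] == pytest.approx(0.79)
    assert out[space.first_slot(stm.EXIT_HLM)] == pytest.approx(0.01)
    assert out.sum() == pytest.approx(1.0)


def test_zero_hazards_leave_only_forced_progressions(space):
    sched = _single_row_schedule({})
    trace = run_cohort(1.0, 1, space, sched, horizon=12)
    by_state = trace.by_state()
    # interns move on after exactly one cycle
    assert by_state[stm.INTERN].tolist() == [1.0] + [0.0] * 11
    # everyone sits in medical officer until the forced generalist move
    assert by_state.loc[7, stm.MEDICAL_OFFICER] == pytest.approx(1.0)
    assert (by_state.loc[8:, stm.GENERALIST] == 1.0).all()


def test_tunnel_emits_exactly_after_its_dwell_time(space):
    """Mass sent into a 4-cycle registrar tunnel with no exit hazard
    reappears in the specialist state exactly four cycles later."""
    sched = _single_row_schedule({(stm.MEDICAL_OFFICER, "T_M"):
                                  np.array([[0.0], [1.0]] + [[0.0]] * 8)})
    trace = run_cohort(1.0, 1, space, sched, horizon=10)
    by_state = trace.by_state()
    assert (by_state.loc[3:6, stm.REGISTRAR_MALAWI] == 1.0).all()
    assert by_state.loc[6, stm.SPECIALIST_MALAWI] == 0.0
    assert by_state.loc[7, stm.SPECIALIST_MALAWI] == pytest.approx(1.0)
    assert (by_state.loc[7:, stm.SPECIALIST_MALAWI] == 1.0).all()


def test_step_rejects_bad_inputs(space):
    sched = _single_row_schedule({(stm.INTERN, "EM_I"): 0.6,
                                  (stm.INTERN, "EPS_I"): 0.6})
    occ = np.zeros(space.n_slots)
    occ[0] = 1.0
    with pytest.raises(InvalidScheduleError):
        step_cohort(occ, space, sched, t=1, c=1)
    with pytest.raises(ValueError, match="non-negative"):
        step_cohort(occ - 2, space, _single_row_schedule({}), t=1, c=1)


# ---------------------------------------------------------------------------
# cohort-level properties

def _toy_constant_space():
    return StateSpace([
        StateDef("work", "entry", counts_doctor_year=True),
        StateDef("gone_a", "absorbing"),
        StateDef("gone_b", "absorbing"),
    ])


def test_constant_hazards_match_matrix_power_oracle():
    """With constant hazards and no tunnels the trace equals the t-th power
    of the one-step matrix applied to the entry vector."""
    space = _toy_constant_space()
    sched = HazardSchedule({("work", "A"): 0.07, ("work", "B"): 0.11},
                           n_cycles=15, n_cohorts=1,
                           destinations={"A": "gone_a", "B": "gone_b"})
    trace = run_cohort(1.0, 1, space, sched, horizon=15)
    M = transition_matrix(space, sched, 1, 1)
    v = np.array([1.0, 0.0, 0.0])
    for t in range(15):
        expected = v @ np.linalg.matrix_power(M, t)
        np.testing.assert_allclose(trace.occupancy[t], expected, rtol=1e-12,
                                   atol=1e-300)


@given(a=st.floats(0, 0.45), b=st.floats(0, 0.45),
       size=st.floats(0.5, 500))
@settings(max_examples=40, deadline=None)
def test_conservation_and_absorbing_monotonicity(a, b, size):
    space = _toy_constant_space()
    sched = HazardSchedule({("work", "A"): a, ("work", "B"): b},
                           n_cycles=12, n_cohorts=1,
                           destinations={"A": "gone_a", "B": "gone_b"})
    trace = run_cohort(size, 1, space, sched, horizon=12)
    sums = trace.occupancy.sum(axis=1)
    np.testing.assert_allclose(sums, size, atol=1e-9 * max(size, 1))
    for name in ("gone_a", "gone_b"):
        col = trace.by_state()[name].to_numpy()
        assert np.all(np.diff(col) >= -1e-12)


def test_default_model_conserves_mass_and_respects_hierarchy(space, schedule):
    trace = run_cohort(100.0, 1, space, schedule, horizon=40, cohort_index=3)
    np.testing.assert_allclose(trace.occupancy.sum(axis=1), 100.0, atol=1e-8)
    for name in (stm.EXIT_MALAWI, stm.EXIT_PUBLIC_SECTOR, stm.EXIT_HLM):
        col = trace.by_state()[name].to_numpy()
        assert np.all(np.diff(col) >= -1e-9)
    # seniority: no mass ever flows downward
    for t in (1, 2, 7, 20):
        M = transition_matrix(space, schedule, t, c=3)
        for i, si in enumerate(space.slots):
            for j, sj in enumerate(space.slots):
                if M[i, j] > 0:
                    assert SENIORITY[sj.state] >= SENIORITY[si.state]


# ---------------------------------------------------------------------------
# compiled engine equivalence

def test_compiled_matrices_match_reference(space, schedule):
    model = CompiledModel(space, schedule)
    for t in (1, 2, 7, 13, 40):
        for c in (1, 5, 40):
            np.testing.assert_allclose(
                model.matrix(t, c), transition_matrix(space, schedule, t, c),
                rtol=0, atol=1e-15)


def test_batched_cohorts_match_reference_runs(space, schedule):
    model = CompiledModel(space, schedule)
    unit = model.run_unit_cohorts(horizon=25)
    for c in (1, 7, 31):
        ref = run_cohort(1.0, 1, space, schedule, horizon=25, cohort_index=c)
        np.testing.assert_allclose(unit[c - 1], ref.occupancy, atol=1e-14)


def test_stock_advance_matches_reference(space, schedule):
    model = CompiledModel(space, schedule)
    occ0 = np.zeros(space.n_slots)
    occ0[space.entry_slot(stm.SPECIALIST_MALAWI, established=True)] = 30.0
    fast = model.advance_rows(occ0, initial_career_cycle=12, n_cycles=20)[0]
    ref = run_cohort(30.0, 1, space, schedule, horizon=20,
                     initial_occupancy=occ0, initial_career_cycle=12)
    np.testing.assert_allclose(fast, ref.occupancy, atol=1e-12)
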