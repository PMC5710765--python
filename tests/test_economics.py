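"""Discounting, state costing and effect accounting."""

import numpy as np
import pytest

from medretain import states as stm
from medretain.economics import (
    CostSchedule,
    accumulate,
    annual_state_cost,
    discount,
    valuation_thresholds,
)
from medretain.states import CohortTrace


@pytest.fixture()
def sparse_costs():
    """Minimal cost table: only the components under test are non-zero."""
    return CostSchedule(
        salary={stm.GENERALIST: 100.0},
        pension_uplift_fraction=0.10,
        tuition_per_training_year={stm.SOUTH_AFRICA: 15.0, stm.MALAWI: 2.0},
        registrar_allowances=3.0,
        one_off_vehicle=8.0,
    )


# ---------------------------------------------------------------------------
# discounting

def test_discount_base_cycle_conventions():
    assert discount(100.0, 1, 0.03) == 100.0
    assert discount(103.0, 2, 0.03) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        discount(1.0, 0, 0.03)


def test_constant_stream_matches_annuity_due_closed_form():
    """A unit stream over 40 cycles discounted at 3% equals the annuity-due
    closed form (1 - 1.03^-40)/0.03 * 1.03."""
    summed = sum(discount(1.0, t, 0.03) for t in range(1, 41))
    closed = (1 - 1.03 ** -40) / 0.03 * 1.03
    assert summed == pytest.approx(closed, rel=1e-12)


# ---------------------------------------------------------------------------
# per-state costs

def test_salary_uplift_arithmetic(space, sparse_costs):
    assert annual_state_cost(stm.GENERALIST, 1, sparse_costs, space) == \
        pytest.approx(110.0)


def test_sa_registrar_cycle_costs_tuition_and_allowances_only(
        space, sparse_costs):
    cost = annual_state_cost(stm.REGISTRAR_SA, 2, sparse_costs, space)
    assert cost == pytest.approx(15.0 + 3.0)  # no Malawian salary abroad


def test_first_specialist_cycle_adds_exactly_the_vehicle(space, sparse_costs):
    first = annual_state_cost(stm.SPECIALIST_MALAWI, 1, sparse_costs, space)
    second = annual_state_cost(stm.SPECIALIST_MALAWI, 2, sparse_costs, space)
    assert first - second == pytest.approx(8.0)


def test_absorbing_states_cost_nothing(space, sparse_costs):
    assert annual_state_cost(stm.EXIT_MALAWI, 1, sparse_costs, space) == 0.0
    with pytest.raises(KeyError):
        annual_state_cost("surgeon", 1, sparse_costs, space)


# ---------------------------------------------------------------------------
# accumulation

def _trace_in(space, slot, n, value=1.0):
    occ = np.zeros((n, space.n_slots))
    occ[:, slot] = value
    return CohortTrace(occupancy=occ, space=space, entry_cycle=1,
                       entry_size=value)


def test_zero_occupancy_accumulates_nothing(space, sparse_costs):
    occ = np.zeros((5, space.n_slots))
    tr = CohortTrace(occ, space, entry_cycle=1, entry_size=1.0)
    costs, effects = accumulate(tr, sparse_costs, space, rate=0.03)
    assert costs.total == 0.0
    assert effects.doctor_years == 0.0
    assert effects.specialist_years == 0.0


def test_forty_undiscounted_years_in_a_malawi_state(space, sparse_costs):
    tr = _trace_in(space, space.first_slot(stm.GENERALIST), 40)
    _, effects = accumulate(tr, sparse_costs, space, rate=0.0)
    assert effects.doctor_years == pytest.approx(40.0)
    assert effects.specialist_years == 0.0


def test_sa_training_years_cost_but_do_not_count(space, sparse_costs):
    """Four undiscounted cycles in the South-Africa registrar tunnel accrue
    4 x (tuition + allowances) of cost and zero doctor-years."""
    occ = np.zeros((4, space.n_slots))
    for k, i in enumerate(space.slot_indices(stm.REGISTRAR_SA)):
        occ[k, i] = 1.0
    tr = CohortTrace(occ, space, entry_cycle=1, entry_size=1.0)
    costs, effects = accumulate(tr, sparse_costs, space, rate=0.0)
    assert effects.doctor_years == 0.0
    assert costs.total == pytest.approx(4 * (15.0 + 3.0))


def test_sandwich_training_counts_only_malawi_cycles(space, sparse_costs):
    occ = np.zeros((4, space.n_slots))
    for k, i in enumerate(space.slot_indices(stm.REGISTRAR_SANDWICH)):
        occ[k, i] = 1.0
    tr = CohortTrace(occ, space, entry_cycle=1, entry_size=1.0)
    _, effects = accumulate(tr, sparse_costs, space, rate=0.0)
    assert effects.doctor_years == pytest.approx(2.0)  # cycles 1 and 4 home


def test_discounted_totals_never_exceed_undiscounted(
        bundle, space, results_wp):
    r = results_wp["baseline"]
    assert r.costs.total < r.costs.total_undiscounted
    assert r.effects.doctor_years < r.effects.doctor_years_undiscounted
    assert r.effects.specialist_years <= r.effects.doctor_years


def test_cost_homogeneity_and_effect_invariance(bundle, space, schedule):
    """Doubling every cost entry doubles costs and leaves effects alone."""
    from medretain.population import EntryPlan, simulate_population

    pop = simulate_population(EntryPlan(100, 5, 3), None, space, schedule,
                              horizon=12)
    c1, e1 = accumulate(pop, bundle.costs, space, 0.03)
    c2, e2 = accumulate(pop, bundle.costs.scaled(2.0), space, 0.03)
    assert c2.total == pytest.approx(2 * c1.total, rel=1e-12)
    assert e2.doctor_years == e1.doctor_years


# ---------------------------------------------------------------------------
# valuation thresholds

def test_constant_cost_career_prices_at_exactly_that_cost(space):
    costs = CostSchedule(salary={stm.GENERALIST: 50.0,
                                 stm.SPECIALIST_MALAWI: 70.0},
                         pension_uplift_fraction=0.0)
    tr = _trace_in(space, space.first_slot(stm.GENERALIST), 40)
    c, e = accumulate(tr, costs, space, rate=0.03)
    vt = valuation_thresholds(c, e, space, costs, rate=0.03)
    assert vt.per_doctor_year == pytest.approx(50.0)


def test_specialists_are_valued_above_doctors(bundle, space, results_wp):
    base = results_wp["baseline"]
    vt = valuation_thresholds(base.costs, base.effects, space, bundle.costs)
    assert vt.per_specialist_year / vt.per_doctor_year > 1.0


def test_thresholds_scale_with_the_cost_table(bundle, space, results_wp):
    base = results_wp["baseline"]
    vt1 = valuation_thresholds(base.costs, base.effects, space, bundle.costs)
    doubled_cost = base.costs
    import dataclasses
    doubled = dataclasses.replace(
        base.costs, total=2 * base.costs.total,
        by_component={k: 2 * v for k, v in base.costs.by_component.items()},
        total_undiscounted=2 * base.costs.total_undiscounted)
    vt2 = valuation_thresholds(doubled, base.effects, space,
                               bundle.costs.scaled(2.0))
    assert vt2.per_doctor_year == pytest.approx(2 * vt1.per_doctor_year)
    assert vt2.per_specialist_year == pytest.approx(
        2 * vt1.per_specialist_year)


def test_cost_schedule_csv_round_trip(bundle):
    frame = bundle.costs.to_frame()
    back = CostSchedule.from_frame(frame)
    assert back == bundle.costs
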