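"""Probabilistic sensitivity analysis.

Standard health-economics practice: probabilities get beta distributions,
rows of competing hazards are drawn jointly from a dirichlet (so the
simplex constraint cannot be violated at the anchors), and costs get
gamma distributions — all by method of moments around the deterministic
central values with a default relative standard error of 0.2.  One master
seed spawns a child generator per draw; within a draw the same drawn
parameter set evaluates every scenario (common random numbers), so
scenario comparisons are draw-wise coherent.

A drawn parameter set can still push a hazard row past 1 at some cycle
(the anchors sit on the simplex but trends grow the exit-health-labour-
market hazard), in which case the offending row is renormalised
proportionally — preserving its dirichlet shares — and the event logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scenarios as sc
from .params import ParameterBundle
from .runmodel import RunSettings, evaluate_scenarios, ScenarioResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamDist:
    """One sampled parameter (or jointly sampled hazard row)."""

    kind: str            # "beta" | "gamma" | "dirichlet"
    target: tuple        # symbolic address inside the bundle
    mean: tuple          # central value(s)
    rse: float           # relative standard error of the (leading) mean


@dataclass
class PSASpec:
    """Distributions assigned to every sampled parameter of a bundle."""

    entries: list[ParamDist] = field(default_factory=list)
    rse: float = 0.2


def _beta_params(m: float, rse: float) -> tuple[float, float]:
    var = (rse * m) ** 2
    if var >= m * (1 - m):
        raise ValueError(
            f"beta mean {m:.3f} with rse {rse} exceeds the [0,1] support"
        )
    common = m * (1 - m) / var - 1.0
    return m * common, (1 - m) * common


def _dirichlet_alpha(hazard_means: np.ndarray, stay: float, rse: float
                     ) -> np.ndarray:
    """Concentration chosen so the largest *hazard* component (not the stay
    remainder) has the target relative standard error."""
    p = float(hazard_means.max())
    nu = (1 - p) / (p * rse ** 2) - 1.0
    if nu <= 0:
        raise ValueError(f"dirichlet mean {p:.3f} too large for rse {rse}")
    return nu * np.append(hazard_means, stay)


def assign_distributions(
    parameter_set: ParameterBundle, dispersion_policy: float = 0.2
) -> PSASpec:
    """Assign a distribution to every uncertain parameter of the bundle:
    hazard rows -> dirichlet, uptake and the baseline training rate ->
    beta, the baseline allocation -> dirichlet, costs -> gamma."""
    rse = float(dispersion_policy)
    spec = PSASpec(rse=rse)
    for origin in sorted(parameter_set.hazard_anchors):
        hazards = parameter_set.hazard_anchors[origin]
        names = tuple(sorted(hazards))
        means = tuple(float(hazards[n]) for n in names)
        spec.entries.append(ParamDist(
            "dirichlet", ("hazard_row", origin, names), means, rse))
    spec.entries.append(ParamDist(
        "beta", ("training_rate",),
        (float(parameter_set.baseline_training_rate),), rse))
    spec.entries.append(ParamDist(
        "dirichlet", ("allocation",),
        tuple(float(x) for x in parameter_set.baseline_allocation), rse))
    for idx, row in parameter_set.uptake.reset_index(drop=True).iterrows():
        spec.entries.append(ParamDist(
            "beta",
            ("uptake", str(row["subgroup"]), str(row["location"]),
             int(row["service_years"])),
            (float(row["uptake"]),), rse))
    cs = parameter_set.costs
    for group, d in (("salary", cs.salary), ("transport", cs.transport),
                     ("monthly_allowances", cs.monthly_allowances),
                     ("tuition", cs.tuition_per_training_year)):
        for key in sorted(d):
            spec.entries.append(ParamDist(
                "gamma", ("cost", group, key), (float(d[key]),), rse))
    for scalar in ("annual_housing", "one_off_vehicle", "registrar_allowances"):
        spec.entries.append(ParamDist(
            "gamma", ("cost", "scalar", scalar), (float(getattr(cs, scalar)),),
            rse))
    return spec


def _draw_value(entry: ParamDist, rng: np.random.Generator):
    means = np.asarray(entry.mean, dtype=float)
    if entry.rse == 0 or np.all(means == 0):
        return tuple(means)  # zero-variance limit: degenerate at the mean
    if entry.kind == "beta":
        a, b = _beta_params(float(means[0]), entry.rse)
        return (float(rng.beta(a, b)),)
    if entry.kind == "gamma":
        k = 1.0 / entry.rse ** 2
        return (float(rng.gamma(k, float(means[0]) / k)),)
    if entry.kind == "dirichlet":
        stay = 1.0 - means.sum()
        if stay <= 1e-12:  # full simplex (e.g. the baseline allocation)
            alpha = _dirichlet_alpha(means[:-1], means[-1], entry.rse)
            return tuple(rng.dirichlet(alpha))
        alpha = _dirichlet_alpha(means, stay, entry.rse)
        draw = rng.dirichlet(alpha)
        return tuple(draw[:-1])
    raise ValueError(f"unknown distribution kind {entry.kind!r}")


def draw_bundle(
    spec: PSASpec, central: ParameterBundle, rng: np.random.Generator
) -> ParameterBundle:
    """One Monte-Carlo parameter set around the central bundle."""
    out = central.copy()
    uptake = out.uptake.reset_index(drop=True)
    uptake_key = {
        (str(r["subgroup"]), str(r["location"]), int(r["service_years"])): i
        for i, r in uptake.iterrows()
    }
    for entry in spec.entries:
        values = _draw_value(entry, rng)
        t = entry.target
        if t[0] == "hazard_row":
            _, origin, names = t
            for name, v in zip(names, values):
                out.hazard_anchors[origin][name] = v
        elif t[0] == "training_rate":
            out.baseline_training_rate = values[0]
        elif t[0] == "allocation":
            out.baseline_allocation = tuple(values)
        elif t[0] == "uptake":
            uptake.loc[uptake_key[t[1:]], "uptake"] = values[0]
        elif t[0] == "cost":
            _, group, key = t
            if group == "salary":
                out.costs.salary[key] = values[0]
            elif group == "transport":
                out.costs.transport[key] = values[0]
            elif group == "monthly_allowances":
                out.costs.monthly_allowances[key] = values[0]
            elif group == "tuition":
                out.costs.tuition_per_training_year[key] = values[0]
            else:
                setattr(out.costs, key, values[0])
    out.uptake = uptake
    return out


def _renormalize_rows(bundle: ParameterBundle, settings: RunSettings,
                      subgroup: str = "whole_population") -> int:
    """Project any hazard row whose drawn trajectory leaves the simplex back
    onto it (proportional rescale over the whole row — hazards and, for the
    medical-officer row, the training offer — preserving the dirichlet
    shares).  Returns the number of rescaled rows."""
    from .params import build_hazard_schedule

    n_events = 0
    background = bundle.copy()
    background.baseline_training_rate = 0.0
    schedule = build_hazard_schedule(
        background, settings.n_table_cycles(bundle), bundle.entry_plan.n_cohorts)
    # the medical-officer row must absorb the largest uptake this draw
    # will actually offer (evaluated subgroup only)
    rows = bundle.uptake[bundle.uptake["subgroup"] == subgroup]
    max_uptake = float(rows["uptake"].max()) if len(rows) else 0.0
    max_uptake = max(max_uptake, bundle.baseline_training_rate)
    for origin in schedule.origins():
        peak = schedule.row_sum_grid(origin).max()
        limit = 1.0 - 1e-9
        row_total = peak
        if origin == sc.states.MEDICAL_OFFICER:
            row_total = peak + max_uptake
        if row_total > limit:
            scale = limit / row_total
            for name in bundle.hazard_anchors.get(origin, {}):
                bundle.hazard_anchors[origin][name] *= scale
            if origin == sc.states.MEDICAL_OFFICER:
                bundle.uptake = bundle.uptake.copy()
                bundle.uptake["uptake"] *= scale
                bundle.baseline_training_rate *= scale
            n_events += 1
            logger.debug(
                "PSA draw renormalised hazard row %r (peak sum %.4f)",
                origin, row_total,
            )
    return n_events


@dataclass
class PSADraws:
    """Per-scenario Monte-Carlo draws of discounted cost and effects."""

    scenarios: list[str]
    cost: np.ndarray               # (n_draws, n_scenarios)
    doctor_years: np.ndarray
    specialist_years: np.ndarray
    seed: int
    subgroup: str = "whole_population"
    n_renormalized: int = 0

    @property
    def n_draws(self) -> int:
        return self.cost.shape[0]

    def means(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cost": self.cost.mean(axis=0),
            "doctor_years": self.doctor_years.mean(axis=0),
            "specialist_years": self.specialist_years.mean(axis=0),
        }, index=pd.Index(self.scenarios, name="scenario"))

    def to_frame(self) -> pd.DataFrame:
        n, k = self.cost.shape
        return pd.DataFrame({
            "scenario": np.repeat(self.scenarios, n),
            "draw": np.tile(np.arange(1, n + 1), k),
            "cost": self.cost.ravel(order="F"),
            "doctor_years": self.doctor_years.ravel(order="F"),
            "specialist_years": self.specialist_years.ravel(order="F"),
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = 0,
                   subgroup: str = "whole_population") -> "PSADraws":
        names = list(dict.fromkeys(frame["scenario"]))
        piv = {c: frame.pivot_table(index="draw", columns="scenario", values=c,
                                    sort=False)[names].to_numpy()
               for c in ("cost", "doctor_years", "specialist_years")}
        return cls(names, piv["cost"], piv["doctor_years"],
                   piv["specialist_years"], seed=seed, subgroup=subgroup)


def run_psa(
    model_bundle: ParameterBundle,
    n_draws: int = 2000,
    seed: int = 0,
    subgroup: str = "whole_population",
    settings: RunSettings | None = None,
    dispersion_policy: float = 0.2,
    scenario_list: list[sc.Scenario] | None = None,
) -> PSADraws:
    """Monte-Carlo propagation of parameter uncertainty.

    Per draw: sample one parameter set, renormalise any hazard row the
    drawn trends push off the simplex (logged), then evaluate every
    scenario deterministically with that set.
    """
    settings = settings or RunSettings()
    if scenario_list is None:
        scenario_list = sc.enumerate_scenarios(subgroup=subgroup,
                                               include_baseline=True)
    spec = assign_distributions(model_bundle, dispersion_policy)
    names = [s.name for s in scenario_list]
    cost = np.zeros((n_draws, len(names)))
    dy = np.zeros_like(cost)
    sy = np.zeros_like(cost)
    children = np.random.SeedSequence(seed).spawn(n_draws)
    n_renorm = 0
    for d in range(n_draws):
        rng = np.random.default_rng(children[d])
        drawn = draw_bundle(spec, model_bundle, rng)
        n_renorm += _renormalize_rows(drawn, settings, subgroup)
        results = evaluate_scenarios(drawn, scenario_list, subgroup, settings)
        for k, name in enumerate(names):
            r: ScenarioResult = results[name]
            cost[d, k] = r.costs.total
            dy[d, k] = r.effects.doctor_years
            sy[d, k] = r.effects.specialist_years
    if n_renorm:
        logger.warning("PSA renormalised %d hazard rows across %d draws",
                       n_renorm, n_draws)
    return PSADraws(names, cost, dy, sy, seed=seed, subgroup=subgroup,
                    n_renormalized=n_renorm)
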