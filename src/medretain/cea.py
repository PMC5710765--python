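"""ICERs, net monetary benefit and cost-effectiveness acceptability frontiers.

Every intervention is compared pairwise against the baseline: the ICER is
the ratio of incremental discounted cost to incremental discounted effect
(doctor-years or specialist-years), with the usual dominance
classification.  The CEAF scans a willingness-to-pay grid (0 to MWK 50
million in steps of 100,000 by default): at each threshold the optimal
option maximises mean net monetary benefit, and its probability of being
cost-effective is its win-share across the Monte-Carlo draws (ties split
equally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .uncertainty import PSADraws

EFFECTS = ("doctor_years", "specialist_years")

COST_SAVING = "cost_saving_more_effective"
TRADEOFF = "tradeoff"
DOMINATED = "dominated"
LESS_EFFECTIVE_CHEAPER = "less_effective_cheaper"


@dataclass(frozen=True)
class ICERResult:
    scenario: str
    effect: str
    delta_cost: float
    delta_effect: float
    icer: float | None          # None marks an undefined ratio (zero effect)
    dominance: str


def _classify(dc: float, de: float) -> str:
    if de > 0:
        return COST_SAVING if dc < 0 else TRADEOFF
    if de < 0:
        return LESS_EFFECTIVE_CHEAPER if dc < 0 else DOMINATED
    # equal effects: the cheaper option simply saves money
    if dc > 0:
        return DOMINATED
    return COST_SAVING if dc < 0 else TRADEOFF


def icer(scenario_summary, baseline_summary, effect: str = "doctor_years"
         ) -> ICERResult:
    """Incremental cost-effectiveness ratio of one intervention versus
    baseline.  Summaries are mappings with ``cost`` and the effect columns
    (e.g. rows of a results frame or of PSA means)."""
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    dc = float(scenario_summary["cost"] - baseline_summary["cost"])
    de = float(scenario_summary[effect] - baseline_summary[effect])
    name = str(scenario_summary.get("scenario", getattr(
        scenario_summary, "name", "")))
    value = dc / de if de != 0 else None
    return ICERResult(name, effect, dc, de, value, _classify(dc, de))


def nmb(cost: float, effect: float, lam: float) -> float:
    """Net monetary benefit at willingness-to-pay ``lam`` per effect unit."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return lam * effect - cost


def threshold_grid(maximum: float = 50_000_000.0, step: float = 100_000.0
                   ) -> np.ndarray:
    """Willingness-to-pay grid, inclusive of both endpoints."""
    n = int(round(maximum / step))
    return np.linspace(0.0, n * step, n + 1)


def ceaf(psa_draws: PSADraws, grid: np.ndarray | None = None,
         effect: str = "doctor_years") -> pd.DataFrame:
    """Cost-effectiveness acceptability frontier.

    Per threshold: the optimal option (highest mean NMB across draws) and
    the probability it is cost-effective (share of draws in which its NMB
    is highest; exact ties split equally).
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    if psa_draws.n_draws == 0:
        raise ValueError("no PSA draws")
    if grid is None:
        grid = threshold_grid()
    eff = getattr(psa_draws, effect)      # (n_draws, K)
    cost = psa_draws.cost
    mean_eff = eff.mean(axis=0)
    mean_cost = cost.mean(axis=0)
    rows = []
    for lam in np.asarray(grid, dtype=float):
        mean_nmb = lam * mean_eff - mean_cost
        opt = int(np.argmax(mean_nmb))
        draw_nmb = lam * eff - cost
        best = draw_nmb.max(axis=1, keepdims=True)
        is_best = draw_nmb == best
        wins = is_best[:, opt] / is_best.sum(axis=1)
        rows.append({
            "lambda": lam,
            "optimal": psa_draws.scenarios[opt],
            "probability": float(wins.mean()),
            "mean_nmb": float(mean_nmb[opt]),
        })
    return pd.DataFrame(rows)


def ceaf_switch_points(frontier: pd.DataFrame) -> pd.DataFrame:
    """Thresholds at which the frontier's optimal option changes."""
    change = frontier["optimal"] != frontier["optimal"].shift()
    return frontier.loc[change, ["lambda", "optimal"]].reset_index(drop=True)


def percent_gain(proportion: float) -> float:
    """Effect expressed as percentage gain over baseline (1.17 -> 17%)."""
    return (proportion - 1.0) * 100.0


def proportions_of_baseline(results_frame: pd.DataFrame,
                            baseline: str = "baseline") -> pd.DataFrame:
    """Effects of each scenario as a proportion of the baseline scenario
    (discounted and undiscounted), plus percent gains."""
    if baseline not in results_frame.index:
        raise KeyError(f"missing baseline row {baseline!r}")
    base = results_frame.loc[baseline]
    out = pd.DataFrame(index=results_frame.index)
    for col in ("doctor_years", "specialist_years",
                "doctor_years_undiscounted", "specialist_years_undiscounted"):
        if col in results_frame.columns:
            out[f"{col}_prop"] = results_frame[col] / base[col]
    out["doctor_years_gain_pct"] = percent_gain(out["doctor_years_prop"])
    out["specialist_years_gain_pct"] = percent_gain(out["specialist_years_prop"])
    return out


def icer_table(results_frame: pd.DataFrame, baseline: str = "baseline"
               ) -> pd.DataFrame:
    """ICERs versus baseline for both effect measures."""
    if baseline not in results_frame.index:
        raise KeyError(f"missing baseline row {baseline!r}")
    base = results_frame.loc[baseline]
    rows = []
    for name, row in results_frame.iterrows():
        if name == baseline:
            continue
        for effect in EFFECTS:
            r = icer(row, base, effect)
            rows.append({
                "scenario": name, "effect": effect,
                "delta_cost": r.delta_cost, "delta_effect": r.delta_effect,
                "icer": np.nan if r.icer is None else r.icer,
                "dominance": r.dominance,
            })
    return pd.DataFrame(rows)


def summarize(results_frame: pd.DataFrame,
              psa_draws: PSADraws | None = None,
              grid: np.ndarray | None = None,
              baseline: str = "baseline") -> dict[str, pd.DataFrame]:
    """Report bundle: baseline proportions / percent gains, cost-category
    shares, ICER table and (when draws are supplied) both CEAF curves."""
    share_cols = [c for c in results_frame.columns if c.startswith("share_")]
    out = {
        "proportions": proportions_of_baseline(results_frame, baseline),
        "icers": icer_table(results_frame, baseline),
        "cost_shares": results_frame[share_cols].copy(),
    }
    if psa_draws is not None:
        for effect in EFFECTS:
            out[f"ceaf_{effect}"] = ceaf(psa_draws, grid, effect)
    return out
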