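"""Run configuration: a strict YAML schema with the study defaults.

An empty file (or no file) reproduces the study configuration exactly:
40-year horizon, 3% discount on costs and effects, 40 cohorts entering
100 + 5 per cohort, 2000 PSA draws, willingness-to-pay grid 0-50m MWK in
100k steps.  Unknown keys are rejected so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .scenarios import SUBGROUPS


@dataclass
class RunConfig:
    params_dir: str | None = None       # parameter CSVs (from `generate`)
    horizon: int = 40
    discount_rate: float = 0.03
    n_cohorts: int = 40
    first_cohort_size: float = 100.0
    cohort_growth: float = 5.0
    psa_draws: int = 2000
    seed: int = 0
    subgroup: str = "whole_population"
    scenario: str | None = None         # evaluate one scenario only
    threshold_max: float = 50_000_000.0
    threshold_step: float = 100_000.0
    intl_dollar_rate: float = 158.5     # MWK per international dollar
    offer_cycle: int = 2
    uptake_mode: str = "single"         # or "repeated"
    dispersion: float = 0.2             # PSA relative standard error

    def validate(self) -> "RunConfig":
        if self.horizon < 1:
            raise ConfigError(f"horizon must be >= 1, got {self.horizon}")
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        if self.n_cohorts < 1:
            raise ConfigError("n_cohorts must be >= 1")
        if self.first_cohort_size <= 0:
            raise ConfigError("first_cohort_size must be positive")
        if self.psa_draws < 1:
            raise ConfigError("psa_draws must be >= 1")
        if self.subgroup not in SUBGROUPS:
            raise ConfigError(f"unknown subgroup {self.subgroup!r}")
        if self.threshold_max <= 0 or self.threshold_step <= 0:
            raise ConfigError("threshold grid must have positive max and step")
        if self.offer_cycle < 2:
            raise ConfigError("offer_cycle must be >= 2 (not straight "
                              "after internship)")
        if self.uptake_mode not in ("single", "repeated"):
            raise ConfigError("uptake_mode must be 'single' or 'repeated'")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML run configuration; missing keys take the
    study defaults, unknown keys are an error."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config must be a YAML mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        cfg = RunConfig(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
    return cfg.validate()
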