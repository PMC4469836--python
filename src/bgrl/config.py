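"""Run configuration: preset loading, validation, overrides, seeding.

A run is described by an experiment name, a set of named conditions (from
the packaged presets), population size, master seed, optional parameter
overrides and ablation flags.  The fully resolved configuration is echoed
into the output directory so every run is self-describing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .neuromodulators import PDCondition, SerotoninParams
from .striatum import GAIN_PRESETS, GainSet
from .tasks import (
    ExperimentSummary,
    RiskSchedule,
    run_pd_experiment,
    run_reversal_experiment,
    run_risk_experiment,
)

__all__ = ["RunConfig", "load_run_config", "load_preset", "resolve_conditions", "run"]

EXPERIMENTS = ("risk", "reversal", "pd_classification")

_CONFIG_KEYS = {
    "experiment",
    "conditions",
    "n_agents",
    "master_seed",
    "trials_per_state",
    "overrides",
    "no_sign_term",
    "persist_stn_gpe",
    "silence_stn",
    "keep_trials",
    "outdir",
}

_OVERRIDE_KEYS = {
    "alpha_d1",
    "alpha_d2",
    "alpha_d1d2",
    "delta_lim",
    "delta_med",
    "r_b",
    "etas",
}
_GAIN_SITES = ("gains_striatal", "gains_gpi")
_GAIN_PARTS = ("d1", "d2", "h_d1", "h_d2")
_GAIN_CONSTS = ("c1", "c2", "c3")


@dataclass
class RunConfig:
    """Validated run description (presets + overrides + ablations)."""

    experiment: str
    conditions: list[str] | None = None
    n_agents: int = 100
    master_seed: int = 0
    trials_per_state: int | None = None
    overrides: dict = field(default_factory=dict)
    no_sign_term: bool = False
    persist_stn_gpe: bool = False
    silence_stn: bool = False
    keep_trials: bool = False
    outdir: str = "results"

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment: {self.experiment!r}")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.trials_per_state is not None and self.trials_per_state < 1:
            raise ValueError("trials_per_state must be >= 1")
        for key, value in self.overrides.items():
            self._check_override(key, value)

    @staticmethod
    def _check_override(key: str, value) -> None:
        if key in _OVERRIDE_KEYS:
            if key == "etas":
                vals = list(value)
                if len(vals) != 3 or any(float(v) <= 0 for v in vals):
                    raise ValueError("override 'etas' must be three positive rates")
            elif key.startswith("alpha") and float(value) < 0:
                raise ValueError(f"override {key!r} must be >= 0")
            return
        parts = key.split(".")
        if (
            len(parts) == 3
            and parts[0] in _GAIN_SITES
            and parts[1] in _GAIN_PARTS
            and parts[2] in _GAIN_CONSTS
        ):
            float(value)
            return
        raise ValueError(f"unknown override key: {key!r}")


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key: {sorted(unknown)[0]!r}")
    return RunConfig(**raw)


def load_preset(experiment: str) -> dict:
    """Packaged per-experiment preset (gain table names, learning rates,
    named serotonin/PD conditions)."""
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment: {experiment!r}")
    with resources.files("bgrl.presets").joinpath(f"{experiment}.yaml").open() as fh:
        return yaml.safe_load(fh)


def _override_gains(gains: GainSet, site: str, overrides: dict) -> GainSet:
    updates: dict[str, GainSet] = {}
    for key, value in overrides.items():
        parts = key.split(".")
        if len(parts) == 3 and parts[0] == site:
            part = getattr(gains, parts[1])
            if part is None:
                raise ValueError(f"gain component {parts[1]!r} not configured for {site}")
            updates[parts[1]] = dataclasses.replace(part, **{parts[2]: float(value)})
            gains = dataclasses.replace(gains, **updates)
    return gains


def resolve_conditions(config: RunConfig) -> dict:
    """Merge preset values with the config's overrides into a plain dict
    of fully resolved run parameters."""
    preset = load_preset(config.experiment)
    names = config.conditions or list(preset["conditions"])
    unknown = set(names) - set(preset["conditions"])
    if unknown:
        raise ValueError(f"unknown condition: {sorted(unknown)[0]!r}")

    ov = config.overrides
    conditions = {}
    for name in names:
        cond = dict(preset["conditions"][name])
        for k in ("alpha_d1", "alpha_d2", "alpha_d1d2", "delta_lim", "delta_med"):
            if k in ov:
                cond[k] = float(ov[k])
        conditions[name] = cond

    etas = tuple(float(v) for v in ov.get("etas", preset["etas"]))
    resolved = {
        "experiment": config.experiment,
        "gains_striatal": preset["gains_striatal"],
        "gains_gpi": preset["gains_gpi"],
        "etas": etas,
        "n_agents": config.n_agents,
        "master_seed": config.master_seed,
        "conditions": conditions,
        "sign_term": not config.no_sign_term,
        "ablations": {
            "no_sign_term": config.no_sign_term,
            "persist_stn_gpe": config.persist_stn_gpe,
            "silence_stn": config.silence_stn,
        },
    }
    if config.experiment == "risk":
        resolved["r_b"] = float(ov.get("r_b", preset["r_b"]))
        resolved["trials_per_state"] = int(
            config.trials_per_state or preset["trials_per_state"]
        )
    gain_ov = {k: v for k, v in ov.items() if "." in k}
    if gain_ov:
        resolved["gain_overrides"] = dict(gain_ov)
    return resolved


def _build_sero(cond: dict) -> SerotoninParams:
    return SerotoninParams(
        alpha_d1=float(cond.get("alpha_d1", 1.0)),
        alpha_d2=float(cond.get("alpha_d2", 1.0)),
        alpha_d1d2=float(cond.get("alpha_d1d2", 1.0)),
    )


def _build_pd(cond: dict) -> PDCondition:
    return PDCondition(
        status=cond.get("status", "control"),
        delta_lim=float(cond.get("delta_lim", 0.0)),
        delta_med=float(cond.get("delta_med", 0.0)),
    )


def run(config: RunConfig) -> tuple[ExperimentSummary, dict]:
    """Execute the configured experiment; returns the summary and the
    fully resolved configuration dict."""
    resolved = resolve_conditions(config)
    g_str = _override_gains(
        GAIN_PRESETS[resolved["gains_striatal"]], "gains_striatal", config.overrides
    )
    g_gpi = _override_gains(GAIN_PRESETS[resolved["gains_gpi"]], "gains_gpi", config.overrides)

    common = dict(
        n_agents=config.n_agents,
        master_seed=config.master_seed,
        gains_striatal=g_str,
        gains_gpi=g_gpi,
        etas=resolved["etas"],
        sign_term=resolved["sign_term"],
        persist_dynamics=config.persist_stn_gpe,
        silence_stn=config.silence_stn,
        keep_trials=config.keep_trials,
    )
    if config.experiment == "risk":
        summary = run_risk_experiment(
            conditions={n: _build_sero(c) for n, c in resolved["conditions"].items()},
            schedule=RiskSchedule.default(r_b=resolved["r_b"]),
            trials_per_state=resolved["trials_per_state"],
            **common,
        )
    elif config.experiment == "reversal":
        summary = run_reversal_experiment(
            conditions={n: _build_sero(c) for n, c in resolved["conditions"].items()},
            **common,
        )
    else:
        summary = run_pd_experiment(
            conditions={
                n: (_build_sero(c), _build_pd(c)) for n, c in resolved["conditions"].items()
            },
            **common,
        )
    return summary, resolved
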