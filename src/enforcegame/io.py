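"""Scenario configuration and result serialization.

A scenario bundles a full parameter record, a strategy-set preset, and
run lengths.  Configs are YAML or JSON with parameters named by their
model symbols (``b, c, w, tau, p, v, f, l, psi, delta, kappa, mu, eta,
epsilon, gamma_pe, gamma_e, gamma_p, N``).  Every written output is
accompanied by a machine-readable metadata block (parameters, seeds,
package version) so results are reproducible from the files alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .core_types import (
    ModelParameters,
    ParameterError,
    StrategyCode,
    alternative_parameters,
    baseline_parameters,
    build_strategy_set,
)
from .learning_dynamics import RunSummary

PARAM_KEYS = (
    "b", "c", "w", "tau", "p", "v", "f", "l", "psi", "delta",
    "kappa", "mu", "eta", "epsilon", "gamma_pe", "gamma_e", "gamma_p", "N",
)
SCENARIO_KEYS = ("name", "strategies", "periods", "runs", "seed")


def _package_version() -> str:
    try:
        return version("enforcegame")
    except PackageNotFoundError:  # pragma: no cover - editable corner
        return "unknown"


@dataclass
class Scenario:
    """A named, fully validated simulation setup."""

    name: str
    params: ModelParameters
    strategies: str = "CE16"
    periods: int = 1_000_000
    runs: int = 7
    seed: int = 0

    def strategy_set(self) -> list[StrategyCode]:
        return build_strategy_set(self.strategies)

    def to_dict(self) -> dict:
        d = {"name": self.name}
        for key in PARAM_KEYS:
            if key.startswith("gamma_"):
                idx = {"gamma_pe": 0, "gamma_e": 1, "gamma_p": 2}[key]
                d[key] = self.params.gamma[idx]
            else:
                d[key] = getattr(self.params, key)
        d.update(strategies=self.strategies, periods=self.periods, runs=self.runs, seed=self.seed)
        return d


_PRESETS = {
    "baseline": baseline_parameters,
    "alternative": alternative_parameters,
}


def _params_from_mapping(data: dict) -> ModelParameters:
    missing = [k for k in PARAM_KEYS if k not in data]
    if missing:
        raise ParameterError(f"missing required parameters: {', '.join(missing)}")
    gamma = (data["gamma_pe"], data["gamma_e"], data["gamma_p"])
    kwargs = {k: data[k] for k in PARAM_KEYS if not k.startswith("gamma_")}
    return ModelParameters(gamma=gamma, **kwargs)


def load_scenario(source: str | Path, overrides: Optional[dict] = None) -> Scenario:
    """Load a scenario from a preset name or a YAML/JSON config file.

    Overrides (e.g. from CLI flags) are applied after the file or preset
    values and re-validated.  Unknown keys are rejected.
    """
    overrides = dict(overrides or {})
    if isinstance(source, str) and source in _PRESETS:
        data = Scenario(name=source, params=_PRESETS[source]()).to_dict()
    else:
        path = Path(source)
        if not path.exists():
            raise ParameterError(
                f"unknown scenario {source!r}: not a preset ({', '.join(_PRESETS)}) "
                "and no such config file"
            )
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix.lower() in (".yml", ".yaml") else json.loads(text)
        if not isinstance(data, dict):
            raise ParameterError(f"config {source} must be a mapping")
        data.setdefault("name", path.stem)
    unknown = set(data) | set(overrides)
    unknown -= set(PARAM_KEYS) | set(SCENARIO_KEYS)
    if unknown:
        raise ParameterError(f"unknown config keys: {', '.join(sorted(unknown))}")
    data.update(overrides)
    params = _params_from_mapping(data)
    scenario = Scenario(
        name=str(data.get("name", "scenario")),
        params=params,
        strategies=str(data.get("strategies", "CE16")),
        periods=int(data.get("periods", 1_000_000)),
        runs=int(data.get("runs", 7)),
        seed=int(data.get("seed", 0)),
    )
    scenario.strategy_set()  # validate the preset name eagerly
    return scenario


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    path = Path(path)
    data = scenario.to_dict()
    if path.suffix.lower() in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def _metadata(scenario: Optional[Scenario], seeds: Sequence[int] = ()) -> dict:
    meta = {"package": "enforcegame", "version": _package_version()}
    if scenario is not None:
        meta["scenario"] = scenario.to_dict()
    if seeds:
        meta["seeds"] = [int(s) for s in seeds]
    return meta


def write_summary(
    obj,
    path: str | Path,
    fmt: str = "csv",
    scenario: Optional[Scenario] = None,
    strategy_set: Optional[Sequence[StrategyCode]] = None,
) -> Path:
    """Write a :class:`RunSummary` or a DataFrame with a metadata sidecar.

    CSV bodies are deterministic (fixed column order, full float precision);
    the metadata lands next to the output as ``<name>.meta.json``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, RunSummary):
        frame = obj.to_frame(strategy_set)
        seeds = obj.seeds
    elif isinstance(obj, pd.DataFrame):
        frame = obj
        seeds = ()
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format=None)
    elif fmt == "json":
        path.write_text(frame.to_json(orient="records", indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta_path.write_text(json.dumps(_metadata(scenario, seeds), indent=2) + "\n")
    return path
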