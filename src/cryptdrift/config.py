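"""YAML run configuration with strict validation.

One document drives every CLI command. Times may be plain numbers (days) or
strings with an explicit unit suffix: ``"8w"`` (weeks), ``"56d"`` (days),
``"12h"`` (hours); everything is converted to days on read. Row coordinates
are 0-based with row 0 at the crypt base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .lattice import CryptGeometry, KineticParams, preset

__all__ = ["RunConfig", "read_config", "parse_time_days"]

_UNIT_DAYS = {"d": 1.0, "w": 7.0, "h": 1.0 / 24.0}


def parse_time_days(value) -> float:
    """Accept a number of days or a string like '8w', '56d', '12h'."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        s = value.strip().lower()
        if s and s[-1] in _UNIT_DAYS:
            try:
                return float(s[:-1]) * _UNIT_DAYS[s[-1]]
            except ValueError:
                pass
        try:
            return float(s)
        except ValueError:
            pass
    raise ConfigurationError(
        f"cannot parse time {value!r}; use a number of days or e.g. '8w', '56d', '12h'"
    )


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    if not isinstance(block, dict):
        raise ConfigurationError(f"{where} must be a mapping, got {type(block).__name__}")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key {sorted(unknown)[0]!r} in {where}")


@dataclass(frozen=True)
class RunConfig:
    geometry: CryptGeometry
    params: KineticParams
    preset_name: str | None
    experiment: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    seed: int | None = None
    outdir: Path = Path("cryptdrift_out")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory for stochastic commands")
        return int(self.seed)


_TOP_KEYS = {"geometry", "params", "preset", "experiment", "inference", "seed", "outdir"}
_GEOM_KEYS = {"n_rows", "cells_per_row", "lgr5_rows", "centre_rows", "border_rows"}
_PARAM_KEYS = {"k_d", "k_r"}
_EXPERIMENT_KEYS = {
    "type", "times", "n", "start_rows", "duration", "monoclonal_band", "labelling",
}
_INFERENCE_KEYS = {"n_boot", "kd_grid", "n_sim_per_grid", "n_g"}


def read_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected and exactly
    one of ``params``/``preset`` must be given."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None or not isinstance(raw, dict) or not raw:
        raise ConfigurationError(f"config file {path} is empty or not a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    has_params = "params" in raw
    has_preset = "preset" in raw
    if has_params == has_preset:
        raise ConfigurationError("exactly one of 'params' or 'preset' must be given")
    if has_preset:
        preset_name = str(raw["preset"])
        params = preset(preset_name)
    else:
        preset_name = None
        block = raw["params"]
        _check_keys(block, _PARAM_KEYS, "params")
        if "k_d" not in block or "k_r" not in block:
            raise ConfigurationError("params requires both 'k_d' and 'k_r'")
        params = KineticParams(k_d=float(block["k_d"]), k_r=float(block["k_r"]))

    geom_block = raw.get("geometry", {})
    _check_keys(geom_block, _GEOM_KEYS, "geometry")
    kwargs = {}
    for key in ("n_rows", "cells_per_row"):
        if key in geom_block:
            kwargs[key] = int(geom_block[key])
    for key in ("lgr5_rows", "centre_rows", "border_rows"):
        if key in geom_block:
            kwargs[key] = tuple(int(v) for v in geom_block[key])
    geometry = CryptGeometry(**kwargs)

    experiment = dict(raw.get("experiment", {}))
    _check_keys(experiment, _EXPERIMENT_KEYS, "experiment")
    if "times" in experiment:
        experiment["times"] = [parse_time_days(t) for t in experiment["times"]]
    if "duration" in experiment:
        experiment["duration"] = parse_time_days(experiment["duration"])

    inference = dict(raw.get("inference", {}))
    _check_keys(inference, _INFERENCE_KEYS, "inference")

    seed = raw.get("seed")
    if seed is not None:
        seed = int(seed)
    return RunConfig(
        geometry=geometry,
        params=params,
        preset_name=preset_name,
        experiment=experiment,
        inference=inference,
        seed=seed,
        outdir=Path(raw.get("outdir", "cryptdrift_out")),
    )
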