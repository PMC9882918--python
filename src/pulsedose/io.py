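"""Configuration and table I/O.

Run configurations are YAML or JSON mappings with blocks ``model``, ``ic``,
``regimen``, ``noise`` plus scalar options; unknown keys are rejected so a
typo never silently falls back to a default.  All numeric report keys carry
unit suffixes (``_per_h``, ``_h``, ``_log10``) because mixing natural-log
and log10 rates is the easiest mistake to make with this model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import yaml

from .model import InitialCondition, PhaseRates, Trajectory, TwoStateModel
from .regimen import PulseRegimen
from .synth import NoiseSpec

__all__ = ["RunConfig", "load_config", "write_trajectory"]

_TOP_KEYS = {
    "model", "ic", "regimen", "noise",
    "sample_dt_h", "threshold_log10", "seed", "rounding", "t_on_h", "provenance",
}
_PHASE_KEYS = {"K_n", "K_p", "a", "b"}
_MODEL_KEYS = {"on", "off", "cap_log10"}
_IC_KEYS = {"log10_c0", "f0"}
_REGIMEN_KEYS = {"t_on_h", "t_off_h", "n_cycles", "segments"}
_NOISE_KEYS = {"sigma_log10", "plating_volume_ml", "lod_cfu_per_ml"}


def _normalize_onoff(value):
    # YAML 1.1 reads bare on/off as booleans; map them back to phase labels
    if value is True:
        return "on"
    if value is False:
        return "off"
    return value


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    model: Optional[TwoStateModel] = None
    ic: Optional[InitialCondition] = None
    regimen: Optional[PulseRegimen] = None
    noise: Optional[NoiseSpec] = None
    sample_dt_h: float = 0.05
    threshold_log10: float = 0.0
    seed: Optional[int] = None
    rounding: str = "half_hour"
    t_on_h: Optional[float] = None
    provenance: Optional[Dict] = None


def _parse_phase(block: dict, where: str) -> PhaseRates:
    _check_keys(block, _PHASE_KEYS, where)
    return PhaseRates(
        K_n=float(block["K_n"]),
        K_p=float(block["K_p"]),
        a=float(block.get("a", 0.0)),
        b=float(block.get("b", 0.0)),
    )


def _parse_regimen(block: dict) -> PulseRegimen:
    _check_keys(block, _REGIMEN_KEYS, "regimen")
    if "segments" in block:
        records = [
            {**r, "phase": _normalize_onoff(r.get("phase"))} for r in block["segments"]
        ]
        return PulseRegimen.from_records(records)
    return PulseRegimen.uniform(
        float(block["t_on_h"]), float(block["t_off_h"]), int(block["n_cycles"])
    )


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration, validating every key."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    cfg = RunConfig()
    if "model" in raw:
        m = {_normalize_onoff(k): v for k, v in raw["model"].items()}
        _check_keys(m, _MODEL_KEYS, "model")
        cfg.model = TwoStateModel(
            on=_parse_phase(m["on"], "model.on"),
            off=_parse_phase(m["off"], "model.off"),
            cap_log10=(
                float(m["cap_log10"]) if m.get("cap_log10") is not None else None
            ),
        )
    if "ic" in raw:
        _check_keys(raw["ic"], _IC_KEYS, "ic")
        cfg.ic = InitialCondition(
            log10_c0=float(raw["ic"]["log10_c0"]), f0=float(raw["ic"]["f0"])
        )
    if "regimen" in raw:
        cfg.regimen = _parse_regimen(raw["regimen"])
    if "noise" in raw:
        _check_keys(raw["noise"], _NOISE_KEYS, "noise")
        n = raw["noise"]
        cfg.noise = NoiseSpec(
            sigma_log10=float(n.get("sigma_log10", 0.2)),
            plating_volume_ml=(
                float(n["plating_volume_ml"])
                if n.get("plating_volume_ml") is not None
                else None
            ),
            lod_cfu_per_ml=float(n.get("lod_cfu_per_ml", 1.0)),
        )
    for key in ("sample_dt_h", "threshold_log10"):
        if key in raw:
            setattr(cfg, key, float(raw[key]))
    if "seed" in raw and raw["seed"] is not None:
        cfg.seed = int(raw["seed"])
    if "rounding" in raw:
        cfg.rounding = str(raw["rounding"])
    if "t_on_h" in raw and raw["t_on_h"] is not None:
        cfg.t_on_h = float(raw["t_on_h"])
    if "provenance" in raw:
        cfg.provenance = dict(raw["provenance"])
    return cfg


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as delimited text (CSV)."""
    traj.to_frame().to_csv(path, index=False)
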