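"""Synthetic CFU time-series with the structure of pulse-dosing experiments.

Emulates colony-count (CFU/mL) observations from constant-dose kill curves,
growth curves, and uniform or perturbed pulse regimens: lognormal
measurement scatter on the log10 scale, an optional Poisson plating stage
for realistic low-count behaviour, detection-limit censoring, and
saturation of the culture near its carrying capacity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import InitialCondition, PhaseRates, TwoStateModel, propagate
from .regimen import PulseRegimen, Segment

__all__ = [
    "CFUDataset",
    "NoiseSpec",
    "generate",
    "predict_log10",
    "preset",
    "available_presets",
]

LN10 = math.log(10.0)

_COLUMNS = ["t_h", "value", "scale", "censored", "condition", "replicate"]


@dataclass
class CFUDataset:
    """Colony-count observations with censoring flags.

    ``table`` columns: t_h, value, scale ('log10' or 'cfu'), censored (0/1),
    condition, replicate.  Censored records carry the detection limit (LOD)
    as their value — never zero — and uncensored values are always >= LOD.
    ``meta`` records the LOD and, for synthetic data, the generating seed
    and ground-truth parameters.
    """

    table: pd.DataFrame
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset table missing columns: {missing}")
        if (self.table["t_h"] < 0).any():
            raise ValueError("times must be nonnegative")
        lod = self.meta.get("lod_cfu_per_ml")
        if lod is not None:
            vals = self.log10_values()
            unc = vals[self.table["censored"].to_numpy() == 0]
            if len(unc) and unc.min() < math.log10(lod) - 1e-9:
                raise ValueError("uncensored value below the detection limit")

    @property
    def lod(self) -> float:
        return float(self.meta.get("lod_cfu_per_ml", 1.0))

    def log10_values(self) -> np.ndarray:
        """Observations on the log10(CFU/mL) scale regardless of stored scale."""
        v = self.table["value"].to_numpy(dtype=float)
        scale = self.table["scale"].to_numpy()
        out = np.where(scale == "log10", v, np.log10(np.maximum(v, 1e-300)))
        return out

    def subset(self, condition: Optional[str] = None, censored: Optional[bool] = None):
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        if censored is not None:
            t = t[t["censored"] == int(censored)]
        return CFUDataset(table=t.reset_index(drop=True), meta=dict(self.meta))

    def to_csv(self, path, meta_path=None) -> None:
        """Write the table as CSV; metadata goes to a JSON sidecar."""
        path = Path(path)
        self.table.to_csv(path, index=False)
        if meta_path is None:
            meta_path = path.with_suffix(".meta.json")
        Path(meta_path).write_text(json.dumps(self.meta, indent=1, default=float))

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "CFUDataset":
        path = Path(path)
        try:
            table = pd.read_csv(path)
        except Exception as exc:  # surface the offending file, keep the cause
            raise ValueError(f"cannot parse CFU table {path}: {exc}") from exc
        missing = [c for c in _COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(
                f"{path}: header must contain {_COLUMNS}; missing {missing}"
            )
        meta: Dict = {}
        if meta_path is None:
            candidate = path.with_suffix(".meta.json")
            if candidate.exists():
                meta = json.loads(candidate.read_text())
        else:
            meta = json.loads(Path(meta_path).read_text())
        return cls(table=table, meta=meta)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic CFU observations.

    sigma_log10: SD of normal noise added to log10 counts (default 0.2,
    the visual scatter scale of log-plotted colony counts).
    plating_volume_ml: if set, an additional Poisson stage draws the plate
    count at this effective volume and back-converts to CFU/mL.
    lod_cfu_per_ml: detection limit; values below it are censored.
    """

    sigma_log10: float = 0.2
    plating_volume_ml: Optional[float] = None
    lod_cfu_per_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_log10 < 0:
            raise ValueError("sigma_log10 must be >= 0")
        if self.lod_cfu_per_ml <= 0:
            raise ValueError("LOD must be > 0")


def predict_log10(
    model: TwoStateModel,
    regimen: PulseRegimen,
    ic: InitialCondition,
    times: Sequence[float],
    apply_cap: bool = True,
) -> np.ndarray:
    """Noise-free log10 total count at arbitrary times within the regimen.

    Exact piecewise propagation evaluated directly at the requested times
    (plus phase boundaries internally, where the cap is also enforced).
    """
    times = np.asarray(times, dtype=float)
    if (times < -1e-12).any():
        raise ValueError("times must be nonnegative")
    span = regimen.total_duration_h
    if (times > span + 1e-9).any():
        raise ValueError(f"times exceed the regimen span ({span} h)")

    cap = model.cap_log10 if apply_cap else None

    def _cap(state):
        if cap is None:
            return state
        c = state.c
        limit = 10.0 ** cap
        if c > limit:
            from dataclasses import replace

            s = limit / c
            return replace(state, n=state.n * s, p=state.p * s)
        return state

    order = np.argsort(times, kind="stable")
    out = np.empty_like(times)
    state = _cap(ic.state())
    t_start = 0.0
    idx = 0
    for seg in regimen.segments:
        r = model.rates(seg.phase)
        t_end = t_start + seg.duration_h
        while idx < len(order) and times[order[idx]] <= t_end + 1e-12:
            t_obs = min(times[order[idx]], t_end)
            state = _cap(propagate(state, r, max(0.0, t_obs - state.t)))
            out[order[idx]] = state.c
            idx += 1
        state = _cap(propagate(state, r, t_end - state.t))
        t_start = t_end
    with np.errstate(divide="ignore"):
        return np.log10(out)


def generate(
    model: TwoStateModel,
    regimen: PulseRegimen,
    ic: InitialCondition,
    times: Sequence[float],
    replicates: int = 3,
    noise: NoiseSpec = NoiseSpec(),
    seed: Optional[int] = None,
    condition: str = "synthetic",
    apply_cap: bool = True,
) -> CFUDataset:
    """Draw a synthetic CFU dataset around the model's exact trajectory.

    Deterministic given ``seed``.  The mean structure is exactly the
    simulator output; noise is normal on log10 counts, optionally followed
    by a Poisson plating stage; values below the LOD are flagged censored
    and recorded at the LOD.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    mean_log10 = predict_log10(model, regimen, ic, times, apply_cap=apply_cap)

    records: List[dict] = []
    for rep in range(replicates):
        obs_log10 = mean_log10 + (
            rng.normal(0.0, noise.sigma_log10, size=len(times))
            if noise.sigma_log10 > 0
            else 0.0
        )
        values = 10.0 ** obs_log10
        if noise.plating_volume_ml is not None:
            expected = values * noise.plating_volume_ml
            counts = rng.poisson(np.minimum(expected, 1e12))
            values = counts / noise.plating_volume_ml
        for t, v in zip(times, values):
            censored = v < noise.lod_cfu_per_ml
            records.append(
                {
                    "t_h": float(t),
                    "value": math.log10(noise.lod_cfu_per_ml)
                    if censored
                    else math.log10(v),
                    "scale": "log10",
                    "censored": int(censored),
                    "condition": condition,
                    "replicate": rep,
                }
            )

    meta = {
        "lod_cfu_per_ml": noise.lod_cfu_per_ml,
        "sigma_log10": noise.sigma_log10,
        "plating_volume_ml": noise.plating_volume_ml,
        "seed": seed,
        "condition": condition,
        "truth": {
            "on": {"K_n": model.on.K_n, "K_p": model.on.K_p, "a": model.on.a, "b": model.on.b},
            "off": {"K_n": model.off.K_n, "K_p": model.off.K_p, "a": model.off.a, "b": model.off.b},
            "cap_log10": model.cap_log10,
            "log10_c0": ic.log10_c0,
            "f0": ic.f0,
        },
        "regimen": regimen.to_records(),
    }
    return CFUDataset(table=pd.DataFrame.from_records(records), meta=meta)


# ---------------------------------------------------------------------------
# presets: the experimental designs and literature parameter sets this
# package ships as worked examples


def _ecoli_ampicillin_model() -> TwoStateModel:
    # full-fit estimates for E. coli + ampicillin: fast kill of normal cells
    # during the on-phase, slow persister decay; off-phase regrowth with
    # persister resuscitation (b = 1.2/h, K_p_off = -b)
    return TwoStateModel(
        on=PhaseRates(K_n=-3.8, K_p=-0.2, a=0.0, b=0.0),
        off=PhaseRates(K_n=1.35, K_p=-1.2, a=0.0, b=1.2),
        cap_log10=9.0,
    )


def _ecoli_ic() -> InitialCondition:
    return InitialCondition(log10_c0=7.8, f0=9e-7)


@dataclass(frozen=True)
class Preset:
    """A packaged worked example: model/regimen/initial condition and, for
    literature cases where only slopes are known, the slope pair."""

    name: str
    model: Optional[TwoStateModel] = None
    regimen: Optional[PulseRegimen] = None
    ic: Optional[InitialCondition] = None
    K_n_on: Optional[float] = None
    K_n_off: Optional[float] = None
    K_n_off_range: Optional[tuple] = None
    note: str = ""


def _jittered_regimen(seed: int, n_cycles: int = 4) -> PulseRegimen:
    # +-25% seeded jitter around the nominal 3 h on / 2 h off schedule,
    # standing in for a perturbed (non-uniform) validation regimen
    rng = np.random.default_rng(seed)
    segs = []
    for _ in range(n_cycles):
        segs.append(Segment("on", float(3.0 * rng.uniform(0.75, 1.25))))
        segs.append(Segment("off", float(2.0 * rng.uniform(0.75, 1.25))))
    return PulseRegimen(segs)


def preset(name: str, seed: int = 0) -> Preset:
    """Named worked-example presets.

    - 'ecoli_ampicillin_fit': full-fit two-state model, 3h/2h pulse train.
    - 'ecoli_constant_dose': same model under constant antibiotic (control).
    - 'short_term_design': the two short-term slope estimates
      (time-growth 0.5 log10/h, time-kill -1.4 log10/h) and the 3h/2h
      regimen they recommend.
    - 'pulse_0p5_3' / 'pulse_3_18': failing regimens at ratio t_off/t_on = 6.
    - 'nonuniform_jitter': seeded +-25% perturbation of the 3h/2h schedule.
    - 'saureus_ofloxacin': literature slopes K_n_on=-0.6, K_n_off=2.5 (1/h).
    - 'amikacin_paeruginosa', 'amikacin_abaumannii': K_n_on=-3, K_n_off 1-3.
    - 'amikacin_kpneumoniae', 'amikacin_eaerogenes': K_n_on=-5, K_n_off 1-3.
    """
    presets = {
        "ecoli_ampicillin_fit": lambda: Preset(
            name=name,
            model=_ecoli_ampicillin_model(),
            regimen=PulseRegimen.uniform(3.0, 2.0, 3),
            ic=_ecoli_ic(),
            K_n_on=-3.8,
            K_n_off=1.35,
            note="full-fit E. coli / ampicillin parameters, 3h/2h pulse dosing",
        ),
        "ecoli_constant_dose": lambda: Preset(
            name=name,
            model=_ecoli_ampicillin_model(),
            regimen=PulseRegimen.constant("on", 30.0),
            ic=_ecoli_ic(),
            note="constant-dose control arm",
        ),
        "short_term_design": lambda: Preset(
            name=name,
            K_n_on=-1.4 * LN10,
            K_n_off=0.5 * LN10,
            regimen=PulseRegimen.uniform(3.0, 2.0, 3),
            ic=_ecoli_ic(),
            note="time-kill / time-growth slope estimates (log10 slopes -1.4, 0.5)",
        ),
        "pulse_0p5_3": lambda: Preset(
            name=name,
            model=_ecoli_ampicillin_model(),
            regimen=PulseRegimen.uniform(0.5, 3.0, 8),
            ic=_ecoli_ic(),
            note="failing regimen, t_off/t_on = 6 > x_c",
        ),
        "pulse_3_18": lambda: Preset(
            name=name,
            model=_ecoli_ampicillin_model(),
            regimen=PulseRegimen.uniform(3.0, 18.0, 3),
            ic=_ecoli_ic(),
            note="failing regimen, t_off/t_on = 6; trajectory saturates at the cap",
        ),
        "nonuniform_jitter": lambda: Preset(
            name=name,
            model=_ecoli_ampicillin_model(),
            regimen=_jittered_regimen(seed),
            ic=_ecoli_ic(),
            note="seeded +-25% jitter around the nominal 3h/2h schedule",
        ),
        "saureus_ofloxacin": lambda: Preset(
            name=name,
            K_n_on=-0.6,
            K_n_off=2.5,
            note="S. aureus / ofloxacin literature slopes",
        ),
        "amikacin_paeruginosa": lambda: Preset(
            name=name, K_n_on=-3.0, K_n_off_range=(1.0, 3.0),
            note="P. aeruginosa / amikacin literature slopes",
        ),
        "amikacin_abaumannii": lambda: Preset(
            name=name, K_n_on=-3.0, K_n_off_range=(1.0, 3.0),
            note="A. baumannii / amikacin literature slopes",
        ),
        "amikacin_kpneumoniae": lambda: Preset(
            name=name, K_n_on=-5.0, K_n_off_range=(1.0, 3.0),
            note="K. pneumoniae / amikacin literature slopes",
        ),
        "amikacin_eaerogenes": lambda: Preset(
            name=name, K_n_on=-5.0, K_n_off_range=(1.0, 3.0),
            note="E. aerogenes / amikacin literature slopes",
        ),
    }
    try:
        return presets[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None


def available_presets() -> List[str]:
    names = [
        "ecoli_ampicillin_fit",
        "ecoli_constant_dose",
        "short_term_design",
        "pulse_0p5_3",
        "pulse_3_18",
        "nonuniform_jitter",
        "saureus_ofloxacin",
        "amikacin_paeruginosa",
        "amikacin_abaumannii",
        "amikacin_kpneumoniae",
        "amikacin_eaerogenes",
    ]
    return names
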