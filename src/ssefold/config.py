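"""Run configuration: every tunable of the protocol in one round-trippable
object (weights, energy constants, move amplitudes and weights, stage
schedules, temperature control, loop building)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .energy import EnergyConstants, WeightSet
from .moves import MoveConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TemperatureSettings:
    t0: float = 500.0           # initial temperature (su)
    adjust_every: int = 10      # steps between adjustments
    start_target: float = 0.5   # target acceptance ratio at progress 0
    end_target: float = 0.2     # ... at progress 1
    k: float = 1.0              # Boltzmann-like constant
    heat_factor: float = 1.05   # multiplier when acceptance is below target
    cool_factor: float = 0.95   # multiplier otherwise
    t_min: float = 1e-3
    t_max: float = 1e6

    def target(self, progress: float) -> float:
        return self.start_target + (self.end_target - self.start_target) * progress


@dataclass(frozen=True)
class StageSchedule:
    stage: str
    max_steps: int
    max_nonimproving: int


@dataclass(frozen=True)
class LoopSettings:
    growth_candidates: int = 20   # dihedral sets sampled per loop growth
    ccd_tolerance: float = 0.08   # anchor RMSD (Angstrom) counting as closed
    ccd_max_sweeps: int = 200
    force_rounds: int = 5


@dataclass(frozen=True)
class RunConfig:
    weights: WeightSet = field(default_factory=WeightSet.default)
    energy: EnergyConstants = field(default_factory=EnergyConstants)
    move: MoveConfig = field(default_factory=MoveConfig)
    temperature: TemperatureSettings = field(default_factory=TemperatureSettings)
    assembly: StageSchedule = StageSchedule("assembly", 5000, 1000)
    refinement: StageSchedule = StageSchedule("refinement", 2000, 400)
    loop: LoopSettings = field(default_factory=LoopSettings)
    #: compare proposals against the best-so-far energy (the documented
    #: protocol); False switches to the conventional last-accepted comparison
    compare_to_best: bool = True

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if isinstance(obj, WeightSet):
                return dict(obj.weights)
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, dict):
                return {
                    ("|".join(k) if isinstance(k, tuple) else k): enc(v)
                    for k, v in obj.items()
                }
            return obj
        return enc(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def dec_dataclass(klass, d, tuple_keyed=()):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(d) - names
            if unknown:
                raise ConfigError(
                    f"unknown key(s) for {klass.__name__}: {sorted(unknown)}"
                )
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in d:
                    continue
                v = d[f.name]
                if f.name in tuple_keyed and isinstance(v, dict):
                    v = {
                        (tuple(k.split("|")) if isinstance(k, str) and "|" in k else k): vv
                        for k, vv in v.items()
                    }
                kwargs[f.name] = v
            return klass(**kwargs)

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs = {}
        if "weights" in data:
            kwargs["weights"] = WeightSet(dict(data["weights"]))
        if "energy" in data:
            kwargs["energy"] = dec_dataclass(
                EnergyConstants, data["energy"], tuple_keyed=("sse_clash_dmin", "packing_ideal")
            )
        if "move" in data:
            kwargs["move"] = dec_dataclass(
                MoveConfig, data["move"], tuple_keyed=("placement_distance",)
            )
        if "temperature" in data:
            kwargs["temperature"] = dec_dataclass(TemperatureSettings, data["temperature"])
        if "loop" in data:
            kwargs["loop"] = dec_dataclass(LoopSettings, data["loop"])
        for name in ("assembly", "refinement"):
            if name in data:
                kwargs[name] = dec_dataclass(StageSchedule, data[name])
        if "compare_to_best" in data:
            kwargs["compare_to_best"] = bool(data["compare_to_best"])
        return cls(**kwargs)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def digest(self) -> str:
        """Stable short hash for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
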