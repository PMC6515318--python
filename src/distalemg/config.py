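"""Run configuration: a flat, validated key-value structure (YAML on disk).

Every pipeline stage reads its parameters from a :class:`RunConfig`;
command-line flags override file values, and a serialized copy of the
effective configuration is written beside the outputs of every run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .boosting import BoostingParams
from .filterbank import FilterBankSpec, PreprocessConfig
from .signals import ParameterError
from .synth import SynthConfig


@dataclass
class RunConfig:
    sampling_rate: float = 2000.0
    duration_s: float = 10.0
    mains_hz: float = 50.0
    window_seconds: float = 0.1
    full_band: tuple[float, float] = (20.0, 500.0)
    band_window_hz: float = 150.0
    band_step_hz: float = 10.0
    n_rounds: int = 100
    shrinkage: float = 0.3
    max_depth: int = 6
    threshold_fraction: float = 0.20
    cycle_threshold_fraction: float = 0.20
    stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration_s <= 0:
            raise ParameterError("sampling_rate and duration_s must be positive")
        if not 0 < self.threshold_fraction < 1:
            raise ParameterError("threshold_fraction must be in (0, 1)")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")

    def filterbank_spec(self) -> FilterBankSpec:
        lo, hi = self.full_band
        return FilterBankSpec(
            full_band=(lo, hi),
            window_width=self.band_window_hz,
            step=self.band_step_hz,
            search_low=lo,
            search_high=hi,
        )

    def preprocess(self) -> PreprocessConfig:
        return PreprocessConfig(
            mains_hz=self.mains_hz,
            target_band=tuple(self.full_band),
            window_seconds=self.window_seconds,
        )

    def boosting(self) -> BoostingParams:
        return BoostingParams(
            n_rounds=self.n_rounds, shrinkage=self.shrinkage, max_depth=self.max_depth
        )

    def synth(self) -> SynthConfig:
        return SynthConfig(sampling_rate=self.sampling_rate, duration_s=self.duration_s)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["full_band"] = list(self.full_band)
        return d


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    if "full_band" in raw:
        raw["full_band"] = tuple(raw["full_band"])
    return RunConfig(**raw)
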