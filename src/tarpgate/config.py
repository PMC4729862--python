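"""Run configuration: a fully serializable description of one computation.

A run is reproducible from its config alone: scheme variant and rate
overrides, mutant trial, protocol, analysis options and the seed all live
here. Configs load from YAML or JSON; unknown keys are rejected with a
field-level message.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import protocols as pr
from . import scheme as sc

__all__ = ["ProtocolSpec", "RunConfig", "load_config", "PRESET_PROTOCOLS"]


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative protocol description (see PRESET_PROTOCOLS for names)."""

    kind: str = "pulse"             # pulse | two_pulse | train | preset
    preset: str | None = None
    duration: float = 0.5           # s (pulse)
    concentration: float = 0.01     # M
    conditioning: float = 0.5       # s (two_pulse)
    interval: float = 0.2           # s (two_pulse)
    test: float = 0.02              # s (two_pulse)
    pulse: float = 0.001            # s (train)
    frequency: float = 200.0        # Hz (train)
    n_pulses: int = 50
    sample_interval: float = pr.DEFAULT_SAMPLE_INTERVAL

    def build(self) -> pr.ConcentrationProtocol:
        if self.kind == "preset":
            if self.preset not in PRESET_PROTOCOLS:
                raise ValueError(f"unknown preset {self.preset!r}; "
                                 f"choose from {sorted(PRESET_PROTOCOLS)}")
            return PRESET_PROTOCOLS[self.preset]()
        if self.kind == "pulse":
            return pr.make_pulse(self.duration, self.concentration,
                                 sample_interval=self.sample_interval)
        if self.kind == "two_pulse":
            return pr.make_two_pulse(self.conditioning, self.interval,
                                     self.test, self.concentration,
                                     sample_interval=self.sample_interval)
        if self.kind == "train":
            return pr.make_train(self.pulse, self.frequency, self.n_pulses,
                                 self.concentration,
                                 sample_interval=self.sample_interval)
        raise ValueError(f"unknown protocol kind {self.kind!r}")


PRESET_PROTOCOLS = {
    "desensitization": lambda: pr.make_pulse(0.5, 0.01, post=0.05),
    "deactivation": lambda: pr.make_pulse(0.001, 0.01, post=0.15),
    "superactivation": lambda: pr.make_pulse(5.0, 0.01, post=0.1),
    "train200": lambda: pr.make_train(0.001, 200.0, 50, 0.01),
    "train20": lambda: pr.make_train(0.001, 20.0, 50, 0.01),
    "suprarecovery": lambda: pr.make_two_pulse(0.4, 0.2, 0.02, 0.01),
}


@dataclass(frozen=True)
class RunConfig:
    variant: str = "TARP"
    trial: int | None = None
    rates: dict = field(default_factory=dict)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    hh_exponent: int = 2
    n_fit_components: int = 2
    out_dir: str = "tarpgate-out"
    seed: int = 0

    def build_scheme(self) -> sc.KineticScheme:
        rates = sc.RateSet(**self.rates) if self.rates else None
        scheme = sc.build_scheme(self.variant, rates, trial=self.trial)
        balanced, _ = sc.enforce_microscopic_reversibility(scheme)
        return balanced

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _from_dict(data: dict) -> RunConfig:
    data = dict(data)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "protocol" in data and isinstance(data["protocol"], dict):
        pknown = {f.name for f in dataclasses.fields(ProtocolSpec)}
        punknown = set(data["protocol"]) - pknown
        if punknown:
            raise ValueError(
                f"unknown protocol key(s): {sorted(punknown)}")
        data["protocol"] = ProtocolSpec(**data["protocol"])
    if "variant" in data and data["variant"] not in sc.VARIANTS:
        raise ValueError(f"unknown variant {data['variant']!r}")
    if "rates" in data and data["rates"]:
        bad = set(data["rates"]) - set(sc.RATE_NAMES)
        if bad:
            raise ValueError(f"unknown rate name(s): {sorted(bad)}")
    return RunConfig(**data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return _from_dict(data)
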