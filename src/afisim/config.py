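"""Run configuration: serializable description of a simulation run.

A run is reproducible from its config plus seed.  The YAML/JSON schema
mirrors the dataclasses: a ``protocol`` block, either a single
``tissue`` block or a two-pool ``system`` block (optionally with an
``interference`` block), simulation ``settings``, an optional
``noise`` block and the true flip angle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .epg import TissueComponent
from .interference import InterferenceParams, TwoComponentSystem
from .sequence import AFIProtocol, MOMENT_SETS, SimSettings
from .synthetic import NoiseModel

__all__ = ["RunConfig", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Configuration validation failure with a field-level message."""


def _tissue_from(d: dict, where: str) -> TissueComponent:
    try:
        return TissueComponent(
            t1_ms=d["t1_ms"], t2_ms=d["t2_ms"],
            adc_um2_s=d.get("adc_um2_s", 0.0),
            delta_nu_hz=d.get("delta_nu_hz", 0.0))
    except KeyError as exc:
        raise ConfigError(f"{where}: missing field {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


@dataclass
class RunConfig:
    protocol: AFIProtocol
    tissue: TissueComponent | None = None
    system: TwoComponentSystem | None = None
    interference: InterferenceParams | None = None
    settings: SimSettings = field(default_factory=SimSettings)
    noise: NoiseModel | None = None
    alpha_true_deg: float | None = None
    raw: dict = field(default_factory=dict)

    @property
    def two_component(self) -> bool:
        return self.system is not None

    def hash(self) -> str:
        return config_hash(self.raw)


def config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML (or JSON) run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if "protocol" not in raw:
        raise ConfigError(f"{path}: missing 'protocol' block")
    pd_ = dict(raw["protocol"])
    if "moment_set" in pd_:
        name = pd_.pop("moment_set")
        if name not in MOMENT_SETS:
            raise ConfigError(
                f"protocol.moment_set: unknown set {name!r}; "
                f"choose from {sorted(MOMENT_SETS)}")
        pd_["a_g1_mTms_per_m"], pd_["a_g2_mTms_per_m"] = MOMENT_SETS[name]
    try:
        protocol = AFIProtocol.from_dict(pd_)
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"protocol: {exc}") from exc

    tissue = system = interference = None
    if "system" in raw:
        sysd = raw["system"]
        res = _tissue_from(sysd["res"], "system.res")
        off = _tissue_from(sysd["off"], "system.off")
        try:
            system = TwoComponentSystem(res=res, off=off)
        except ValueError as exc:
            raise ConfigError(f"system: {exc}") from exc
        if "interference" in raw:
            try:
                interference = InterferenceParams.from_dict(raw["interference"])
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"interference: {exc}") from exc
    elif "tissue" in raw:
        tissue = _tissue_from(raw["tissue"], "tissue")
    else:
        raise ConfigError(f"{path}: need a 'tissue' or 'system' block")

    settings = SimSettings(**raw.get("settings", {}))
    noise = NoiseModel(**raw["noise"]) if "noise" in raw else None
    return RunConfig(protocol=protocol, tissue=tissue, system=system,
                     interference=interference, settings=settings,
                     noise=noise, alpha_true_deg=raw.get("alpha_true_deg"),
                     raw=raw)
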