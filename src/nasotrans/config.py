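"""Run configuration, serialization and provenance.

A :class:`RunConfig` collects everything that determines a run: physical
constants, bath preset, parameter fixture (or explicit values), filter-bound
fixtures, solver tolerances, variant switches and seeds. Every command writes
its fully resolved configuration next to its outputs so results can be
reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import PhysicalConstants
from .params import (
    BathComposition,
    IonicComposition,
    TransportParams,
    default_baths,
    load_params,
)

__all__ = ["RunConfig", "load_config", "write_results", "write_resolved_config"]

_BATH_KEYS = {"Na", "K", "Cl", "imp"}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    params: TransportParams
    baths: BathComposition
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    seed: int = 0
    variant: str = "default"
    n_samples: int = 0
    params_fixture: str | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "params_fixture": self.params_fixture,
            "baths": {
                side: dataclasses.asdict(getattr(self.baths, side))
                for side in ("lumen", "serosa")
            },
            "constants": dataclasses.asdict(self.constants),
            "seed": self.seed,
            "variant": self.variant,
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def fail(key, why):
            raise ValueError(f"invalid config key {key!r}: {why}")

        fixture = raw.get("params_fixture")
        if "params" in raw and raw["params"] is not None:
            try:
                params = TransportParams.from_dict(raw["params"])
            except TypeError as err:
                fail("params", str(err))
        elif fixture:
            params = load_params(fixture)
        else:
            fail("params", "either 'params' or 'params_fixture' is required")
        if "baths" in raw and raw["baths"] is not None:
            b = raw["baths"]
            for side in ("lumen", "serosa"):
                if side not in b:
                    fail("baths", f"missing side {side!r}")
                extra = set(b[side]) - _BATH_KEYS
                if extra:
                    fail(f"baths.{side}", f"unknown ion keys {sorted(extra)}")
            baths = BathComposition(
                lumen=IonicComposition(**b["lumen"]), serosa=IonicComposition(**b["serosa"])
            )
        else:
            baths = default_baths()
        consts = PhysicalConstants(**raw.get("constants", {}))
        return cls(
            params=params,
            baths=baths,
            constants=consts,
            seed=int(raw.get("seed", 0)),
            variant=str(raw.get("variant", "default")),
            n_samples=int(raw.get("n_samples", 0)),
            params_fixture=fixture,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    with path.open() as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} does not contain a mapping")
    return RunConfig.from_dict(raw)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_results(result: dict, path: str | Path) -> Path:
    """Write a scalar-summary result mapping as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        json.dump(result, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
    return path


def write_resolved_config(config: RunConfig, out_path: str | Path) -> Path:
    """Write the fully resolved config next to an output file (provenance)."""
    out_path = Path(out_path)
    cfg_path = out_path.with_suffix(out_path.suffix + ".config.yaml")
    cfg_path.parent.mkdir(parents=True, exist_ok=True)
    with cfg_path.open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return cfg_path
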