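"""Transport parameters, bath compositions, kinetic constants and packaged fixtures.

The six free transport parameters (apical Na+ and Cl- permeabilities, basolateral
K+ and Cl- permeabilities, pump and cotransporter densities) are the axis of all
inference; the paracellular and water permeabilities are fixed configuration.
Fixture files under ``nasotrans/data`` carry the published baseline and fitted
parameter columns and the physiological filter bounds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "FREE_PARAM_NAMES",
    "TransportParams",
    "IonicComposition",
    "BathComposition",
    "PumpKinetics",
    "NKCCKinetics",
    "KineticConstants",
    "DEFAULT_KINETICS",
    "load_params",
    "load_filter_bounds_table",
    "default_baths",
]

#: The six free transport parameters, in the row order of the published table.
FREE_PARAM_NAMES = ("P_Na_ap", "P_Cl_ap", "P_K_bl", "rho_NaK", "rho_NKCC", "P_Cl_bl")


def _read_data_yaml(name: str) -> dict:
    with resources.files("nasotrans.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class PumpKinetics:
    """Na+/K+-ATPase cycle kinetics: saturating in intracellular Na+ (three
    sites) and serosal K+ (two sites), with maximal turnover ``v_max``."""

    v_max: float  # cycles s^-1 per pump
    K_Na: float = 11.0  # mM, apparent intracellular Na+ affinity
    K_K: float = 1.4  # mM, apparent extracellular K+ affinity


@dataclass(frozen=True)
class NKCCKinetics:
    """Two-conformation Na+-K+-2Cl- carrier kinetics.

    Binding of the four transported ions is treated as a rapid equilibrium on
    each face (dissociation constants ``K_Na``, ``K_K`` and ``K_Cl`` for each
    of the two Cl- sites); ``k_t`` and ``k_e`` are the loaded and empty
    translocation rates. Symmetric rates make the carrier thermodynamically
    consistent: net flux vanishes exactly when the transmembrane product
    [Na][K][Cl]^2 is equal on both faces.
    """

    k_t: float  # s^-1, loaded carrier translocation
    k_e: float  # s^-1, empty carrier translocation
    K_Na: float = 30.0  # mM
    K_K: float = 6.0  # mM
    K_Cl: float = 50.0  # mM


@dataclass(frozen=True)
class KineticConstants:
    pump: PumpKinetics
    nkcc: NKCCKinetics


def _load_kinetics() -> KineticConstants:
    raw = _read_data_yaml("kinetics.yaml")
    return KineticConstants(
        pump=PumpKinetics(**raw["pump"]), nkcc=NKCCKinetics(**raw["nkcc"])
    )


DEFAULT_KINETICS = _load_kinetics()
_DEFAULTS = _read_data_yaml("kinetics.yaml")["fixed_transport"]


@dataclass(frozen=True)
class TransportParams:
    """Membrane transport parameters of a single epithelial cell column.

    Permeabilities are in um s^-1, transporter densities in 1e-10 mol cm^-2
    (the units of the published parameter table). ``P_pa`` scales the
    paracellular (tight-junction) pathway, with per-ion multipliers in
    ``pa_selectivity`` (all 1.0 for the non-selective default). ``P_w_ap`` and
    ``P_w_bl`` are osmotic water permeability coefficients in
    cm^4 mol^-1 s^-1 (volume flux per unit osmolarity difference).
    """

    P_Na_ap: float
    P_Cl_ap: float
    P_K_bl: float
    P_Cl_bl: float
    rho_NaK: float
    rho_NKCC: float
    P_pa: float = _DEFAULTS["P_pa"]
    #: per-ion multipliers on P_pa; "imp" is the substitute (gluconate-like)
    #: anion's permeability relative to the junction's Cl- branch
    pa_selectivity: Mapping[str, float] = field(
        default_factory=lambda: {"Na": 1.0, "K": 1.0, "Cl": 1.0,
                                 "imp": _DEFAULTS.get("pa_substitute", 1.0)}
    )
    P_w_ap: float = _DEFAULTS["P_w"]
    P_w_bl: float = _DEFAULTS["P_w"]

    def __post_init__(self) -> None:
        for name in (*FREE_PARAM_NAMES, "P_pa", "P_w_ap", "P_w_bl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for ion, mult in self.pa_selectivity.items():
            if mult < 0:
                raise ValueError(f"pa_selectivity[{ion}] must be non-negative")

    def free_vector(self) -> tuple[float, ...]:
        """The six free parameters in table row order."""
        return tuple(getattr(self, name) for name in FREE_PARAM_NAMES)

    def with_free_vector(self, values) -> "TransportParams":
        return self.replace(**dict(zip(FREE_PARAM_NAMES, map(float, values))))

    def replace(self, **changes) -> "TransportParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pa_selectivity"] = dict(self.pa_selectivity)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransportParams":
        return cls(**d)


@dataclass(frozen=True)
class IonicComposition:
    """Ionic composition of a well-stirred bath (mM). ``imp`` is the
    impermeant osmolyte (gluconate-like anion substitute in low-Cl- salines)."""

    Na: float
    K: float
    Cl: float
    imp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Na", "K", "Cl", "imp"):
            if getattr(self, name) < 0:
                raise ValueError(f"[{name}] must be non-negative")

    @property
    def osmolarity(self) -> float:
        return self.Na + self.K + self.Cl + self.imp

    def concentration(self, ion: str) -> float:
        return getattr(self, ion)


@dataclass(frozen=True)
class BathComposition:
    """Luminal and serosal perfusate compositions."""

    lumen: IonicComposition
    serosa: IonicComposition

    def replace(self, **changes) -> "BathComposition":
        return dataclasses.replace(self, **changes)

    def validate_physiological(self) -> None:
        for side in ("lumen", "serosa"):
            osm = getattr(self, side).osmolarity
            if not (250.0 <= osm <= 350.0):
                raise ValueError(
                    f"{side} osmolarity {osm:.1f} mM outside the physiological preset range [250, 350]"
                )


def default_baths() -> BathComposition:
    """Symmetric Krebs-Ringer-like saline on both faces (config fixture)."""
    raw = _read_data_yaml("baths.yaml")["default"]
    baths = BathComposition(
        lumen=IonicComposition(**raw["lumen"]), serosa=IonicComposition(**raw["serosa"])
    )
    baths.validate_physiological()
    return baths


def load_params(fixture: str, **overrides) -> TransportParams:
    """Load a packaged parameter fixture.

    Parameters
    ----------
    fixture : str
        One of ``table1_baseline``, ``table1_nonCF``, ``table1_CF``.
    **overrides
        Passed through to :meth:`TransportParams.replace` (e.g. ``P_pa=...``).
    """
    table = _read_data_yaml("table1.yaml")
    if fixture not in table:
        raise KeyError(f"unknown parameter fixture {fixture!r}; have {sorted(table)}")
    params = TransportParams(**table[fixture])
    return params.replace(**overrides) if overrides else params


def load_filter_bounds_table(condition: str) -> dict[str, tuple[float, float]]:
    """Raw (lower, upper) physiological bounds per observable for ``condition``
    (``nonCF`` or ``CF``), exactly as published."""
    table = _read_data_yaml("table2_bounds.yaml")
    if condition not in table:
        raise KeyError(f"unknown condition {condition!r}; have {sorted(table)}")
    return {name: (float(lo), float(hi)) for name, (lo, hi) in table[condition].items()}
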