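"""Toxicological reference registry.

Holds everything the risk pipeline needs besides measured concentrations:
metal descriptors with their IARC carcinogenicity class, oral reference
doses (RfD, mg/kg/day), oral carcinogenic potency slopes (CPSo, per
mg/kg/day), authority maximum-residue limit rules (µg/g wet weight), the
exposure-scenario parameters (ingestion rates, body weight, durations) and
the analytical spike-recovery percentages kept as metadata.

The packaged defaults reproduce the study constants bit-exactly; a registry
may also be loaded from a TOML or JSON config with the same sections.
Lookups fail loudly: an absent reference dose or limit rule raises, it is
never silently zero.
"""
from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

IARC_GROUPS = frozenset({"1", "2A", "2B", "3", "unknown"})
TISSUE_CLASSES = ("muscle", "offal")

__all__ = [
    "MetalDescriptor", "LimitRule", "ExposureParams", "ReferenceRegistry",
    "RegistryError", "MissingReferenceError", "MissingLimitError",
    "load_registry",
]


class RegistryError(ValueError):
    """Config content violates a registry invariant."""


class MissingReferenceError(LookupError):
    """No reference dose / potency slope is defined for the metal."""


class MissingLimitError(LookupError):
    """No permissible-limit rule exists for (authority, metal, tissue class)."""


@dataclass(frozen=True)
class MetalDescriptor:
    symbol: str
    name: str
    iarc_group: str = "unknown"

    def __post_init__(self):
        if self.iarc_group not in IARC_GROUPS:
            raise RegistryError(
                f"metal {self.symbol!r}: IARC group {self.iarc_group!r} "
                f"not one of {sorted(IARC_GROUPS)}")


@dataclass(frozen=True)
class LimitRule:
    authority: str
    metal: str
    tissue_class: str
    limit: float  # µg/g wet weight (identical to mg/kg)

    def __post_init__(self):
        if self.tissue_class not in TISSUE_CLASSES:
            raise RegistryError(
                f"limit rule {self.authority}/{self.metal}: tissue class "
                f"{self.tissue_class!r} not in {TISSUE_CLASSES}")
        if not self.limit > 0:
            raise RegistryError(
                f"limit rule {self.authority}/{self.metal}/{self.tissue_class}: "
                f"limit must be > 0, got {self.limit}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.authority, self.metal, self.tissue_class)


@dataclass(frozen=True)
class ExposureParams:
    """Exposure scenario: an Egyptian adult eating poultry daily.

    fir_muscle/fir_liver are ingestion rates in g/day, bw the body weight in
    kg, ed_* the exposure durations in years (30 y for the chronic
    non-cancer scenario, lifetime 70 y for the cancer scenario), ef the
    exposure frequency in days/year and at_years the averaging time.
    """
    fir_muscle: float = 39.53
    fir_liver: float = 0.1
    bw: float = 70.0
    ed_noncancer: float = 30.0
    ed_cancer: float = 70.0
    ef: float = 365.0
    at_years: float = 70.0

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not value > 0:
                raise RegistryError(f"exposure parameter {name} must be > 0, "
                                    f"got {value}")

    def fir_for(self, tissue: str) -> float:
        return self.fir_liver if tissue == "liver" else self.fir_muscle


@dataclass
class ReferenceRegistry:
    metals: dict[str, MetalDescriptor] = field(default_factory=dict)
    rfd: dict[str, float] = field(default_factory=dict)
    cpso: dict[str, float] = field(default_factory=dict)
    limits: dict[tuple[str, str, str], LimitRule] = field(default_factory=dict)
    exposure: ExposureParams = field(default_factory=ExposureParams)
    qc_recovery: dict[str, float] = field(default_factory=dict)
    guidelines: dict[str, float] = field(default_factory=dict)

    # -- lookups ----------------------------------------------------------
    def get_rfd(self, metal: str) -> float:
        try:
            return self.rfd[metal]
        except KeyError:
            raise MissingReferenceError(
                f"no reference dose defined for metal {metal!r}") from None

    def get_cpso(self, metal: str) -> float:
        try:
            return self.cpso[metal]
        except KeyError:
            raise MissingReferenceError(
                f"no carcinogenic potency slope defined for metal {metal!r}"
            ) from None

    def has_cpso(self, metal: str) -> bool:
        return metal in self.cpso

    def get_limit(self, authority: str, metal: str, tissue_class: str) -> float:
        try:
            return self.limits[(authority, metal, tissue_class)].limit
        except KeyError:
            raise MissingLimitError(
                f"no permissible-limit rule for authority {authority!r}, "
                f"metal {metal!r}, tissue class {tissue_class!r}") from None

    def limit_rule(self, authority: str, metal: str,
                   tissue_class: str) -> LimitRule:
        try:
            return self.limits[(authority, metal, tissue_class)]
        except KeyError:
            raise MissingLimitError(
                f"no permissible-limit rule for authority {authority!r}, "
                f"metal {metal!r}, tissue class {tissue_class!r}") from None

    @property
    def authorities(self) -> list[str]:
        return sorted({k[0] for k in self.limits})

    # -- construction -----------------------------------------------------
    def _add_metal(self, desc: MetalDescriptor) -> None:
        if desc.symbol in self.metals:
            raise RegistryError(f"duplicate metal symbol {desc.symbol!r}")
        self.metals[desc.symbol] = desc

    def _require_metal(self, symbol: str, where: str) -> None:
        if symbol not in self.metals:
            raise RegistryError(
                f"{where}: unknown metal symbol {symbol!r} "
                f"(declare it under [metals])")

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ReferenceRegistry":
        reg = cls(exposure=ExposureParams(**cfg.get("exposure", {})))
        for entry in cfg.get("metals", []):
            reg._add_metal(MetalDescriptor(**entry))
        for symbol, value in cfg.get("rfd", {}).items():
            reg._require_metal(symbol, f"rfd entry {symbol!r}")
            if not value > 0:
                raise RegistryError(
                    f"rfd entry {symbol!r}: must be > 0, got {value}")
            reg.rfd[symbol] = float(value)
        for symbol, value in cfg.get("cpso", {}).items():
            reg._require_metal(symbol, f"cpso entry {symbol!r}")
            if not value > 0:
                raise RegistryError(
                    f"cpso entry {symbol!r}: must be > 0, got {value}")
            reg.cpso[symbol] = float(value)
        for entry in cfg.get("limits", []):
            rule = LimitRule(**entry)
            reg._require_metal(rule.metal, f"limit rule {rule.key}")
            if rule.key in reg.limits:
                raise RegistryError(f"duplicate limit rule {rule.key}")
            reg.limits[rule.key] = rule
        for symbol, value in cfg.get("qc_recovery", {}).items():
            reg._require_metal(symbol, f"qc_recovery entry {symbol!r}")
            if not value > 0:
                raise RegistryError(
                    f"qc_recovery entry {symbol!r}: must be > 0, got {value}")
            reg.qc_recovery[symbol] = float(value)
        reg.guidelines = {k: float(v)
                          for k, v in cfg.get("guidelines", {}).items()}
        return reg

    def to_dict(self) -> dict:
        return {
            "metals": [asdict(m) for m in self.metals.values()],
            "rfd": dict(self.rfd),
            "cpso": dict(self.cpso),
            "limits": [asdict(r) for r in self.limits.values()],
            "exposure": asdict(self.exposure),
            "qc_recovery": dict(self.qc_recovery),
            "guidelines": dict(self.guidelines),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _default_config() -> dict:
    text = (resources.files("metalrisk.data") / "default_registry.toml"
            ).read_text()
    return tomllib.loads(text)


def load_registry(source: str | Path | Mapping = "defaults"
                  ) -> ReferenceRegistry:
    """Build a registry from ``"defaults"``, a mapping, or a TOML/JSON file."""
    if isinstance(source, Mapping):
        return ReferenceRegistry.from_dict(source)
    if source == "defaults":
        return ReferenceRegistry.from_dict(_default_config())
    path = Path(source)
    text = path.read_text()
    if path.suffix == ".json":
        return ReferenceRegistry.from_dict(json.loads(text))
    return ReferenceRegistry.from_dict(tomllib.loads(text))
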