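"""Configuration registry: parameters, actions, arrhythmia sets, chains.

Monitor vocabularies are site- and configuration-specific (basic versus
enhanced arrhythmia analysis, unit-level alarm profiles), so everything
here is data, not code: the registry ships with sensible defaults seeded
from the vendor's documented message vocabulary and can be overridden
from a YAML or JSON file.  Unknown parameter names still parse — the
registry then supplies generic attributes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

__all__ = ["ParameterInfo", "Registry", "DEFAULT_REGISTRY"]

# Chains used by the announcement priority algorithm.  Only the
# highest-priority active alarm within a chain is announced; parameters
# outside the three chains announce independently.
CHAINS = ("pvc", "beat_detection", "rate", "none")


@dataclass(frozen=True)
class ParameterInfo:
    """Per-parameter attributes consulted by the parser and simulator.

    ``limit_side`` states which bound a bare "<param> Limit <n>" settings
    message refers to (e.g. desaturation has only a lower limit).
    ``yellow_class`` splits yellow alarms into the long/short announcement
    classes; membership is not published, so defaults are overridable.
    ``hard_stop`` marks vendor settings not editable by clinicians.
    """

    name: str
    kind: str = "numerical"  # "numerical" | "categorical"
    units: Optional[str] = None
    limit_side: Optional[str] = None  # "lower" | "upper" | None
    chain: str = "none"
    latching: bool = False
    yellow_class: str = "short"  # "long" | "short"
    hard_stop: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("numerical", "categorical"):
            raise ValueError(f"bad kind {self.kind!r} for {self.name}")
        if self.chain not in CHAINS:
            raise ValueError(f"bad chain {self.chain!r} for {self.name}")


def _params(*infos: ParameterInfo) -> dict[str, ParameterInfo]:
    return {p.name: p for p in infos}


_DEFAULT_PARAMETERS = _params(
    # Numerical limit alarms
    ParameterInfo("HR", units="beats/min", chain="rate"),
    ParameterInfo("RR", units="breaths/min"),
    ParameterInfo("SpO2", units="%", limit_side="lower"),
    ParameterInfo("Desat", units="%", limit_side="lower", yellow_class="long"),
    ParameterInfo("Apnea", units="s", yellow_class="long"),
    ParameterInfo("PVCs/min", units="PVCs/min", limit_side="upper", chain="pvc"),
    ParameterInfo("ABP", units="mmHg"),
    ParameterInfo("ABPs", units="mmHg"),
    ParameterInfo("ABPd", units="mmHg"),
    ParameterInfo("ABPm", units="mmHg"),
    ParameterInfo("NBP", units="mmHg"),
    ParameterInfo("NBPs", units="mmHg"),
    ParameterInfo("PAP", units="mmHg"),
    ParameterInfo("PAPd", units="mmHg"),
    ParameterInfo("PAPs", units="mmHg"),
    ParameterInfo("ST-V2", units="mm"),
    # Categorical arrhythmia alarms
    ParameterInfo("Asystole", kind="categorical", chain="beat_detection",
                  latching=True),
    ParameterInfo("Ventricular Fibrillation", kind="categorical",
                  chain="beat_detection", latching=True),
    ParameterInfo("Ventricular Tachycardia", kind="categorical", chain="rate",
                  latching=True),
    ParameterInfo("Extreme Tachycardia", kind="categorical", chain="rate"),
    ParameterInfo("Extreme Bradycardia", kind="categorical", chain="rate"),
    ParameterInfo("Non-Sustained Ventricular Tachycardia", kind="categorical",
                  chain="rate"),
    ParameterInfo("Supraventricular Tachycardia", kind="categorical",
                  chain="rate"),
    ParameterInfo("Ventricular Bradycardia", kind="categorical", chain="rate"),
    ParameterInfo("Ventricular Rhythm", kind="categorical", chain="pvc"),
    ParameterInfo("Run PVCs High", kind="categorical", chain="pvc"),
    ParameterInfo("Pair PVCs", kind="categorical", chain="pvc",
                  yellow_class="long"),
    ParameterInfo("Multiform PVCs", kind="categorical", chain="pvc"),
    ParameterInfo("Bigeminy PVCs", kind="categorical", chain="pvc"),
    ParameterInfo("Trigeminy PVCs", kind="categorical", chain="pvc"),
    ParameterInfo("R-on-T PVCs", kind="categorical", chain="pvc"),
    ParameterInfo("Missed Beat", kind="categorical", chain="beat_detection"),
    ParameterInfo("Pause", kind="categorical", chain="beat_detection"),
    ParameterInfo("Pacer Not Capture", kind="categorical",
                  chain="beat_detection"),
    ParameterInfo("Pacer Not Pacing", kind="categorical",
                  chain="beat_detection"),
    ParameterInfo("AFIB", kind="categorical"),
    ParameterInfo("Irregular Heart Rate", kind="categorical"),
    # Vendor hard stops: listed so tools can name them as unchangeable;
    # their internals are out of scope.
    ParameterInfo("TachyClamp", units="beats/min", hard_stop=True),
    ParameterInfo("BradyClamp", units="beats/min", hard_stop=True),
    # Technical (INOP) conditions — always categorical
    ParameterInfo("ECG Leads Off", kind="categorical"),
    ParameterInfo("Leads Off", kind="categorical"),
    ParameterInfo("Check Patient ID", kind="categorical"),
    ParameterInfo("Check Equipment", kind="categorical"),
    ParameterInfo("Batt Empty", kind="categorical"),
    ParameterInfo("Noisy ECG", kind="categorical"),
)

# Sub/superscript spellings collapse to one canonical token.
_DEFAULT_ALIASES = {
    "SpO_2": "SpO2",
    "SpO_2_": "SpO2",
    "SPO2": "SpO2",
    "Paired PVCs": "Pair PVCs",
}

# Basic arrhythmia analysis records 10 alarm classes; enhanced analysis
# adds 13 more.  Only a handful of class names are documented for each
# tier; the remainder are standard arrhythmia classes chosen as
# placeholders and freely overridable.
_ARRHYTHMIA_BASIC = (
    "Asystole",
    "Ventricular Fibrillation",
    "Ventricular Tachycardia",
    "Extreme Tachycardia",
    "Extreme Bradycardia",
    "PVCs/min",
    "Pacer Not Capture",
    "Pacer Not Pacing",
    "HR",
    "Missed Beat",
)
_ARRHYTHMIA_ENHANCED_EXTRA = (
    "Non-Sustained Ventricular Tachycardia",
    "Supraventricular Tachycardia",
    "Run PVCs High",
    "Pair PVCs",
    "Multiform PVCs",
    "Bigeminy PVCs",
    "Trigeminy PVCs",
    "R-on-T PVCs",
    "Ventricular Rhythm",
    "Ventricular Bradycardia",
    "Pause",
    "Irregular Heart Rate",
    "AFIB",
)

# The vendor's action search criteria comprise 21 categories; the named
# subset is documented, the rest are placeholders pending site config.
_DEFAULT_ACTIONS = (
    "Silence",
    "Pause Alarms",
    "Resume Alarms",
    "Measurement On",
    "Measurement Off",
    "Alarm On",
    "Alarm Off",
    "Alarm Limit Change",
    "Stand By On",
    "Stand By Off",
    "Admission",
    "Discharge",
    "Transfer",
    "Paced Status Changed",
    "Patient Category Changed",
    "Equipment Online",
    "Equipment Offline",
    "Arrhythmia Relearn",
    "Print Record",
    "Monitoring Mode Changed",
    "Other",
)


@dataclass
class Registry:
    """Open vocabulary of parameters, actions, and arrhythmia sets."""

    parameters: dict[str, ParameterInfo] = field(
        default_factory=lambda: dict(_DEFAULT_PARAMETERS))
    aliases: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_ALIASES))
    arrhythmia_basic: tuple[str, ...] = _ARRHYTHMIA_BASIC
    arrhythmia_enhanced_extra: tuple[str, ...] = _ARRHYTHMIA_ENHANCED_EXTRA
    actions: tuple[str, ...] = _DEFAULT_ACTIONS

    # -- lookup ------------------------------------------------------------

    def canonical(self, name: str) -> str:
        name = re.sub(r"\s+", " ", name.strip())
        return self.aliases.get(name, name)

    def lookup(self, name: str, *, numerical_hint: bool | None = None
               ) -> ParameterInfo:
        """Return attributes for ``name``; unknown parameters get generic
        attributes (the vocabulary is open, never a closed enum)."""
        canon = self.canonical(name)
        info = self.parameters.get(canon)
        if info is not None:
            return info
        kind = "numerical" if numerical_hint else "categorical"
        if numerical_hint is None:
            kind = "numerical"
        return ParameterInfo(canon, kind=kind)

    def known(self, name: str) -> bool:
        return self.canonical(name) in self.parameters

    def arrhythmia_classes(self, mode: str = "basic") -> tuple[str, ...]:
        """Alarm classes recorded under ``basic`` or ``enhanced`` analysis."""
        if mode == "basic":
            return self.arrhythmia_basic
        if mode == "enhanced":
            return self.arrhythmia_basic + self.arrhythmia_enhanced_extra
        raise ValueError(f"unknown arrhythmia mode {mode!r}")

    # -- construction ------------------------------------------------------

    def register(self, info: ParameterInfo) -> None:
        self.parameters[info.name] = info

    @classmethod
    def from_dict(cls, data: dict) -> "Registry":
        reg = cls()
        for name, attrs in (data.get("parameters") or {}).items():
            reg.register(ParameterInfo(name=name, **(attrs or {})))
        reg.aliases.update(data.get("aliases") or {})
        if "arrhythmia_basic" in data:
            reg.arrhythmia_basic = tuple(data["arrhythmia_basic"])
        if "arrhythmia_enhanced_extra" in data:
            reg.arrhythmia_enhanced_extra = tuple(
                data["arrhythmia_enhanced_extra"])
        if "actions" in data:
            reg.actions = tuple(data["actions"])
        return reg

    @classmethod
    def from_file(cls, path: str | Path) -> "Registry":
        """Load overrides from a YAML or JSON registry file."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text)) or {}
        return cls.from_dict(data)


DEFAULT_REGISTRY = Registry()
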