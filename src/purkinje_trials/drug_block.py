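"""Pore-block drug model and the bundled reference-compound library.

A drug at concentration ``C`` scales a channel's maximal conductance by
the residual fraction ``1 / (1 + (C / IC50)^h)`` with Hill coefficient
``h = 1`` by default.  Channels with no measured IC50 (no effect in the
tested range) keep residual 1.0.  Only four channels carry IC50s in the
library (INa, ICaL, Ito, IKr); the remaining eight currents are never
drug-targeted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence

import yaml

from .cell_model import BlockSet, CurrentId

logger = logging.getLogger(__name__)

BLOCKABLE_CHANNELS = (CurrentId.INa, CurrentId.ICaL, CurrentId.Ito, CurrentId.IKr)
TDP_CLASSES = ("1", "2", "NC")


def residual_fraction(concentration_um: float, ic50_um: float, hill: float = 1.0) -> float:
    """Residual current fraction after pore block: 1 / (1 + (C/IC50)^h)."""
    if ic50_um <= 0:
        raise ValueError("IC50 must be > 0")
    if hill <= 0:
        raise ValueError("Hill coefficient must be > 0")
    if concentration_um < 0:
        raise ValueError("concentration must be >= 0")
    if concentration_um == 0.0:
        return 1.0
    return 1.0 / (1.0 + (concentration_um / ic50_um) ** hill)


@dataclass(frozen=True)
class DrugSpec:
    """One reference compound: targets, assay design and clinical TdP class."""

    name: str
    ic50_um: Dict[CurrentId, float]
    concentrations_um: tuple
    frequencies_hz: tuple
    tdp_class: str
    hill: Dict[CurrentId, float] = field(default_factory=dict)
    n_preparations: Optional[int] = None
    eftpc_max_um: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "concentrations_um", tuple(float(c) for c in self.concentrations_um))
        object.__setattr__(self, "frequencies_hz", tuple(float(f) for f in self.frequencies_hz))
        for ch, ic50 in self.ic50_um.items():
            if ch not in BLOCKABLE_CHANNELS:
                raise ValueError(f"{self.name}: {ch} is not a drug-targetable channel")
            if ic50 <= 0:
                raise ValueError(f"{self.name}: IC50 for {ch.name} must be > 0")
        for ch, h in self.hill.items():
            if h <= 0:
                raise ValueError(f"{self.name}: Hill coefficient for {ch.name} must be > 0")
        if any(c <= 0 for c in self.concentrations_um):
            raise ValueError(f"{self.name}: concentrations must be > 0")
        if list(self.concentrations_um) != sorted(self.concentrations_um):
            raise ValueError(f"{self.name}: concentrations must be ascending")
        if self.tdp_class not in TDP_CLASSES:
            raise ValueError(f"{self.name}: tdp_class must be one of {TDP_CLASSES}")

    @property
    def slow_rate_hz(self) -> float:
        """The compound's slow pacing rate (0.2 or 0.25 Hz)."""
        return min(self.frequencies_hz)

    @property
    def is_risky(self) -> bool:
        """Clinical truth: TdP classes 1 and 2 are risky, NC is safe."""
        return self.tdp_class in ("1", "2")

    def hill_for(self, channel: CurrentId) -> float:
        return self.hill.get(channel, 1.0)


@dataclass(frozen=True)
class DoseRequest:
    """A drug at one extracellular concentration."""

    drug: DrugSpec
    concentration_um: float

    def __post_init__(self):
        if self.concentration_um < 0:
            raise ValueError("concentration must be >= 0")
        if (self.concentration_um not in self.drug.concentrations_um
                and self.concentration_um != 0.0):
            # concentrations beyond the assay's list are allowed (e.g. above
            # solubility limits) but recorded as extrapolation
            logger.info("extrapolating %s beyond tested concentrations: %g uM",
                        self.drug.name, self.concentration_um)


def block_set(request: DoseRequest) -> BlockSet:
    """Residual fraction per channel for one dose; untargeted channels get 1.0."""
    residuals = {}
    for ch, ic50 in request.drug.ic50_um.items():
        residuals[ch] = residual_fraction(request.concentration_um, ic50,
                                          request.drug.hill_for(ch))
    return BlockSet.from_dict(residuals)


def _parse_drug(entry: Mapping) -> DrugSpec:
    required = {"name", "ic50_um", "concentrations_um", "frequencies_hz", "tdp_class"}
    missing = required - set(entry)
    if missing:
        raise ValueError(f"drug entry missing fields: {sorted(missing)}")
    try:
        ic50 = {CurrentId[k]: float(v) for k, v in (entry["ic50_um"] or {}).items()}
    except KeyError as exc:
        raise ValueError(f"{entry['name']}: unknown channel key {exc}") from None
    hill = {CurrentId[k]: float(v) for k, v in entry.get("hill", {}).items()}
    return DrugSpec(
        name=str(entry["name"]),
        ic50_um=ic50,
        concentrations_um=tuple(entry["concentrations_um"]),
        frequencies_hz=tuple(entry["frequencies_hz"]),
        tdp_class=str(entry["tdp_class"]),
        hill=hill,
        n_preparations=entry.get("n_preparations"),
        eftpc_max_um=entry.get("eftpc_max_um"),
    )


def load_drug_library(path=None) -> List[DrugSpec]:
    """Load the drug library (bundled reference set when ``path`` is None)."""
    if path is None:
        text = resources.files("purkinje_trials").joinpath("data/drug_library.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "drugs" not in doc:
        raise ValueError("drug library must be a mapping with a 'drugs' list")
    return [_parse_drug(entry) for entry in doc["drugs"]]


def get_drug(name: str, library: Optional[Sequence[DrugSpec]] = None) -> DrugSpec:
    library = library if library is not None else load_drug_library()
    for drug in library:
        if drug.name == name:
            return drug
    raise KeyError(f"unknown drug {name!r}")
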