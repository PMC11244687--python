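"""Uncertainty budgets for photon and electron beam calibration.

A budget is a named set of uncertainty sources, each with a sampling law
(:class:`~tg51mc.sampling.DistributionSpec`), a unit, and a flag marking
whether the source is under the clinical user's control (setup-type
quantities: SSD, depths, temperature, pressure, field size, I50) or not
(chamber calibration factor, k_Q data, formula accuracies, ...).

The defaults encode the budget of a careful clinical user with standard
instrumentation: a Farmer chamber calibrated at an ADCL (0.75 % relative,
k=1), SSD set with the optical distance indicator to +/-2 mm, depths set to
+/-1 mm, worst-case digital barometer (+/-8 mbar), two field thermometers
(0.25 degC Type A scatter, +/-0.4 degC stated accuracy).  Percent-valued
sigmas are stored as relative fractions (0.004 means 0.4 %).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import yaml

from .sampling import DistributionSpec

MODALITIES = ("photon", "electron")

#: sources the clinical user can influence (shaded vs unshaded budget rows)
USER_CONTROLLED = {
    "photon": frozenset(
        {"SSD", "depth_meas", "depth_scan", "temperature_A", "temperature_B",
         "pressure", "field_size"}
    ),
    "electron": frozenset(
        {"SSD", "dset", "temperature_A", "temperature_B", "pressure", "I50"}
    ),
}

# canonical source table: name -> (kind, sigma-or-None, half_width-or-None, unit)
_U = "uniform"
_N = "normal"
_PHOTON_DEFAULTS = {
    "SSD": (_U, None, 0.2, "cm"),
    "depth_meas": (_U, None, 0.1, "cm"),
    "depth_scan": (_U, None, 0.1, "cm"),
    "temperature_A": (_N, 0.25, None, "degC"),
    "temperature_B": (_U, 0.23, None, "degC"),
    "pressure": (_U, None, 8.0, "mbar"),
    "field_size": (_U, None, 0.2, "cm"),
    "kQ_intrinsic": (_N, 0.004, None, "rel"),
    "kQ_formula": (_N, 0.0007, None, "rel"),
    "repeatability": (_N, 0.0004, None, "rel"),
    "stability": (_N, 0.004, None, "rel"),
    "extracameral": (_N, 0.001, None, "rel"),
    "electrometer_calibration": (_N, 0.001, None, "rel"),
    "chamber_calibration": (_N, 0.0075, None, "rel"),
    "interim_formula": (_U, None, 0.02, "pct_dd"),
    "pion_formula": (_N, 0.002, None, "rel"),
    "humidity": (_U, None, 0.0015, "rel"),
}
_ELECTRON_DEFAULTS = {
    "SSD": (_U, None, 0.2, "cm"),
    "dset": (_U, None, 0.1, "cm"),
    "I50": (_U, 0.087, None, "cm"),
    "R50_formula": (_U, None, 0.04, "cm"),
    "temperature_A": (_N, 0.25, None, "degC"),
    "temperature_B": (_U, 0.23, None, "degC"),
    "pressure": (_U, None, 8.0, "mbar"),
    "kecal": (_N, 0.005, None, "rel"),
    "kprime_formula": (_U, None, 0.002, "rel"),
    "repeatability": (_N, 0.0004, None, "rel"),
    "stability": (_N, 0.003, None, "rel"),
    "extracameral": (_N, 0.001, None, "rel"),
    "electrometer_calibration": (_N, 0.001, None, "rel"),
    "chamber_calibration": (_N, 0.0075, None, "rel"),
    "pion_formula": (_N, 0.002, None, "rel"),
    "humidity": (_U, None, 0.0015, "rel"),
}
_DEFAULTS = {"photon": _PHOTON_DEFAULTS, "electron": _ELECTRON_DEFAULTS}

#: unit expected for each physical source; "rel" sources are dimensionless fractions
_PHYSICAL_UNITS = {"cm", "degC", "mbar", "pct_dd"}


@dataclass(frozen=True)
class UncertaintySource:
    name: str
    spec: DistributionSpec
    user_controlled: bool
    unit: str = "rel"

    def zeroed(self) -> "UncertaintySource":
        if self.spec.kind == "uniform":
            z = DistributionSpec("uniform", half_width=0.0, center=self.spec.center)
        else:
            z = DistributionSpec("normal", sigma=0.0, center=self.spec.center)
        return replace(self, spec=z)


class UncertaintyBudget:
    """Named uncertainty sources for one calibration modality."""

    def __init__(self, modality: str, sources: Iterable[UncertaintySource]):
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        self.modality = modality
        self.sources: dict[str, UncertaintySource] = {}
        for s in sources:
            if s.name in self.sources:
                raise ValueError(f"duplicate source {s.name!r}")
            if s.name not in _DEFAULTS[modality]:
                raise ValueError(f"unknown source {s.name!r} for {modality} budget")
            self.sources[s.name] = s

    def __getitem__(self, name: str) -> UncertaintySource:
        return self.sources[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sources

    def __iter__(self):
        return iter(self.sources.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, UncertaintyBudget):
            return NotImplemented
        return self.modality == other.modality and self.sources == other.sources

    def sigma(self, name: str) -> float:
        return self.sources[name].spec.sigma

    def validate(self) -> None:
        """Check every source consumed by the matching chain is present."""
        missing = set(_DEFAULTS[self.modality]) - set(self.sources)
        if missing:
            raise ValueError(
                f"{self.modality} budget missing sources: {sorted(missing)}"
            )
        for s in self:
            if s.spec.sigma < 0:
                raise ValueError(f"source {s.name!r} has negative sigma")

    def replace_source(self, name: str, spec: DistributionSpec) -> "UncertaintyBudget":
        if name not in self.sources:
            raise ValueError(f"unknown source {name!r}")
        out = copy.deepcopy(self)
        out.sources[name] = replace(out.sources[name], spec=spec)
        return out

    def to_document(self) -> dict:
        doc = {"modality": self.modality, "inherit_defaults": False, "sources": {}}
        for s in self:
            block = {
                "distribution": s.spec.kind,
                "unit": s.unit,
                "user_controlled": s.user_controlled,
            }
            if s.spec.kind == "uniform":
                block["half_width"] = float(s.spec.half_width)
            else:
                block["sigma"] = float(s.spec.sigma)
            if s.spec.center:
                block["center"] = float(s.spec.center)
            doc["sources"][s.name] = block
        return doc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_document(), sort_keys=True)


def default_budget(modality: str) -> UncertaintyBudget:
    """The default (table) budget for ``"photon"`` or ``"electron"``."""
    if modality not in _DEFAULTS:
        raise ValueError(f"unknown modality {modality!r}")
    sources = []
    for name, (kind, sigma, hw, unit) in _DEFAULTS[modality].items():
        spec = DistributionSpec(kind, sigma=sigma, half_width=hw)
        sources.append(
            UncertaintySource(
                name=name,
                spec=spec,
                user_controlled=name in USER_CONTROLLED[modality],
                unit=unit,
            )
        )
    b = UncertaintyBudget(modality, sources)
    b.validate()
    return b


def _source_from_block(name: str, block: Mapping, modality: str) -> UncertaintySource:
    try:
        kind = block["distribution"]
    except KeyError as exc:
        raise ValueError(f"source {name!r}: missing 'distribution'") from exc
    default_unit = _DEFAULTS[modality][name][3]
    unit = block.get("unit", default_unit)
    if default_unit in _PHYSICAL_UNITS and "unit" not in block:
        raise ValueError(f"source {name!r}: physical source requires an explicit unit")
    if default_unit in _PHYSICAL_UNITS and unit != default_unit:
        raise ValueError(
            f"source {name!r}: unit {unit!r} does not match expected {default_unit!r}"
        )
    try:
        spec = DistributionSpec(
            kind,
            sigma=block.get("sigma"),
            half_width=block.get("half_width"),
            center=block.get("center", 0.0),
        )
    except ValueError as exc:
        raise ValueError(f"source {name!r}: {exc}") from exc
    user = block.get("user_controlled", name in USER_CONTROLLED[modality])
    return UncertaintySource(name=name, spec=spec, user_controlled=bool(user), unit=unit)


def load_budget(document: str | Mapping) -> UncertaintyBudget:
    """Parse a YAML/JSON budget document.

    The document declares ``modality``, optionally ``inherit_defaults: true``
    (unlisted sources fall back to the default budget) and one block per
    source::

        modality: photon
        inherit_defaults: true
        sources:
          pressure: {distribution: uniform, sigma: 1.0, unit: mbar}

    Unknown source names, negative sigmas and inconsistent
    ``sigma``/``half_width`` pairs raise a :class:`ValueError` naming the
    offending source.
    """
    doc = yaml.safe_load(document) if isinstance(document, str) else dict(document)
    if doc is None:
        doc = {}
    modality = doc.get("modality")
    if modality not in MODALITIES:
        raise ValueError(f"document must declare modality in {MODALITIES}, got {modality!r}")
    inherit = bool(doc.get("inherit_defaults", False))
    blocks = doc.get("sources") or {}
    known = _DEFAULTS[modality]
    for name in blocks:
        if name not in known:
            raise ValueError(f"unknown source {name!r} in {modality} budget document")
    sources: dict[str, UncertaintySource] = {}
    if inherit:
        sources.update({s.name: s for s in default_budget(modality)})
    for name, block in blocks.items():
        sources[name] = _source_from_block(name, block, modality)
    budget = UncertaintyBudget(modality, sources.values())
    budget.validate()
    return budget


def zero_sources(
    budget: UncertaintyBudget, selector: str | Iterable[str]
) -> UncertaintyBudget:
    """Copy of ``budget`` with selected sources' widths set to zero.

    ``selector`` is either the string ``"user_controlled"`` (zero every
    user-controlled source, the "careful user" limit) or an iterable of
    source names.  The original budget is unchanged.
    """
    out = copy.deepcopy(budget)
    if selector == "user_controlled":
        names = [s.name for s in budget if s.user_controlled]
    elif selector == "all":
        names = list(budget.sources)
    else:
        names = list(selector)
    for name in names:
        if name not in out.sources:
            raise ValueError(f"unknown source {name!r}")
        out.sources[name] = out.sources[name].zeroed()
    return out
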