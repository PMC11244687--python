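"""Canned end-to-end scenarios and golden-run checks.

Four self-contained scenarios pin the package's reference conditions:

* ``6MV``  -- photon, %dd(10)x = 67.74, interim formula inactive;
* ``18MV`` -- photon, %dd(10)x = 78.85 via the interim formula (its
  uniform +/-2 % accuracy source active) and k_Q intrinsic sigma 0.45 %;
* ``6MeV``  -- electron, I50 = 2.40 cm, DI gradient ~0.8 %/mm at d_ref;
* ``18MeV`` -- electron, I50 = 7.50 cm, gradient roughly half the 6 MeV one.

Each scenario is a :class:`ScenarioManifest`: budget + geometry + chamber +
settings + (n, seed).  Re-running a manifest at its stored seed reproduces
its summary bit-for-bit; :func:`golden_check` verifies that against a
previously frozen summary.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .beam import electron_geometry, photon_geometry
from .budget import UncertaintyBudget, default_budget
from .model import ElectronCalibrationModel, PhotonCalibrationModel, _BaseCalibrationModel
from .photon import ChamberSpec, ProtocolSettings
from .sampling import DistributionSpec

__all__ = ["ScenarioManifest", "build_scenario", "golden_check", "freeze_summary"]

SCENARIO_IDS = ("6MV", "18MV", "6MeV", "18MeV")


@dataclass
class ScenarioManifest:
    """A fully self-contained simulation scenario."""

    scenario_id: str
    modality: str
    budget: UncertaintyBudget
    geometry: object
    chamber: ChamberSpec
    settings: ProtocolSettings
    n: int = 10**6
    seed: int = 12345
    #: loose sanity bounds on the k=1 relative sigma (%), for smoke checks
    expected_rel_sigma_bounds: tuple = (0.0, float("inf"))

    def to_model(self) -> _BaseCalibrationModel:
        cls = PhotonCalibrationModel if self.modality == "photon" else ElectronCalibrationModel
        return cls(
            budget=self.budget,
            geometry=self.geometry,
            chamber=self.chamber,
            settings=self.settings,
        )

    def run(self, n: int | None = None, seed: int | None = None):
        return self.to_model().fit(
            n=self.n if n is None else n, seed=self.seed if seed is None else seed
        )

    def to_yaml(self) -> str:
        doc = {
            "scenario_id": self.scenario_id,
            "modality": self.modality,
            "n": self.n,
            "seed": self.seed,
            "budget": self.budget.to_document(),
            "chamber": asdict(self.chamber),
            "settings": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.settings).items()
            },
            "geometry": {
                k: (v if np.isscalar(v) or isinstance(v, (bool, str)) else "synthetic")
                for k, v in asdict(self.geometry).items()
            },
        }
        return yaml.safe_dump(doc, sort_keys=True)


def build_scenario(scenario_id: str) -> ScenarioManifest:
    """Build one of the pinned scenarios ('6MV', '18MV', '6MeV', '18MeV')."""
    if scenario_id == "6MV":
        return ScenarioManifest(
            scenario_id="6MV",
            modality="photon",
            budget=default_budget("photon"),
            geometry=photon_geometry("6MV"),
            chamber=ChamberSpec(),
            settings=ProtocolSettings(),
            expected_rel_sigma_bounds=(0.9, 1.5),
        )
    if scenario_id == "18MV":
        budget = default_budget("photon").replace_source(
            "kQ_intrinsic", DistributionSpec("normal", sigma=0.0045)
        )
        return ScenarioManifest(
            scenario_id="18MV",
            modality="photon",
            budget=budget,
            geometry=photon_geometry("18MV"),
            chamber=ChamberSpec(),
            settings=ProtocolSettings(),
            expected_rel_sigma_bounds=(0.9, 1.6),
        )
    if scenario_id == "6MeV":
        return ScenarioManifest(
            scenario_id="6MeV",
            modality="electron",
            budget=default_budget("electron"),
            geometry=electron_geometry("6MeV"),
            chamber=ChamberSpec(),
            settings=ProtocolSettings(),
            expected_rel_sigma_bounds=(1.0, 1.7),
        )
    if scenario_id == "18MeV":
        return ScenarioManifest(
            scenario_id="18MeV",
            modality="electron",
            budget=default_budget("electron"),
            geometry=electron_geometry("18MeV"),
            chamber=ChamberSpec(),
            settings=ProtocolSettings(),
            expected_rel_sigma_bounds=(0.9, 1.6),
        )
    raise ValueError(f"unknown scenario {scenario_id!r}; options {SCENARIO_IDS}")


def freeze_summary(manifest: ScenarioManifest, n: int | None = None) -> dict:
    """Run a manifest and return its summary as a JSON-serializable dict."""
    res = manifest.run(n=n)
    out = res.summary_stats.to_dict()
    out["scenario_id"] = manifest.scenario_id
    out["seed"] = manifest.seed
    return out


def golden_check(
    manifest: ScenarioManifest, frozen: dict | str | Path, n: int | None = None
) -> dict:
    """Re-run a manifest and compare bit-exactly against a frozen summary.

    ``frozen`` is a dict from :func:`freeze_summary` or a path to its JSON.
    Returns ``{"passed": bool, "mismatches": [field names]}``; any numeric
    drift at all (same seed, same code) is a failure.
    """
    if not isinstance(frozen, dict):
        frozen = json.loads(Path(frozen).read_text())
    if frozen.get("seed") != manifest.seed:
        raise ValueError("frozen summary was produced at a different seed")
    fresh = freeze_summary(manifest, n=n)
    mismatches = []
    for key, want in frozen.items():
        got = fresh.get(key)
        if isinstance(want, float):
            if got != want:
                mismatches.append(key)
        elif got != want:
            mismatches.append(key)
    return {"passed": not mismatches, "mismatches": mismatches, "fresh": fresh}
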