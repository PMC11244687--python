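"""Model / results interface over the calibration chains.

A :class:`PhotonCalibrationModel` or :class:`ElectronCalibrationModel`
bundles an uncertainty budget, a beam geometry, a chamber and the protocol
settings; ``fit(n, seed)`` runs the Monte Carlo chain and returns a
:class:`CalibrationResults` carrying the dose samples, the k=1/k=2
uncertainties, shape diagnostics and event counters.  Contribution tables
and sensitivity sweeps hang off the model (they re-run the chain under
modified budgets); plotting hangs off the results.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .beam import (
    ElectronBeamGeometry,
    PhotonBeamGeometry,
    electron_geometry,
    photon_geometry,
)
from .budget import UncertaintyBudget, default_budget, zero_sources
from .electron import run_electron
from .photon import ChainResult, ChamberSpec, ProtocolSettings, run_photon
from .reporting import (
    ELECTRON_TABLE_GROUPS,
    PHOTON_TABLE_GROUPS,
    SimulationSummary,
    SweepCurve,
    contribution_table,
    normality_report,
    sensitivity_sweep,
    summarize,
)

__all__ = ["PhotonCalibrationModel", "ElectronCalibrationModel", "CalibrationResults"]


class _BaseCalibrationModel:
    """Shared plumbing of the photon and electron calibration models."""

    modality: str = ""

    def __init__(
        self,
        budget: UncertaintyBudget | None = None,
        geometry=None,
        chamber: ChamberSpec | None = None,
        settings: ProtocolSettings | None = None,
    ):
        self.budget = budget if budget is not None else default_budget(self.modality)
        if self.budget.modality != self.modality:
            raise ValueError(
                f"budget modality {self.budget.modality!r} != model {self.modality!r}"
            )
        self.geometry = geometry if geometry is not None else self._default_geometry()
        self.chamber = chamber if chamber is not None else ChamberSpec()
        self.settings = settings if settings is not None else ProtocolSettings()

    def _default_geometry(self):
        raise NotImplementedError

    def _run(self, budget: UncertaintyBudget, n: int, seed: int) -> ChainResult:
        raise NotImplementedError

    # -- fitting ---------------------------------------------------------

    def fit(self, n: int = 10**6, seed: int = 0) -> "CalibrationResults":
        """Run ``n`` Monte Carlo calibrations and summarize the dose samples."""
        if n < 10**4:
            import warnings

            warnings.warn(
                f"n={n} is small for stable summary statistics (recommend >= 1e4)",
                stacklevel=2,
            )
        chain = self._run(self.budget, n, seed)
        return CalibrationResults(self, chain, n=n, seed=seed)

    # -- derived analyses ------------------------------------------------

    def contributions(self, n: int = 2 * 10**5, seed: int = 0, grouped: bool = True):
        """Per-source contribution table (each source run alone)."""
        groups = None
        if grouped:
            groups = (
                PHOTON_TABLE_GROUPS if self.modality == "photon" else ELECTRON_TABLE_GROUPS
            )
        return contribution_table(
            lambda b: self._run(b, n, seed), self.budget, groups=groups
        )

    def sweep(
        self,
        source: str,
        half_widths_mm: Sequence[float] | None = None,
        n: int = 10**5,
        seed: int = 0,
    ) -> SweepCurve:
        """Sweep one user-controlled source's uniform half-width (mm grid)."""
        if half_widths_mm is None:
            half_widths_mm = np.arange(0.0, 2.0 + 1e-9, 0.25)
        return sensitivity_sweep(
            lambda b: self._run(b, n, seed), source, half_widths_mm, self.budget
        )

    def user_zeroed(self) -> "_BaseCalibrationModel":
        """Copy of the model with all user-controlled sources zeroed."""
        out = self.__class__(
            budget=zero_sources(self.budget, "user_controlled"),
            geometry=self.geometry,
            chamber=self.chamber,
            settings=self.settings,
        )
        return out

    @classmethod
    def from_scenario(cls, scenario_id: str) -> "_BaseCalibrationModel":
        """Model for a canned scenario ('6MV', '18MV', '6MeV', '18MeV')."""
        from .scenarios import build_scenario

        manifest = build_scenario(scenario_id)
        model = manifest.to_model()
        if not isinstance(model, cls):
            raise ValueError(
                f"scenario {scenario_id!r} is a {model.modality} scenario"
            )
        return model


class PhotonCalibrationModel(_BaseCalibrationModel):
    """Monte Carlo model of a TG-51 photon calibration."""

    modality = "photon"

    def _default_geometry(self) -> PhotonBeamGeometry:
        return photon_geometry("6MV")

    def _run(self, budget, n, seed):
        return run_photon(n, seed, budget, self.geometry, self.chamber, self.settings)


class ElectronCalibrationModel(_BaseCalibrationModel):
    """Monte Carlo model of a TG-51 electron (Farmer chamber) calibration."""

    modality = "electron"

    def _default_geometry(self) -> ElectronBeamGeometry:
        return electron_geometry("6MeV")

    def _run(self, budget, n, seed):
        return run_electron(n, seed, budget, self.geometry, self.chamber, self.settings)


class CalibrationResults:
    """Results of one fitted (simulated) calibration model."""

    def __init__(self, model: _BaseCalibrationModel, chain: ChainResult, n: int, seed: int):
        self.model = model
        self.chain = chain
        self.n = n
        self.seed = seed
        self.summary_stats: SimulationSummary = summarize(chain.samples, chain.flags)

    # convenience accessors
    @property
    def samples(self) -> np.ndarray:
        return self.chain.samples

    @property
    def rel_sigma(self) -> float:
        """k=1 relative standard deviation of the dose, percent."""
        return self.summary_stats.rel_sigma

    @property
    def expanded_95(self) -> float:
        """k=2 expanded interval, percent (exactly 2 x rel_sigma)."""
        return self.summary_stats.expanded_95

    @property
    def flags(self) -> dict:
        return self.summary_stats.flags

    def normality(self, bins: int = 80) -> dict:
        return normality_report(self.samples, bins=bins)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of a model-results report."""
        s = self.summary_stats
        geom_label = getattr(self.model.geometry, "energy_label", "")
        lines = [
            "TG-51 Monte Carlo calibration uncertainty",
            "=" * 46,
            f"modality:             {self.model.modality} ({geom_label})",
            f"chamber:              {self.model.chamber.model_name}",
            f"iterations (n):       {s.n}",
            f"seed:                 {self.seed}",
            "-" * 46,
            f"mean relative dose:   {s.mean:.5f}",
            f"k=1 rel. sigma:       {s.rel_sigma:.3f} %",
            f"k=2 expanded (95%):   {s.expanded_95:.2f} %",
            f"1.96 sigma interval:  {s.ci_1p96:.2f} %",
            f"2.5-97.5 percentile:  {s.empirical_interval:.2f} % (half-width)",
            f"skewness:             {s.skewness:+.4f}",
            f"excess kurtosis:      {s.excess_kurtosis:+.4f}",
            "-" * 46,
            f"flags: {s.flags}",
        ]
        return "\n".join(lines)

    def plot_distribution(self, ax=None, bins: int = 80):
        """Histogram of the dose samples with the matched normal overlaid."""
        import matplotlib.pyplot as plt

        rep = self.normality(bins=bins)
        if ax is None:
            _, ax = plt.subplots()
        centers = 0.5 * (rep["bin_edges"][:-1] + rep["bin_edges"][1:])
        ax.bar(
            centers,
            rep["bin_density"],
            width=np.diff(rep["bin_edges"]),
            alpha=0.5,
            label="simulated dose",
        )
        ax.plot(centers, rep["normal_density"], "k-", label="matched normal")
        ax.set_xlabel("relative dose $D_i / D_{nominal}$")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        return (
            f"<CalibrationResults {self.model.modality} n={self.n} "
            f"rel_sigma={self.rel_sigma:.3f}%>"
        )
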