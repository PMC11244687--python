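"""Beam descriptions, depth-dose sensitivities and synthetic curves.

Photon beam quality enters through %dd(10), the percent depth dose at 10 cm;
its sensitivity to setup errors is a first-order expansion of

    dd(d) ~ ((SSD+dm)/(SSD+d))^2 * Sp(fd) * TMR(d, fd)

so a perturbation in scan depth, SSD or field size maps linearly onto a
relative %dd(10) error.  For a 6 MV beam the depth term dominates with a
coefficient of -0.032 cm^-1 (i.e. -0.32 %/mm).

Electron beam quality enters through I50, the depth of 50 % ionization of
the scanned depth-ionization (DI) curve; the charge-measurement sensitivity
to depth errors is the local relative gradient (dDI/dd)/DI of the shifted DI
curve at the measurement depth d_ref + 0.5 r_cav, obtained by fitting a
cubic polynomial in a window around that depth.

Synthetic curve generators provide self-contained, realistic stand-ins for
scanned curves: the photon profile is pinned to %dd(10) = 67.74 and the
-0.032 cm^-1 depth coefficient; the electron profiles are smooth DI falloffs
pinned to the nominal I50 and a relative gradient of about 0.8 %/mm at the
measurement depth for the 6 MeV-like beam (about half that at 18 MeV-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DepthIonizationCurve",
    "PhotonBeamGeometry",
    "ElectronBeamGeometry",
    "relative_dd_perturbation",
    "interim_ddx",
    "shift_curve",
    "local_relative_gradient",
    "fit_photon_depth_coefficient",
    "synth_curves",
    "read_curve_csv",
    "write_curve_csv",
    "photon_geometry",
    "electron_geometry",
]


@dataclass(frozen=True)
class DepthIonizationCurve:
    """A depth-dose or depth-ionization curve on the percent scale.

    Depths are cm from the water surface, strictly increasing; values are
    normalized so the maximum is 100.  ``shift_applied`` records the total
    upstream (toward-surface) effective-point-of-measurement shift already
    applied, e.g. 0.6 r_cav for photon PDD scans or 0.5 r_cav for electron
    DI scans with a cylindrical chamber.
    """

    depths: np.ndarray
    values: np.ndarray
    shift_applied: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.ndim != 1 or v.shape != d.shape:
            raise ValueError("depths and values must be 1-D arrays of equal length")
        if d.size < 7:
            raise ValueError("curve needs at least 7 points")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("curve values must be positive")
        v = 100.0 * v / v.max()
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "values", v)

    def value_at(self, depth: float) -> float:
        return float(np.interp(depth, self.depths, self.values))


def shift_curve(curve: DepthIonizationCurve, shift: float) -> DepthIonizationCurve:
    """Shift a scanned curve upstream (toward the surface) by ``shift`` cm.

    Depths decrease by ``shift``; the accumulated ``shift_applied`` grows.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0 (upstream only)")
    return DepthIonizationCurve(
        depths=curve.depths - shift,
        values=curve.values.copy(),
        shift_applied=curve.shift_applied + shift,
    )


def local_relative_gradient(
    curve: DepthIonizationCurve, at_depth: float, window: float = 0.75
) -> float:
    """Relative gradient (dDI/dd)/DI at ``at_depth``, per cm.

    A least-squares cubic is fitted to the curve points inside
    ``[at_depth - window, at_depth + window]`` and differentiated
    analytically at ``at_depth``.
    """
    mask = np.abs(curve.depths - at_depth) <= window
    if mask.sum() < 4:
        raise ValueError(
            f"need >= 4 curve points within +/-{window} cm of {at_depth} cm, "
            f"found {int(mask.sum())}"
        )
    x = curve.depths[mask] - at_depth
    y = curve.values[mask]
    coeffs = np.polynomial.polynomial.polyfit(x, y, 3)
    value, slope = coeffs[0], coeffs[1]
    if value == 0:
        raise ZeroDivisionError("fitted curve value is zero at evaluation depth")
    return float(slope / value)


def fit_photon_depth_coefficient(
    curve: DepthIonizationCurve, SSD: float, d: float, d_m: float, window: float = 2.0
) -> float:
    """Depth coefficient of the %dd(10) sensitivity fitted from a PDD curve.

    The raw curve log-slope at ``d`` gives the sensitivity of the reading at
    fixed normalization; because a surface-setting error shifts the
    normalization depth by the same amount, the %dd coefficient adds back
    the inverse-square term at d_m: ``coeff = slope + 2/(SSD + d_m)``.
    """
    slope = local_relative_gradient(curve, d, window=window)
    return slope + 2.0 / (SSD + d_m)


@dataclass(frozen=True)
class PhotonBeamGeometry:
    """Nominal photon calibration geometry and local sensitivity coefficients.

    ``scan_*_coeff`` are the linearised %dd(10) sensitivities (per cm) to
    scan depth, SSD and field-size errors; the charge-measurement
    counterparts are derived: the measurement depth coefficient removes the
    normalization-shift term (``scan_depth_coeff - 2/(SSD + d_m)``) and the
    measurement SSD coefficient is the pure inverse-square ``-2/(SSD + d)``.
    """

    SSD: float = 100.0          # cm
    d: float = 10.0             # calibration depth, cm
    d_m: float = 1.5            # depth of maximum dose, cm
    f: float = 10.0             # field side at isocenter, cm
    f_d: float = 11.0           # field side at depth, cm
    dd10: float = 67.74         # nominal %dd(10)
    use_interim: bool = False   # apply interim %dd(10)x formula (>10 MV)
    scan_depth_coeff: float = -0.032   # cm^-1
    scan_ssd_coeff: float = 0.0015     # cm^-1
    scan_field_coeff: float = 0.010    # cm^-1
    energy_label: str = "6MV"

    def __post_init__(self):
        if self.scan_depth_coeff >= 0:
            raise ValueError("scan depth coefficient must be negative at 10 cm depth")
        ddx = self.dd10x
        if not (63.0 < ddx < 86.0):
            raise ValueError(f"nominal %dd(10)x {ddx:.2f} outside k_Q validity (63, 86)")

    @property
    def dd10x(self) -> float:
        """Nominal %dd(10)x (interim formula applied above 10 MV)."""
        if self.use_interim:
            return interim_ddx(self.dd10, 0.0)
        return self.dd10

    @property
    def meas_depth_coeff(self) -> float:
        return self.scan_depth_coeff - 2.0 / (self.SSD + self.d_m)

    @property
    def meas_ssd_coeff(self) -> float:
        return -2.0 / (self.SSD + self.d)

    @property
    def meas_field_coeff(self) -> float:
        return self.scan_field_coeff

    @classmethod
    def from_curve(
        cls,
        curve: DepthIonizationCurve,
        SSD: float = 100.0,
        d: float = 10.0,
        d_m: float = 1.5,
        scan_field_coeff: float = 0.010,
        **kwargs,
    ) -> "PhotonBeamGeometry":
        """Build a geometry with sensitivities fitted from a PDD curve."""
        depth_coeff = fit_photon_depth_coefficient(curve, SSD, d, d_m)
        ssd_coeff = 2.0 * (d - d_m) / ((SSD + d) * (SSD + d_m))
        return cls(
            SSD=SSD,
            d=d,
            d_m=d_m,
            dd10=curve.value_at(d),
            scan_depth_coeff=depth_coeff,
            scan_ssd_coeff=ssd_coeff,
            scan_field_coeff=scan_field_coeff,
            **kwargs,
        )


def relative_dd_perturbation(
    geom: PhotonBeamGeometry, delta_d, delta_ssd, delta_f
):
    """First-order relative %dd(10) error for setup perturbations (fractions).

    Linear combination of the inverse-square SSD term, the depth term (the
    surface-setting error shifts d and d_m together) and the field-size
    term.  Accepts scalars or arrays.
    """
    return (
        geom.scan_depth_coeff * np.asarray(delta_d)
        + geom.scan_ssd_coeff * np.asarray(delta_ssd)
        + geom.scan_field_coeff * np.asarray(delta_f)
    )


def interim_ddx(dd10, delta):
    """Interim photon beam-quality formula %dd(10)x = 1.267 %dd(10) - 20.

    Used above 10 MV in place of a lead-foil measurement; ``delta`` is the
    formula-accuracy perturbation in %dd(10)x percentage points (the formula
    can err by up to 2 % in extreme cases, sampled uniform +/-2).
    """
    return 1.267 * np.asarray(dd10) - 20.0 + np.asarray(delta)


@dataclass(frozen=True)
class ElectronBeamGeometry:
    """Nominal electron calibration geometry.

    The charge is measured once, at ``d_ref + 0.5 r_cav``, which absorbs the
    gradient correction P_gr exactly.  Depth sensitivity of the reading is
    the local relative DI gradient there, either fitted from ``di_curve`` or
    supplied directly via ``gradient_override`` (fraction per cm).
    ``VSD``, ``g`` and ``d_m`` are documentation fields of the virtual
    source model (VSD + d_m + g ~ 100 cm); the SSD sensitivity of the
    reading is ``-ssd_coeff`` per cm.
    """

    I50_nominal: float          # cm
    SSD: float = 100.0
    di_curve: DepthIonizationCurve | None = None
    gradient_override: float | None = None   # (dDI/dd)/DI at meas depth, per cm
    ssd_coeff: float = 0.02     # cm^-1
    r_cav: float = 0.3          # Farmer cavity radius, cm
    gradient_window: float = 0.75
    VSD: float = 95.0
    g: float = 3.5
    d_m: float = 1.5
    energy_label: str = "6MeV"

    def __post_init__(self):
        if not (2.0 <= self.I50_nominal <= 10.0):
            raise ValueError("I50 must lie in [2, 10] cm")
        if self.di_curve is None and self.gradient_override is None:
            raise ValueError("provide di_curve or gradient_override")

    @property
    def R50_nominal(self) -> float:
        return 1.029 * self.I50_nominal - 0.06

    @property
    def d_ref(self) -> float:
        return 0.6 * self.R50_nominal - 0.1

    @property
    def meas_depth(self) -> float:
        return self.d_ref + 0.5 * self.r_cav

    def relative_gradient(self) -> float:
        """Relative DI gradient at the measurement depth, per cm."""
        if self.gradient_override is not None:
            return self.gradient_override
        return local_relative_gradient(
            self.di_curve, self.meas_depth, window=self.gradient_window
        )


# ---------------------------------------------------------------------------
# synthetic curves

def _photon_curve(dd10_target: float, SSD: float, d: float, d_m: float,
                  eq_depth_coeff: float) -> DepthIonizationCurve:
    # dd(d) = 100 * ((SSD+dm)/(SSD+d))^2 * exp(-mu*(d-dm) - nu*(d-dm)^2),
    # with (mu, nu) solved so dd(10) and the %dd depth coefficient match.
    geo = ((SSD + d_m) / (SSD + d)) ** 2
    L = -math.log(dd10_target / 100.0 / geo)           # -ln TMR(d)
    t_tmr = eq_depth_coeff + 2.0 / (SSD + d) - 2.0 / (SSD + d_m)
    s = -t_tmr
    delta = d - d_m
    nu = (s * delta - L) / delta**2
    mu = s - 2.0 * nu * delta
    depths = np.arange(0.0, 25.0 + 1e-9, 0.1)
    vals = np.empty_like(depths)
    deep = depths >= d_m
    dd = depths[deep] - d_m
    vals[deep] = 100.0 * ((SSD + d_m) / (SSD + depths[deep])) ** 2 * np.exp(
        -mu * dd - nu * dd**2
    )
    # smooth parabolic buildup from ~50 % surface value to the maximum
    shallow = ~deep
    vals[shallow] = 100.0 * (1.0 - 0.5 * ((d_m - depths[shallow]) / d_m) ** 2)
    return DepthIonizationCurve(depths=depths, values=vals, shift_applied=0.18)


def _electron_curve(I50: float, grad_target: float, r_cav: float = 0.3
                    ) -> DepthIonizationCurve:
    # Gaussian falloff DI = 100 exp(-(d - dmax)^2 / (2 s^2)) with (dmax, s)
    # solved so DI(I50) = 50 and (dDI/dd)/DI = grad_target (< 0) at the
    # measurement depth d_ref + 0.5 r_cav.
    R50 = 1.029 * I50 - 0.06
    d_meas = 0.6 * R50 - 0.1 + 0.5 * r_cav
    g = abs(grad_target)
    c = I50 - d_meas
    b = 2.0 * c - 2.0 * math.log(2.0) / g
    disc = b * b - 4.0 * c * c
    if disc <= 0:
        raise ValueError("no Gaussian solution for the requested gradient/I50 pair")
    u = (-b - math.sqrt(disc)) / 2.0   # small root: d_meas just beyond dmax
    s2 = u / g
    dmax = d_meas - u
    depths = np.arange(0.0, I50 + 3.0 * math.sqrt(s2) + 1e-9, 0.02)
    vals = 100.0 * np.exp(-((depths - dmax) ** 2) / (2.0 * s2))
    vals = np.clip(vals, 1e-6, None)
    return DepthIonizationCurve(depths=depths, values=vals,
                                shift_applied=0.5 * 0.3)  # CC13 scan shift


_PROFILES = {
    "photon_6MV": dict(kind="photon", dd10=67.74, d_m=1.5),
    "photon_18MV": dict(kind="photon", dd10=(78.85 + 20.0) / 1.267, d_m=3.2),
    "electron_6MeV": dict(kind="electron", I50=2.40, gradient=-0.08),
    "electron_18MeV": dict(kind="electron", I50=7.50, gradient=-0.042),
}


def synth_curves(profile: str, **overrides) -> DepthIonizationCurve:
    """Deterministic synthetic curve for a named beam profile.

    Profiles: ``photon_6MV``, ``photon_18MV``, ``electron_6MeV``,
    ``electron_18MeV``.  Overrides: ``dd10``, ``d_m``, ``SSD``, ``d``,
    ``eq_depth_coeff`` (photon) or ``I50``, ``gradient`` (electron).
    """
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; options {sorted(_PROFILES)}")
    params = {**_PROFILES[profile], **overrides}
    if params.pop("kind") == "photon":
        return _photon_curve(
            dd10_target=params.get("dd10"),
            SSD=params.get("SSD", 100.0),
            d=params.get("d", 10.0),
            d_m=params.get("d_m"),
            eq_depth_coeff=params.get("eq_depth_coeff", -0.032),
        )
    return _electron_curve(
        I50=params.get("I50"),
        grad_target=params.get("gradient"),
        r_cav=params.get("r_cav", 0.3),
    )


def photon_geometry(energy_label: str = "6MV") -> PhotonBeamGeometry:
    """Default photon geometry for the pinned 6 MV / 18 MV scenarios.

    6 MV uses the printed sensitivity coefficients; 18 MV reuses them (its
    own coefficients are not pinned) with the interim %dd(10)x formula
    active and a deeper d_m.
    """
    if energy_label == "6MV":
        return PhotonBeamGeometry(energy_label="6MV")
    if energy_label == "18MV":
        return PhotonBeamGeometry(
            d_m=3.2,
            dd10=(78.85 + 20.0) / 1.267,
            use_interim=True,
            energy_label="18MV",
        )
    raise ValueError(f"unknown photon energy label {energy_label!r}")


def electron_geometry(energy_label: str = "6MeV") -> ElectronBeamGeometry:
    """Default electron geometry (synthetic DI curve attached)."""
    if energy_label == "6MeV":
        return ElectronBeamGeometry(
            I50_nominal=2.40, di_curve=synth_curves("electron_6MeV"),
            VSD=95.0, g=3.5, d_m=1.4, energy_label="6MeV",
        )
    if energy_label == "18MeV":
        return ElectronBeamGeometry(
            I50_nominal=7.50, di_curve=synth_curves("electron_18MeV"),
            VSD=95.0, g=2.0, d_m=3.0, energy_label="18MeV",
        )
    raise ValueError(f"unknown electron energy label {energy_label!r}")


# ---------------------------------------------------------------------------
# curve files

def read_curve_csv(path: str | Path, shift_applied: float = 0.0) -> DepthIonizationCurve:
    """Read a two-column ``depth_cm,value`` CSV curve file."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["depth_cm", "value"]:
        raise ValueError(f"{path}: expected header 'depth_cm,value'")
    return DepthIonizationCurve(
        depths=df["depth_cm"].to_numpy(float),
        values=df["value"].to_numpy(float),
        shift_applied=shift_applied,
    )


def write_curve_csv(curve: DepthIonizationCurve, path: str | Path) -> None:
    pd.DataFrame({"depth_cm": curve.depths, "value": curve.values}).to_csv(
        path, index=False
    )
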