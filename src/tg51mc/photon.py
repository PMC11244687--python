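"""Per-iteration photon calibration chain and the full photon simulation.

One Monte Carlo iteration re-enacts a complete TG-51 photon calibration:

1. a %dd(10) scan perturbed by scan-depth, SSD and field-size errors;
2. the beam-quality specifier %dd(10)x (identity below 10 MV, interim
   formula above) and the chamber's quadratic k_Q fit, plus the intrinsic
   and fit-accuracy perturbations of the protocol data;
3. the temperature-pressure air-density correction P_TP from sampled T, p;
4. a correlated raw-reading ensemble (M_raw, M+, M_H, M_L) sharing the
   setup errors and stability/extracameral terms but with independent
   repeatability draws, from which P_pol (polarity) and P_ion (two-voltage
   recombination, clamped at 1.000) are computed exactly as a user would;
5. the dose product M_raw P_ion P_TP P_elec P_pol k_Q N_D,w (1 + humidity),
   normalized by the all-nominal dose.

Because P_ion and P_pol reuse the same raw readings as M_raw, their
correlations with the reading are propagated exactly rather than assumed
away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beam import PhotonBeamGeometry, interim_ddx, relative_dd_perturbation
from .budget import UncertaintyBudget
from .sampling import DistributionSpec, RandomStream, draw

__all__ = [
    "ChamberSpec",
    "ProtocolSettings",
    "ChainResult",
    "sample_calibration_factor",
    "kq",
    "ptp",
    "pion",
    "ppol",
    "run_photon",
]

KQ_VALID_RANGE = (63.0, 86.0)
_REF_MBAR = 1013.25
_REF_MMHG = 760.0


@dataclass(frozen=True)
class ChamberSpec:
    """Ionization-chamber constants.

    ``kq_A/B/C`` are the quadratic beam-quality fit constants
    (k_Q = A + B*1e-3*ddx + C*1e-5*ddx^2); defaults are the PTW N30013
    Farmer values.  Calibration-factor and electrometer uncertainties are
    k=1 relative fractions.
    """

    kq_A: float = 0.9652
    kq_B: float = 2.141      # units 1e-3 per %
    kq_C: float = -2.623     # units 1e-5 per %^2
    r_cav: float = 0.3       # cm
    N_Dw_rel_u: float = 0.0075
    P_elec_nominal: float = 1.000
    P_elec_rel_u: float = 0.001
    k_ecal_nominal: float = 0.897
    model_name: str = "PTW N30013"

    def kq_nominal(self, ddx: float) -> float:
        return self.kq_A + self.kq_B * 1e-3 * ddx + self.kq_C * 1e-5 * ddx**2


@dataclass(frozen=True)
class ProtocolSettings:
    """Protocol-level constants of the simulated calibration session."""

    voltage_ratio: float = 2.0      # V_H / V_L, exact
    MU: float = 100.0
    P_ion_nominal: float = 1.003    # not printed by any table; configurable
    P_pol_nominal: float = 1.000
    P_ion_bounds: tuple = (1.00, 1.05)
    T0: float = 20.7                # degC
    p0: float = 990.1               # in pressure_unit
    pressure_unit: str = "mbar"     # "mbar" or "mmHg"
    charge_sign: int = -1
    clamp_pion: bool = True         # set P_ion < 1 to exactly 1.000

    def __post_init__(self):
        if not (1.00 <= self.P_ion_nominal < 1.05):
            raise ValueError("P_ion_nominal must lie in [1.00, 1.05)")
        if self.voltage_ratio != 2.0:
            raise ValueError("two-voltage chain requires voltage ratio exactly 2")


@dataclass
class ChainResult:
    """Relative dose samples plus per-run event counters."""

    samples: np.ndarray
    n_kq_range_flags: int = 0
    n_pion_clamped: int = 0
    n_pion_above_max: int = 0
    nominal_dose: float = 1.0

    @property
    def flags(self) -> dict:
        return {
            "kq_range": self.n_kq_range_flags,
            "pion_clamped": self.n_pion_clamped,
            "pion_above_max": self.n_pion_above_max,
        }


def sample_calibration_factor(nominal, rel_draw):
    """Multiplicative factor sample: ``nominal * (1 + rel_draw)``.

    Used for N_D,w, P_elec and k_ecal, whose uncertainties are declared as
    k=1 relative fractions.
    """
    return np.asarray(nominal) * (1.0 + np.asarray(rel_draw))


def kq(ddx, delta0, delta_f, chamber: ChamberSpec):
    """Beam-quality conversion factor with intrinsic and fit perturbations.

    ``k_Q = [A + B 1e-3 ddx + C 1e-5 ddx^2] + (delta0 + delta_f) k_Q,nom``
    where ``delta0`` (protocol-data accuracy, normal sigma 0.004) and
    ``delta_f`` (fit rms, normal sigma 0.0007) are relative fractions.
    The quadratic is valid for 63 < %dd(10)x < 86; out-of-range samples are
    flagged by the caller, not rejected.
    """
    ddx = np.asarray(ddx, dtype=float)
    if np.any((ddx < 0) | (ddx > 100)):
        raise ValueError("%dd(10)x outside [0, 100]")
    base = chamber.kq_A + chamber.kq_B * 1e-3 * ddx + chamber.kq_C * 1e-5 * ddx**2
    nominal = base if np.ndim(base) == 0 else base
    return base + (np.asarray(delta0) + np.asarray(delta_f)) * nominal


def ptp(T, p, pressure_unit: str = "mbar"):
    """Temperature-pressure correction ``(p_ref/p) (273.2 + T)/295.2``.

    Reference conditions 22 degC and 1 atm, with the reference pressure
    expressed in the caller's declared unit (760 mmHg == 1013.25 mbar).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pressure must be positive")
    T = np.asarray(T, dtype=float)
    if np.any((T < 0) | (T > 50)):
        raise ValueError("temperature outside plausible range 0-50 degC")
    if pressure_unit == "mbar":
        ref = _REF_MBAR
    elif pressure_unit == "mmHg":
        ref = _REF_MMHG
    else:
        raise ValueError(f"unknown pressure unit {pressure_unit!r}")
    return (ref / p) * ((273.2 + T) / 295.2)


def pion(M_H, M_L, delta_formula, settings: ProtocolSettings):
    """Two-voltage recombination correction with formula perturbation.

    ``P = -1/(M_H/M_L - 2) + delta_formula * P_ion,nom``.  Values below
    1.000 are clamped to exactly 1.000 (physical bound enforced by the
    protocol); values above 1.05 are counted by the caller but not clamped.

    Returns ``(P, n_clamped)``.
    """
    r = np.asarray(M_H, dtype=float) / np.asarray(M_L, dtype=float)
    if np.any(r == 2.0):
        raise ZeroDivisionError("M_H/M_L equals the voltage ratio: singular")
    P = -1.0 / (r - 2.0) + np.asarray(delta_formula) * settings.P_ion_nominal
    n_clamped = 0
    if settings.clamp_pion:
        low = P < 1.0
        n_clamped = int(np.count_nonzero(low))
        P = np.where(low, 1.0, P)
    return P, n_clamped


def ppol(M_plus, M_minus, M):
    """Polarity correction ``|(M+ - M-) / (2 M)|`` from signed readings."""
    M = np.asarray(M, dtype=float)
    if np.any(M == 0):
        raise ZeroDivisionError("reference reading M is zero")
    return np.abs((np.asarray(M_plus) - np.asarray(M_minus)) / (2.0 * M))


def _src_draw(budget: UncertaintyBudget, name: str, n: int, stream: RandomStream,
              label: str | None = None) -> np.ndarray:
    return draw(budget[name].spec, n, stream, label or name)


def _reading_ensemble(correlated: np.ndarray, budget: UncertaintyBudget,
                      n: int, stream: RandomStream, settings: ProtocolSettings):
    """Signed reading ensemble (M_raw, M_plus, M_H, M_L) magnitudes.

    The correlated part (setup + stability + extracameral) is common to all
    readings of one iteration; each reading adds its own repeatability
    draw.  M_H is identified with M_raw (common clinical practice), and M_L
    is constructed so the all-nominal two-voltage formula returns
    P_ion_nominal.  The opposite-polarity reading M_plus has nominal equal
    magnitude (P_pol_nominal = 1).
    """
    r_main = _src_draw(budget, "repeatability", n, stream, "repeatability#main")
    r_plus = _src_draw(budget, "repeatability", n, stream, "repeatability#plus")
    r_low = _src_draw(budget, "repeatability", n, stream, "repeatability#low")
    M_raw_mag = 1.0 + correlated + r_main
    M_plus_mag = 1.0 + correlated + r_plus
    ratio0 = 2.0 - 1.0 / settings.P_ion_nominal   # nominal M_H/M_L
    M_low_mag = (1.0 + correlated + r_low) / ratio0
    return M_raw_mag, M_plus_mag, M_raw_mag, M_low_mag


def mraw_ensemble(
    delta_d: np.ndarray,
    delta_ssd: np.ndarray,
    delta_f: np.ndarray,
    geom: PhotonBeamGeometry,
    budget: UncertaintyBudget,
    n: int,
    stream: RandomStream,
    settings: ProtocolSettings,
):
    """Photon raw-reading ensemble for shared setup draws."""
    correlated = (
        geom.meas_depth_coeff * delta_d
        + geom.meas_ssd_coeff * delta_ssd
        + geom.meas_field_coeff * delta_f
        + _src_draw(budget, "stability", n, stream)
        + _src_draw(budget, "extracameral", n, stream)
    )
    return _reading_ensemble(correlated, budget, n, stream, settings)


def run_photon(
    n: int,
    seed: int,
    budget: UncertaintyBudget,
    geom: PhotonBeamGeometry,
    chamber: ChamberSpec = ChamberSpec(),
    settings: ProtocolSettings = ProtocolSettings(),
) -> ChainResult:
    """Simulate ``n`` photon calibrations; return normalized dose samples."""
    budget.validate()
    if budget.modality != "photon":
        raise ValueError("run_photon requires a photon budget")
    stream = RandomStream(seed)

    # shared setup draws (same SSD/field for scan and charge measurements;
    # scan depth and Farmer depth are independent sessions)
    d_scan = _src_draw(budget, "depth_scan", n, stream)
    d_meas = _src_draw(budget, "depth_meas", n, stream)
    d_ssd = _src_draw(budget, "SSD", n, stream)
    d_f = _src_draw(budget, "field_size", n, stream)

    # beam quality: scan -> %dd(10) -> %dd(10)x -> k_Q
    dd10 = geom.dd10 * (1.0 + relative_dd_perturbation(geom, d_scan, d_ssd, d_f))
    if geom.use_interim:
        ddx = interim_ddx(dd10, _src_draw(budget, "interim_formula", n, stream))
    else:
        ddx = dd10
    kq_i = kq(
        ddx,
        _src_draw(budget, "kQ_intrinsic", n, stream),
        _src_draw(budget, "kQ_formula", n, stream),
        chamber,
    )
    n_kq_flags = int(np.count_nonzero((ddx <= KQ_VALID_RANGE[0]) | (ddx >= KQ_VALID_RANGE[1])))

    # environment
    T_i = settings.T0 + _src_draw(budget, "temperature_A", n, stream) \
        + _src_draw(budget, "temperature_B", n, stream)
    p_i = settings.p0 + _src_draw(budget, "pressure", n, stream)
    ptp_i = ptp(T_i, p_i, settings.pressure_unit)

    # readings and reading-derived corrections
    M_raw, M_plus, M_H, M_L = mraw_ensemble(
        d_meas, d_ssd, d_f, geom, budget, n, stream, settings
    )
    sign = settings.charge_sign
    pol = ppol(-sign * M_plus, sign * M_raw, sign * M_raw)
    pion_i, n_clamped = pion(
        M_H, M_L, _src_draw(budget, "pion_formula", n, stream), settings
    )
    n_above = int(np.count_nonzero(pion_i > settings.P_ion_bounds[1]))

    # multiplicative factors
    p_elec = sample_calibration_factor(
        chamber.P_elec_nominal, _src_draw(budget, "electrometer_calibration", n, stream)
    )
    n_dw = sample_calibration_factor(
        1.0, _src_draw(budget, "chamber_calibration", n, stream)
    )
    humidity = 1.0 + _src_draw(budget, "humidity", n, stream)

    dose = M_raw * pion_i * ptp_i * p_elec * pol * kq_i * n_dw * humidity

    nominal = (
        1.0
        * settings.P_ion_nominal
        * ptp(settings.T0, settings.p0, settings.pressure_unit)
        * chamber.P_elec_nominal
        * settings.P_pol_nominal
        * chamber.kq_nominal(geom.dd10x)
    )
    return ChainResult(
        samples=dose / nominal,
        n_kq_range_flags=n_kq_flags,
        n_pion_clamped=n_clamped,
        n_pion_above_max=n_above,
        nominal_dose=nominal,
    )
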