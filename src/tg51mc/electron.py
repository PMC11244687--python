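"""Per-iteration electron calibration chain and the full electron simulation.

The electron chain re-enacts a Farmer-chamber TG-51 electron calibration:

1. the measured 50 %-ionization depth I50 (uniform error), the Ding
   conversion R50 = 1.029 I50 - 0.06 with its own formula error, and the
   reference depth d_ref = 0.6 R50 - 0.1 with a depth-setting error; the
   same R50 draw feeds both the d_ref displacement and k'R50, preserving
   their (partially cancelling) correlation;
2. the chamber conversion k_ecal (relative, normal) and the cylindrical
   chamber quality factor k'R50 = 0.9905 + 0.071 exp(-R50/3.67) with a
   bounded-uniform fit-accuracy perturbation;
3. the raw-reading ensemble at the single measurement depth
   d_ref + 0.5 r_cav (which absorbs the gradient correction P_gr exactly),
   with depth sensitivity given by the local relative DI-curve gradient and
   SSD sensitivity -0.02 per cm from the virtual-source model;
4. P_pol, P_ion, P_TP, P_elec and humidity exactly as for photons;
5. the normalized dose product
   M_raw P_ion P_TP P_elec P_pol k'R50 k_ecal N_D,w (1 + humidity).
"""

from __future__ import annotations

import numpy as np

from .beam import ElectronBeamGeometry
from .budget import UncertaintyBudget
from .photon import (
    ChainResult,
    ChamberSpec,
    ProtocolSettings,
    _reading_ensemble,
    _src_draw,
    pion,
    ppol,
    ptp,
    sample_calibration_factor,
)
from .sampling import RandomStream

__all__ = [
    "beam_quality_chain",
    "kprime_r50",
    "mraw_ensemble_electron",
    "run_electron",
]

R50_VALID_RANGE = (2.0, 9.0)


def beam_quality_chain(I50_nominal, delta_I50, delta_R50_formula, delta_d_set):
    """Electron beam-quality sub-chain.

    ``I50_i = I50 + dI50``; ``R50_i = 1.029 I50_i - 0.06 + dR50``;
    ``d_ref`` displacement ``= 0.6 (R50_nom - R50_i) + dd_set`` (an
    overestimated R50 leaves the chamber effectively shallow).

    Returns ``(R50_i, delta_d_ref_i, d_ref_nominal)``.
    """
    if not (2.0 <= I50_nominal <= 10.0):
        raise ValueError("I50 must lie in [2, 10] cm")
    I50_i = I50_nominal + np.asarray(delta_I50)
    R50_nom = 1.029 * I50_nominal - 0.06
    R50_i = 1.029 * I50_i - 0.06 + np.asarray(delta_R50_formula)
    delta_d_ref = 0.6 * (R50_nom - R50_i) + np.asarray(delta_d_set)
    d_ref_nom = 0.6 * R50_nom - 0.1
    return R50_i, delta_d_ref, d_ref_nom


def kprime_r50(R50_i, delta_formula):
    """Cylindrical-chamber electron quality factor with formula perturbation.

    ``k'R50 = [0.9905 + 0.071 exp(-R50/3.67)] (1 + delta_formula)``, the
    analytic expression being valid for 2 <= R50 <= 9 cm (out-of-range
    values are the caller's to flag, not rejected here).
    """
    R50_i = np.asarray(R50_i, dtype=float)
    if np.any(R50_i <= 0):
        raise ValueError("R50 must be positive")
    base = 0.9905 + 0.071 * np.exp(-R50_i / 3.67)
    return base * (1.0 + np.asarray(delta_formula))


def mraw_ensemble_electron(
    delta_d_ref: np.ndarray,
    delta_ssd: np.ndarray,
    geom: ElectronBeamGeometry,
    budget: UncertaintyBudget,
    n: int,
    stream: RandomStream,
    settings: ProtocolSettings,
):
    """Electron raw-reading ensemble at the measurement depth.

    The correlated part converts the chamber displacement to a reading
    error through the local relative DI gradient and adds the SSD
    (virtual-source inverse-square), stability and extracameral terms.
    """
    grad = geom.relative_gradient()
    correlated = (
        grad * delta_d_ref
        - geom.ssd_coeff * delta_ssd
        + _src_draw(budget, "stability", n, stream)
        + _src_draw(budget, "extracameral", n, stream)
    )
    return _reading_ensemble(correlated, budget, n, stream, settings)


def run_electron(
    n: int,
    seed: int,
    budget: UncertaintyBudget,
    geom: ElectronBeamGeometry,
    chamber: ChamberSpec = ChamberSpec(),
    settings: ProtocolSettings = ProtocolSettings(),
) -> ChainResult:
    """Simulate ``n`` electron calibrations; return normalized dose samples."""
    budget.validate()
    if budget.modality != "electron":
        raise ValueError("run_electron requires an electron budget")
    stream = RandomStream(seed)

    # beam quality (shared R50 draw feeds both d_ref and k'R50)
    d_I50 = _src_draw(budget, "I50", n, stream)
    d_R50f = _src_draw(budget, "R50_formula", n, stream)
    d_set = _src_draw(budget, "dset", n, stream)
    R50_i, delta_d_ref, _ = beam_quality_chain(geom.I50_nominal, d_I50, d_R50f, d_set)
    n_r50_flags = int(
        np.count_nonzero((R50_i < R50_VALID_RANGE[0]) | (R50_i > R50_VALID_RANGE[1]))
    )

    kprime_i = kprime_r50(R50_i, _src_draw(budget, "kprime_formula", n, stream))
    kecal_i = sample_calibration_factor(
        chamber.k_ecal_nominal, _src_draw(budget, "kecal", n, stream)
    )

    # environment
    T_i = settings.T0 + _src_draw(budget, "temperature_A", n, stream) \
        + _src_draw(budget, "temperature_B", n, stream)
    p_i = settings.p0 + _src_draw(budget, "pressure", n, stream)
    ptp_i = ptp(T_i, p_i, settings.pressure_unit)

    # readings at d_ref + 0.5 r_cav
    d_ssd = _src_draw(budget, "SSD", n, stream)
    M_raw, M_plus, M_H, M_L = mraw_ensemble_electron(
        delta_d_ref, d_ssd, geom, budget, n, stream, settings
    )
    sign = settings.charge_sign
    pol = ppol(-sign * M_plus, sign * M_raw, sign * M_raw)
    pion_i, n_clamped = pion(
        M_H, M_L, _src_draw(budget, "pion_formula", n, stream), settings
    )
    n_above = int(np.count_nonzero(pion_i > settings.P_ion_bounds[1]))

    p_elec = sample_calibration_factor(
        chamber.P_elec_nominal, _src_draw(budget, "electrometer_calibration", n, stream)
    )
    n_dw = sample_calibration_factor(
        1.0, _src_draw(budget, "chamber_calibration", n, stream)
    )
    humidity = 1.0 + _src_draw(budget, "humidity", n, stream)

    dose = (
        M_raw * pion_i * ptp_i * p_elec * pol * kprime_i * kecal_i * n_dw * humidity
    )
    nominal = (
        1.0
        * settings.P_ion_nominal
        * ptp(settings.T0, settings.p0, settings.pressure_unit)
        * chamber.P_elec_nominal
        * settings.P_pol_nominal
        * float(kprime_r50(geom.R50_nominal, 0.0))
        * chamber.k_ecal_nominal
    )
    return ChainResult(
        samples=dose / nominal,
        n_kq_range_flags=n_r50_flags,
        n_pion_clamped=n_clamped,
        n_pion_above_max=n_above,
        nominal_dose=nominal,
    )
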