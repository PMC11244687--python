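"""Photon chain: k_Q, P_TP, P_pol, P_ion, reading ensemble and full run."""

import numpy as np
import pytest
from scipy import stats

from tg51mc.budget import default_budget, zero_sources
from tg51mc.beam import photon_geometry
from tg51mc.photon import (
    ChamberSpec,
    ProtocolSettings,
    kq,
    pion,
    ppol,
    ptp,
    run_photon,
    sample_calibration_factor,
)
from tg51mc.reporting import summarize
from tg51mc.sampling import DistributionSpec, RandomStream, draw


def _solo(budget, names):
    return zero_sources(budget, set(budget.sources) - set(names))


class TestCalibrationFactor:
    def test_nominal(self):
        assert sample_calibration_factor(1.0, 0.0) == 1.0

    @pytest.mark.parametrize("sigma, expect_pct", [(0.001, 0.1), (0.0075, 0.75)])
    def test_relative_sigma_passthrough(self, sigma, expect_pct):
        r = draw(DistributionSpec("normal", sigma=sigma), 10**5, RandomStream(1), "cal")
        f = sample_calibration_factor(1.0, r)
        assert 100 * f.std(ddof=1) / f.mean() == pytest.approx(expect_pct, rel=0.02)


class TestKq:
    @pytest.mark.parametrize("ddx, expected", [(67.74, 0.98987), (78.85, 0.97094)])
    def test_quadratic_values(self, ddx, expected):
        assert kq(ddx, 0.0, 0.0, ChamberSpec()) == pytest.approx(expected, abs=1e-5)

    def test_out_of_physical_range(self):
        with pytest.raises(ValueError):
            kq(120.0, 0.0, 0.0, ChamberSpec())

    def test_full_sampling_sigma_6mv(self):
        """Scan -> %dd(10) -> k_Q plus intrinsic/fit terms: sigma ~0.40 %."""
        g = photon_geometry("6MV")
        b = default_budget("photon")
        solo = _solo(b, ["depth_scan", "SSD", "field_size", "kQ_intrinsic", "kQ_formula"])
        # isolate k_Q by turning off measurement-side pathways: compare k_Q
        # directly via the chain primitives
        stream = RandomStream(9)
        n = 10**6
        from tg51mc.beam import relative_dd_perturbation

        u = relative_dd_perturbation(
            g,
            draw(solo["depth_scan"].spec, n, stream, "depth_scan"),
            draw(solo["SSD"].spec, n, stream, "SSD"),
            draw(solo["field_size"].spec, n, stream, "field_size"),
        )
        k = kq(
            g.dd10 * (1 + u),
            draw(solo["kQ_intrinsic"].spec, n, stream, "k0"),
            draw(solo["kQ_formula"].spec, n, stream, "kf"),
            ChamberSpec(),
        )
        assert 100 * k.std(ddof=1) / k.mean() == pytest.approx(0.40, abs=0.03)


class TestPtp:
    def test_reference_conditions(self):
        assert ptp(22.0, 760.0, "mmHg") == pytest.approx(1.0)

    def test_closed_form_example(self):
        assert ptp(20.7, 742.8, "mmHg") == pytest.approx(1.01865, abs=2e-5)

    def test_errors(self):
        with pytest.raises(ValueError):
            ptp(20.0, -5.0)
        with pytest.raises(ValueError):
            ptp(80.0, 1000.0)
        with pytest.raises(ValueError):
            ptp(20.0, 1000.0, "psi")

    def test_sampled_sigma(self):
        b = default_budget("photon")
        stream = RandomStream(4)
        n = 10**6
        T = 20.7 + draw(b["temperature_A"].spec, n, stream, "ta") \
            + draw(b["temperature_B"].spec, n, stream, "tb")
        p = 990.1 + draw(b["pressure"].spec, n, stream, "p")
        v = ptp(T, p)
        assert 100 * v.std(ddof=1) / v.mean() == pytest.approx(0.48, abs=0.03)


class TestPion:
    def test_unity_ratio(self):
        P, _ = pion(1.0, 1.0, 0.0, ProtocolSettings())
        assert P == pytest.approx(1.0)

    def test_closed_form(self):
        P, _ = pion(1.00299, 1.0, 0.0, ProtocolSettings(clamp_pion=False))
        assert P == pytest.approx(1.0 / (2.0 - 1.00299), abs=1e-6)

    def test_clamp_to_one(self):
        P, n_clamped = pion(np.array([0.999]), np.array([1.0]), 0.0, ProtocolSettings())
        assert P[0] == 1.0
        assert n_clamped == 1

    def test_singularity(self):
        with pytest.raises(ZeroDivisionError):
            pion(2.0, 1.0, 0.0, ProtocolSettings())

    def test_clamp_point_mass_matches_analytic_tail(self):
        """Weight of the point mass at 1.000 = pre-clamp P(X < 1)."""
        b = _solo(default_budget("photon"), ["pion_formula"])
        res = run_photon(2 * 10**5, 21, b, photon_geometry("6MV"))
        s = ProtocolSettings()
        sigma = b.sigma("pion_formula") * s.P_ion_nominal
        expect = stats.norm.cdf((1.0 - s.P_ion_nominal) / sigma)
        got = res.n_pion_clamped / res.samples.size
        assert got == pytest.approx(expect, abs=0.005)


class TestPpol:
    @pytest.mark.parametrize(
        "mp, mm, m, expected",
        [(10.0, -10.0, -10.0, 1.0), (10.05, -10.0, -10.0, 1.0025)],
    )
    def test_values(self, mp, mm, m, expected):
        assert ppol(mp, mm, m) == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            ppol(1.0, -1.0, 0.0)

    def test_full_sampling_sigma(self):
        """Repeatability-only polarity spread ~0.03 %."""
        # isolate P_pol via its definition: only repeatability spreads the
        # opposite-polarity reading against the reference reading
        b = _solo(default_budget("photon"), ["repeatability"])
        from tg51mc.photon import mraw_ensemble

        stream = RandomStream(13)
        n = 4 * 10**5
        zeros = np.zeros(n)
        M_raw, M_plus, _, _ = mraw_ensemble(
            zeros, zeros, zeros, photon_geometry("6MV"), b, n, stream, ProtocolSettings()
        )
        pol = ppol(M_plus, -M_raw, -M_raw)
        assert 100 * pol.std(ddof=1) == pytest.approx(0.03, abs=0.005)


class TestRunPhoton:
    def test_all_zero_budget_gives_unit_dose(self):
        b = zero_sources(default_budget("photon"), "all")
        res = run_photon(10**4, 0, b, photon_geometry("6MV"))
        assert np.allclose(res.samples, 1.0, atol=1e-12)

    def test_depth_only_sigma(self):
        b = _solo(default_budget("photon"), ["depth_meas"])
        res = run_photon(4 * 10**5, 2, b, photon_geometry("6MV"))
        assert summarize(res.samples).rel_sigma == pytest.approx(0.30, abs=0.02)

    def test_mraw_sigma_about_half_percent(self):
        names = ["depth_meas", "SSD", "field_size", "stability", "extracameral",
                 "repeatability"]
        b = _solo(default_budget("photon"), names)
        from tg51mc.photon import mraw_ensemble
        stream = RandomStream(6)
        n = 4 * 10**5
        M_raw, _, _, _ = mraw_ensemble(
            draw(b["depth_meas"].spec, n, stream, "depth_meas"),
            draw(b["SSD"].spec, n, stream, "SSD"),
            draw(b["field_size"].spec, n, stream, "field_size"),
            photon_geometry("6MV"), b, n, stream, ProtocolSettings(),
        )
        assert 100 * M_raw.std(ddof=1) == pytest.approx(0.5, abs=0.1)

    def test_seed_reproducibility_bit_exact(self):
        b = default_budget("photon")
        a = run_photon(10**4, 99, b, photon_geometry("6MV"))
        c = run_photon(10**4, 99, b, photon_geometry("6MV"))
        assert np.array_equal(a.samples, c.samples)

    def test_increasing_one_sigma_never_decreases_total(self):
        """Monotonicity of the total in each single source's width."""
        base = default_budget("photon")
        g = photon_geometry("6MV")
        for source, widths in [("pressure", [4.0, 8.0, 12.0]),
                               ("depth_meas", [0.05, 0.1, 0.2])]:
            sigmas = []
            for hw in widths:
                b = base.replace_source(source, DistributionSpec("uniform", half_width=hw))
                sigmas.append(summarize(run_photon(10**5, 31, b, g).samples).rel_sigma)
            assert sigmas == sorted(sigmas)

    def test_wrong_modality_budget_rejected(self):
        with pytest.raises(ValueError):
            run_photon(100, 0, default_budget("electron"), photon_geometry("6MV"))
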