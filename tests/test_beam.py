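"""Beam sensitivities, curve handling and synthetic curve generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tg51mc.beam import (
    DepthIonizationCurve,
    ElectronBeamGeometry,
    PhotonBeamGeometry,
    electron_geometry,
    fit_photon_depth_coefficient,
    interim_ddx,
    local_relative_gradient,
    photon_geometry,
    read_curve_csv,
    relative_dd_perturbation,
    shift_curve,
    synth_curves,
    write_curve_csv,
)
from tg51mc.sampling import DistributionSpec, RandomStream, draw


class TestRelativeDdPerturbation:
    def test_zero_perturbations(self):
        assert relative_dd_perturbation(photon_geometry("6MV"), 0, 0, 0) == 0

    def test_depth_coefficient_6mv(self):
        # -0.032 / cm: a 1 mm depth error moves %dd(10) by 0.32 % relative
        val = relative_dd_perturbation(photon_geometry("6MV"), 0.1, 0.0, 0.0)
        assert val == pytest.approx(-0.0032, rel=1e-12)

    def test_propagated_dd10_sigma(self):
        """Uniform +/-1 mm depth, +/-2 mm SSD and field -> sigma ~0.22 %."""
        g = photon_geometry("6MV")
        stream = RandomStream(5)
        n = 10**6
        dd = draw(DistributionSpec("uniform", half_width=0.1), n, stream, "d")
        ds = draw(DistributionSpec("uniform", half_width=0.2), n, stream, "s")
        df = draw(DistributionSpec("uniform", half_width=0.2), n, stream, "f")
        u = relative_dd_perturbation(g, dd, ds, df)
        assert 100 * u.std(ddof=1) == pytest.approx(0.22, abs=0.01)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=-3, max_value=3, allow_nan=False),
        dd=st.floats(min_value=-0.2, max_value=0.2, allow_nan=False),
        dssd=st.floats(min_value=-0.3, max_value=0.3, allow_nan=False),
        df=st.floats(min_value=-0.3, max_value=0.3, allow_nan=False),
    )
    def test_first_order_expansion_is_exactly_linear(self, a, dd, dssd, df):
        g = photon_geometry("6MV")
        f1 = relative_dd_perturbation(g, a * dd, a * dssd, a * df)
        f0 = relative_dd_perturbation(g, dd, dssd, df)
        assert f1 == pytest.approx(a * f0, abs=1e-15)


class TestInterimDdx:
    @pytest.mark.parametrize(
        "dd10, delta, expected",
        [(78.02, 0.0, 78.85), (70.0, 0.0, 68.69), (70.0, 2.0, 70.69)],
    )
    def test_values(self, dd10, delta, expected):
        assert interim_ddx(dd10, delta) == pytest.approx(expected, abs=0.005)

    def test_mc_sigma_matches_quadrature(self):
        """Affine chain: MC sigma equals first-order quadrature exactly."""
        stream = RandomStream(11)
        n = 10**6
        sigma_dd = 0.15  # absolute %-points spread fed into the formula
        dd = 70.0 + draw(DistributionSpec("normal", sigma=sigma_dd), n, stream, "dd")
        delta = draw(DistributionSpec("uniform", half_width=2.0), n, stream, "i")
        ddx = interim_ddx(dd, delta)
        expect = math.hypot(1.267 * sigma_dd, 2.0 / math.sqrt(3))
        assert ddx.std(ddof=1) == pytest.approx(expect, rel=0.01)


class TestCurves:
    def _cubic_curve(self):
        d = np.linspace(4.0, 8.0, 41)
        v = 80.0 + 1.5 * (d - 6) - 0.8 * (d - 6) ** 2 + 0.1 * (d - 6) ** 3
        return DepthIonizationCurve(depths=d, values=v)

    def test_shift_accumulates_and_preserves_values(self):
        c = self._cubic_curve()
        s0 = shift_curve(c, 0.0)
        assert np.array_equal(s0.depths, c.depths)
        s = shift_curve(shift_curve(c, 0.15), 0.15)
        assert s.shift_applied == pytest.approx(0.30)
        assert np.allclose(s.depths, c.depths - 0.30)
        with pytest.raises(ValueError):
            shift_curve(c, -0.1)

    def test_cubic_gradient_recovered_to_machine_precision(self):
        c = self._cubic_curve()
        at = 6.0
        # normalization to max=100 rescales values but not the relative gradient
        analytic = 1.5 / 80.0
        got = local_relative_gradient(c, at, window=1.0)
        assert got == pytest.approx(analytic, rel=1e-6)

    def test_constant_curve_zero_gradient(self):
        c = DepthIonizationCurve(depths=np.linspace(0, 5, 20), values=np.full(20, 7.0))
        assert local_relative_gradient(c, 2.5, window=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_points_raises(self):
        c = self._cubic_curve()
        with pytest.raises(ValueError, match="4 curve points"):
            local_relative_gradient(c, 6.0, window=0.11)

    def test_validation(self):
        with pytest.raises(ValueError):
            DepthIonizationCurve(depths=np.array([1, 2, 3]), values=np.array([1, 2, 3]))
        d = np.linspace(0, 5, 10)
        with pytest.raises(ValueError):
            DepthIonizationCurve(depths=d[::-1], values=np.ones(10))

    def test_csv_round_trip(self, tmp_path):
        c = self._cubic_curve()
        path = tmp_path / "curve.csv"
        write_curve_csv(c, path)
        back = read_curve_csv(path)
        assert np.allclose(back.depths, c.depths)
        assert np.allclose(back.values, c.values)


class TestSyntheticCurves:
    def test_photon_6mv_dd10_pinned(self):
        c = synth_curves("photon_6MV")
        assert c.value_at(10.0) == pytest.approx(67.74, abs=0.1)

    def test_photon_6mv_depth_coefficient_recovered(self):
        c = synth_curves("photon_6MV")
        coeff = fit_photon_depth_coefficient(c, SSD=100.0, d=10.0, d_m=1.5)
        assert coeff == pytest.approx(-0.032, rel=0.05)

    def test_geometry_from_curve_matches_pinned_geometry(self):
        g = PhotonBeamGeometry.from_curve(synth_curves("photon_6MV"))
        ref = photon_geometry("6MV")
        assert g.dd10 == pytest.approx(ref.dd10, abs=0.1)
        assert g.scan_depth_coeff == pytest.approx(ref.scan_depth_coeff, rel=0.05)
        assert g.scan_ssd_coeff == pytest.approx(ref.scan_ssd_coeff, rel=0.05)

    def test_electron_6mev_gradient_near_0p8_pct_per_mm(self):
        g = electron_geometry("6MeV")
        grad = g.relative_gradient()
        assert -0.10 <= grad <= -0.06

    def test_electron_curve_i50_consistent(self):
        c = synth_curves("electron_6MeV")
        # depth of 50 % ionization on the generated curve equals the nominal I50
        d50 = np.interp(50.0, c.values[np.argmax(c.values):][::-1],
                        c.depths[np.argmax(c.values):][::-1])
        assert d50 == pytest.approx(2.40, abs=0.02)

    def test_18mev_to_6mev_gradient_ratio_about_half(self):
        r = (electron_geometry("18MeV").relative_gradient()
             / electron_geometry("6MeV").relative_gradient())
        assert r == pytest.approx(0.5, abs=0.15)

    def test_unknown_profile(self):
        with pytest.raises(ValueError):
            synth_curves("proton_200MeV")


class TestGeometries:
    def test_photon_18mv_nominal_ddx(self):
        g = photon_geometry("18MV")
        assert g.use_interim
        assert g.dd10x == pytest.approx(78.85, abs=0.01)

    def test_photon_measurement_coefficients(self):
        g = photon_geometry("6MV")
        assert g.meas_ssd_coeff == pytest.approx(-2.0 / 110.0)
        assert g.meas_depth_coeff == pytest.approx(-0.032 - 2.0 / 101.5)

    def test_kq_validity_guard(self):
        with pytest.raises(ValueError, match="validity"):
            PhotonBeamGeometry(dd10=60.0)

    def test_electron_reference_depths(self):
        g = electron_geometry("6MeV")
        assert g.R50_nominal == pytest.approx(2.4096)
        assert g.d_ref == pytest.approx(1.3458, abs=1e-4)
        assert g.meas_depth == pytest.approx(1.3458 + 0.15, abs=1e-4)

    def test_electron_i50_range_guard(self):
        with pytest.raises(ValueError):
            ElectronBeamGeometry(I50_nominal=1.0, gradient_override=-0.1)
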