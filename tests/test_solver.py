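"""Exact piecewise pipe-flow solutions: profiles, flow rate, averages, inverse solve."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nozzleflow as nf
from nozzleflow.solver import interval_radii
from nozzleflow.viscosity import PiecewisePowerLaw

GEO = nf.ChannelGeometry(radius=1e-3, length=10e-3)


def hagen_poiseuille_u(eta, A, G, r):
    return -G * (A * A - r * r) / (4.0 * eta)


class TestIntervalRadii:
    def test_newtonian_closed_form(self):
        # unit-viscosity segments with a node at 2 1/s: R = 2*1*2/4000 = 1e-3 m
        pw = PiecewisePowerLaw(
            bounds=np.array([1.0, 2.0, 4.0]),
            log_K=np.zeros(2),
            n=np.ones(2),
        )
        R = interval_radii(pw, -4000.0)
        assert R[1] == pytest.approx(1e-3, rel=1e-14)

    def test_radii_strictly_increasing(self, chitosan):
        pw = nf.interpolate_piecewise(chitosan, nf.ShearRateGrid(1e-6, 1e8, 200))
        R = interval_radii(pw, -7.0e7)
        assert np.all(np.diff(R) > 0)

    def test_simplified_cy_node_radius(self, simplified_fluid):
        # R at the node Gamma = 1 1/s equals 2*eta(1)*1/(-G) since K*Gamma**n
        # = eta(Gamma)*Gamma there.
        # 700 intervals over 14 decades puts a node exactly at 1 1/s
        grid = nf.ShearRateGrid(1e-6, 1e8, 700)
        pw = nf.interpolate_piecewise(simplified_fluid, grid)
        G = -1.95e6
        j = int(np.argmin(np.abs(pw.bounds - 1.0)))
        assert pw.bounds[j] == pytest.approx(1.0, rel=1e-9)  # node lands on 1
        R = interval_radii(pw, G)
        expected = 2.0 * 50.0 * 1.0 / (-G)
        assert R[j] == pytest.approx(expected, rel=1e-9)

    def test_positive_gradient_rejected(self, simplified_fluid):
        pw = nf.interpolate_piecewise(simplified_fluid)
        with pytest.raises(nf.SignConventionError):
            interval_radii(pw, 4000.0)


class TestClosedFormLimits:
    def test_hagen_poiseuille_profile_and_flow_rate(self):
        sol = nf.solve_pressure_driven(nf.Newtonian(1.0), GEO, -4000.0)
        r = np.linspace(0.0, GEO.radius, 101)
        u_exact = hagen_poiseuille_u(1.0, GEO.radius, -4000.0, r)
        assert np.max(np.abs(sol.velocity(r) - u_exact)) <= 1e-10 * u_exact[0]
        assert sol.max_velocity() == pytest.approx(1.0e-3, rel=1e-10)
        Q_exact = math.pi * 4000.0 * GEO.radius**4 / 8.0
        assert sol.flow_rate() == pytest.approx(Q_exact, rel=1e-10)
        av = sol.averages()
        assert av.u_avg / av.u_max == pytest.approx(0.5, rel=1e-10)
        assert av.gammadot_avg == pytest.approx(2.0 / 3.0 * sol.wall_shear_rate, rel=1e-10)
        assert av.eta_avg == pytest.approx(1.0, rel=1e-10)

    def test_power_law_profile_and_flow_rate(self):
        K, n = 1.0, 0.5
        sol = nf.solve_pressure_driven(nf.PowerLaw(K, n), GEO, -2000.0)
        A = GEO.radius
        c = (2000.0 / (2 * K)) ** (1 / n)
        u0_exact = c * n / (n + 1) * A ** (1 + 1 / n)
        assert sol.max_velocity() == pytest.approx(u0_exact, rel=1e-10)
        assert sol.max_velocity() == pytest.approx(3.3333333333e-4, rel=1e-9)
        Q_exact = math.pi * n / (3 * n + 1) * c * A ** (3 + 1 / n)
        assert sol.flow_rate() == pytest.approx(Q_exact, rel=1e-10)
        assert sol.flow_rate() == pytest.approx(6.283185307e-10, rel=1e-9)
        r = np.linspace(0, A, 51)
        u_exact = c * n / (n + 1) * (A ** (1 + 1 / n) - r ** (1 + 1 / n))
        assert np.max(np.abs(sol.velocity(r) - u_exact)) <= 1e-10 * u0_exact

    def test_zero_gradient_gives_quiescent_fluid(self, simplified_fluid):
        sol = nf.solve_pressure_driven(simplified_fluid, GEO, 0.0)
        r = np.linspace(0, GEO.radius, 5)
        assert np.all(sol.velocity(r) == 0.0)
        assert np.all(sol.shear_rate(r) == 0.0)
        assert sol.flow_rate() == 0.0

    def test_positive_gradient_rejected(self, simplified_fluid):
        with pytest.raises(nf.SignConventionError):
            nf.solve_pressure_driven(simplified_fluid, GEO, 4000.0)


# stress bound of the simplified law (eta_0/K = 1e4 Pa) stays above the
# wall stress -GA/2 = 3500 Pa used in these invariant checks
MODELS = [
    nf.Newtonian(2.0),
    nf.PowerLaw(1.5, 0.6),
    nf.SimplifiedCarreauYasuda(100.0, 0.01),
    nf.CarreauYasuda3(6.8, 27.9, 0.78),
    nf.CarreauYasuda5(0.0, 5807.0, 5.33, 1.35, 0.87),
]


class TestSolutionInvariants:
    @pytest.mark.parametrize("model", MODELS, ids=lambda m: type(m).__name__)
    def test_no_slip_and_monotone_velocity(self, model, nozzle_100um):
        sol = nf.solve_pressure_driven(model, nozzle_100um, -7.0e7)
        A = nozzle_100um.radius
        u0 = sol.max_velocity()
        assert abs(sol.velocity(A)) <= 1e-12 * u0
        r = np.linspace(0, A, 400)
        assert np.all(np.diff(sol.velocity(r)) < 0)

    @pytest.mark.parametrize("model", MODELS, ids=lambda m: type(m).__name__)
    def test_stress_profile_linear_and_material_independent(self, model, nozzle_100um):
        G = -7.0e7
        sol = nf.solve_pressure_driven(model, nozzle_100um, G)
        r = np.linspace(0, nozzle_100um.radius, 97)
        sigma = sol.stress(r)
        assert np.max(np.abs(sigma + G * r / 2.0)) <= 1e-12 * (-G) * nozzle_100um.radius / 2
        assert sol.averages().sigma_avg == pytest.approx(-G * nozzle_100um.radius / 3, rel=1e-12)

    def test_wall_stress_chitosan(self, chitosan, nozzle_100um):
        sol = nf.solve_pressure_driven(chitosan, nozzle_100um, -7.0e7)
        assert sol.wall_shear_stress == pytest.approx(3500.0, rel=1e-15)

    def test_velocity_and_shear_rate_continuous_across_shells(self, chitosan, nozzle_100um):
        sol = nf.solve_pressure_driven(
            chitosan, nozzle_100um, -7.0e7, grid=nf.ShearRateGrid(1e-6, 1e8, 300)
        )
        u0 = sol.max_velocity()
        for i, R in enumerate(sol.interval_radii):
            left = sol._u_interval(R, i)
            right = sol._u_interval(R, i + 1)
            assert abs(left - right) <= 1e-12 * u0
            # shear rate at R_i equals the grid node by construction
            node = sol.pw.bounds[i + 1]
            assert sol.shear_rate(R) == pytest.approx(node, rel=1e-12)

    def test_flow_rate_two_routes_agree(self, chitosan, nozzle_100um):
        sol = nf.solve_pressure_driven(chitosan, nozzle_100um, -7.0e7)
        Q1 = sol.flow_rate()
        Q2 = sol._flow_rate_velocity_route()
        assert Q2 == pytest.approx(Q1, rel=1e-10)

    def test_flow_rate_increases_with_gradient(self, alginate_cy3, needle):
        pw = nf.interpolate_piecewise(alginate_cy3, nf.DEFAULT_FIT_GRID)
        Gs = -np.geomspace(1e4, 1e7, 12)
        Qs = [nf.solve_pressure_driven(pw, needle, G).flow_rate() for G in Gs]
        assert np.all(np.diff(Qs) > 0)

    @given(
        eta_0=st.floats(1.0, 1e3),
        gammadot_c=st.floats(1.0, 100.0),
        alpha=st.floats(0.4, 0.95),
        logG=st.floats(5.0, 8.5),
    )
    def test_stress_law_random_cy3(self, eta_0, gammadot_c, alpha, logG):
        """sigma(r) = -G r/2 regardless of material parameters."""
        model = nf.CarreauYasuda3(eta_0, gammadot_c, alpha)
        G = -(10.0**logG)
        geo = nf.ChannelGeometry(100e-6, 10e-3)
        sol = nf.solve_pressure_driven(model, geo, G, grid=nf.ShearRateGrid(1e-6, 1e9, 150))
        r = np.linspace(0, geo.radius, 11)
        assert np.max(np.abs(sol.stress(r) + G * r / 2)) <= 1e-12 * (-G) * geo.radius / 2


class TestGridExhaustion:
    def test_exhaustion_raises_with_hint(self, alginate_cy3, needle):
        with pytest.raises(nf.GridExhaustedError, match="gammadot_max"):
            nf.solve_pressure_driven(
                alginate_cy3, needle, -200e3 / needle.length,
                grid=nf.ShearRateGrid(1e-6, 1e2, 100),
            )

    def test_auto_extend_recovers(self, alginate_cy3, needle):
        sol = nf.solve_pressure_driven(
            alginate_cy3, needle, -200e3 / needle.length,
            grid=nf.ShearRateGrid(1e-6, 1e2, 100), auto_extend=True,
        )
        ref = nf.solve_pressure_driven(alginate_cy3, needle, -200e3 / needle.length)
        assert sol.flow_rate() == pytest.approx(ref.flow_rate(), rel=1e-3)


class TestFlowDriven:
    def test_newtonian_inverts_hagen_poiseuille(self):
        Q = math.pi * 4000.0 * GEO.radius**4 / 8.0
        sol = nf.solve_flow_driven(nf.Newtonian(1.0), GEO, Q)
        assert sol.G == pytest.approx(-4000.0, rel=1e-8)

    def test_zero_flow_rate(self, simplified_fluid):
        sol = nf.solve_flow_driven(simplified_fluid, GEO, 0.0)
        assert sol.G == 0.0
        assert sol.flow_rate() == 0.0

    def test_chitosan_round_trip(self, chitosan, nozzle_100um):
        G0 = -7.0e7
        Q = nf.solve_pressure_driven(chitosan, nozzle_100um, G0).flow_rate()
        sol = nf.solve_flow_driven(chitosan, nozzle_100um, Q)
        assert sol.G == pytest.approx(G0, rel=1e-6)

    def test_negative_flow_rate_rejected(self, simplified_fluid):
        with pytest.raises(ValueError):
            nf.solve_flow_driven(simplified_fluid, GEO, -1e-9)


class TestProfileTable:
    def test_two_point_table(self, simplified_fluid, nozzle_100um):
        sol = nf.solve_pressure_driven(simplified_fluid, nozzle_100um, -1.95e6)
        df = sol.sample_profile(2)
        assert df["r_m"].iloc[0] == 0.0
        assert df["r_m"].iloc[-1] == nozzle_100um.radius
        assert df["u_m_per_s"].iloc[-1] == pytest.approx(0.0, abs=1e-15)

    def test_rows_satisfy_stress_law_and_closed_form(self):
        sol = nf.solve_pressure_driven(nf.Newtonian(1.0), GEO, -4000.0)
        df = sol.sample_profile(50)
        r = df["r_m"].to_numpy()
        assert np.allclose(df["shear_stress_Pa"], 2000.0 * r, rtol=1e-14)
        assert np.allclose(
            df["u_m_per_s"], hagen_poiseuille_u(1.0, GEO.radius, -4000.0, r), rtol=1e-10
        )

    def test_interior_radii_included(self, chitosan, nozzle_100um):
        sol = nf.solve_pressure_driven(
            chitosan, nozzle_100um, -7.0e7, grid=nf.ShearRateGrid(1e-6, 1e8, 100)
        )
        df = sol.sample_profile(10)
        interior = sol.interval_radii[sol.interval_radii < nozzle_100um.radius]
        assert np.all(np.isin(np.round(interior, 20), np.round(df["r_m"].to_numpy(), 20)))

    def test_too_few_points_rejected(self, simplified_fluid, nozzle_100um):
        sol = nf.solve_pressure_driven(simplified_fluid, nozzle_100um, -1.95e6)
        with pytest.raises(ValueError):
            sol.sample_profile(1)

    def test_csv_round_trip_lossless(self, tmp_path, simplified_fluid, nozzle_100um):
        import pandas as pd

        sol = nf.solve_pressure_driven(simplified_fluid, nozzle_100um, -1.95e6)
        path = tmp_path / "profile.csv"
        sol.write_profile_csv(path, n_points=20)
        back = pd.read_csv(path, comment="#", float_precision="round_trip")
        df = sol.sample_profile(20)
        for col in df.columns:
            assert np.allclose(back[col], df[col], rtol=1e-15, atol=0)

    def test_stress_out_of_range_rejected(self, simplified_fluid, nozzle_100um):
        sol = nf.solve_pressure_driven(simplified_fluid, nozzle_100um, -1.95e6)
        with pytest.raises(ValueError, match="outside"):
            sol.stress(2 * nozzle_100um.radius)
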