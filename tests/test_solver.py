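"""Steady-state diffusion solver: oracles, conservation, and monotonicity."""

import numpy as np
import pytest

import gradientforge as gf
from gradientforge.geometry import UnitCellGrid
from gradientforge.solver import PROFILE_Z_UM

CONST = gf.PhysicalConstants()

INERT = gf.CatalystKinetics(
    name="inert",
    channels=(gf.ORRChannel(i0=0.0, n_rds=1.0, n_stoich=4),),
    dD=20.0,
)


class TestSolveO2:
    def test_inert_electrode_keeps_bulk_everywhere(self):
        grid = gf.build_grid(gf.Morphology(30, 3, 50), INERT, spacing=2.0)
        field = gf.solve_o2(grid, INERT, 0.5)
        assert np.allclose(field.values, CONST.C_O2_bulk, rtol=1e-12)

    def test_planar_limit_matches_1d_closed_form(self, pt_kin):
        # a vanishing wire over an active base approximates a flat active
        # plane at z = 0 below a Dirichlet plane at z = z_bulk: the 1D
        # solution is linear with c(0) = C * D / (D + k * z_bulk)
        kin = gf.CatalystKinetics(name="pt-planar", channels=pt_kin.channels, dD=30.0)
        morph = gf.Morphology(30, 0.2, 1)
        grid = gf.build_grid(morph, kin, spacing=0.5, include_base=True)
        field = gf.solve_o2(grid, kin, 0.5)
        profile = gf.extract_profile(field)

        k_o2, _ = gf.effective_rate_constants(kin, gf.overpotential(0.5), CONST)
        z_bulk_m = grid.z_bulk_um * 1e-6
        c0 = CONST.C_O2_bulk * CONST.D_O2 / (CONST.D_O2 + k_o2 * z_bulk_m)
        for z, c in zip(profile.z_um, profile.c_mM):
            expected = (CONST.C_O2_bulk if z >= grid.z_bulk_um
                        else c0 + (CONST.C_O2_bulk - c0) * z / grid.z_bulk_um)
            assert c == pytest.approx(expected, rel=5e-3)

    def test_deep_depletion_inside_dense_array(self, pt_kin):
        # dense long wires at reductive potential strip the base of oxygen
        o2, _ = gf.simulate(gf.Morphology(15, 4, 50), pt_kin, 0.5,
                            gf.SolverSettings(spacing_um=1.0))
        assert o2.c_mM[0] < 0.05

    def test_maximum_principle_on_random_conditions(self, au_kin, coarse_settings):
        for s in gf.sample_conditions(8, seed=42):
            o2, h2o2 = gf.simulate(s.morph, au_kin, s.E_appl, coarse_settings)
            assert np.all(o2.c_mM >= -1e-15)
            assert np.all(o2.c_mM <= CONST.C_O2_bulk * (1 + 1e-12))
            assert np.all(h2o2.c_mM >= -1e-15)

    def test_flux_conservation_at_steady_state(self, pt_kin, au_kin):
        for kin, e in ((pt_kin, 0.5), (au_kin, 0.45)):
            grid = gf.build_grid(gf.Morphology(17, 3, 30), kin, spacing=1.0)
            o2 = gf.solve_o2(grid, kin, e)
            influx, consumed = gf.flux_balance(o2)
            assert influx == pytest.approx(consumed, rel=5e-3)
            h2o2 = gf.solve_h2o2(grid, kin, e, o2)
            if kin.has_peroxide_channel:
                efflux, produced = gf.flux_balance(h2o2)
                assert -efflux == pytest.approx(produced, rel=5e-3)

    def test_depletion_monotone_in_applied_potential(self, pt_kin, coarse_settings):
        profiles = [gf.simulate(gf.Morphology(30, 3, 50), pt_kin, e, coarse_settings)[0]
                    for e in (0.6, 0.5, 0.4, 0.3, 0.2)]
        for higher, lower in zip(profiles, profiles[1:]):
            sub_bulk = higher.c_mM < CONST.C_O2_bulk
            assert np.all(lower.c_mM[sub_bulk] < higher.c_mM[sub_bulk])

    def test_depletion_monotone_in_geometry(self, pt_kin, coarse_settings):
        base = gf.simulate(gf.Morphology(30, 3, 30), pt_kin, 0.5, coarse_settings)[0]
        longer = gf.simulate(gf.Morphology(30, 3, 50), pt_kin, 0.5, coarse_settings)[0]
        denser = gf.simulate(gf.Morphology(15, 3, 30), pt_kin, 0.5, coarse_settings)[0]
        assert longer.c_mM[0] < base.c_mM[0]
        assert denser.c_mM[0] < base.c_mM[0]


class TestSolveH2O2:
    def test_pt_yields_identically_zero_field(self, pt_kin):
        grid = gf.build_grid(gf.Morphology(30, 3, 50), pt_kin, spacing=2.0)
        o2 = gf.solve_o2(grid, pt_kin, 0.5)
        h2o2 = gf.solve_h2o2(grid, pt_kin, 0.5, o2)
        assert np.all(h2o2.values == 0.0)

    def test_field_linear_in_generation_rate(self, au_kin):
        # doubling the 2e- exchange current doubles k_gen; against a fixed O2
        # field the H2O2 solution must double exactly (linear system)
        grid = gf.build_grid(gf.Morphology(17, 3, 30), au_kin, spacing=2.0)
        o2 = gf.solve_o2(grid, au_kin, 0.45)
        ch4, ch2 = au_kin.channels
        doubled = gf.CatalystKinetics(
            name="au2x",
            channels=(ch4, gf.ORRChannel(2 * ch2.i0, ch2.n_rds, ch2.n_stoich, ch2.alpha_c)),
            dD=au_kin.dD,
        )
        f1 = gf.solve_h2o2(grid, au_kin, 0.45, o2)
        f2 = gf.solve_h2o2(grid, doubled, 0.45, o2)
        assert np.allclose(f2.values, 2.0 * f1.values, rtol=1e-9)

    def test_weak_depletion_scaling_with_overpotential(self, au_kin):
        # sparse short wires barely deplete O2, so the H2O2 field scales as
        # the Tafel factor of the 2e- channel between two potentials
        morph = gf.Morphology(40, 2, 10)
        grid = gf.build_grid(morph, au_kin, spacing=1.0)
        fields = {}
        for e in (1.23, 0.5):
            o2 = gf.solve_o2(grid, au_kin, e, window=None)
            fields[e] = gf.solve_h2o2(grid, au_kin, e, o2, window=None)
        ch2 = au_kin.channels[1]
        expected = np.exp(-ch2.alpha_c * CONST.F * (1.23 - 0.5 - 0.0)
                          * ch2.n_rds / (CONST.R * CONST.T))
        ratio = fields[1.23].values.max() / fields[0.5].values.max()
        assert ratio == pytest.approx(expected, rel=0.03)

    def test_grid_mismatch_rejected(self, au_kin):
        g1 = gf.build_grid(gf.Morphology(17, 3, 30), au_kin, spacing=2.0)
        g2 = gf.build_grid(gf.Morphology(17, 3, 30), au_kin, spacing=2.0)
        o2 = gf.solve_o2(g1, au_kin, 0.45)
        with pytest.raises(ValueError, match="grid"):
            gf.solve_h2o2(g2, au_kin, 0.45, o2)


class TestExtractProfile:
    def test_uniform_field_reports_uniform_profile(self):
        grid = gf.build_grid(gf.Morphology(30, 3, 50), INERT, spacing=2.0)
        field = gf.solve_o2(grid, INERT, 0.5)
        profile = gf.extract_profile(field)
        assert np.allclose(profile.c_mM, 0.246, rtol=1e-12)

    def test_ladder_is_twenty_points_every_5_um(self):
        assert len(PROFILE_Z_UM) == 20
        assert PROFILE_Z_UM[0] == 5.0 and PROFILE_Z_UM[-1] == 100.0
        assert np.all(np.diff(PROFILE_Z_UM) == 5.0)

    def test_area_weighted_mean_toy_cross_section(self):
        # two cells of areas (1, 3) with values (0.1, 0.2): mean = 0.175
        grid = UnitCellGrid(
            mode="axisym", morphology=gf.Morphology(10, 1, 10),
            include_base=True, height_um=200.0, z_bulk_um=200.0, spacing_um=1.0,
            n_fluid=2,
            layer_z_um=np.array([10.0]),
            cell_layer=np.array([0, 0]),
            cell_xsarea=np.array([1.0, 3.0]),
        )
        field = gf.ConcentrationField(
            species="O2", values=np.array([0.1, 0.2]), grid=grid,
            condition={}, dirichlet_value=0.246,
        )
        profile = gf.extract_profile(field)
        assert profile.c_mM[0] == pytest.approx(0.175)  # z = 5, clamped to layer
        assert profile.c_mM[1] == pytest.approx(0.175)  # z = 10, on the layer

    def test_heights_above_bulk_plane_report_dirichlet_value(self, pt_kin):
        o2, h2o2 = gf.simulate(gf.Morphology(17, 3, 30), gf.load_catalyst("au"), 0.45,
                               gf.SolverSettings(spacing_um=2.0))
        above = PROFILE_Z_UM >= 80.0  # z_bulk = L + dD = 80 um
        assert np.allclose(o2.c_mM[above], 0.246)
        assert np.allclose(h2o2.c_mM[above], 0.0)


class TestSimulate:
    def test_repeat_runs_are_bit_identical(self, pt_kin, coarse_settings):
        a = gf.simulate(gf.Morphology(30, 3, 50), pt_kin, 0.5, coarse_settings)
        b = gf.simulate(gf.Morphology(30, 3, 50), pt_kin, 0.5, coarse_settings)
        assert np.array_equal(a[0].c_mM, b[0].c_mM)
        assert np.array_equal(a[1].c_mM, b[1].c_mM)

    def test_out_of_window_potential_rejected(self, pt_kin):
        with pytest.raises(ValueError, match=r"\[0.2, 0.6\]"):
            gf.simulate(gf.Morphology(30, 3, 50), pt_kin, 0.8)

    def test_refinement_convergence(self, pt_kin):
        coarse = gf.simulate(gf.Morphology(30, 3, 50), pt_kin, 0.5,
                             gf.SolverSettings(spacing_um=1.0))[0]
        fine = gf.simulate(gf.Morphology(30, 3, 50), pt_kin, 0.5,
                           gf.SolverSettings(spacing_um=0.5))[0]
        assert np.all(np.abs(coarse.c_mM - fine.c_mM) / fine.c_mM < 0.02)

    def test_axisymmetric_agrees_with_cartesian3d(self, pt_kin):
        axi = gf.simulate(gf.Morphology(15, 4, 50), pt_kin, 0.5,
                          gf.SolverSettings(mode="axisym", spacing_um=1.0))[0]
        full = gf.simulate(gf.Morphology(15, 4, 50), pt_kin, 0.5,
                           gf.SolverSettings(mode="cartesian3d", spacing_um=1.0))[0]
        assert np.all(np.abs(axi.c_mM - full.c_mM)
                      / np.maximum(full.c_mM, 0.05 * CONST.C_O2_bulk) < 0.05)
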