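import numpy as np
import pytest

from epfem import (
    ConductivityModel,
    GeometryConfig,
    SAConfig,
    SolverSettings,
    build_plate_model,
    isotropic_tissue,
    iv_sweep,
    single_tissue_registry,
    slab_current,
    solve_fixed_sigma,
    solve_npa,
    solve_sa,
)
from epfem.metrics import r_squared
from epfem.solvers import SolverNonConvergence, baseline_sigma_elem, sa_currents


@pytest.fixture(scope="module")
def linear_plate(small_plate=None):
    cfg = GeometryConfig(case="plate_single", gap_mm=10.0, width_mm=10.0,
                         height_mm=10.0, resolution_mm=2.5)
    mesh = build_plate_model(cfg)
    model = ConductivityModel("linear", sigma0=0.05, k_sigma=1e-4)
    return mesh, single_tissue_registry("liver", model)


def closed_form_linear(U, sigma0=0.05, k=1e-4, d_cm=1.0, area_m2=1e-4):
    e_vcm = U / d_cm
    return (sigma0 + k * e_vcm) * (e_vcm * 100.0) * area_m2


class TestNPA:
    def test_uniform_field_linear_sigma_exact(self, linear_plate):
        """Field is U/d regardless of sigma, so I has a closed form."""
        mesh, registry = linear_plate
        for U in (50.0, 300.0, 900.0):
            sol = solve_npa(mesh, registry, U)
            assert sol.I == pytest.approx(closed_form_linear(U), rel=1e-8)

    def test_constant_model_reduces_to_linear_solve(self, small_plate):
        registry = single_tissue_registry(
            "liver", ConductivityModel("constant", sigma0=0.1)
        )
        a = solve_npa(small_plate, registry, 123.0)
        b = solve_fixed_sigma(small_plate, np.full(small_plate.n_elements, 0.1), 123.0)
        assert a.I == pytest.approx(b.I, rel=1e-10)

    def test_heaviside_slab_matches_1d_oracle(self, slab_mesh_registry,
                                              slab_layers):
        mesh, registry = slab_mesh_registry
        settings = SolverSettings()
        for U in (150.0, 250.0, 400.0):
            oracle = slab_current(slab_layers, 1.0, U)
            sol = solve_npa(mesh, registry, U, settings)
            assert sol.I == pytest.approx(oracle, rel=0.01)

    def test_picard_and_newton_agree_at_convergence(self):
        """Lagged-conductivity iteration and the consistent-tangent Newton
        land on the same fixed point (mild two-layer step nonlinearity;
        Picard contracts too slowly to be practical on steep laws)."""
        a = ConductivityModel("heaviside", sigma0=0.1, factor=1.5,
                              E_rev=200.0, E_irrev=600.0)
        b = ConductivityModel("constant", sigma0=0.3)
        cfg = GeometryConfig(case="plate_single", gap_mm=4.0, width_mm=8.0,
                             height_mm=8.0, resolution_mm=1.0,
                             layers=(("a", 1.0), ("b", 3.0)))
        mesh = build_plate_model(cfg)
        registry = single_tissue_registry("a", a)
        registry.register(isotropic_tissue("b", b))
        U = 200.0
        newton = solve_npa(mesh, registry, U, SolverSettings(scheme="full_newton"))
        picard = solve_npa(mesh, registry, U, SolverSettings(scheme="picard"))
        assert picard.I == pytest.approx(newton.I, rel=1e-6)

    def test_fixed_point_consistency(self, slab_mesh_registry):
        """Re-solving with the converged field's conductivity barely moves I."""
        mesh, registry = slab_mesh_registry
        settings = SolverSettings()
        sol = solve_npa(mesh, registry, 250.0, settings)
        from epfem.solvers import evaluate_sigma_elem

        resolved = solve_fixed_sigma(
            mesh, evaluate_sigma_elem(mesh, registry, sol.E), 250.0
        )
        assert resolved.I == pytest.approx(sol.I, rel=10 * settings.newton_tol)

    def test_negative_voltage_rejected(self, linear_plate):
        mesh, registry = linear_plate
        with pytest.raises(ValueError):
            solve_npa(mesh, registry, -5.0)


class TestIVSweep:
    def test_constant_sigma_curve_is_linear(self, small_plate):
        registry = single_tissue_registry(
            "liver", ConductivityModel("constant", sigma0=0.1)
        )
        curve = iv_sweep(small_plate, registry, np.linspace(50, 500, 6))
        fit = np.polyfit(curve.U, curve.I, 1)
        assert r_squared(curve.I, np.polyval(fit, curve.U)).r2 == pytest.approx(1.0)
        assert abs(fit[1]) < 1e-10  # zero intercept

    def test_conductance_nondecreasing_for_sigma_e(self, slab_mesh_registry):
        mesh, registry = slab_mesh_registry
        curve = iv_sweep(mesh, registry, np.linspace(50, 500, 8))
        G = curve.I / curve.U
        assert np.all(np.diff(G) >= -1e-9 * G[:-1])

    def test_sigma_e_current_exceeds_baseline(self, slab_mesh_registry):
        mesh, registry = slab_mesh_registry
        U = 400.0
        nonlinear = solve_npa(mesh, registry, U).I
        baseline = solve_fixed_sigma(
            mesh, baseline_sigma_elem(mesh, registry), U
        ).I
        assert nonlinear >= baseline

    def test_nonincreasing_voltages_rejected(self, slab_mesh_registry):
        mesh, registry = slab_mesh_registry
        with pytest.raises(ValueError):
            iv_sweep(mesh, registry, [100.0, 100.0])

    def test_determinism(self, slab_mesh_registry):
        mesh, registry = slab_mesh_registry
        a = iv_sweep(mesh, registry, [100.0, 300.0])
        b = iv_sweep(mesh, registry, [100.0, 300.0])
        assert np.array_equal(a.I, b.I)
        assert [p.iterations for p in a.points] == [p.iterations for p in b.points]


class TestSA:
    def test_constant_tissue_current_never_changes(self, small_plate):
        registry = single_tissue_registry(
            "liver", ConductivityModel("constant", sigma0=0.1)
        )
        sols = solve_sa(small_plate, registry, 200.0, SAConfig(n_steps=4))
        I = sa_currents(sols)
        assert np.allclose(I, I[0], rtol=1e-12)

    def test_fine_sequence_approaches_oracle(self, slab_mesh_registry, slab_layers):
        mesh, registry = slab_mesh_registry
        for U in (150.0, 250.0, 400.0):
            oracle = slab_current(slab_layers, 1.0, U)
            fine = sa_currents(
                solve_sa(mesh, registry, U, SAConfig(n_steps=15, levels=64))
            )[-1]
            assert fine == pytest.approx(oracle, rel=0.02)

    def test_more_steps_no_worse_than_fewer(self, slab_mesh_registry, slab_layers):
        """k=15 ends at least as close to the self-consistent current as k=5."""
        mesh, registry = slab_mesh_registry
        U = 250.0
        ref = slab_current(slab_layers, 1.0, U)
        i5 = sa_currents(solve_sa(mesh, registry, U, SAConfig(n_steps=5, levels=64)))[-1]
        i15 = sa_currents(solve_sa(mesh, registry, U, SAConfig(n_steps=15, levels=64)))[-1]
        assert abs(i15 - ref) <= abs(i5 - ref) + 1e-12

    def test_ratchet_keeps_sigma_rising(self, slab_mesh_registry):
        mesh, registry = slab_mesh_registry
        sols = solve_sa(mesh, registry, 400.0,
                        SAConfig(n_steps=6, levels=8, ratchet=True))
        I = sa_currents(sols)
        assert np.all(np.diff(I) >= -1e-9 * I[:-1])

    def test_current_rises_from_baseline(self, slab_mesh_registry):
        mesh, registry = slab_mesh_registry
        I = sa_currents(solve_sa(mesh, registry, 400.0, SAConfig()))
        assert I[-1] > I[0]
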