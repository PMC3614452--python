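import math

import numpy as np
import pytest

from epfem import GeometryConfig, build_mesh, mesh_convergence_study
from epfem.fem import solve_fixed_sigma
from epfem.geometry import (
    FACET_TAGS,
    GeometryError,
    build_needle_model,
    build_plate_model,
    build_tumor_model,
)


def boundary_area(mesh):
    return mesh.facet_areas().sum()


class TestPlate:
    def test_volume_and_contact_areas(self, small_plate):
        # 10 mm cube with full-face plates
        assert small_plate.tet_volumes().sum() == pytest.approx(1e-6, rel=1e-9)
        assert small_plate.electrode_area("anode") == pytest.approx(1e-4, rel=1e-9)
        assert small_plate.electrode_area("cathode") == pytest.approx(1e-4, rel=1e-9)

    def test_boundary_tiles_cube_surface(self, small_plate):
        assert boundary_area(small_plate) == pytest.approx(6e-4, rel=1e-9)

    def test_partial_contact_window(self):
        cfg = GeometryConfig(case="plate_single", gap_mm=10, width_mm=10,
                             height_mm=10, contact_width_mm=5,
                             contact_height_mm=4, resolution_mm=1.0)
        mesh = build_plate_model(cfg)
        assert mesh.electrode_area("anode") == pytest.approx(20e-6, rel=1e-9)

    def test_contact_larger_than_face_rejected(self):
        with pytest.raises(GeometryError, match="contact"):
            build_plate_model(
                GeometryConfig(case="plate_single", width_mm=10,
                               contact_width_mm=12.0)
            )

    def test_refinement_multiplies_elements(self):
        cfg = GeometryConfig(case="plate_single", resolution_mm=2.0)
        n_coarse = build_plate_model(cfg).n_elements
        cfg2 = GeometryConfig(case="plate_single", resolution_mm=1.0)
        n_fine = build_plate_model(cfg2).n_elements
        assert n_fine >= 8 * n_coarse

    def test_layered_partition(self, slab_mesh_registry):
        mesh, _ = slab_mesh_registry
        total = mesh.tet_volumes().sum()
        per = sum(mesh.region_volume(r) for r in mesh.regions())
        assert per == pytest.approx(total, rel=1e-9)
        assert mesh.region_volume("skin_a") == pytest.approx(0.1e-6, rel=1e-9)


class TestNeedle:
    @pytest.fixture(scope="class")
    def needle(self):
        return build_needle_model(GeometryConfig(case="needle_single",
                                                 resolution_mm=1.0))

    def test_tags_present_and_disjoint(self, needle):
        needle.validate()
        assert set(np.unique(needle.bfacet_tags)) == {0, 1, 2}

    def test_bore_wall_area_matches_cylinder(self, needle):
        # pi * D * insertion depth, within 5% (polygonal bore wall)
        expected = math.pi * 1.1e-3 * 7e-3
        for tag in ("anode", "cathode"):
            assert needle.electrode_area(tag) == pytest.approx(expected, rel=0.05)

    def test_volume_excludes_bores(self, needle):
        bore = math.pi * (0.55e-3) ** 2 * 7e-3
        block = 24e-3 * 16e-3 * 10e-3
        assert needle.tet_volumes().sum() == pytest.approx(block - 2 * bore, rel=0.01)

    def test_swapping_electrodes_preserves_current_magnitude(self, needle):
        sig = np.full(needle.n_elements, 0.046)
        a = solve_fixed_sigma(needle, sig, 300.0)
        b = solve_fixed_sigma(needle.swap_electrodes(), sig, 300.0)
        assert b.I == pytest.approx(a.I, rel=1e-9)

    def test_needles_outside_block_rejected(self):
        with pytest.raises(GeometryError, match="outside"):
            build_needle_model(
                GeometryConfig(case="needle_single", width_mm=6.0,
                               needle_spacing_mm=8.0)
            )


class TestTumor:
    @pytest.fixture(scope="class")
    def tumor(self):
        return build_tumor_model(GeometryConfig(case="tumor_composite",
                                                resolution_mm=0.5))

    def test_four_regions_partition_domain(self, tumor):
        assert set(tumor.regions()) == {
            "stratum_corneum_epidermis", "dermis_fat", "tumor", "muscle"
        }
        total = tumor.tet_volumes().sum()
        per = sum(tumor.region_volume(r) for r in tumor.regions())
        assert per == pytest.approx(total, rel=1e-9)
        assert total == pytest.approx(5.2e-3 * 6e-3 * 6e-3, rel=1e-9)

    def test_tumor_volume_near_sphere(self, tumor):
        exact = 4.0 / 3.0 * math.pi * (1.25e-3) ** 3
        assert tumor.region_volume("tumor") == pytest.approx(exact, rel=0.08)

    def test_no_inverted_elements_after_snapping(self, tumor):
        assert tumor.tet_volumes().min() > 0

    def test_default_gap_is_5p2_mm(self):
        assert GeometryConfig(case="tumor_composite").gap_mm == 5.2

    def test_tumor_touching_boundary_rejected(self):
        with pytest.raises(GeometryError, match="tumor"):
            build_tumor_model(
                GeometryConfig(case="tumor_composite", tumor_diameter_mm=5.5)
            )

    def test_registry_lookup_enforced(self, tumor):
        from epfem import TissueRegistry

        with pytest.raises(KeyError):
            build_tumor_model(
                GeometryConfig(case="tumor_composite", resolution_mm=0.5),
                TissueRegistry([]),
            )


class TestDeterminismAndConvergence:
    def test_identical_config_identical_mesh(self):
        cfg = GeometryConfig(case="needle_single", resolution_mm=1.5)
        a, b = build_mesh(cfg), build_mesh(cfg)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.tets, b.tets)
        assert np.array_equal(a.bfacet_tags, b.bfacet_tags)

    def test_constant_sigma_plate_converges_immediately(self):
        """The uniform-field solution is exact at any resolution."""
        cfg = GeometryConfig(case="plate_single", gap_mm=10, width_mm=10,
                             height_mm=10, resolution_mm=5.0)

        def out(mesh):
            return solve_fixed_sigma(mesh, np.full(mesh.n_elements, 0.1), 100.0).I

        rep = mesh_convergence_study(build_mesh, cfg, out, max_levels=3)
        assert rep.converged and rep.converged_level == 1
        assert all(np.isnan(r) or r >= 0 for _, _, r in rep.levels)

    def test_needle_current_monotone_refinement(self):
        """Dirichlet energy over-estimates: current decreases toward the
        limit and successive deltas shrink."""
        cfg = GeometryConfig(case="needle_single", resolution_mm=2.0)

        def out(mesh):
            return solve_fixed_sigma(mesh, np.full(mesh.n_elements, 0.046), 100.0).I

        rep = mesh_convergence_study(build_mesh, cfg, out, max_levels=3,
                                     rtol=1e-6)
        vals = [v for _, v, _ in rep.levels]
        assert vals[0] > vals[1] > vals[2]
        assert (vals[0] - vals[1]) > (vals[1] - vals[2])
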