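import numpy as np
import pytest

from epfem import (
    ConductivityModel,
    GeometryConfig,
    TissueRegistry,
    build_plate_model,
    isotropic_tissue,
)


@pytest.fixture(scope="session")
def small_plate():
    """10 mm cube, 2 mm resolution: the analytic parallel-plate block."""
    cfg = GeometryConfig(
        case="plate_single", gap_mm=10.0, width_mm=10.0, height_mm=10.0,
        resolution_mm=2.0,
    )
    return build_plate_model(cfg)


@pytest.fixture(scope="session")
def coarse_plate():
    """Tiny 4 mm block used by the inverse-analysis tests."""
    cfg = GeometryConfig(
        case="plate_single", gap_mm=4.0, width_mm=8.0, height_mm=8.0,
        resolution_mm=2.0,
    )
    return build_plate_model(cfg)


@pytest.fixture(scope="session")
def slab_layers():
    """Three-layer heaviside stack: resistive step skins around a core."""
    skin = ConductivityModel("heaviside", sigma0=0.05, factor=10.0,
                             E_rev=400.0, E_irrev=800.0)
    core = ConductivityModel("heaviside", sigma0=0.3, factor=2.5,
                             E_rev=400.0, E_irrev=800.0)
    return [(skin, 1.0), (core, 3.0), (skin, 1.0)]


@pytest.fixture(scope="session")
def slab_mesh_registry(slab_layers):
    (skin, t1), (core, t2), _ = slab_layers
    cfg = GeometryConfig(
        case="plate_single", gap_mm=t1 + t2 + t1, width_mm=10.0,
        height_mm=10.0, resolution_mm=1.0,
        layers=(("skin_a", t1), ("core", t2), ("skin_b", t1)),
    )
    mesh = build_plate_model(cfg)
    registry = TissueRegistry([
        isotropic_tissue("skin_a", skin),
        isotropic_tissue("core", core),
        isotropic_tissue("skin_b", skin),
    ])
    return mesh, registry
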