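import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epfem.conductivity import (
    ConductivityModel,
    ConductivityError,
    TissueProperties,
    TissueRegistry,
    isotropic_tissue,
    subcutaneous_tumor_registry,
)

FAMS = st.sampled_from(["constant", "linear", "exponential", "heaviside", "sigmoid"])


def random_model(family, sigma0, slope, factor, e_rev, e_irrev):
    return ConductivityModel(
        family=family, sigma0=sigma0,
        k_sigma=slope * 1e-4, c1=slope * sigma0, c2=slope * 1e-3,
        factor=factor, E_rev=e_rev, E_irrev=e_rev + e_irrev,
    )


model_st = st.builds(
    random_model,
    family=FAMS,
    sigma0=st.floats(1e-3, 2.0),
    slope=st.floats(0.0, 2.0),
    factor=st.floats(1.0, 100.0),
    e_rev=st.floats(50.0, 500.0),
    e_irrev=st.floats(50.0, 1000.0),
)


class TestEvalSigma:
    @pytest.mark.parametrize(
        "model,e,expected",
        [
            # baseline of the linear law is sigma(0) = sigma0
            (ConductivityModel("linear", sigma0=0.088145, k_sigma=3e-4), 0.0, 0.088145),
            # exponential law at E = 0: c1 (e^0 - 1) = 0
            (ConductivityModel("exponential", sigma0=0.1, c1=0.05, c2=2e-3), 0.0, 0.1),
            # stratum-corneum step fully saturated above E_irrev: 100 x 0.008
            (ConductivityModel("heaviside", sigma0=0.008, factor=100,
                               E_rev=400, E_irrev=1200), 1500.0, 0.8),
            # constant family ignores the field
            (ConductivityModel("constant", sigma0=0.25), 900.0, 0.25),
        ],
    )
    def test_known_values(self, model, e, expected):
        assert model.sigma(e) == pytest.approx(expected, rel=1e-12)

    def test_negative_field_rejected(self):
        m = ConductivityModel("linear", sigma0=0.1, k_sigma=1e-4)
        with pytest.raises(ConductivityError):
            m.sigma(-1.0)
        with pytest.raises(ConductivityError):
            m.dsigma_dE(-1.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConductivityError):
            ConductivityModel("nope", sigma0=0.1)
        with pytest.raises(ConductivityError):
            ConductivityModel("constant", sigma0=-0.1)
        with pytest.raises(ConductivityError):
            ConductivityModel("heaviside", sigma0=0.1, factor=2,
                              E_rev=800, E_irrev=400)
        with pytest.raises(ConductivityError):
            ConductivityModel("heaviside", sigma0=0.1, factor=2)

    @settings(max_examples=150, deadline=None)
    @given(model=model_st, e1=st.floats(0, 5000), e2=st.floats(0, 5000))
    def test_monotone_nondecreasing(self, model, e1, e2):
        lo, hi = sorted((e1, e2))
        assert model.sigma(hi) >= model.sigma(lo) - 1e-12
        assert model.sigma(lo) >= model.sigma0 - 1e-12

    @settings(max_examples=100, deadline=None)
    @given(model=model_st, e=st.floats(1.0, 3000.0))
    def test_derivative_matches_finite_difference(self, model, e):
        h = 1e-3
        fd = (model.sigma(e + h) - model.sigma(e - h)) / (2 * h)
        an = model.dsigma_dE(e)
        # abs floor covers the O(h^2) finite-difference residual right at a
        # threshold, where the analytic derivative is exactly zero
        assert an == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_step_families_saturate(self):
        for fam in ("heaviside", "sigmoid"):
            m = ConductivityModel(fam, sigma0=0.1, factor=10,
                                  E_rev=400, E_irrev=800)
            assert m.sigma(0.0) == pytest.approx(0.1, rel=0.01)
            assert m.sigma(8000.0) == pytest.approx(1.0, rel=0.01)

    def test_heaviside_c2_continuity(self):
        """First and second derivatives continuous across both thresholds."""
        m = ConductivityModel("heaviside", sigma0=0.1, factor=10,
                              E_rev=400, E_irrev=800)
        h = 1e-4
        for e0 in (400.0, 800.0):
            d1 = (m.sigma(e0 + h) - m.sigma(e0 - h)) / (2 * h)
            d2 = (m.sigma(e0 + h) - 2 * m.sigma(e0) + m.sigma(e0 - h)) / h**2
            assert abs(d1) < 1e-5
            assert abs(d2) < 1e-3


class TestTensor:
    def test_isotropic_is_scalar_identity(self):
        reg = subcutaneous_tumor_registry("T1")
        t = reg["tumor"].sigma_tensor([100.0, 0.0, 0.0])
        assert np.allclose(t, 0.3 * np.eye(3))

    def test_muscle_baseline_diagonal(self):
        reg = subcutaneous_tumor_registry("T1")
        t = reg["muscle"].sigma_tensor([0.0, 0.0, 0.0])
        assert np.allclose(np.diag(t), [0.75, 0.135, 0.135])

    def test_frame_covariance(self):
        """Rotating frame and field together conjugates the tensor by R."""
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        m_par = ConductivityModel("linear", sigma0=0.75, k_sigma=2e-4)
        m_perp = ConductivityModel("linear", sigma0=0.135, k_sigma=1e-4)
        e = np.array([250.0, 40.0, -90.0])
        lab = TissueProperties("m", (m_par, m_perp, m_perp), np.eye(3))
        rot = TissueProperties("m", (m_par, m_perp, m_perp), np.eye(3) @ q)
        t_lab = lab.sigma_tensor(e)
        t_rot = rot.sigma_tensor(q.T @ e)
        assert np.allclose(q.T @ t_lab @ q, t_rot, atol=1e-12)

    def test_nonorthonormal_frame_rejected(self):
        m = ConductivityModel("constant", sigma0=0.1)
        with pytest.raises(ConductivityError):
            TissueProperties("x", (m, m, m), np.ones((3, 3)))


class TestRegistry:
    def test_table_values(self):
        for var, s in (("T1", 0.3), ("T2", 0.6), ("T3", 0.9)):
            reg = subcutaneous_tumor_registry(var)
            tum = reg["tumor"].models[0]
            assert (tum.sigma0, tum.factor, tum.E_rev, tum.E_irrev) == (s, 2.5, 400, 800)
        reg = subcutaneous_tumor_registry()
        se = reg["stratum_corneum_epidermis"].models[0]
        assert (se.sigma0, se.factor, se.E_rev, se.E_irrev) == (0.008, 100, 400, 1200)
        df = reg["dermis_fat"].models[0]
        assert (df.sigma0, df.factor, df.E_rev, df.E_irrev) == (0.25, 4, 300, 1200)
        mus = reg["muscle"]
        assert [m.sigma0 for m in mus.models] == [0.75, 0.135, 0.135]
        assert [m.E_rev for m in mus.models] == [80, 200, 200]
        assert all(m.E_irrev == 800 for m in mus.models)

    def test_unknown_lookup_fails_loudly(self):
        reg = subcutaneous_tumor_registry()
        with pytest.raises(KeyError, match="unknown tissue"):
            reg["bone"]

    def test_yaml_roundtrip(self, tmp_path):
        reg = subcutaneous_tumor_registry("T2")
        p = tmp_path / "reg.yaml"
        reg.to_yaml(p)
        back = TissueRegistry.from_yaml(p)
        for t in reg:
            for a, b in zip(t.models, back[t.name].models):
                assert a == b

    def test_shipped_file_matches_builtin(self):
        from importlib.resources import files

        path = files("epfem").joinpath("data/subcutaneous_tumor_tissues.yaml")
        shipped = TissueRegistry.from_yaml(str(path))
        for var in ("T1", "T2", "T3"):
            builtin = subcutaneous_tumor_registry(var)
            assert shipped[f"tumor_{var}"].models == builtin["tumor"].models
        for name in ("stratum_corneum_epidermis", "dermis_fat", "muscle"):
            assert shipped[name].models == subcutaneous_tumor_registry()[name].models

    def test_as_constant_freezes_baseline(self):
        reg = subcutaneous_tumor_registry().as_constant()
        m = reg["stratum_corneum_epidermis"].models[0]
        assert m.family == "constant"
        assert m.sigma(5000.0) == 0.008
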