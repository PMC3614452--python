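"""Field-dependent tissue conductivity models sigma(E).

Electroporation increases bulk tissue conductivity once the local electric
field exceeds a reversible threshold ``E_rev``; above the irreversible
threshold ``E_irrev`` the increase saturates at ``factor * sigma0``.  Five
functional families are provided:

``constant``
    sigma(E) = sigma0 (non-electroporated, linear conductor).
``linear``
    sigma(E) = sigma0 + k_sigma * E.
``exponential``
    sigma(E) = sigma0 + c1 * (exp(c2 * E) - 1).
``heaviside``
    smoothed Heaviside step between sigma0 and factor * sigma0 over
    [E_rev, E_irrev], realised as the quintic smoothstep
    S(t) = 6 t^5 - 15 t^4 + 10 t^3, which has vanishing first and second
    derivatives at both ends (C2-continuous).
``sigmoid``
    logistic step sigma0 + (factor - 1) sigma0 / (1 + exp(-(E - E_c)/B))
    with E_c = (E_rev + E_irrev)/2 and B = (E_irrev - E_rev)/12 by default,
    so the curve is within ~0.25% of its asymptotes at the thresholds.

Field magnitudes are always in V/cm at this interface (see :mod:`epfem.units`).
All evaluators are vectorised over E.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import yaml

FAMILIES = ("constant", "linear", "exponential", "heaviside", "sigmoid")


class ConductivityError(ValueError):
    """Invalid conductivity-model configuration or evaluation domain."""


def _smoothstep(t: np.ndarray) -> np.ndarray:
    """Quintic smoothstep S(t)=6t^5-15t^4+10t^3 clamped to [0, 1]."""
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def _smoothstep_d(t: np.ndarray) -> np.ndarray:
    """dS/dt, zero outside (0, 1)."""
    inside = (t > 0.0) & (t < 1.0)
    t = np.clip(t, 0.0, 1.0)
    return np.where(inside, 30.0 * t * t * (t - 1.0) * (t - 1.0), 0.0)


@dataclass(frozen=True)
class ConductivityModel:
    """One sigma(E) law with its parameters.

    Parameters
    ----------
    family : str
        One of ``constant | linear | exponential | heaviside | sigmoid``.
    sigma0 : float
        Baseline conductivity of non-electroporated tissue, S/m; sigma(0).
    k_sigma : float
        Slope of the linear family, S/m per V/cm.
    c1, c2 : float
        Exponential-family parameters, S/m and cm/V.
    factor : float
        Saturated conductivity multiplier for the step families (>= 1).
    E_rev, E_irrev : float, optional
        Reversible / irreversible electroporation thresholds, V/cm.
    sigmoid_center, sigmoid_width : float, optional
        Override the logistic midpoint E_c and width B (V/cm).
    """

    family: str
    sigma0: float
    k_sigma: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    factor: float = 1.0
    E_rev: Optional[float] = None
    E_irrev: Optional[float] = None
    sigmoid_center: Optional[float] = None
    sigmoid_width: Optional[float] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConductivityError(f"unknown conductivity family {self.family!r}")
        if not self.sigma0 > 0:
            raise ConductivityError(f"sigma0 must be > 0, got {self.sigma0}")
        if self.factor < 1.0:
            raise ConductivityError(f"factor must be >= 1, got {self.factor}")
        if self.family in ("heaviside", "sigmoid"):
            if self.E_rev is None or self.E_irrev is None:
                raise ConductivityError(
                    f"{self.family} family requires E_rev and E_irrev"
                )
        if self.E_rev is not None and self.E_irrev is not None:
            if not self.E_rev < self.E_irrev:
                raise ConductivityError(
                    f"E_rev ({self.E_rev}) must be < E_irrev ({self.E_irrev})"
                )
        if self.family == "linear" and self.k_sigma < 0:
            raise ConductivityError("k_sigma must be >= 0 (sigma non-decreasing)")
        if self.family == "exponential" and (self.c1 < 0 or self.c2 < 0):
            raise ConductivityError("c1, c2 must be >= 0 (sigma non-decreasing)")

    # -- logistic parameters ------------------------------------------------
    def _sigmoid_params(self) -> Tuple[float, float]:
        ec = self.sigmoid_center
        if ec is None:
            ec = 0.5 * (self.E_rev + self.E_irrev)
        b = self.sigmoid_width
        if b is None:
            b = (self.E_irrev - self.E_rev) / 12.0
        return ec, b

    # -- evaluation ---------------------------------------------------------
    def sigma(self, e_vcm) -> np.ndarray:
        """Evaluate sigma(E) [S/m] at field magnitude(s) ``e_vcm`` [V/cm]."""
        e = np.asarray(e_vcm, dtype=float)
        if np.any(e < 0):
            raise ConductivityError("field magnitude must be >= 0")
        if self.family == "constant":
            out = np.full_like(e, self.sigma0)
        elif self.family == "linear":
            out = self.sigma0 + self.k_sigma * e
        elif self.family == "exponential":
            out = self.sigma0 + self.c1 * np.expm1(self.c2 * e)
        elif self.family == "heaviside":
            t = (e - self.E_rev) / (self.E_irrev - self.E_rev)
            out = self.sigma0 * (1.0 + (self.factor - 1.0) * _smoothstep(t))
        else:  # sigmoid
            ec, b = self._sigmoid_params()
            out = self.sigma0 * (
                1.0
                + (self.factor - 1.0) / (1.0 + np.exp(-(e - ec) / b))
            )
        return out if out.shape else float(out)

    def dsigma_dE(self, e_vcm) -> np.ndarray:
        """Analytic d sigma / dE [S/m per V/cm] at ``e_vcm`` [V/cm]."""
        e = np.asarray(e_vcm, dtype=float)
        if np.any(e < 0):
            raise ConductivityError("field magnitude must be >= 0")
        if self.family == "constant":
            out = np.zeros_like(e)
        elif self.family == "linear":
            out = np.full_like(e, self.k_sigma)
        elif self.family == "exponential":
            out = self.c1 * self.c2 * np.exp(self.c2 * e)
        elif self.family == "heaviside":
            w = self.E_irrev - self.E_rev
            t = (e - self.E_rev) / w
            out = self.sigma0 * (self.factor - 1.0) * _smoothstep_d(t) / w
        else:  # sigmoid
            ec, b = self._sigmoid_params()
            s = 1.0 / (1.0 + np.exp(-(e - ec) / b))
            out = self.sigma0 * (self.factor - 1.0) * s * (1.0 - s) / b
        return out if out.shape else float(out)

    def as_constant(self) -> "ConductivityModel":
        """The nested linear-conductor model sigma = sigma0 = const."""
        return ConductivityModel(
            family="constant",
            sigma0=self.sigma0,
            E_rev=self.E_rev,
            E_irrev=self.E_irrev,
        )


@dataclass(frozen=True)
class TissueProperties:
    """Possibly anisotropic tissue: one sigma(E) model per principal axis.

    ``fiber_frame`` rows are the orthonormal principal axes expressed in the
    lab frame; isotropic tissues repeat one model three times with the
    identity frame.  Each axis model is evaluated on the field *magnitude*
    |E| (with its own thresholds), not on the field component, because the
    degree of membrane electroporation is set by the local field strength.
    """

    name: str
    models: Tuple[ConductivityModel, ConductivityModel, ConductivityModel]
    fiber_frame: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        frame = np.asarray(self.fiber_frame, dtype=float)
        if frame.shape != (3, 3):
            raise ConductivityError("fiber_frame must be 3x3")
        if not np.allclose(frame @ frame.T, np.eye(3), atol=1e-12):
            raise ConductivityError(f"fiber_frame of {self.name!r} not orthonormal")
        object.__setattr__(self, "fiber_frame", frame)
        if len(self.models) != 3:
            raise ConductivityError("exactly 3 axis models required")

    @property
    def isotropic(self) -> bool:
        return self.models[0] == self.models[1] == self.models[2]

    def principal_sigmas(self, e_mag_vcm) -> np.ndarray:
        """Per-axis sigma(|E|), shape (..., 3)."""
        return np.stack([m.sigma(e_mag_vcm) for m in self.models], axis=-1)

    def sigma_tensor(self, e_vec_vcm) -> np.ndarray:
        """3x3 lab-frame conductivity tensor at lab-frame field ``e_vec_vcm``.

        Diagonal in the fiber frame with per-axis sigma(|E|), rotated to the
        lab frame: sigma_lab = F^T diag(s) F for frame rows F.
        """
        e = np.asarray(e_vec_vcm, dtype=float)
        if not np.all(np.isfinite(e)):
            raise ConductivityError("field vector must be finite")
        mag = float(np.linalg.norm(e))
        s = self.principal_sigmas(mag)
        return self.fiber_frame.T @ np.diag(s) @ self.fiber_frame

    def as_constant(self) -> "TissueProperties":
        return TissueProperties(
            name=self.name,
            models=tuple(m.as_constant() for m in self.models),
            fiber_frame=self.fiber_frame,
        )


def isotropic_tissue(name: str, model: ConductivityModel) -> TissueProperties:
    """Convenience constructor for an isotropic tissue."""
    return TissueProperties(name=name, models=(model, model, model))


class TissueRegistry:
    """Named mapping tissue-name -> :class:`TissueProperties`.

    Lookups of unknown names raise ``KeyError`` naming the tissue.
    """

    def __init__(self, tissues=()):
        self._tissues = {}
        for t in tissues:
            self.register(t)

    def register(self, props: TissueProperties) -> None:
        self._tissues[props.name] = props

    def __getitem__(self, name: str) -> TissueProperties:
        try:
            return self._tissues[name]
        except KeyError:
            raise KeyError(
                f"unknown tissue {name!r}; known: {sorted(self._tissues)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._tissues

    def __iter__(self):
        return iter(self._tissues.values())

    def names(self):
        return list(self._tissues)

    def as_constant(self) -> "TissueRegistry":
        """Registry with every sigma(E) frozen at its baseline (linear model)."""
        return TissueRegistry(t.as_constant() for t in self)

    # -- (de)serialisation --------------------------------------------------
    def to_yaml(self, path) -> None:
        blocks = {}
        for t in self:
            axes = []
            for m in t.models:
                d = {"family": m.family, "sigma0_S_per_m": m.sigma0}
                if m.family == "linear":
                    d["k_sigma_S_per_m_per_V_per_cm"] = m.k_sigma
                if m.family == "exponential":
                    d["c1_S_per_m"] = m.c1
                    d["c2_cm_per_V"] = m.c2
                if m.factor != 1.0:
                    d["factor"] = m.factor
                if m.E_rev is not None:
                    d["E_rev_V_per_cm"] = m.E_rev
                if m.E_irrev is not None:
                    d["E_irrev_V_per_cm"] = m.E_irrev
                axes.append(d)
            blocks[t.name] = {
                "axes": axes,
                "fiber_frame": np.asarray(t.fiber_frame).tolist(),
            }
        with open(path, "w") as fh:
            yaml.safe_dump(blocks, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TissueRegistry":
        with open(path) as fh:
            blocks = yaml.safe_load(fh)
        tissues = []
        for name, blk in blocks.items():
            models = []
            for d in blk["axes"]:
                models.append(
                    ConductivityModel(
                        family=d["family"],
                        sigma0=d["sigma0_S_per_m"],
                        k_sigma=d.get("k_sigma_S_per_m_per_V_per_cm", 0.0),
                        c1=d.get("c1_S_per_m", 0.0),
                        c2=d.get("c2_cm_per_V", 0.0),
                        factor=d.get("factor", 1.0),
                        E_rev=d.get("E_rev_V_per_cm"),
                        E_irrev=d.get("E_irrev_V_per_cm"),
                    )
                )
            tissues.append(
                TissueProperties(
                    name=name,
                    models=tuple(models),
                    fiber_frame=np.asarray(
                        blk.get("fiber_frame", np.eye(3).tolist()), dtype=float
                    ),
                )
            )
        return cls(tissues)


# ---------------------------------------------------------------------------
# Subcutaneous-tumor tissue parameters (smoothed-Heaviside sigma(E) for every
# tissue).  Baselines sigma_SE = 0.008, sigma_DF = 0.25, sigma_T1/T2/T3 =
# 0.3/0.6/0.9, sigma_M_perp = 0.135, sigma_M_par = 0.75 S/m with conductivity
# increase factors 100/4/2.5/2.5/2.5 and thresholds per tissue.  The muscle is
# anisotropic: longitudinal model on the X (fiber) axis, transversal on Y, Z.
# ---------------------------------------------------------------------------

TUMOR_VARIANTS = {"T1": 0.3, "T2": 0.6, "T3": 0.9}


def _hv(sigma0, factor, e_rev, e_irrev) -> ConductivityModel:
    return ConductivityModel(
        family="heaviside", sigma0=sigma0, factor=factor, E_rev=e_rev, E_irrev=e_irrev
    )


def subcutaneous_tumor_registry(tumor_variant: str = "T1") -> TissueRegistry:
    """The built-in subcutaneous-tumor tissue registry.

    ``tumor_variant`` selects which of the three examined target-tumor
    baselines (0.3, 0.6 or 0.9 S/m) the ``tumor`` entry carries.
    """
    if tumor_variant not in TUMOR_VARIANTS:
        raise ConductivityError(
            f"tumor_variant must be one of {sorted(TUMOR_VARIANTS)}"
        )
    sigma_t = TUMOR_VARIANTS[tumor_variant]
    muscle_long = _hv(0.75, 2.5, 80.0, 800.0)
    muscle_trans = _hv(0.135, 2.5, 200.0, 800.0)
    return TissueRegistry(
        [
            isotropic_tissue("stratum_corneum_epidermis", _hv(0.008, 100.0, 400.0, 1200.0)),
            isotropic_tissue("dermis_fat", _hv(0.25, 4.0, 300.0, 1200.0)),
            isotropic_tissue("tumor", _hv(sigma_t, 2.5, 400.0, 800.0)),
            TissueProperties(
                name="muscle",
                models=(muscle_long, muscle_trans, muscle_trans),
                fiber_frame=np.eye(3),
            ),
        ]
    )


def single_tissue_registry(name: str, model: ConductivityModel) -> TissueRegistry:
    """Registry with one isotropic tissue (liver-block cases)."""
    return TissueRegistry([isotropic_tissue(name, model)])
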