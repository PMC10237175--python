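"""Continuum quantities for morphoelastic growth of neo-Hookean bilayers.

Multiplicative decomposition of the plane-strain deformation gradient,

    F = Fe . Fg,     Fg = theta * I,

splits the observed deformation into an elastic part ``Fe`` (the only part
that generates stress) and an isotropic, purely morphogenetic growth part
parameterised by the growth factor ``theta >= 1``.  Two constitutive
branches are provided:

* an incompressible neo-Hookean law used by the analytical stability
  module, ``sigma = mu Fe^T Fe - p I`` with the pressure ``p`` acting as a
  Lagrange multiplier, and
* a compressible neo-Hookean law used by the finite-element simulator,
  ``sigma = [lam ln(Je) - mu] I + mu Fe^T Fe``.

The compressible expression is implemented verbatim as the default law.  A
frame-correct variant that divides by ``Je`` (so the expression becomes a
true Cauchy stress rather than a Kirchhoff-type stress) and builds the
left Cauchy-Green tensor ``Fe Fe^T`` is available through
``frame_correct=True``; for the symmetric elastic states that dominate the
flat bilayer the two tensor choices coincide.

Units are fixed to millimetres and kilopascals throughout the package; the
growth factor and time are dimensionless (the growth rate ``G`` absorbs
the time scale of the quasi-static loading).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParams",
    "Kinematics",
    "Stress",
    "InvalidKinematicsError",
    "IncompressibilityError",
    "decompose_growth",
    "cauchy_stress_compressible",
    "cauchy_stress_incompressible",
    "grow",
    "growth_jacobian",
]

_I2 = np.eye(2)

#: tolerance on |det(Fe) - 1| for the incompressible branch
INCOMPRESSIBILITY_TOL = 1e-8


class InvalidKinematicsError(ValueError):
    """Raised for non-positive determinants or growth factors below one."""


class IncompressibilityError(ValueError):
    """Raised when det(Fe) deviates from one on the incompressible branch."""


@dataclass(frozen=True)
class MaterialParams:
    """Material and growth constants of one region (layer or substrate).

    Parameters
    ----------
    mu : float
        Shear modulus in kPa, strictly positive.
    lam : float
        First Lame constant in kPa; zero selects the incompressible branch.
    growing : bool
        Whether this region grows.  Non-growing material must have G = 0.
    G : float
        Growth-factor rate (1/time, dimensionless time).
    """

    mu: float
    lam: float = 0.0
    growing: bool = False
    G: float = 0.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"shear modulus must be positive, got {self.mu}")
        if self.lam < 0:
            raise ValueError(f"first Lame constant must be >= 0, got {self.lam}")
        if self.G < 0:
            raise ValueError(f"growth rate must be >= 0, got {self.G}")
        if not self.growing and self.G != 0:
            raise ValueError("non-growing material must have G = 0")


@dataclass(frozen=True)
class Kinematics:
    """Deformation state with multiplicative growth split (plane strain)."""

    F: np.ndarray
    theta: float = 1.0
    ndim: int = 2

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "F", F)
        if F.shape != (2, 2):
            raise InvalidKinematicsError(f"F must be 2x2, got shape {F.shape}")
        if np.linalg.det(F) <= 0:
            raise InvalidKinematicsError("det(F) must be positive")
        if self.theta < 1.0:
            raise InvalidKinematicsError("growth factor theta must be >= 1")

    @property
    def Fe(self) -> np.ndarray:
        return decompose_growth(self.F, self.theta)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def Jg(self) -> float:
        return growth_jacobian(self.theta, self.ndim)

    @property
    def Je(self) -> float:
        return self.J / self.Jg


@dataclass(frozen=True)
class Stress:
    """Symmetric Cauchy stress (kPa), with the pressure multiplier if any."""

    sigma: np.ndarray
    p: float | None = None

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "sigma", sigma)
        if not np.allclose(sigma, sigma.T, atol=1e-12 * max(1.0, abs(sigma).max())):
            raise ValueError("Cauchy stress must be symmetric")


def decompose_growth(F: np.ndarray, theta: float) -> np.ndarray:
    """Elastic part ``Fe = F / theta`` of the growth decomposition.

    With isotropic growth ``Fg = theta I`` the elastic tensor is simply the
    total deformation gradient scaled back by the growth factor, so that
    ``Fe @ (theta I)`` reproduces ``F`` to machine precision.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (2, 2):
        raise InvalidKinematicsError(f"F must be 2x2, got shape {F.shape}")
    if np.linalg.det(F) <= 0:
        raise InvalidKinematicsError("det(F) must be positive")
    if theta < 1.0:
        raise InvalidKinematicsError("growth factor theta must be >= 1")
    return F / theta


def cauchy_stress_compressible(
    Fe: np.ndarray, mat: MaterialParams, frame_correct: bool = False
) -> Stress:
    """Compressible neo-Hookean stress of the elastic tensor.

    Default evaluates ``[lam ln(Je) - mu] I + mu Fe^T Fe`` exactly as
    written.  With ``frame_correct=True`` the expression is divided by
    ``Je`` and uses ``Fe Fe^T``, which is the Cauchy stress of the strain
    energy ``W = mu/2 (tr C - 2) - mu ln Je + lam/2 (ln Je)^2``.
    """
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    if Je <= 0:
        raise InvalidKinematicsError("det(Fe) must be positive")
    if frame_correct:
        b = Fe @ Fe.T
        sigma = (mat.mu * (b - _I2) + mat.lam * np.log(Je) * _I2) / Je
    else:
        C = Fe.T @ Fe
        sigma = mat.mu * (C - _I2) + mat.lam * np.log(Je) * _I2
    return Stress(sigma=0.5 * (sigma + sigma.T))


def cauchy_stress_incompressible(Fe: np.ndarray, mu: float, p: float) -> Stress:
    """Incompressible neo-Hookean stress ``mu Fe^T Fe - p I``."""
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    if abs(Je - 1.0) > INCOMPRESSIBILITY_TOL:
        raise IncompressibilityError(
            f"|det(Fe) - 1| = {abs(Je - 1.0):.3e} exceeds tolerance"
        )
    sigma = mu * (Fe.T @ Fe) - p * _I2
    return Stress(sigma=0.5 * (sigma + sigma.T), p=p)


def grow(theta: float, G: float, dt: float) -> float:
    """Advance the growth factor one step: ``theta + G dt`` (linear kinetics)."""
    if dt <= 0:
        raise ValueError("time step must be positive")
    return theta + G * dt


def growth_jacobian(theta: float, ndim: int = 2) -> float:
    """Grown volume ``Jg = theta**ndim``."""
    return float(theta) ** ndim
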