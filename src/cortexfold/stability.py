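"""Onset-of-folding analysis of a growing incompressible neo-Hookean layer
on an incompressible substrate (plane strain).

Model
-----
The layer occupies the reference strip Y in [0, 1], the substrate the
half-space Y <= 0.  The layer grows isotropically, ``Fg = theta I``; the
substrate does not grow.  Laterally constrained growth leaves the layer
with elastic principal stretches ``(1/theta, theta)`` (flat solution
``y = theta^2 Y``) while the substrate stays unstressed.

The incremental (linearised) equilibrium of this grown base state is
solved with the classical exponential-solution (Stroh-type) ansatz for a
stream function ``psi = f(y) sin(kx) / k``: inside the layer ``f`` is a
combination of ``exp(s k y)`` with ``s = +-1, +-1/theta^2``; in the
unstrained substrate the degenerate exponents give
``f = (D1 + D2 k y) exp(k y)``.  Displacement and traction continuity at
the interface, a traction-free top surface and decay at depth yield a
6 x 6 boundary-condition matrix whose vanishing determinant defines the
dispersion relation ``D(theta, k) = 0``.  For each wavenumber the lowest
root ``theta(k)`` is found by bracketing and bisection; minimising over
``k`` gives the critical growth ``theta_crit`` and wavenumber ``k_c``.

Two classical limits validate the formulation: for ``beta -> infinity``
the stiff-film asymptote ``k_c t -> (3/beta)^(1/3)`` with vanishing
critical strain, and for ``k -> infinity`` the surface instability of a
growth-compressed half-space at the Biot stretch
``lambda_B = 0.5437`` (``theta_B = 1.8393``).

Below a threshold stiffness ratio the finite-wavelength minimum merges
into the Biot plateau and the critical wavenumber diverges; the
post-buckling thickness-asymmetry coefficient ``a`` is positive (gyri
thicker than sulci) on the entire finite-wavelength branch and ceases to
exist at that same threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BilayerStabilityConfig",
    "StabilityResult",
    "FoldProfile",
    "NoFoldingModeError",
    "dispersion_matrix",
    "dispersion_det",
    "theta_root_at_k",
    "critical_growth",
    "mode_shape",
    "asymmetry_coefficient",
    "folding_threshold",
    "biot_limit",
    "biot_growth",
    "fold_profile",
    "thickness_asymmetry",
    "scan_dispersion",
]


class NoFoldingModeError(RuntimeError):
    """No finite-wavenumber folding minimum exists for this stiffness ratio."""


@dataclass(frozen=True)
class BilayerStabilityConfig:
    """Stiffness ratio and scan windows for the bilayer stability problem."""

    beta: float
    theta_range: tuple[float, float] = (1.005, 4.0)
    k_range: tuple[float, float] = (0.05, 20.0)
    n_k: int = 80

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("stiffness ratio beta must be positive")


@dataclass(frozen=True)
class StabilityResult:
    """Critical point and post-buckling asymmetry of the folding mode."""

    beta: float
    theta_crit: float
    k_crit: float
    a: float
    Y: np.ndarray = field(repr=False)
    F1: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class FoldProfile:
    """First-order fold shape ``y(x, Y) = theta^2 Y + A k F1(Y) cos(k x)``."""

    theta: float
    k: float
    A: float
    Y: np.ndarray
    F1: np.ndarray

    def __call__(self, x, Y):
        x = np.asarray(x, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.min() < self.Y.min() - 1e-12 or Y.max() > self.Y.max() + 1e-12:
            raise ValueError("Y outside tabulated mode-shape range")
        F1 = np.interp(Y, self.Y, self.F1)
        base = np.where(Y >= 0, self.theta**2 * Y, Y)
        return base + self.A * self.k * F1 * np.cos(self.k * x)


def biot_growth() -> float:
    """Growth factor of the zero-wavelength (Biot) surface instability.

    The layer surface destabilises at compression stretch ``lambda_B``
    solving ``l^6 + l^4 + 3 l^2 - 1 = 0``; with lateral stretch
    ``1/theta`` this is ``theta_B = 1/lambda_B = 1.83929``.
    """
    r = np.roots([1.0, 0.0, 1.0, 0.0, 3.0, 0.0, -1.0])
    lam = r[(abs(r.imag) < 1e-9) & (r.real > 0)].real.min()
    return 1.0 / lam


def dispersion_matrix(theta, k, beta):
    """Boundary-condition matrix of the incremental bilayer problem.

    Vectorised over broadcastable ``theta`` and ``k``; columns 0..3 are
    the layer exponentials (scaled to avoid overflow, which leaves the
    determinant's sign structure intact), columns 4..5 the substrate
    solution.  mu_s is normalised to one, mu_l = beta.
    """
    theta = np.asarray(theta, dtype=float)
    k = np.asarray(k, dtype=float)
    theta, k = np.broadcast_arrays(theta, k)
    m = 1.0 / theta**2
    h = theta**2                       # current layer thickness
    gl = beta * theta**2               # gamma_l = mu_l * lam2^2
    Pl = beta / theta**2 + 2 * beta * theta**2   # alpha_l + gamma_l + p_l
    s = np.stack([np.ones_like(theta), -np.ones_like(theta), m, -m], axis=-1)
    kh = (k * h)[..., None]
    scale = np.exp(-np.maximum(s, 0.0) * kh)
    e_top = np.exp(s * kh - np.maximum(s, 0.0) * kh)
    e_bot = scale
    glx = gl[..., None]
    Plx = Pl[..., None]
    M = np.zeros(theta.shape + (6, 6))
    M[..., 0, :4] = s * e_bot                        # u continuity
    M[..., 1, :4] = e_bot                            # v continuity
    M[..., 2, :4] = glx * (s**2 + 1) * e_bot         # shear traction
    M[..., 3, :4] = (glx * s**3 - Plx * s) * e_bot   # normal traction
    M[..., 4, :4] = (s**2 + 1) * e_top               # free top: shear
    M[..., 5, :4] = (glx * s**3 - Plx * s) * e_top   # free top: normal
    # substrate (unstrained, double exponent): f = (D1 + D2 k y) e^{ky}
    M[..., 0, 4] = -1.0
    M[..., 0, 5] = -1.0
    M[..., 1, 4] = -1.0
    M[..., 2, 4] = -2.0
    M[..., 2, 5] = -2.0
    M[..., 3, 4] = 2.0
    return M


def dispersion_det(theta, k, beta):
    """Determinant whose roots in theta define the folding instability."""
    return np.linalg.det(dispersion_matrix(theta, k, beta))


def theta_root_at_k(k, beta, theta_range=(1.005, 4.0), n_grid=600):
    """Lowest growth factor at which the mode of wavenumber ``k`` is marginal.

    Brackets the first sign change of the determinant on a theta grid and
    refines it by bisection.  Returns ``nan`` when no root exists in the
    scanned range.
    """
    th = np.linspace(*theta_range, n_grid)
    d = dispersion_det(th, np.full_like(th, k), beta)
    sgn = np.sign(d)
    idx = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
    if len(idx) == 0:
        return np.nan
    a, b = th[idx[0]], th[idx[0] + 1]
    return brentq(lambda t: dispersion_det(t, k, beta), a, b, xtol=1e-12)


def scan_dispersion(beta, theta_range=(1.005, 4.0), k_range=(0.05, 20.0),
                    n_theta=600, n_k=80):
    """Brute-force grid scan: theta(k) on a log-spaced wavenumber grid.

    Serves as the independent oracle for the production minimiser; returns
    ``(k_grid, theta_of_k)`` with nan where no instability exists.
    """
    ks = np.geomspace(*k_range, n_k)
    ths = np.array([theta_root_at_k(k, beta, theta_range) for k in ks])
    return ks, ths


def critical_growth(beta, theta_range=(1.005, 4.0), k_range=(0.05, 20.0),
                    n_k=80):
    """Critical growth factor and wavenumber minimising theta(k).

    Raises :class:`NoFoldingModeError` when the minimum sits at the upper
    wavenumber edge (zero-wavelength regime below the folding threshold).
    """
    ks, ths = scan_dispersion(beta, theta_range, k_range, n_k=n_k)
    if not np.isfinite(ths).any():
        raise NoFoldingModeError(f"no instability found for beta={beta}")
    i = int(np.nanargmin(ths))
    if i >= len(ks) - 1:
        raise NoFoldingModeError(
            f"critical wavenumber at scan edge for beta={beta}: "
            "zero-wavelength (Biot) regime, no finite-k folding mode"
        )
    lo = ks[max(i - 1, 0)]
    hi = ks[min(i + 1, len(ks) - 1)]
    f = lambda k: theta_root_at_k(k, beta, theta_range)
    for _ in range(60):  # golden-section refinement of the smooth minimum
        k1 = lo + 0.381966 * (hi - lo)
        k2 = hi - 0.381966 * (hi - lo)
        if f(k1) < f(k2):
            hi = k2
        else:
            lo = k1
        if hi - lo < 1e-8 * hi:
            break
    k_c = 0.5 * (lo + hi)
    return float(f(k_c)), float(k_c)


def mode_shape(beta, theta_c, k_c, n_layer=120, substrate_depth=4.0,
               n_sub=160):
    """Null vector of the boundary-condition matrix, tabulated as F1(Y).

    The vertical displacement of the critical mode is
    ``v(x, Y) = A k F1(Y) cos(k x)``.  F1 is normalised so that
    ``max |F1| = 1`` over the layer, with its top-surface value negative
    so the gyral crest sits at ``x = pi / k`` (matching the convention in
    which gyral thickness is read at that station).
    """
    M = dispersion_matrix(theta_c, k_c, beta)
    _, _, vt = np.linalg.svd(M)
    x = vt[-1]
    m = 1.0 / theta_c**2
    h = theta_c**2
    s = np.array([1.0, -1.0, m, -m])
    C = x[:4] * np.exp(-np.maximum(s, 0.0) * k_c * h)  # undo column scaling
    D1, D2 = x[4], x[5]
    Y_lay = np.linspace(0.0, 1.0, n_layer)
    y_lay = h * Y_lay                       # current height in the layer
    f_lay = (C[None, :] * np.exp(np.outer(y_lay, s) * k_c)).sum(axis=1)
    Y_sub = np.linspace(-substrate_depth, 0.0, n_sub, endpoint=False)
    f_sub = (D1 + D2 * k_c * Y_sub) * np.exp(k_c * Y_sub)
    Y = np.concatenate([Y_sub, Y_lay])
    f = np.concatenate([f_sub, f_lay])
    F1 = -f  # v = -f(y) cos(kx) in the stream-function convention
    norm = np.abs(F1[len(Y_sub):]).max()
    F1 = F1 / norm
    if F1[-1] > 0:  # enforce F1(1) < 0: crest at x = pi/k
        F1 = -F1
    return Y, F1


def asymmetry_coefficient(beta, result=None, **kwargs):
    """Thickness-asymmetry coefficient ``a`` of the critical mode.

    From the first-order fold ``y = theta^2 Y + A k F1(Y) cos(kx)`` the
    normalised gyral/sulcal thicknesses are ``1 +- a A`` with
    ``a = (k_c / theta_crit^2) (F1(0) - F1(1))`` under the normalisation
    of :func:`mode_shape`.  Positive ``a`` means gyri thicken.
    """
    if result is None:
        theta_c, k_c = critical_growth(beta, **kwargs)
        Y, F1 = mode_shape(beta, theta_c, k_c)
    else:
        theta_c, k_c, Y, F1 = result.theta_crit, result.k_crit, result.Y, result.F1
    i0 = int(np.argmin(np.abs(Y - 0.0)))
    a = (k_c / theta_c**2) * (F1[i0] - F1[-1])
    return float(a)


def analyze(beta, **kwargs) -> StabilityResult:
    """Full stability analysis: critical point, mode shape, asymmetry."""
    theta_c, k_c = critical_growth(beta, **kwargs)
    Y, F1 = mode_shape(beta, theta_c, k_c)
    res = StabilityResult(beta=beta, theta_crit=theta_c, k_crit=k_c,
                          a=0.0, Y=Y, F1=F1)
    a = asymmetry_coefficient(beta, result=res)
    return StabilityResult(beta=beta, theta_crit=theta_c, k_crit=k_c,
                           a=a, Y=Y, F1=F1)


def _plateau_gap(beta, k_probe=10.0, theta_B=None):
    """Signed gap ``theta_B - theta(k_probe)``.

    Positive when the dispersion curve dips below the Biot plateau at
    large wavenumber (a finite-wavelength folding minimum exists),
    negative when the curve approaches the plateau from above (the
    minimising wavenumber diverges).  Its root in beta is the folding
    threshold.
    """
    if theta_B is None:
        theta_B = biot_growth()
    th = theta_root_at_k(k_probe, beta, theta_range=(1.4, 2.2), n_grid=2000)
    if not np.isfinite(th):
        return -1.0
    return theta_B - th


def folding_threshold(bracket=(0.40, 0.70), k_probe=10.0, xtol=1e-4):
    """Stiffness ratio at which the asymmetry coefficient changes sign.

    On the finite-wavelength branch ``a > 0`` throughout; the branch
    terminates where the dispersion minimum merges into the zero-
    wavelength Biot plateau, and ``a`` ceases to exist there.  The
    threshold is computed as the root of the signed plateau gap.
    """
    theta_B = biot_growth()
    f = lambda b: _plateau_gap(b, k_probe=k_probe, theta_B=theta_B)
    a, b = bracket
    fa, fb = f(a), f(b)
    if fa * fb > 0:
        raise RuntimeError(
            f"folding-threshold bracket failure: gap({a})={fa:.2e}, "
            f"gap({b})={fb:.2e}"
        )
    return float(brentq(f, a, b, xtol=xtol))


def biot_limit(bracket=(0.40, 0.70), k_edge=20.0, n_k=60, xtol=2e-3):
    """Stiffness ratio below which the critical wavenumber diverges.

    Bisects on whether the wavenumber minimising theta(k) over the scan
    window sits in the interior (finite-wavelength folding) or at the
    upper edge (zero-wavelength Biot regime).
    """

    def interior(beta):
        ks, ths = scan_dispersion(beta, theta_range=(1.4, 2.2),
                                  k_range=(0.3, k_edge), n_theta=1200, n_k=n_k)
        if not np.isfinite(ths).any():
            return False
        return int(np.nanargmin(ths)) < len(ks) - 1

    a, b = bracket
    if interior(a) or not interior(b):
        raise RuntimeError("biot-limit bracket failure")
    while b - a > xtol:
        c = 0.5 * (a + b)
        if interior(c):
            b = c
        else:
            a = c
    return 0.5 * (a + b)


def fold_profile(theta_crit, k, A, Y, F1) -> FoldProfile:
    """First-order fold profile object (callable as ``y(x, Y)``)."""
    return FoldProfile(theta=theta_crit, k=k, A=A,
                       Y=np.asarray(Y, float), F1=np.asarray(F1, float))


def thickness_asymmetry(a, A):
    """Normalised gyral/sulcal thicknesses and their relative difference.

    Returns ``(t_g, t_s, kappa)`` with ``t_g = 1 + aA``, ``t_s = 1 - aA``
    and ``kappa = (t_g - t_s)/(t_g + t_s) = aA``; thicknesses are
    normalised by the onset thickness ``theta_crit^2``.
    """
    aA = a * A
    if abs(aA) >= 1:
        import warnings

        warnings.warn("a*A >= 1: outside the linear post-buckling regime",
                      stacklevel=2)
    return 1.0 + aA, 1.0 - aA, aA
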