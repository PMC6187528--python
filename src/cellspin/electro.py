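"""Electrorotation physics: Clausius-Mossotti factor and torque balance.

A polarisable sphere of radius ``r`` in a medium of complex permittivity
``eps_m*`` under an AC field of angular frequency ``omega`` experiences a
rotational torque proportional to the imaginary part of the
Clausius-Mossotti (CM) factor

    K(omega) = (eps_p* - eps_m*) / (eps_p* + 2 eps_m*),
    eps*     = eps - j sigma / omega.

At steady state the driving torque 4 pi r^3 eps_m Im[K] E_rms^2 balances
the Stokes drag torque 8 pi eta V r^3, giving the rotation rate

    V = eps_m * Im[K(omega)] * E_rms^2 / (2 eta)     [rad/s].

Inverting this yields Im[K] from a measured rotation rate, and two
measurements at distinct frequencies constrain the cell's own permittivity
and conductivity (homogeneous single-shell-free sphere model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.constants import epsilon_0

__all__ = [
    "DielectricSpec",
    "RotationConditions",
    "NoSolutionError",
    "complex_permittivity",
    "cm_factor",
    "steady_state_velocity",
    "imag_cm_from_velocity",
    "solve_cell_dielectrics",
]

#: default search bounds for the cell dielectric inversion (SI units):
#: permittivity from vacuum to 100x the relative permittivity of water,
#: conductivity over the physiological-to-saline range
EPS_BOUNDS = (epsilon_0, 100 * 80 * epsilon_0)
SIGMA_BOUNDS = (1e-6, 10.0)


class NoSolutionError(RuntimeError):
    """No physical (eps_p, sigma_p) reproduces the measured velocities."""


@dataclass(frozen=True)
class DielectricSpec:
    """Real permittivity ``eps`` (F/m) and conductivity ``sigma`` (S/m).

    ``relative=True`` interprets ``eps`` as a relative permittivity and
    multiplies by the vacuum permittivity.
    """

    eps: float
    sigma: float

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError(f"permittivity must be positive, got {self.eps}")
        if self.sigma < 0:
            raise ValueError(f"conductivity must be non-negative, got {self.sigma}")

    @classmethod
    def from_relative(cls, eps_rel: float, sigma: float) -> "DielectricSpec":
        return cls(eps=eps_rel * epsilon_0, sigma=sigma)


@dataclass(frozen=True)
class RotationConditions:
    """Experimental constants: cell radius ``r`` (m), medium viscosity
    ``eta`` (Pa s), RMS field strength ``e_rms`` (V/m), angular frequency
    ``omega`` (rad/s)."""

    r: float
    eta: float
    e_rms: float
    omega: float

    def __post_init__(self) -> None:
        for name in ("r", "eta", "e_rms", "omega"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def complex_permittivity(spec: DielectricSpec, omega: float) -> complex:
    """eps* = eps - j sigma / omega at angular frequency ``omega``."""
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    return complex(spec.eps, -spec.sigma / omega)


def cm_factor(cell: DielectricSpec, medium: DielectricSpec, omega: float) -> complex:
    """Clausius-Mossotti factor K(omega) of a homogeneous sphere.

    For physical specs (eps > 0, sigma >= 0) the real part lies in
    [-1/2, 1]. Raises ``ZeroDivisionError`` if the denominator vanishes.
    """
    ep = complex_permittivity(cell, omega)
    em = complex_permittivity(medium, omega)
    den = ep + 2 * em
    if abs(den) == 0:
        raise ZeroDivisionError("CM denominator eps_p* + 2 eps_m* vanishes")
    return (ep - em) / den


def steady_state_velocity(cell: DielectricSpec, medium: DielectricSpec,
                          cond: RotationConditions) -> float:
    """Steady electrorotation rate (rad/s) from the torque balance.

    4 pi r^3 eps_m Im[K] E^2 = 8 pi eta V r^3 gives
    V = eps_m Im[K] E_rms^2 / (2 eta); the sign of V follows Im[K].
    """
    im_k = cm_factor(cell, medium, cond.omega).imag
    return medium.eps * im_k * cond.e_rms ** 2 / (2.0 * cond.eta)


def imag_cm_from_velocity(v_meas: float, medium: DielectricSpec,
                          cond: RotationConditions) -> float:
    """Invert the torque balance: Im[K] = 2 eta V / (eps_m E_rms^2).

    Exact algebraic inverse of :func:`steady_state_velocity`.
    """
    return 2.0 * cond.eta * v_meas / (medium.eps * cond.e_rms ** 2)


def solve_cell_dielectrics(
    meas: list[tuple[float, float]],
    medium: DielectricSpec,
    cond: RotationConditions,
    eps_bounds: tuple[float, float] = EPS_BOUNDS,
    sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
    rel_tol: float = 1e-6,
) -> DielectricSpec:
    """Recover the cell's (eps_p, sigma_p) from rotation rates measured at
    two distinct frequencies.

    Each measurement ``(omega_k, V_k)`` pins Im[K(omega_k)] through the
    torque balance; the two resulting equations are solved for the cell
    spec by bounded least squares in log-parameter space from a grid of
    starts. The physical root with the smallest residual is returned; a
    residual above ``rel_tol`` (relative to the Im[K] magnitudes) raises
    :class:`NoSolutionError` with the residual report, and multiple
    distinct near-zero roots trigger a warning.
    """
    if len(meas) != 2:
        raise ValueError("exactly two (omega, V) measurements are required")
    (w1, v1), (w2, v2) = meas
    if w1 == w2:
        raise ValueError("the two measurement frequencies must be distinct")
    targets = np.array([
        imag_cm_from_velocity(v1, medium, RotationConditions(
            cond.r, cond.eta, cond.e_rms, w1)),
        imag_cm_from_velocity(v2, medium, RotationConditions(
            cond.r, cond.eta, cond.e_rms, w2)),
    ])
    omegas = (w1, w2)
    lb = np.log(np.array([eps_bounds[0], sigma_bounds[0]]))
    ub = np.log(np.array([eps_bounds[1], sigma_bounds[1]]))

    def resid(logx: np.ndarray) -> np.ndarray:
        eps_p, sig_p = np.exp(logx)
        spec = DielectricSpec(eps=eps_p, sigma=sig_p)
        return np.array([
            cm_factor(spec, medium, w).imag - t for w, t in zip(omegas, targets)
        ])

    scale = max(float(np.max(np.abs(targets))), 1e-12)
    roots: list[tuple[float, np.ndarray]] = []
    for le in np.linspace(lb[0], ub[0], 5):
        for ls in np.linspace(lb[1], ub[1], 5):
            sol = optimize.least_squares(resid, x0=[le, ls], bounds=(lb, ub),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
            roots.append((float(np.linalg.norm(sol.fun)), sol.x))
    roots.sort(key=lambda t: t[0])
    best_res, best_x = roots[0]
    if best_res > rel_tol * scale:
        raise NoSolutionError(
            f"no (eps_p, sigma_p) within bounds reproduces the measurements; "
            f"best residual {best_res:.3e} on Im[K] scale {scale:.3e}"
        )
    good = [x for res, x in roots if res <= rel_tol * scale]
    distinct = {tuple(np.round(x, 3)) for x in good}
    if len(distinct) > 1:
        warnings.warn(
            "multiple dielectric roots fit the two measurements; returning "
            "the one with the smallest residual", stacklevel=2)
    eps_p, sig_p = np.exp(best_x)
    return DielectricSpec(eps=float(eps_p), sigma=float(sig_p))
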