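"""Closed-form continuum-limit toolkit.

In the continuum limit the molecule concentration n(x, t) obeys a
reaction-diffusion equation with Dirichlet (absorbing) boundary conditions
n(b_-, t) = n(b_+, t) = 0.  For a constant uniform force the steady state is

    nbar(x) = rho (lambda1/lambda2) (sigma/sigma_ref)
              * (1 - cosh(x/Lambda_D)/cosh(L/(2 Lambda_D)))

and the steady boundary fluxes J = -+ D dn/dx(b_+-) are equal at both ends.
Requiring the flux to equal the reference value J0 gives an effective
Wolff's law F(L): the force under which a wall of width L is homeostatic.
This module evaluates those steady states, the force-length laws for both
stimulus modes, the full-resorption threshold, the quasi-steady profile and
boundary fluxes under an affine force gradient, and the boundary-dynamics
phase portrait of the instantaneous cell model.

Hyperbolic expressions are evaluated in overflow-safe form so that walls
much wider than the diffusion length are handled correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .mechanics import stress
from .parameters import ModelParams

__all__ = [
    "ContinuumSteady",
    "steady_profile_uniform",
    "steady_flux_uniform",
    "force_length_stress",
    "force_length_sed",
    "full_resorption_threshold",
    "invert_force_length",
    "quasi_steady_profile_gradient",
    "gradient_boundary_fluxes",
    "coincident_boundary_flux_limit",
    "gradient_homeostatic_point",
    "phase_portrait_velocity",
]


@dataclass(frozen=True)
class ContinuumSteady:
    """A (quasi-)steady continuum state on [b_minus, b_plus].

    ``n_profile`` maps position (um) to concentration (molecules/um) and
    vanishes at both boundaries; ``sigma_profile`` maps position to stress
    (MPa); ``J_minus``/``J_plus`` are the outgoing boundary fluxes (/day).
    """

    b_minus: float
    b_plus: float
    n_profile: Callable[[np.ndarray], np.ndarray]
    sigma_profile: Callable[[np.ndarray], np.ndarray]
    J_minus: float
    J_plus: float

    @property
    def L(self) -> float:
        return self.b_plus - self.b_minus


def _cosh_ratio(a: float | np.ndarray, b: float) -> float | np.ndarray:
    """cosh(a)/cosh(b) without overflow, for |a| <= b; exactly even in a."""
    a = np.abs(np.asarray(a, dtype=float))
    return np.exp(a - b) * (1.0 + np.exp(-2.0 * a)) / (1.0 + math.exp(-2.0 * b))


def _sinh_ratio(a: float | np.ndarray, b: float) -> float | np.ndarray:
    """sinh(a)/sinh(b) without overflow, for 0 <= a <= b."""
    a = np.asarray(a, dtype=float)
    return np.exp(a - b) * (1.0 - np.exp(-2.0 * a)) / (1.0 - math.exp(-2.0 * b))


def _coth(b: float) -> float:
    """coth(b) for b > 0, stable for large b."""
    return 1.0 + 2.0 / math.expm1(2.0 * b)


def steady_profile_uniform(L: float, F: float, params: ModelParams) -> ContinuumSteady:
    """Steady concentration profile under a uniform force on [-L/2, L/2]."""
    if L <= 0.0:
        raise ValueError("L must be > 0")
    sigma = stress(F, -L / 2.0, L / 2.0, params.W)
    lam = params.diffusion_length
    amp = params.rho * params.lambda1 / params.lambda2 * sigma / params.sigma_ref
    half = L / (2.0 * lam)

    def n_profile(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return amp * (1.0 - _cosh_ratio(x / lam, half))

    J = steady_flux_uniform(L, F, params)
    return ContinuumSteady(
        b_minus=-L / 2.0,
        b_plus=L / 2.0,
        n_profile=n_profile,
        sigma_profile=lambda x: np.full_like(np.asarray(x, dtype=float), sigma),
        J_minus=J,
        J_plus=J,
    )


def steady_flux_uniform(L: float, F: float, params: ModelParams) -> float:
    """Steady outgoing boundary flux (equal at both ends), /day."""
    if L <= 0.0:
        raise ValueError("L must be > 0")
    lam = params.diffusion_length
    return (
        params.rho * params.lambda1 * lam
        * (F / params.F_ref) / (L / params.L_ref)
        * math.tanh(L / (2.0 * lam))
    )


def full_resorption_threshold(params: ModelParams) -> float:
    """The L -> 0 limit of the stress-mode force-length law, N.

    Below this force no homeostatic wall width exists under the stress
    stimulus and the bone is fully resorbed.
    """
    lam = params.diffusion_length
    return 2.0 * lam * params.F_ref / params.L_ref * math.tanh(params.L_ref / (2.0 * lam))


def force_length_stress(L: float, params: ModelParams) -> float:
    """Homeostatic force for wall width L under the stress stimulus, N.

    F(L) = F_ref * (L/L_ref) * tanh(L_ref/(2 Lambda_D)) / tanh(L/(2 Lambda_D));
    the L=0 value is the full-resorption threshold (finite limit).
    """
    if L < 0.0:
        raise ValueError("L must be >= 0")
    if L == 0.0:
        return full_resorption_threshold(params)
    lam = params.diffusion_length
    return (
        params.F_ref * (L / params.L_ref)
        * math.tanh(params.L_ref / (2.0 * lam)) / math.tanh(L / (2.0 * lam))
    )


def force_length_sed(L: float, params: ModelParams) -> float:
    """Homeostatic force for wall width L under the strain-energy stimulus, N.

    F(L) = F_ref * (L/L_ref) * sqrt(tanh(L_ref/(2 Lambda_D))/tanh(L/(2 Lambda_D)));
    F ~ sqrt(L) for small L, so F(0) = 0 and arbitrarily small loads retain
    a nonzero homeostatic width.
    """
    if L < 0.0:
        raise ValueError("L must be >= 0")
    if L == 0.0:
        return 0.0
    lam = params.diffusion_length
    ratio = math.tanh(params.L_ref / (2.0 * lam)) / math.tanh(L / (2.0 * lam))
    return params.F_ref * (L / params.L_ref) * math.sqrt(ratio)


def invert_force_length(
    F: float, mode: str, params: ModelParams, L_max: float | None = None
) -> float | None:
    """Homeostatic wall width L for force F (the effective Wolff's law L(F)).

    Returns ``None`` ("no solution: full resorption") in stress mode when F
    is at or below the full-resorption threshold, and 0.0 in sed mode when
    F = 0.  Uses a bracketed root find on (0, L_max] (default 10*L_ref) at
    1e-9 relative tolerance.
    """
    if F < 0.0:
        raise ValueError("F must be >= 0")
    if L_max is None:
        L_max = 10.0 * params.L_ref
    if mode == "stress":
        law = force_length_stress
        if F <= full_resorption_threshold(params):
            return None
    elif mode == "sed":
        law = force_length_sed
        if F == 0.0:
            return 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    F_hi = law(L_max, params)
    if F > F_hi:
        raise ValueError(
            f"F = {F} exceeds the force-length law at L_max = {L_max} "
            f"(F(L_max) = {F_hi}); enlarge L_max"
        )
    lo = 1.0e-9 * params.L_ref
    return brentq(lambda L: law(L, params) - F, lo, L_max, rtol=1.0e-9)


def _sigma_over_ref(x: np.ndarray, b_minus: float, b_plus: float,
                    F_base: float, F_x: float, params: ModelParams) -> np.ndarray:
    """Normalised stress sigma(x)/sigma_ref under the affine force field."""
    x = np.asarray(x, dtype=float)
    L = b_plus - b_minus
    return (F_base + F_x * x) * params.L_ref / (L * params.F_ref)


def quasi_steady_profile_gradient(
    b_minus: float, b_plus: float, F_base: float, F_x: float, params: ModelParams
) -> ContinuumSteady:
    """Quasi-steady profile under F(x) = F_base + F_x*x on [b_minus, b_plus].

    The boundaries are treated as frozen (they move slowly compared to
    molecular signalling).  With F_x = 0 and b_+- = +-L/2 this reduces
    pointwise to the uniform steady profile.
    """
    if b_plus <= b_minus:
        raise ValueError("b_plus must exceed b_minus")
    lam = params.diffusion_length
    Lb = b_plus - b_minus
    pref = params.rho * params.lambda1 / params.lambda2
    s_minus = float(_sigma_over_ref(b_minus, b_minus, b_plus, F_base, F_x, params))
    s_plus = float(_sigma_over_ref(b_plus, b_minus, b_plus, F_base, F_x, params))

    def n_profile(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        s = _sigma_over_ref(x, b_minus, b_plus, F_base, F_x, params)
        return pref * (
            s
            - s_plus * _sinh_ratio((x - b_minus) / lam, Lb / lam)
            - s_minus * _sinh_ratio((b_plus - x) / lam, Lb / lam)
        )

    J_minus, J_plus = gradient_boundary_fluxes(b_minus, b_plus, F_base, F_x, params)

    def sigma_profile(x: np.ndarray) -> np.ndarray:
        return _sigma_over_ref(x, b_minus, b_plus, F_base, F_x, params) * params.sigma_ref

    return ContinuumSteady(b_minus, b_plus, n_profile, sigma_profile, J_minus, J_plus)


def gradient_boundary_fluxes(
    b_minus: float, b_plus: float, F_base: float, F_x: float, params: ModelParams
) -> tuple[float, float]:
    """Outgoing boundary fluxes (J_minus, J_plus) of the quasi-steady profile.

    Unlike the uniform case these depend on b_minus and b_plus individually,
    not only on the width b_plus - b_minus.
    """
    if b_plus <= b_minus:
        raise ValueError("b_plus must exceed b_minus")
    lam = params.diffusion_length
    Lb = b_plus - b_minus
    z = Lb / lam
    # Cancellation-free regrouping of the coth/csch terms: with
    # c = L_ref/(Lb*F_ref) and P = D*rho*lambda1/lambda2,
    #   J_- = P*c*( F_x*(1 - z*csch(z)) + (F_base + F_x*b_-)*tanh(z/2)/lam )
    #   J_+ = P*c*( (F_base + F_x*b_+)*tanh(z/2)/lam - F_x*(1 - z*csch(z)) )
    # which is exact and stable for Lb << lam (both factors vanish ~ z) and
    # for Lb >> lam (no overflow).
    pref = params.D * params.rho * params.lambda1 / params.lambda2
    c = params.L_ref / (Lb * params.F_ref)
    if z < 1.0e-3:
        one_minus_zcsch = z * z / 6.0 - 7.0 * z**4 / 360.0
    else:
        zcsch = 2.0 * z * math.exp(-z) / (1.0 - math.exp(-2.0 * z))
        one_minus_zcsch = 1.0 - zcsch
    th = math.tanh(z / 2.0) / lam
    J_minus = pref * c * (F_x * one_minus_zcsch + (F_base + F_x * b_minus) * th)
    J_plus = pref * c * ((F_base + F_x * b_plus) * th - F_x * one_minus_zcsch)
    return J_minus, J_plus


def coincident_boundary_flux_limit(
    b: float, F_base: float, F_x: float, params: ModelParams
) -> float:
    """Limit of both boundary fluxes as the wall width shrinks to zero at b.

    J = rho*lambda1*L_ref/(2 F_ref) * (F_base + F_x*b); linear in b.
    """
    return params.rho * params.lambda1 * params.L_ref / (2.0 * params.F_ref) * (
        F_base + F_x * b
    )


def gradient_homeostatic_point(F_base: float, F_x: float, params: ModelParams) -> float:
    """The unique coincident-boundary homeostatic position b under a gradient.

    Solves F_base + F_x*b = full-resorption threshold: the only point where
    both boundary fluxes can equal J0 is a zero-width wall located where the
    local force equals the threshold.
    """
    if F_x == 0.0:
        raise ValueError("F_x = 0: no unique homeostatic point under a uniform force")
    return (full_resorption_threshold(params) - F_base) / F_x


def phase_portrait_velocity(
    b_minus: float, b_plus: float, v_speed: float,
    F_base: float, F_x: float, params: ModelParams,
) -> tuple[float, float]:
    """Boundary velocities (db_minus/dt, db_plus/dt) um/day.

    Continuum limit of the instantaneous cell model with equal formation and
    resorption speeds v_speed, on the quasi-steady gradient fluxes:
    db_+/dt = v*(J_+ - J0)/J0 and db_-/dt = -v*(J_- - J0)/J0.  The signs
    follow from the boundary evolution law (formation extends the wall
    outward on both sides), so an excess flux moves b_- left and b_+ right.
    """
    J0 = params.reference_flux
    J_minus, J_plus = gradient_boundary_fluxes(b_minus, b_plus, F_base, F_x, params)
    return (
        -v_speed * (J_minus - J0) / J0,
        v_speed * (J_plus - J0) / J0,
    )
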