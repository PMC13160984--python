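"""Model constants, unit conventions and the calibration chain.

All quantities are held in a single internal unit system:

====================  ========
length                um
time                  day
force                 N
stress / energy dens  MPa
molecule counts       dimensionless (deterministic expected counts)
====================  ========

Every unit conversion used by the package is centralised here
(``MPA_PER_N_PER_UM2``, ``N_PER_MPA_UM2``, ``SECONDS_PER_DAY``), because the
source quantities are naturally quoted in a mix of mm^2/day, um^2/s, MPa and N.

Derived quantities -- the diffusivity ``D``, the diffusion length ``Lambda_D``
and the reference boundary flux ``J0`` -- are always *computed* from the
primitive parameters, never hand-entered, so the primitive and derived
constants cannot drift apart.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = [
    "ModelParams",
    "ParameterError",
    "derive_diffusivity",
    "derive_velocity",
    "derive_diffusion_length",
    "derive_reference_force",
    "calibrate_reference_flux",
    "rms_displacement",
    "validate_params",
    "MPA_PER_N_PER_UM2",
    "N_PER_MPA_UM2",
    "SECONDS_PER_DAY",
]

#: 1 N/um^2 = 1e12 Pa = 1e6 MPa.
MPA_PER_N_PER_UM2 = 1.0e6
#: 1 MPa * um^2 = 1e-6 N.
N_PER_MPA_UM2 = 1.0e-6
SECONDS_PER_DAY = 86400.0

STIMULUS_MODES = ("stress", "sed")
CELL_MODELS = ("instantaneous", "differential")


class ParameterError(ValueError):
    """A model-parameter invariant is violated; message names the invariant."""


@dataclass(frozen=True)
class ModelParams:
    """All model constants.

    Defaults are the calibrated reference parameter set for a mouse tibia
    cortical-wall slice (osteocyte spacing 10 um, reference wall width
    200 um, reference stress 10 MPa).  Fields left at ``None`` (only ``J0``)
    are derived by :func:`validate_params`.

    Attributes
    ----------
    dx : float
        Osteocyte spacing, um.
    dt : float
        Time step, day.
    q_left, q_stay, q_right : float
        Fractions of a site's molecules that jump left, stay, jump right in
        one time step.  Must sum to 1.
    lambda1, lambda2 : float
        Molecule creation and degradation rates, /day.
    W : float
        Lateral width of the slice, um.
    L_ref, F_ref, sigma_ref, psi_ref : float
        Reference wall width (um), force (N), stress (MPa) and strain energy
        density (MPa) tied together by sigma_ref = F_ref/(L_ref*W) and
        psi_ref = sigma_ref^2/(2E).
    E : float
        Young's modulus, MPa.
    J0 : float or None
        Reference boundary flux, /day; boundaries are stationary when the
        molecule flux equals J0.  Derived from the calibration constraint
        when None.
    kf, kr : float
        Bone formed/resorbed per cell per day, um/day.
    vf, vr : float
        Formation/resorption speeds of the instantaneous cell model, um/day.
    alpha_ob, alpha_oc, A_ob, A_oc : float
        Osteoblast/osteoclast creation and elimination rates, /day.
    stimulus_mode : str
        ``"stress"`` or ``"sed"`` (strain energy density).
    cell_model : str
        ``"instantaneous"`` or ``"differential"``.
    """

    dx: float = 10.0
    dt: float = 1.0e-5
    q_left: float = 0.32
    q_stay: float = 0.36
    q_right: float = 0.32
    lambda1: float = 11_059_200.0
    lambda2: float = 320.0
    W: float = 20.0
    L_ref: float = 200.0
    F_ref: float = 0.04
    sigma_ref: float = 10.0
    psi_ref: float = 5.0e-3
    E: float = 1.0e4
    J0: float | None = None
    kf: float = 20.0
    kr: float = 100.0
    vf: float = 10.0
    vr: float = 10.0
    alpha_ob: float = 0.04
    alpha_oc: float = 0.2
    A_ob: float = 0.2
    A_oc: float = 1.0
    stimulus_mode: str = "stress"
    cell_model: str = "differential"

    # -- derived, read-only -------------------------------------------------

    @property
    def rho(self) -> float:
        """Osteocyte density, /um.  Tied exactly to the spacing: rho*dx = 1."""
        return 1.0 / self.dx

    @property
    def D(self) -> float:
        """Continuum-limit diffusivity, um^2/day."""
        return derive_diffusivity(self)

    @property
    def diffusion_length(self) -> float:
        """Diffusion length Lambda_D = sqrt(D/lambda2), um."""
        return derive_diffusion_length(self.D, self.lambda2)

    @property
    def reference_flux(self) -> float:
        """J0, /day: the configured value if set, else the calibrated one."""
        if self.J0 is not None:
            return self.J0
        return calibrate_reference_flux(self)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, config: dict[str, Any]) -> "ModelParams":
        """Build from a configuration dict; unspecified keys keep defaults."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(config) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return validate_params(cls(**config))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)


def derive_diffusivity(params: ModelParams) -> float:
    """Continuum-limit diffusivity D = dx^2/(2 dt) * (q_left + q_right), um^2/day."""
    _check_jump_fractions(params)
    return params.dx**2 / (2.0 * params.dt) * (params.q_left + params.q_right)


def derive_velocity(params: ModelParams) -> float:
    """Continuum-limit advective velocity v = dx/dt * (q_right - q_left), um/day.

    Valid for spatially homogeneous jump fractions (the dD/dx term vanishes).
    """
    return params.dx / params.dt * (params.q_right - params.q_left)


def derive_diffusion_length(D: float, lambda2: float) -> float:
    """Diffusion length Lambda_D = sqrt(D/lambda2), um.

    The mean distance a molecule diffuses during its lifetime 1/lambda2; it
    sets the signalling range of the osteocyte network.
    """
    if D <= 0.0:
        raise ParameterError("diffusivity: D must be > 0")
    if lambda2 <= 0.0:
        raise ParameterError("degradation rate: lambda2 must be > 0")
    return math.sqrt(D / lambda2)


def derive_reference_force(sigma_ref: float, L_ref: float, W: float) -> float:
    """Force (N) producing the reference stress: F = sigma_ref * L_ref * W.

    sigma_ref in MPa, lengths in um; the MPa*um^2 -> N conversion is applied.
    """
    return sigma_ref * L_ref * W * N_PER_MPA_UM2


def calibrate_reference_flux(params: ModelParams) -> float:
    """Reference boundary flux J0 = rho*lambda1*Lambda_D*tanh(L_ref/(2 Lambda_D)).

    This is the unique J0 for which the homeostatic force-length law passes
    through the reference point (L_ref, F_ref), i.e. a wall of reference
    width loaded by the reference force is stationary in the continuum limit.
    """
    lam = params.diffusion_length
    return params.rho * params.lambda1 * lam * math.tanh(params.L_ref / (2.0 * lam))


def rms_displacement(params: ModelParams, seconds: float = 1.0) -> float:
    """Diffusive root-mean-square displacement sqrt(2 D t) over `seconds`, um."""
    D_per_s = params.D / SECONDS_PER_DAY
    return math.sqrt(2.0 * D_per_s * seconds)


def _check_jump_fractions(params: ModelParams) -> None:
    q = (params.q_left, params.q_stay, params.q_right)
    if any(qi < 0.0 or qi > 1.0 for qi in q):
        raise ParameterError("jump fractions: each of q_left, q_stay, q_right must lie in [0, 1]")
    if abs(sum(q) - 1.0) > 1.0e-12:
        raise ParameterError(f"jump fractions: q_left + q_stay + q_right = {sum(q)!r}, must equal 1")


def validate_params(params: ModelParams) -> ModelParams:
    """Check every invariant and populate derived fields.

    Returns a new :class:`ModelParams` with ``J0`` filled in from the
    calibration constraint if it was unset.  A configured ``J0`` deviating
    from the calibrated value by more than 0.01% is rejected as inconsistent.

    Raises
    ------
    ParameterError
        Naming the first violated invariant.
    """
    _check_jump_fractions(params)
    positive = {
        "dx": params.dx, "dt": params.dt,
        "lambda1": params.lambda1, "lambda2": params.lambda2,
        "W": params.W, "L_ref": params.L_ref, "F_ref": params.F_ref,
        "sigma_ref": params.sigma_ref, "psi_ref": params.psi_ref, "E": params.E,
        "kf": params.kf, "kr": params.kr, "vf": params.vf, "vr": params.vr,
        "alpha_ob": params.alpha_ob, "alpha_oc": params.alpha_oc,
        "A_ob": params.A_ob, "A_oc": params.A_oc,
    }
    for name, value in positive.items():
        if not value > 0.0 or not math.isfinite(value):
            raise ParameterError(f"{name}: must be strictly positive and finite")
    if params.lambda2 * params.dt >= 1.0:
        raise ParameterError("positivity guard: lambda2*dt must be < 1 for the explicit update")
    if params.A_ob * params.dt >= 1.0 or params.A_oc * params.dt >= 1.0:
        raise ParameterError("positivity guard: A_ob*dt and A_oc*dt must be < 1")
    if params.stimulus_mode not in STIMULUS_MODES:
        raise ParameterError(f"stimulus_mode: must be one of {STIMULUS_MODES}")
    if params.cell_model not in CELL_MODELS:
        raise ParameterError(f"cell_model: must be one of {CELL_MODELS}")

    j0_cal = calibrate_reference_flux(params)
    if params.J0 is None:
        return params.replace(J0=j0_cal)
    if abs(params.J0 - j0_cal) > 1.0e-4 * j0_cal:
        raise ParameterError(
            f"J0: configured value {params.J0!r} conflicts with the calibration "
            f"constraint ({j0_cal!r}) by more than 0.01%"
        )
    return params


def derived_parameter_table(params: ModelParams) -> dict[str, float]:
    """The calibration chain as a name -> value mapping (internal units)."""
    return {
        "D_um2_per_day": params.D,
        "D_mm2_per_day": params.D * 1.0e-6,
        "v_um_per_day": derive_velocity(params),
        "Lambda_D_um": params.diffusion_length,
        "rho_per_um": params.rho,
        "F_ref_N": derive_reference_force(params.sigma_ref, params.L_ref, params.W),
        "psi_ref_MPa": params.sigma_ref**2 / (2.0 * params.E),
        "J0_per_day": params.reference_flux,
        "J0_over_lambda1": params.reference_flux / params.lambda1,
        "rms_displacement_1s_um": rms_displacement(params, 1.0),
    }
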