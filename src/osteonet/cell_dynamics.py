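"""Osteoblast/osteoclast response to boundary fluxes and boundary motion.

Two cell-generation models translate the signalling-molecule flux J at a
bone surface into bone-forming (osteoblast) and bone-resorbing (osteoclast)
activity, relative to the reference flux J0:

* instantaneous: the formation/resorption *speed* is directly proportional
  to the positive part of the relative flux excess/deficit.  At most one is
  nonzero at a time.
* differential (default): the *rate of change* of the cell populations is
  proportional to the flux excess/deficit, with first-order elimination.
  Populations are continuous non-negative reals (averages over a
  representative surface patch) and both kinds may coexist transiently.

Boundary motion: b_minus retreats (formation) or advances (resorption) with
speed kf*Ob - kr*Oc, mirrored at b_plus.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ModelParams

__all__ = [
    "CellState",
    "TotalResorption",
    "instantaneous_cell_rates",
    "differential_cells_step",
    "update_boundaries",
]


class TotalResorption(Exception):
    """Raised when a boundary update makes the boundaries cross."""


@dataclass(frozen=True)
class CellState:
    """Osteoblast/osteoclast populations at each boundary (cells, >= 0)."""

    ob_minus: float = 0.0
    ob_plus: float = 0.0
    oc_minus: float = 0.0
    oc_plus: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ob_minus", "ob_plus", "oc_minus", "oc_plus"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")


def _pos(x: float) -> float:
    return x if x > 0.0 else 0.0


def instantaneous_cell_rates(J: float, params: ModelParams) -> tuple[float, float]:
    """Formation and resorption speeds (um/day) at flux J, instantaneous model.

    formation = vf * [(J - J0)/J0]^+, resorption = vr * [(J0 - J)/J0]^+;
    at most one is nonzero.
    """
    J0 = params.reference_flux
    if J0 <= 0.0:
        raise ValueError("reference flux J0 must be > 0")
    rel = (J - J0) / J0
    return params.vf * _pos(rel), params.vr * _pos(-rel)


def differential_cells_step(
    cells: CellState, J_minus: float, J_plus: float, params: ModelParams
) -> CellState:
    """One explicit Euler step of the differential cell model at the global dt.

    Ob += alpha_ob*[(J - J0)/J0]^+ dt - A_ob*Ob dt (per boundary), and the
    osteoclast update mirrors it with the flux deficit.  The explicit update
    preserves non-negativity provided A_ob*dt < 1 and A_oc*dt < 1.
    """
    dt = params.dt
    if params.A_ob * dt >= 1.0 or params.A_oc * dt >= 1.0:
        raise ValueError("stability: A_ob*dt and A_oc*dt must be < 1")
    J0 = params.reference_flux
    rel_m = (J_minus - J0) / J0
    rel_p = (J_plus - J0) / J0
    return CellState(
        ob_minus=cells.ob_minus + (params.alpha_ob * _pos(rel_m) - params.A_ob * cells.ob_minus) * dt,
        ob_plus=cells.ob_plus + (params.alpha_ob * _pos(rel_p) - params.A_ob * cells.ob_plus) * dt,
        oc_minus=cells.oc_minus + (params.alpha_oc * _pos(-rel_m) - params.A_oc * cells.oc_minus) * dt,
        oc_plus=cells.oc_plus + (params.alpha_oc * _pos(-rel_p) - params.A_oc * cells.oc_plus) * dt,
    )


def update_boundaries(
    b_minus: float,
    b_plus: float,
    cells_or_rates: CellState | tuple[tuple[float, float], tuple[float, float]],
    params: ModelParams,
) -> tuple[float, float]:
    """Advance the boundaries by one time step.

    ``cells_or_rates`` is either a :class:`CellState` (differential model:
    net speed kf*Ob - kr*Oc per boundary) or a pair
    ``((formation_minus, resorption_minus), (formation_plus, resorption_plus))``
    of speeds in um/day (instantaneous model).

    Raises
    ------
    TotalResorption
        If the updated boundaries cross (zero or negative wall width).
    """
    dt = params.dt
    if isinstance(cells_or_rates, CellState):
        v_minus = params.kf * cells_or_rates.ob_minus - params.kr * cells_or_rates.oc_minus
        v_plus = params.kf * cells_or_rates.ob_plus - params.kr * cells_or_rates.oc_plus
    else:
        (form_m, res_m), (form_p, res_p) = cells_or_rates
        v_minus = form_m - res_m
        v_plus = form_p - res_p
    new_b_minus = b_minus - v_minus * dt
    new_b_plus = b_plus + v_plus * dt
    if new_b_minus >= new_b_plus:
        raise TotalResorption(
            f"boundaries crossed: b_minus={new_b_minus}, b_plus={new_b_plus}"
        )
    return new_b_minus, new_b_plus
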