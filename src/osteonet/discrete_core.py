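"""Dynamic osteocyte lattice: occupancy update, flux accounting, topology.

Osteocytes sit at lattice sites x_i = i*dx for i in [i_minus, i_plus].  Each
carries a continuous, non-negative molecule occupancy N_i (the deterministic
expected count of the underlying random walk).  Per step a fraction q_left
jumps left, q_right right, q_stay stays; jumps past the extreme osteocytes
are absorbed by the bone surface and accumulated in the outgoing counters.
Effectively the absorbing "ghost" sites sit at (i_minus-1)*dx and
(i_plus+1)*dx.

As the bone boundaries move, osteocytes are created (boundary advanced a
full spacing beyond the extreme osteocyte; new cell starts with zero
molecules) or removed (boundary moved onto/past the extreme osteocyte; its
molecules are freed to the same outgoing counter, producing the single-step
flux spike characteristic of resorption).

The functions here are the plain-NumPy reference implementation, one update
at a time; :mod:`osteonet.scenarios` drives a compiled kernel with identical
semantics for long runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .continuum import steady_profile_uniform
from .parameters import ModelParams

__all__ = [
    "NetworkState",
    "TopologyEvent",
    "init_state_from_continuum",
    "step_occupancies",
    "boundary_fluxes",
    "apply_boundary_motion_events",
]

logger = logging.getLogger(__name__)

LEFT, RIGHT = "left", "right"
CREATED, REMOVED = "created", "removed"


@dataclass(frozen=True)
class TopologyEvent:
    """Creation or removal of an osteocyte at one end of the network."""

    kind: str       # "created" | "removed"
    side: str       # "left" | "right"
    index: int      # lattice index of the affected osteocyte
    freed_molecules: float  # molecules released on removal (0 for creation)
    t: float        # day

    def __post_init__(self) -> None:
        if self.freed_molecules < 0.0:
            raise ValueError("freed_molecules must be >= 0")
        if self.kind == CREATED and self.freed_molecules != 0.0:
            raise ValueError("creation events free no molecules")


@dataclass
class NetworkState:
    """Lattice state at time t.

    ``occupancy[k]`` is the molecule count of osteocyte ``i_minus + k``;
    ``b_minus``/``b_plus`` are the continuous bone boundaries (um);
    ``cum_out_*`` are the cumulative molecules absorbed at each surface and
    ``last_out_*`` the same counters one step earlier (flux = difference/dt).
    """

    t: float
    i_minus: int
    i_plus: int
    occupancy: np.ndarray
    b_minus: float
    b_plus: float
    cum_out_minus: float = 0.0
    cum_out_plus: float = 0.0
    last_out_minus: float = 0.0
    last_out_plus: float = 0.0
    n_steps: int = 0

    @property
    def n_sites(self) -> int:
        return self.i_plus - self.i_minus + 1

    @property
    def L(self) -> float:
        return self.b_plus - self.b_minus

    def positions(self, dx: float) -> np.ndarray:
        """Osteocyte positions x_i = i*dx, um."""
        return np.arange(self.i_minus, self.i_plus + 1) * dx

    def total_molecules(self) -> float:
        return float(self.occupancy.sum())

    def check_registration(self, dx: float) -> None:
        """Assert the boundaries lie within one spacing of the extreme sites."""
        if not (self.i_plus * dx < self.b_plus <= (self.i_plus + 1) * dx):
            raise AssertionError(
                f"right registration violated: x_i+={self.i_plus * dx}, b_plus={self.b_plus}"
            )
        if not ((self.i_minus - 1) * dx <= self.b_minus < self.i_minus * dx):
            raise AssertionError(
                f"left registration violated: x_i-={self.i_minus * dx}, b_minus={self.b_minus}"
            )

    def copy(self) -> "NetworkState":
        return replace(self, occupancy=self.occupancy.copy())

    def write_snapshot(self, outdir, dx: float) -> None:
        """Write snapshot.csv (index, position_um, occupancy) and snapshot.json
        (t, boundaries, cumulative counters) into `outdir`."""
        import json
        from pathlib import Path

        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "index": np.arange(self.i_minus, self.i_plus + 1),
            "position_um": self.positions(dx),
            "occupancy": self.occupancy,
        }).to_csv(outdir / "snapshot.csv", index=False)
        header = {
            "t_day": self.t,
            "b_minus_um": self.b_minus,
            "b_plus_um": self.b_plus,
            "cum_out_minus": self.cum_out_minus,
            "cum_out_plus": self.cum_out_plus,
        }
        (outdir / "snapshot.json").write_text(json.dumps(header, indent=2))


def init_state_from_continuum(L0: float, F0: float, params: ModelParams) -> NetworkState:
    """Initial state: boundaries at +-L0/2, occupancies from the continuum steady state.

    Osteocytes occupy every lattice site strictly inside (-L0/2, L0/2); when
    L0 is a multiple of dx the absorbing ghost sites then coincide with the
    boundaries (e.g. L0=200, dx=10: 19 osteocytes at -90..90 um).  Each site
    starts with N_i = dx * nbar(x_i), the lattice load of the continuum
    steady concentration at (L0, F0).  Counters start at zero.
    """
    dx = params.dx
    if L0 <= 2.0 * dx:
        raise ValueError(f"L0 = {L0} must exceed 2*dx = {2 * dx}")
    half = L0 / 2.0
    i_minus = math.floor(-half / dx) + 1
    i_plus = math.ceil(half / dx) - 1
    # floor/ceil land on the boundary itself when L0 is a lattice multiple;
    # "strictly inside" excludes sites exactly at +-L0/2.
    if i_minus * dx <= -half:
        i_minus += 1
    if i_plus * dx >= half:
        i_plus -= 1
    if i_plus < i_minus:
        raise ValueError(f"L0 = {L0} brackets no lattice site")
    x = np.arange(i_minus, i_plus + 1) * dx
    if F0 == 0.0:
        occ = np.zeros_like(x, dtype=float)
    else:
        steady = steady_profile_uniform(L0, F0, params)
        occ = dx * steady.n_profile(x)
    return NetworkState(
        t=0.0, i_minus=i_minus, i_plus=i_plus, occupancy=occ,
        b_minus=-half, b_plus=half,
    )


def step_occupancies(
    state: NetworkState, production: np.ndarray, params: ModelParams
) -> NetworkState:
    """One molecule-transport update (returns a new state at t + dt).

    N_i(t+dt) = q_right*N_{i-1} + q_left*N_{i+1} + q_stay*N_i + R_i*dt, with
    out-of-range neighbours contributing zero; the fractions jumping past
    the extreme osteocytes are added to the cumulative outgoing counters.
    The previous counters are retained so the flux of this step can be read
    with :func:`boundary_fluxes`.
    """
    N = state.occupancy
    production = np.asarray(production, dtype=float)
    if production.shape != N.shape:
        raise ValueError("production must have one rate per osteocyte")
    ql, qs, qr, dt = params.q_left, params.q_stay, params.q_right, params.dt

    new = qs * N + production * dt
    new[1:] += qr * N[:-1]
    new[:-1] += ql * N[1:]
    if np.any(new < 0.0):
        logger.warning("negative occupancy clamped to zero at t=%g", state.t)
        new = np.maximum(new, 0.0)

    out = state.copy()
    out.occupancy = new
    out.t = state.t + dt
    out.n_steps = state.n_steps + 1
    out.last_out_minus = state.cum_out_minus
    out.last_out_plus = state.cum_out_plus
    out.cum_out_minus = state.cum_out_minus + ql * N[0]
    out.cum_out_plus = state.cum_out_plus + qr * N[-1]
    return out


def boundary_fluxes(state: NetworkState, params: ModelParams) -> tuple[float, float]:
    """Outgoing fluxes (J_minus, J_plus) of the last completed step, /day.

    Includes molecules absorbed by jumps and molecules freed by osteocyte
    resorption credited to the counters within the same step.
    """
    if state.n_steps == 0:
        raise ValueError("boundary fluxes undefined before the first step")
    dt = params.dt
    return (
        (state.cum_out_minus - state.last_out_minus) / dt,
        (state.cum_out_plus - state.last_out_plus) / dt,
    )


def apply_boundary_motion_events(
    state: NetworkState, new_b_minus: float, new_b_plus: float, params: ModelParams
) -> tuple[NetworkState, list[TopologyEvent]]:
    """Move the boundaries and create/remove osteocytes as required.

    Right side: a boundary advanced strictly beyond x_{i_plus} + dx creates
    an osteocyte at the next lattice site with zero molecules; a boundary at
    or past x_{i_plus} (ties included) removes the extreme osteocyte and
    credits its molecules to the outgoing counter.  The left side mirrors
    this.  Rules are re-applied until no condition holds.  If the network
    empties (or the boundaries cross), total resorption is signalled by
    returning a state with ``i_plus < i_minus``; this is a terminal state,
    not an error.
    """
    dx = params.dx
    out = state.copy()
    out.b_minus = new_b_minus
    out.b_plus = new_b_plus
    events: list[TopologyEvent] = []
    occ = list(out.occupancy)

    if new_b_minus >= new_b_plus:
        out.cum_out_minus += sum(occ)
        occ = []
        out.i_plus = out.i_minus - 1
        out.occupancy = np.array(occ)
        return out, events

    changed = True
    while changed and occ:
        changed = False
        if new_b_plus > (out.i_plus + 1) * dx:
            out.i_plus += 1
            occ.append(0.0)
            events.append(TopologyEvent(CREATED, RIGHT, out.i_plus, 0.0, out.t))
            changed = True
        elif new_b_plus <= out.i_plus * dx:
            freed = occ.pop()
            out.cum_out_plus += freed
            events.append(TopologyEvent(REMOVED, RIGHT, out.i_plus, freed, out.t))
            out.i_plus -= 1
            changed = True
        if not occ:
            break
        if new_b_minus < (out.i_minus - 1) * dx:
            out.i_minus -= 1
            occ.insert(0, 0.0)
            events.append(TopologyEvent(CREATED, LEFT, out.i_minus, 0.0, out.t))
            changed = True
        elif new_b_minus >= out.i_minus * dx:
            freed = occ.pop(0)
            out.cum_out_minus += freed
            events.append(TopologyEvent(REMOVED, LEFT, out.i_minus, freed, out.t))
            out.i_minus += 1
            changed = True

    out.occupancy = np.array(occ, dtype=float)
    return out, events
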