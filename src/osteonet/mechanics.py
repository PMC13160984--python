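"""Loading protocols, mechanical stress/strain-energy, and molecule production.

The slice is loaded by a compressive force that is piecewise constant in time
and affine in space, F(x, t) = F_base(t) + F_x(t) * x.  Stress is force per
cross-sectional area, sigma = F / (L W) with L the current wall width and W
the lateral osteocyte spacing; the strain energy density follows from Hooke's
law, Psi = sigma^2 / (2E).

Osteocytes produce signalling molecules at a rate proportional to their
mechanical stimulus (stress or strain energy density, normalised by its
reference value) minus first-order degradation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .parameters import MPA_PER_N_PER_UM2, ModelParams

__all__ = [
    "Epoch",
    "LoadingProtocol",
    "MechanicalStimulus",
    "evaluate_force",
    "stress",
    "strain_energy_density",
    "production_rate",
]


@dataclass(frozen=True)
class Epoch:
    """One constant-in-time loading epoch: F(x) = F_base + F_x * x from t_start on."""

    t_start: float  # day
    F_base: float   # N
    F_x: float = 0.0  # N/um


@dataclass(frozen=True)
class LoadingProtocol:
    """Piecewise-constant-in-time, affine-in-space force field.

    Epochs must start at t=0 and have strictly increasing start times; the
    last epoch is open-ended.  A new epoch's force applies from its start
    time inclusive.
    """

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        if self.epochs[0].t_start != 0.0:
            raise ValueError("first epoch must start at t = 0")
        starts = [e.t_start for e in self.epochs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")

    @classmethod
    def constant(cls, F_base: float, F_x: float = 0.0) -> "LoadingProtocol":
        return cls((Epoch(0.0, F_base, F_x),))

    @classmethod
    def from_steps(cls, steps: Sequence[tuple[float, float] | tuple[float, float, float]]) -> "LoadingProtocol":
        """Build from (t_start, F_base[, F_x]) records."""
        return cls(tuple(Epoch(*s) for s in steps))

    @classmethod
    def from_json(cls, path: str | Path) -> "LoadingProtocol":
        records = json.loads(Path(path).read_text())
        return cls(tuple(Epoch(r["t_start"], r["F_base"], r.get("F_x", 0.0)) for r in records))

    def to_records(self) -> list[dict[str, float]]:
        return [{"t_start": e.t_start, "F_base": e.F_base, "F_x": e.F_x} for e in self.epochs]

    def epoch_at(self, t: float) -> Epoch:
        if t < 0.0:
            raise ValueError("t must be >= 0")
        current = self.epochs[0]
        for epoch in self.epochs[1:]:
            if t >= epoch.t_start:
                current = epoch
            else:
                break
        return current

    def force(self, x: float, t: float) -> float:
        return evaluate_force(self, x, t)


@dataclass(frozen=True)
class MechanicalStimulus:
    """Stress sigma (MPa), strain energy density psi (MPa), strain (dimensionless)."""

    sigma: float
    psi: float
    strain: float


def evaluate_force(protocol: LoadingProtocol, x: float, t: float) -> float:
    """Applied force F(x, t) in N.

    The epoch switching convention is inclusive of the new epoch's start
    time.  Negative forces are rejected: the model is compression-only and
    its behaviour under tension is undefined.
    """
    epoch = protocol.epoch_at(t)
    F = epoch.F_base + epoch.F_x * x
    if F < 0.0:
        raise ValueError(f"negative force F({x}, {t}) = {F}; compression-only model")
    return F


def stress(F: float, b_minus: float, b_plus: float, W: float) -> float:
    """Stress sigma = F / (L W) in MPa, with L = b_plus - b_minus in um.

    The wall width uses the continuous boundary positions, not the lattice
    registration of the extreme osteocytes.
    """
    L = b_plus - b_minus
    if L <= 0.0:
        raise ValueError("degenerate bone: b_plus must exceed b_minus")
    if W <= 0.0:
        raise ValueError("lateral width W must be > 0")
    return F / (L * W) * MPA_PER_N_PER_UM2


def strain_energy_density(sigma: float, E: float) -> MechanicalStimulus:
    """Strain energy density Psi = sigma^2/(2E) and strain eps = sigma/E."""
    if E <= 0.0:
        raise ValueError("Young's modulus E must be > 0")
    return MechanicalStimulus(sigma=sigma, psi=sigma**2 / (2.0 * E), strain=sigma / E)


def production_rate(
    stimulus: MechanicalStimulus, N: float | np.ndarray, params: ModelParams
) -> float | np.ndarray:
    """Molecule production rate R at occupancy N, molecules/day.

    R = lambda1 * (stimulus / reference stimulus) - lambda2 * N, where the
    stimulus is the stress (mode ``"stress"``) or the strain energy density
    (mode ``"sed"``), per ``params.stimulus_mode``.
    """
    if params.stimulus_mode == "stress":
        if params.sigma_ref <= 0.0:
            raise ValueError("reference stress sigma_ref is unset")
        drive = stimulus.sigma / params.sigma_ref
    elif params.stimulus_mode == "sed":
        if params.psi_ref <= 0.0:
            raise ValueError("reference strain energy density psi_ref is unset")
        drive = stimulus.psi / params.psi_ref
    else:  # pragma: no cover - guarded by validate_params
        raise ValueError(f"unknown stimulus mode {params.stimulus_mode!r}")
    return params.lambda1 * drive - params.lambda2 * N
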