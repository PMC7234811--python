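"""Map species trajectories to stopped-flow fluorescence intensities.

The instantaneous intensity is the equilibrium-normalised weighted sum of the
two complex species,

    FI(t) = (c [P*I*](t) + c* [(PI)*](t)) / (c [P*I*]_eq + c* [(PI)*]_eq) * SC + Baseline

where c and c* are FRET-efficiency weights of the encounter and rearranged
complex, SC is an instrument scaling factor and Baseline the basal
fluorescence.  The (c, c*) pair is only identifiable up to a common scale, so
fits conventionally pin c = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateEquilibriumError, InvalidStateError
from .kinetics import SpeciesState, SpeciesTrajectory

__all__ = ["FretCalibration", "intensity", "normalized_complex_signal"]


@dataclass(frozen=True)
class FretCalibration:
    """FRET weights and instrument parameters of one transient."""

    c: float = 1.0
    c_star: float = 1.0
    sc: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.c < 0 or self.c_star < 0 or (self.c == 0 and self.c_star == 0):
            raise InvalidStateError("c, c_star must be >= 0 and not both 0")
        if not (math.isfinite(self.sc) and math.isfinite(self.baseline)):
            raise InvalidStateError("SC and Baseline must be finite")

    def to_dict(self) -> dict[str, float]:
        return {"c": self.c, "c_star": self.c_star,
                "sc": self.sc, "baseline": self.baseline}

    @classmethod
    def from_dict(cls, d: dict) -> "FretCalibration":
        return cls(c=float(d.get("c", 1.0)), c_star=float(d["c_star"]),
                   sc=float(d.get("sc", 1.0)), baseline=float(d.get("baseline", 0.0)))


def normalized_complex_signal(
    enc: np.ndarray, final: np.ndarray, eq_state: SpeciesState, c: float, c_star: float
) -> np.ndarray:
    """(c enc + c* final) / (c enc_eq + c* final_eq) — the unitless part of FI."""
    denom = c * eq_state.enc + c_star * eq_state.final
    if denom <= 0:
        raise DegenerateEquilibriumError(
            "no complex present at equilibrium (c*enc_eq + c_star*final_eq = 0); "
            "check kb > 0 and that both totals are nonzero"
        )
    return (c * np.asarray(enc) + c_star * np.asarray(final)) / denom


def intensity(
    traj: SpeciesTrajectory, eq_state: SpeciesState, calib: FretCalibration
) -> np.ndarray:
    """Fluorescence intensity time series for a trajectory.

    ``eq_state`` must be the algebraic equilibrium for the same rates and
    totals as ``traj`` (see :func:`kinbind.kinetics.equilibrium`); the
    normalisation is taken from the model, not from the trace's plateau.
    """
    norm = normalized_complex_signal(
        traj["enc"], traj["final"], eq_state, calib.c, calib.c_star
    )
    return norm * calib.sc + calib.baseline
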