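"""Five-species kinetic model of coupled conformational selection and induced fit.

The reaction scheme couples a pre-binding conformational equilibrium of the free,
disordered inhibitor with a two-step binding pathway to the nucleotide-saturated
kinase::

    I  <=[k1 / k_minus1]=>  I*                    (conformational selection)
    P* + I*  <=[kb / k_minusb]=>  P*I*            (encounter complex)
    P*I*  <=[kr / k_minusr]=>  (PI)*              (induced-fit rearrangement)

The kinase exists only in its active, nucleotide-bound form P*; the apo/intermediate
equilibrium of the enzyme is deliberately outside the model.  Internal units are
molar and seconds everywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (
    AbsorbingStateWarning,
    DegenerateEquilibriumError,
    InvalidStateError,
    NumericalInstabilityError,
    SolverError,
)

__all__ = [
    "RateConstants",
    "SpeciesState",
    "MixingCondition",
    "SpeciesTrajectory",
    "derivative",
    "jacobian",
    "simulate",
    "equilibrium",
]

_SPECIES = ("P_star", "I", "I_star", "enc", "final")


@dataclass(frozen=True)
class RateConstants:
    """The six rate constants of the binding scheme.

    Parameters
    ----------
    k1, k_minus1 : float
        Forward/reverse first-order rates (s^-1) of the free-inhibitor
        conformational exchange I <-> I*.
    kb : float
        Second-order association rate (M^-1 s^-1) of P* + I* -> P*I*.
    k_minusb : float
        First-order dissociation rate (s^-1) of the encounter complex.
    kr, k_minusr : float
        Forward/reverse first-order rates (s^-1) of the rearrangement
        P*I* <-> (PI)*.
    """

    k1: float
    k_minus1: float
    kb: float
    k_minusb: float
    kr: float
    k_minusr: float

    def __post_init__(self) -> None:
        for name, value in self.to_dict().items():
            if not math.isfinite(value) or value < 0:
                raise InvalidStateError(
                    f"rate constant {name}={value!r} must be finite and >= 0"
                )

    def to_dict(self) -> dict[str, float]:
        return {
            "k1": self.k1,
            "k_minus1": self.k_minus1,
            "kb": self.kb,
            "k_minusb": self.k_minusb,
            "kr": self.kr,
            "k_minusr": self.k_minusr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateConstants":
        return cls(**{k: float(d[k]) for k in
                      ("k1", "k_minus1", "kb", "k_minusb", "kr", "k_minusr")})

    @property
    def competent_fraction(self) -> float:
        """Equilibrium fraction of free inhibitor in the binding-competent
        conformation, k1/(k1 + k_minus1); 0 when both rates vanish."""
        s = self.k1 + self.k_minus1
        return self.k1 / s if s > 0 else 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.k1, self.k_minus1, self.kb, self.k_minusb, self.kr, self.k_minusr]
        )


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (M) of the five species at one instant."""

    P_star: float
    I: float
    I_star: float
    enc: float
    final: float

    def as_array(self) -> np.ndarray:
        return np.array([self.P_star, self.I, self.I_star, self.enc, self.final])

    @classmethod
    def from_array(cls, a) -> "SpeciesState":
        return cls(*(float(x) for x in a))

    @property
    def P_total(self) -> float:
        return self.P_star + self.enc + self.final

    @property
    def I_total(self) -> float:
        return self.I + self.I_star + self.enc + self.final


@dataclass(frozen=True)
class MixingCondition:
    """Initial condition of a stopped-flow mixing experiment.

    ``pre_equilibrated=True`` partitions the free inhibitor between I and I*
    at the k1/k_minus1 equilibrium (the inhibitor equilibrates in the syringe
    before mixing); ``False`` places all of it in I.  Mixing starts the
    reaction, so the complexes are always zero initially.
    """

    P_total: float
    I_total: float
    pre_equilibrated: bool = True

    def __post_init__(self) -> None:
        if self.P_total < 0 or self.I_total < 0:
            raise InvalidStateError("total concentrations must be >= 0")
        if self.P_total == 0 and self.I_total == 0:
            raise InvalidStateError("at least one of P_total, I_total must be > 0")

    def initial_state(self, rates: RateConstants) -> SpeciesState:
        phi = rates.competent_fraction if self.pre_equilibrated else 0.0
        return SpeciesState(
            P_star=self.P_total,
            I=(1.0 - phi) * self.I_total,
            I_star=phi * self.I_total,
            enc=0.0,
            final=0.0,
        )


@dataclass
class SpeciesTrajectory:
    """Time-resolved concentrations of the five species.

    ``states`` is an (n_times, 5) array in the order
    (P*, I, I*, P*I*, (PI)*).
    """

    time: np.ndarray
    states: np.ndarray
    rates: RateConstants
    mixing: MixingCondition

    species = _SPECIES

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, _SPECIES.index(name)]

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState.from_array(self.states[i])

    @property
    def P_total(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 3] + self.states[:, 4]

    @property
    def I_total(self) -> np.ndarray:
        return self.states[:, 1:].sum(axis=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "P_star_M": self["P_star"],
                "I_M": self["I"],
                "I_star_M": self["I_star"],
                "enc_M": self["enc"],
                "final_M": self["final"],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None, logx: bool = False):
        """Plot all species concentrations versus time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = ("[P*]", "[I]", "[I*]", "[P*I*]", "[(PI)*]")
        for j, lab in enumerate(labels):
            ax.plot(self.time, self.states[:, j], label=lab)
        if logx:
            ax.set_xscale("log")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("concentration (M)")
        ax.legend()
        return ax


def derivative(state: SpeciesState, rates: RateConstants) -> np.ndarray:
    """Mass-action time derivatives (M/s) of the five species.

    Returns d/dt of (P*, I, I*, P*I*, (PI)*).  The two conservation sums
    (P* + enc + final and I + I* + enc + final) have derivative zero by
    construction.
    """
    y = state.as_array() if isinstance(state, SpeciesState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise InvalidStateError(f"non-finite species state {y!r}")
    p, i, istar, enc, fin = y
    r = rates
    bind = r.kb * p * istar - r.k_minusb * enc
    conv = r.k1 * i - r.k_minus1 * istar
    rearr = r.kr * enc - r.k_minusr * fin
    return np.array([-bind, -conv, conv - bind, bind - rearr, rearr])


def jacobian(state, rates: RateConstants) -> np.ndarray:
    """Analytic Jacobian of :func:`derivative` with respect to the species."""
    y = state.as_array() if isinstance(state, SpeciesState) else np.asarray(state, float)
    p, i, istar, enc, fin = y
    r = rates
    J = np.zeros((5, 5))
    # d(bind)/d(p, istar, enc)
    db_dp, db_di, db_de = r.kb * istar, r.kb * p, -r.k_minusb
    J[0] = [-db_dp, 0.0, -db_di, -db_de, 0.0]
    J[1] = [0.0, -r.k1, r.k_minus1, 0.0, 0.0]
    J[2] = [-db_dp, r.k1, -r.k_minus1 - db_di, -db_de, 0.0]
    J[3] = [db_dp, 0.0, db_di, db_de - r.kr, r.k_minusr]
    J[4] = [0.0, 0.0, 0.0, r.kr, -r.k_minusr]
    return J


def simulate(
    rates: RateConstants,
    mixing: MixingCondition,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-13,
    method: str = "LSODA",
    engine: str = "scipy",
) -> SpeciesTrajectory:
    """Integrate the kinetic scheme on a time grid starting at 0.

    The system is stiff for realistic parameter sets (rates span ~0.5 to
    ~3x10^4 s^-1), so the default integrator is implicit (LSODA with the
    analytic Jacobian).  ``engine="fast"`` dispatches to the package's
    compiled Rosenbrock(2,3) stepper used inside the global fit.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or t_grid[0] != 0.0:
        raise InvalidStateError("t_grid must be 1-D, start at 0 and have >= 2 points")
    if np.any(np.diff(t_grid) <= 0):
        raise InvalidStateError("t_grid must be strictly increasing")

    y0 = mixing.initial_state(rates).as_array()

    if engine == "fast":
        from ._fast_ode import integrate_reduced

        states, ok = integrate_reduced(
            rates.as_array(), mixing.P_total, mixing.I_total,
            y0, t_grid, rtol, atol,
        )
        if not ok:
            raise SolverError("Rosenbrock(2,3) stepper failed (step size underflow)")
    else:
        sol = solve_ivp(
            lambda t, y: derivative(y, rates),
            (t_grid[0], t_grid[-1]),
            y0,
            method=method,
            t_eval=t_grid,
            jac=lambda t, y: jacobian(y, rates),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(f"ODE integration failed: {sol.message}")
        states = sol.y.T

    floor = -10.0 * max(atol, 1e-300)
    if states.min() < floor:
        raise NumericalInstabilityError(
            f"negative concentration {states.min():.3e} M beyond tolerance {floor:.1e}"
        )
    return SpeciesTrajectory(time=t_grid, states=states, rates=rates, mixing=mixing)


def equilibrium(rates: RateConstants, P_total: float, I_total: float) -> SpeciesState:
    """Algebraic equilibrium of the scheme under both conservation laws.

    At equilibrium I*/I = k1/k_minus1, enc = (kb/k_minusb) P* I*, and
    final = (kr/k_minusr) enc, which reduces to a single quadratic in the
    total bound concentration B = enc + final.
    """
    r = rates
    if P_total < 0 or I_total < 0:
        raise InvalidStateError("totals must be >= 0")
    if r.k1 + r.k_minus1 <= 0:
        raise InvalidStateError("k1 + k_minus1 must be > 0 to define the free partition")
    phi = r.competent_fraction

    def _free(I_free_total: float) -> tuple[float, float]:
        return (1.0 - phi) * I_free_total, phi * I_free_total

    if P_total == 0 or I_total == 0:
        i, istar = _free(I_total)
        return SpeciesState(P_total, i, istar, 0.0, 0.0)

    if r.kb == 0 or r.k_minusb == 0:
        raise DegenerateEquilibriumError(
            "kb and k_minusb must both be > 0 for a finite, non-trivial equilibrium"
        )

    if r.kr > 0 and r.k_minusr == 0:
        warnings.warn(
            "k_minusr = 0 with kr > 0: (PI)* is absorbing; "
            "all bindable material ends in the rearranged complex",
            AbsorbingStateWarning,
            stacklevel=2,
        )
        B = min(P_total, I_total)
        i, istar = _free(I_total - B)
        return SpeciesState(P_total - B, i, istar, 0.0, B)

    Kr = r.kr / r.k_minusr if r.k_minusr > 0 else 0.0
    alpha = (r.kb / r.k_minusb) * (1.0 + Kr) * phi
    if alpha == 0:  # no binding-competent inhibitor at equilibrium
        i, istar = _free(I_total)
        return SpeciesState(P_total, i, istar, 0.0, 0.0)

    # alpha B^2 - (alpha (P+I) + 1) B + alpha P I = 0, physical root is the smaller one
    b = alpha * (P_total + I_total) + 1.0
    disc = b * b - 4.0 * alpha * alpha * P_total * I_total
    B = (b - math.sqrt(max(disc, 0.0))) / (2.0 * alpha)
    B = min(B, P_total, I_total)
    enc = B / (1.0 + Kr)
    fin = B - enc
    i, istar = _free(I_total - B)
    return SpeciesState(P_total - B, i, istar, enc, fin)
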