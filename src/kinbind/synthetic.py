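"""Synthetic inputs with known ground truth for every stage of the pipeline.

Three generators, all pure functions of (parameters, seed):

* :func:`generate_titration` — stopped-flow FRET titrations produced by the
  kinetic scheme plus the observation model, with additive Gaussian noise.
  The default designs mirror the experiments: the labelled kinase fixed at
  100 nM with the inhibitor titrated up to 250-fold excess, or the
  double-labelled inhibitor fixed at 100 nM with unlabelled kinase titrated
  up to 800-fold excess.
* :func:`generate_peak_table` — residue-wise NMR peak intensities built from
  mono-exponential decays with known NOE / R2 / Rex / PRE-Gamma2 ground truth.
* :func:`generate_discrete_trajectories` — Markov-chain state sequences from
  a known transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidStateError
from .fret import FretCalibration, intensity
from .kinetics import MixingCondition, RateConstants, equilibrium, simulate

__all__ = [
    "TitrationDesign",
    "TitrationSeries",
    "NmrAcquisition",
    "SyntheticPeakTable",
    "generate_titration",
    "generate_peak_table",
    "generate_discrete_trajectories",
    "KINASE_FIXED_MULTIPLES",
    "INHIBITOR_FIXED_MULTIPLES",
]

#: Default fold-excess grids, log-spaced over the titration ranges of the two
#: experimental designs (0–250x inhibitor over fixed kinase; 0–800x kinase
#: over the fixed double-labelled inhibitor), with a zero-titrant control.
KINASE_FIXED_MULTIPLES = (0.0, 1.0, 2.5, 6.3, 16.0, 40.0, 100.0, 250.0)
INHIBITOR_FIXED_MULTIPLES = (0.0, 2.0, 8.0, 25.0, 80.0, 250.0, 800.0)


@dataclass(frozen=True)
class TitrationDesign:
    """Design of one stopped-flow titration series.

    ``noise_sigma`` is the Gaussian noise standard deviation expressed as a
    fraction of the scale factor SC (i.e. of the equilibrium amplitude of the
    normalised signal).  ``dead_time`` seconds are discarded from the front of
    every trace, emulating the mixing dead time of the instrument.
    """

    seed: int
    fixed_species: str = "kinase"  # which partner is held at fixed_conc
    fixed_conc: float = 1e-7
    titrant_multiples: tuple = KINASE_FIXED_MULTIPLES
    scheme: str = "ACCEPTOR-3"
    duration: float = 5.0
    sample_rate: float = 1000.0
    dead_time: float = 1.5e-3
    noise_sigma: float = 0.01
    pre_equilibrated: bool = True

    def __post_init__(self) -> None:
        if self.fixed_species not in ("kinase", "inhibitor"):
            raise InvalidStateError("fixed_species must be 'kinase' or 'inhibitor'")
        if min(self.titrant_multiples) < 0:
            raise InvalidStateError("titrant multiples must be >= 0")
        if not self.duration > self.dead_time:
            raise InvalidStateError("duration must exceed dead_time")
        if self.sample_rate <= 0:
            raise InvalidStateError("sample_rate must be > 0")

    def totals(self, multiple: float) -> tuple[float, float]:
        """(P_total, I_total) in M for one titrant multiple."""
        titrant = multiple * self.fixed_conc
        if self.fixed_species == "kinase":
            return self.fixed_conc, titrant
        return titrant, self.fixed_conc


@dataclass
class TitrationSeries:
    """A set of fluorescence transients sharing one post-dead-time grid."""

    design: TitrationDesign
    time: np.ndarray                 # post-dead-time grid, s
    concentrations: np.ndarray       # titrant concentration per transient, M
    transients: list                 # one intensity array per concentration
    flags: list                      # None or 'no-binding' per transient
    truth: dict = field(default_factory=dict)  # {'rates': ..., 'calib': ...}

    def __len__(self) -> int:
        return len(self.transients)

    def usable(self):
        """(concentration, trace) pairs that carry a binding signal."""
        return [
            (c, y)
            for c, y, f in zip(self.concentrations, self.transients, self.flags)
            if f is None
        ]

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c, y in zip(self.concentrations, self.transients):
            ax.plot(self.time, y, lw=0.8, label=f"{c * 1e6:.2g} uM")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("fluorescence (a.u.)")
        ax.legend(fontsize=7)
        return ax


def generate_titration(
    rates: RateConstants, calib: FretCalibration, design: TitrationDesign,
    rtol: float = 1e-8, atol: float = 1e-13,
) -> TitrationSeries:
    """Simulate a full titration series with additive Gaussian noise.

    Every transient is intensity(simulate(...)) evaluated on the shared
    post-dead-time grid plus i.i.d. noise of sigma = noise_sigma * SC; the
    zero-titrant control (no complex can form) is emitted as a flat
    Baseline-only trace flagged ``'no-binding'``.  Identical seeds give
    bit-identical output.
    """
    dt = 1.0 / design.sample_rate
    full_grid = np.arange(0.0, design.duration + 0.5 * dt, dt)
    observed = full_grid >= design.dead_time - 1e-12
    time = full_grid[observed]

    rng = np.random.default_rng(design.seed)
    sigma = design.noise_sigma * abs(calib.sc)

    concentrations, transients, flags = [], [], []
    for m in design.titrant_multiples:
        P_total, I_total = design.totals(m)
        concentrations.append(m * design.fixed_conc)
        if P_total == 0 or I_total == 0:
            y = np.full(time.shape, calib.baseline)
            flags.append("no-binding")
        else:
            mix = MixingCondition(P_total, I_total,
                                  pre_equilibrated=design.pre_equilibrated)
            traj = simulate(rates, mix, full_grid, rtol=rtol, atol=atol)
            eq = equilibrium(rates, P_total, I_total)
            fi = intensity(traj, eq, calib)
            y = fi[observed].copy()
            flags.append(None)
        if sigma > 0:
            y = y + rng.normal(0.0, sigma, size=y.shape)
        transients.append(y)

    return TitrationSeries(
        design=design,
        time=time,
        concentrations=np.asarray(concentrations),
        transients=transients,
        flags=flags,
        truth={"rates": rates, "calib": calib},
    )


# ---------------------------------------------------------------------------
# NMR peak tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NmrAcquisition:
    """Acquisition parameters for the synthetic peak tables.

    Delays follow the two-time-point PRE scheme (4 and 14 ms) and a total
    CPMG time of 40 ms with refocusing frequencies of 0, 12.5 and 1000 Hz.
    ``noise_rms`` is the absolute spectral root-mean-square noise on a peak
    of reference intensity ``i0``.
    """

    i0: float = 1.0
    noise_rms: float = 0.0
    pre_ta: float = 0.004
    pre_tb: float = 0.014
    cpmg_time: float = 0.040
    nu_cpmg: tuple = (0.0, 12.5, 1000.0)
    max_retries: int = 10


@dataclass
class SyntheticPeakTable:
    """Long-format peak-intensity table plus the ground truth used to build it."""

    table: pd.DataFrame
    truth: pd.DataFrame
    acquisition: NmrAcquisition


def _noisy(rng, value, sigma, retries):
    """Sample value + noise, resampling negatives up to a retry cap.

    Returns (intensity, detectable).  A peak whose true intensity lies below
    the spectral noise floor, or that cannot be drawn positive within the
    retry cap, is reported undetectable — emulating resonances broadened
    beyond detection.
    """
    if sigma == 0:
        return value, value > 0
    if value < sigma:  # signal-to-noise < 1: indistinguishable from noise
        return np.nan, False
    for _ in range(retries):
        x = value + rng.normal(0.0, sigma)
        if x > 0:
            return x, True
    return np.nan, False


def generate_peak_table(
    truth: pd.DataFrame, acquisition: NmrAcquisition = NmrAcquisition(), *, seed: int
) -> SyntheticPeakTable:
    """Build residue-wise peak intensities from known relaxation ground truth.

    ``truth`` must have columns ``residue, noe, r2_dia, gamma2, rex``.  Peak
    intensities follow I(T) = I0 exp(-R T) with the channel-appropriate rate
    (Gamma2 adds to R for the paramagnetic rows; Rex adds for the low
    refocusing-frequency CPMG rows), plus Gaussian spectral noise.
    """
    req = {"residue", "noe", "r2_dia", "gamma2", "rex"}
    if not req.issubset(truth.columns):
        raise InvalidStateError(f"truth table needs columns {sorted(req)}")
    if acquisition.pre_tb <= acquisition.pre_ta or acquisition.pre_ta <= 0:
        raise InvalidStateError("PRE delays must satisfy Tb > Ta > 0")

    rng = np.random.default_rng(seed)
    acq = acquisition
    rows = []

    def emit(residue, channel, delay, nu, clean):
        val, ok = _noisy(rng, clean, acq.noise_rms, acq.max_retries)
        rows.append(
            {
                "residue": residue,
                "channel": channel,
                "delay_s": delay,
                "nu_cpmg_hz": nu,
                "intensity": val,
                "noise_rms": acq.noise_rms,
                "flag": None if ok else "undetectable",
            }
        )

    for rec in truth.itertuples(index=False):
        i0 = acq.i0
        # heteronuclear NOE pair
        emit(rec.residue, "unsat", np.nan, np.nan, i0)
        emit(rec.residue, "sat", np.nan, np.nan, i0 * rec.noe)
        # CPMG reference and relaxation-period intensities
        emit(rec.residue, "cpmg_ref", 0.0, np.nan, i0)
        for nu in acq.nu_cpmg:
            r = rec.r2_dia + (rec.rex if nu < 100.0 else 0.0)
            emit(rec.residue, "cpmg", acq.cpmg_time, nu,
                 i0 * np.exp(-r * acq.cpmg_time))
        # two-time-point PRE pairs
        for t in (acq.pre_ta, acq.pre_tb):
            emit(rec.residue, "dia", t, np.nan, i0 * np.exp(-rec.r2_dia * t))
            emit(rec.residue, "para", t, np.nan,
                 i0 * np.exp(-(rec.r2_dia + rec.gamma2) * t))

    return SyntheticPeakTable(
        table=pd.DataFrame(rows), truth=truth.copy(), acquisition=acq
    )


# ---------------------------------------------------------------------------
# Discrete Markov trajectories
# ---------------------------------------------------------------------------

def generate_discrete_trajectories(
    T: np.ndarray, n_traj: int, length: int, *, seed: int
) -> list:
    """Sample integer state sequences from a row-stochastic transition matrix.

    Initial states are drawn uniformly over the states; each subsequent state
    is drawn from the corresponding matrix row.  Empirical transition counts
    converge to ``T`` as ``length`` grows.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise InvalidStateError("transition matrix must be square")
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise InvalidStateError("transition matrix rows must be non-negative and sum to 1")

    n = T.shape[0]
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    trajs = []
    for _ in range(n_traj):
        s = np.empty(length, dtype=np.int64)
        s[0] = rng.integers(n)
        u = rng.random(length - 1)
        for t in range(1, length):
            s[t] = np.searchsorted(cum[s[t - 1]], u[t - 1], side="right")
        trajs.append(s)
    return trajs
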